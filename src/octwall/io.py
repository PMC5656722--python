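"""Reading and writing of frame stacks, contours, labels and reports.

Frame stacks are multi-page TIFFs or directories of single-frame
TIFF/PNG images with a sidecar YAML holding {geometry,
pixel_size_axial_um, n_frames}.  Contours and labels travel as plain CSV;
Cartesian polylines and evaluation reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .health_classifier import HealthLabels
from .multilayer_dp import LayerContours
from .polar_geometry import Frame, LumenContour

__all__ = ["read_stack", "write_stack", "read_lumen_csv", "write_lumen_csv",
           "contours_to_frame_df", "write_contours_csv", "read_contours_csv",
           "write_labels_csv", "read_labels_csv", "write_carpet_png",
           "write_polylines_json"]


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.max() > 1.0:
        info_max = 255.0 if img.max() <= 255 else 65535.0
        img = img / info_max
    return np.clip(img, 0.0, 1.0)


def write_stack(frames: list[Frame], path, manifest: dict | None = None) -> None:
    """Write frames as a multi-page TIFF plus a sidecar YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([(f.pixels * 65535).astype(np.uint16) for f in frames])
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"geometry": frames[0].geometry,
            "pixel_size_axial_um": frames[0].pixel_size_axial,
            "n_frames": len(frames)}
    if manifest:
        meta.update(manifest)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_stack(path) -> list[Frame]:
    """Read a multi-page TIFF (or directory of rasters) with sidecar YAML."""
    path = Path(path)
    if path.is_dir():
        meta_path = path / "stack.yaml"
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        pages = [iio.imread(p) for p in files]
    else:
        meta_path = path.with_suffix(".yaml")
        data = tifffile.imread(path)
        pages = list(data) if data.ndim == 3 else [data]
    if not meta_path.exists():
        raise FileNotFoundError(
            f"sidecar metadata {meta_path} not found: pixel_size_axial required")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if "pixel_size_axial_um" not in meta:
        raise KeyError("pixel_size_axial required in sidecar YAML")
    return [Frame(pixels=_normalize(p), geometry=meta.get("geometry", "polar"),
                  pixel_size_axial=float(meta["pixel_size_axial_um"]),
                  frame_index=i)
            for i, p in enumerate(pages)]


def write_lumen_csv(lumens: list[LumenContour], path) -> None:
    """One row per frame, columns = per-A-line lumen depth in pixels."""
    arr = np.stack([l.depth_per_aline for l in lumens])
    pd.DataFrame(arr).to_csv(path, index=False,
                             header=[f"a{i}" for i in range(arr.shape[1])])


def read_lumen_csv(path) -> list[LumenContour]:
    df = pd.read_csv(path)
    return [LumenContour(row.to_numpy(dtype=float)) for _, row in df.iterrows()]


def contours_to_frame_df(contours: LayerContours, frame_index: int
                         ) -> pd.DataFrame:
    ps = contours.pixel_size_axial
    return pd.DataFrame({
        "frame_index": frame_index,
        "column": np.arange(contours.n_angles),
        "y1_px": contours.y1, "y2_px": contours.y2, "y3_px": contours.y3,
        "y1_um": contours.y1 * ps, "y2_um": contours.y2 * ps,
        "y3_um": contours.y3 * ps,
    })


def write_contours_csv(per_frame: list[LayerContours], path) -> None:
    df = pd.concat([contours_to_frame_df(c, i)
                    for i, c in enumerate(per_frame)], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.6g")


def read_contours_csv(path, pixel_size_axial: float) -> list[LayerContours]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("frame_index", sort=True):
        out.append(LayerContours(
            y1=grp["y1_px"].to_numpy(), y2=grp["y2_px"].to_numpy(),
            y3=grp["y3_px"].to_numpy(), n_angles=len(grp),
            pixel_size_axial=pixel_size_axial))
    return out


def write_polylines_json(polylines: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: np.asarray(v).tolist() for k, v in polylines.items()},
                  fh)


def write_labels_csv(per_frame: list[HealthLabels], path) -> None:
    rows = []
    for lab in per_frame:
        for c, v in enumerate(lab.labels):
            rows.append((lab.frame_index, c, "NA" if v == -1 else int(v)))
    pd.DataFrame(rows, columns=["frame_index", "column", "label"]).to_csv(
        path, index=False)


def read_labels_csv(path) -> list[HealthLabels]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for fi, grp in df.groupby("frame_index", sort=True):
        lab = np.array([-1 if v == "NA" else int(v) for v in grp["label"]])
        out.append(HealthLabels(labels=lab, frame_index=int(fi)))
    return out


def write_carpet_png(per_frame: list[HealthLabels], path) -> None:
    """Angle-by-frame carpet map: healthy green, diseased red, guidewire grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    grid = np.stack([lab.labels for lab in per_frame], axis=1)  # angle x frame
    cmap = ListedColormap(["0.6", "#c03030", "#30a040"])
    fig, ax = plt.subplots(figsize=(max(4, grid.shape[1] / 10), 4))
    ax.imshow(grid + 1, cmap=cmap, vmin=0, vmax=2, aspect="auto",
              origin="lower", interpolation="nearest")
    ax.set_xlabel("frame")
    ax.set_ylabel("angular column")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
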