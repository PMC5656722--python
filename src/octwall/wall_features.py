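"""Per-A-line features of the wall region R.

For each column of the sub-image a region ``R`` spans from the luminal
interface (row 0) down to 300 um below the detected AP contour.  From the
intensity profile, the gradient profile, and the tentative contours, 17
features are computed; the first eight (texture statistics, interface
gradients and the profile-shape indices) were confirmed relevant by the
feature-selection study and form the default classifier input:

  1. contrast (GLCM)            2. MSE of a degree-1 linear fit
  3. homogeneity (GLCM)         4. gradient at the MA interface
  5. correlation (GLCM)         6. gradient at the IM interface
  7. gradient at the LI interface (row 0)
  8. monotony index: median |i - i'| over the stable descending sort
  9. sum of negative gradients          10. entropy (GLCM)
 11. median intensity, media           12. energy (GLCM)
 13. median intensity, adventitia     14. median intensity, intima
 15-17. LI-IM, LI-AP, LI-MA distances (um)

GLCM statistics use the Haralick definitions on a 16-level symmetric,
normalised co-occurrence matrix with a one-pixel offset along depth (a
column is one-dimensional, so depth is the only well-defined direction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FEATURE_NAMES", "RELEVANT_FEATURES", "RegionR",
           "extract_region", "compute_features", "compute_feature_matrix",
           "normalize_features", "glcm_matrix", "glcm_features",
           "monotony_index"]

FEATURE_NAMES = [
    "contrast", "mse_linear_fit", "homogeneity", "gradient_at_MA",
    "correlation", "gradient_at_IM", "gradient_at_LI", "monotony_index",
    "sum_negative_gradients", "entropy", "median_intensity_media", "energy",
    "median_intensity_adventitia", "median_intensity_intima",
    "dist_LI_IM", "dist_LI_AP", "dist_LI_MA",
]
RELEVANT_FEATURES = FEATURE_NAMES[:8]


@dataclass
class RegionR:
    """One column's analysis region: lumen to 300 um below the AP contour."""

    intensity: np.ndarray
    gradient: np.ndarray
    y1: float
    y2: float
    y3: float
    pixel_size_axial: float
    clamped: bool = False
    excluded: bool = False  # guidewire column

    def __post_init__(self) -> None:
        if len(self.intensity) == 0:
            raise ValueError("region must be nonempty")
        if len(self.intensity) <= self.y3:
            raise ValueError("region must extend below the AP contour")


def extract_region(sub, contours, margin_um: float = 300.0) -> list[RegionR]:
    """Per-column region vectors, clamped (and flagged) at the image bottom."""
    from .cost_maps import gradient_image
    I_G = gradient_image(sub)
    return extract_region_from(sub, I_G, contours, margin_um)


def extract_region_from(sub, I_G: np.ndarray, contours,
                        margin_um: float = 300.0) -> list[RegionR]:
    margin_px = int(np.ceil(margin_um / sub.pixel_size_axial))
    regions = []
    for c in range(sub.n_angles):
        y3 = int(round(contours.y3[c]))
        end = y3 + margin_px  # last row is the point ~300 um below the AP
        clamped = end > sub.depth_px
        end = min(end, sub.depth_px)
        regions.append(RegionR(
            intensity=sub.I[:end, c].copy(),
            gradient=I_G[:end, c].copy(),
            y1=float(contours.y1[c]), y2=float(contours.y2[c]), y3=float(y3),
            pixel_size_axial=sub.pixel_size_axial,
            clamped=clamped, excluded=bool(sub.guidewire_mask[c])))
    return regions


# ---------------------------------------------------------------------------
# texture and profile statistics
# ---------------------------------------------------------------------------

def glcm_matrix(x: np.ndarray, levels: int = 16) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix of a 1D profile.

    Intensities are quantised to ``levels`` bins over the fixed [0, 1]
    dynamic range; co-occurring pairs are taken at offset 1 along depth.
    """
    q = np.clip((np.asarray(x, dtype=float) * levels).astype(int), 0,
                levels - 1)
    counts = np.zeros((levels, levels))
    if len(q) > 1:
        np.add.at(counts, (q[:-1], q[1:]), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """Haralick contrast, homogeneity, correlation, entropy and energy."""
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(np.sum(p * (i - j) ** 2))
    homogeneity = float(np.sum(p / (1.0 + (i - j) ** 2)))
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = np.sum(np.arange(levels) * pi), np.sum(np.arange(levels) * pj)
    var_i = np.sum((np.arange(levels) - mu_i) ** 2 * pi)
    var_j = np.sum((np.arange(levels) - mu_j) ** 2 * pj)
    if var_i > 1e-15 and var_j > 1e-15:
        correlation = float(np.sum(p * (i - mu_i) * (j - mu_j))
                            / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0  # zero-variance region: defined as 0
        logger.debug("degenerate region: GLCM correlation set to 0")
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz))) if nz.size else 0.0
    energy = float(np.sqrt(np.sum(p ** 2)))
    return {"contrast": contrast, "homogeneity": homogeneity,
            "correlation": correlation, "entropy": entropy, "energy": energy}


def monotony_index(x: np.ndarray) -> float:
    """Median displacement needed to sort the profile in descending order.

    ``i'`` is each sample's index after a stable descending sort (ties keep
    original order); the index is the median of ``|i - i'|``.  Zero for an
    already monotonically decreasing profile, and invariant to any strictly
    increasing rescaling of the intensities.
    """
    x = np.asarray(x, dtype=float)
    order = np.argsort(-x, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(x))
    return float(np.median(np.abs(np.arange(len(x)) - inv)))


def _mse_linear_fit(x: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return 0.0
    t = np.arange(n, dtype=float)
    coef = np.polyfit(t, x, 1)
    resid = x - np.polyval(coef, t)
    return float(np.mean(resid ** 2))


def _median_between(x: np.ndarray, lo: float, hi: float) -> float:
    a, b = int(round(lo)), int(round(hi))
    a = max(0, min(a, len(x) - 1))
    b = max(a + 1, min(b, len(x)))
    return float(np.median(x[a:b]))


def compute_features(region: RegionR) -> np.ndarray:
    """The 17 features of one region, in canonical order."""
    x, g = region.intensity, region.gradient
    ps = region.pixel_size_axial
    y1 = int(np.clip(round(region.y1), 0, len(g) - 1))
    y2 = int(np.clip(round(region.y2), 0, len(g) - 1))
    tex = glcm_features(glcm_matrix(x))
    vals = {
        "contrast": tex["contrast"],
        "mse_linear_fit": _mse_linear_fit(x),
        "homogeneity": tex["homogeneity"],
        "gradient_at_MA": float(g[y2]),
        "correlation": tex["correlation"],
        "gradient_at_IM": float(g[y1]),
        "gradient_at_LI": float(g[0]),
        "monotony_index": monotony_index(x),
        "sum_negative_gradients": float(np.sum(np.minimum(g, 0.0))),
        "entropy": tex["entropy"],
        "median_intensity_media": _median_between(x, region.y1, region.y2),
        "energy": tex["energy"],
        "median_intensity_adventitia": _median_between(x, region.y2,
                                                       region.y3),
        "median_intensity_intima": _median_between(x, 0, region.y1),
        "dist_LI_IM": region.y1 * ps,
        "dist_LI_AP": region.y3 * ps,
        "dist_LI_MA": region.y2 * ps,
    }
    out = np.array([vals[name] for name in FEATURE_NAMES])
    if not np.all(np.isfinite(out)):
        raise AssertionError("non-finite feature value")
    return out


def compute_feature_matrix(sub, costs, contours,
                           margin_um: float = 300.0) -> pd.DataFrame:
    """All 17 features for every column of one frame.

    The gradient profile comes from the frame's unreplicated gradient
    image; guidewire columns are computed but flagged ``excluded`` so they
    can be dropped from training and evaluation.
    """
    regions = extract_region_from(sub, costs.I_G, contours, margin_um)
    rows = [compute_features(r) for r in regions]
    df = pd.DataFrame(rows, columns=FEATURE_NAMES)
    df.insert(0, "column", np.arange(sub.n_angles))
    df["excluded"] = [r.excluded for r in regions]
    df["clamped"] = [r.clamped for r in regions]
    return df


def normalize_features(df: pd.DataFrame,
                       stats: dict[str, tuple[float, float]] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Per-feature min-max normalisation to [0, 1].

    In training mode (``stats is None``) the ranges come from the data; in
    inference mode the supplied training ranges are used and values outside
    them are clipped.  A zero-range feature maps to 0.5 with a warning.
    """
    out = df.copy()
    if stats is None:
        stats = {name: (float(df[name].min()), float(df[name].max()))
                 for name in FEATURE_NAMES}
    for name in FEATURE_NAMES:
        lo, hi = stats[name]
        if hi - lo < 1e-12:
            logger.warning("constant feature %r: normalised to 0.5", name)
            out[name] = 0.5
        else:
            out[name] = np.clip((df[name] - lo) / (hi - lo), 0.0, 1.0)
    return out, stats
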