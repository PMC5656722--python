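"""Agreement metrics for contours and healthy-region labels.

Contours are compared point-to-point along the rays crossing the lumen
center (one ray per angular column), in micrometres.  Layer thicknesses
(intima: LI to IM, media: IM to MA, adventitia: MA to AP) are compared
with absolute error, signed bias and 95% limits of agreement.  Healthy-arc
agreement uses the Dice coefficient D = 2|A n B| / (|A| + |B|) on angular
columns, and the accuracy / sensitivity / specificity of the per-column
confusion counts with healthy as the positive class.  Guidewire-masked
columns are excluded everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "point_distance_error", "thickness_error", "dice",
           "confusion_metrics"]

INTERFACES = ("IM", "MA", "AP")
LAYERS = ("intima", "media", "adventitia")


@dataclass
class EvalReport:
    contour_error_um: dict = field(default_factory=dict)
    thickness: dict = field(default_factory=dict)
    dice: float | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "contour_error_um": self.contour_error_um,
            "thickness": self.thickness,
            "dice": self.dice, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "counts": self.counts,
        }


def _valid_columns(auto, ref, ref_mask):
    n = auto.n_angles
    if ref.n_angles != n:
        raise ValueError("contour sets must share n_angles")
    valid = np.ones(n, dtype=bool) if ref_mask is None else \
        np.asarray(ref_mask, dtype=bool)
    if not valid.any():
        raise ValueError("no comparable columns")
    return valid


def point_distance_error(auto, ref, ref_mask=None) -> dict[str, dict]:
    """Per-interface |y_auto - y_ref| * pixel size, mean +- SD in um.

    ``ref_mask`` restricts the comparison to an annotated arc; columns
    outside it are skipped.
    """
    valid = _valid_columns(auto, ref, ref_mask)
    ps = auto.pixel_size_axial
    out = {}
    for name, ya, yr in zip(INTERFACES, (auto.y1, auto.y2, auto.y3),
                            (ref.y1, ref.y2, ref.y3)):
        err = np.abs(np.asarray(ya, float) - np.asarray(yr, float))[valid] * ps
        out[name] = {"mean_um": float(err.mean()), "sd_um": float(err.std()),
                     "n": int(valid.sum())}
    return out


def thickness_error(auto, ref, ref_mask=None) -> dict[str, dict]:
    """Per-layer thickness agreement: absolute error, bias, 95% LoA, relative.

    Relative error compares the absolute thickness error to the reference
    thickness of the same layer; columns with zero reference thickness are
    excluded from the relative statistic (their count is reported).
    """
    valid = _valid_columns(auto, ref, ref_mask)
    ps = auto.pixel_size_axial

    def layers(c):
        y1, y2, y3 = (np.asarray(y, float) for y in (c.y1, c.y2, c.y3))
        return {"intima": y1, "media": y2 - y1, "adventitia": y3 - y2}

    ta, tr = layers(auto), layers(ref)
    out = {}
    for name in LAYERS:
        d = (ta[name] - tr[name])[valid] * ps
        ref_um = tr[name][valid] * ps
        bias = float(d.mean())
        sd = float(d.std())
        nz = ref_um > 0
        if not nz.all():
            logger.info("thickness_error: %d zero-reference columns "
                        "excluded from relative error", int((~nz).sum()))
        rel = np.abs(d[nz]) / ref_um[nz] if nz.any() else np.array([])
        out[name] = {
            "abs_mean_um": float(np.abs(d).mean()),
            "abs_sd_um": float(np.abs(d).std()),
            "bias_um": bias,
            "loa_um": (bias - 1.96 * sd, bias + 1.96 * sd),
            "rel_mean": float(rel.mean()) if rel.size else float("nan"),
            "n_zero_ref": int((~nz).sum()),
        }
    return out


def dice(region_a, region_b) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) on angular column sets.

    Two empty regions are identical by convention, giving 1 (logged).
    """
    a = set(np.asarray(list(region_a), dtype=int).tolist())
    b = set(np.asarray(list(region_b), dtype=int).tolist())
    if not a and not b:
        logger.debug("dice: both regions empty, defined as 1")
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def confusion_metrics(auto, ref) -> dict:
    """Accuracy, sensitivity and specificity of per-column labels.

    Healthy (1) is the positive class; masked columns (label -1 in either
    input) are excluded.  A metric with a zero denominator is reported as
    NaN while the counts stay intact.
    """
    a = np.asarray(getattr(auto, "labels", auto), dtype=int)
    r = np.asarray(getattr(ref, "labels", ref), dtype=int)
    if a.shape != r.shape:
        raise ValueError("label arrays must have the same shape")
    keep = (a != -1) & (r != -1)
    a, r = a[keep], r[keep]
    tp = int(np.sum((a == 1) & (r == 1)))
    tn = int(np.sum((a == 0) & (r == 0)))
    fp = int(np.sum((a == 1) & (r == 0)))
    fn = int(np.sum((a == 0) & (r == 1)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "TP": tp, "TN": tn, "FP": fp, "FN": fn,
    }
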