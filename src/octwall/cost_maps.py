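"""Gradient image and front-propagation cost maps.

The anatomical interfaces of the arterial wall live at depth positions of
extremum axial intensity gradient: strongly positive (dark-to-bright with
increasing depth) at the media-adventitia interface, strongly negative at
the intima-media and adventitia-periadventitia interfaces.  The gradient
image ``I_G`` is obtained by convolving each A-line (column) of the polar
sub-image with the first derivative of a Gaussian.  It is replicated three
times horizontally (``I'''_G = [I_G, I_G, I_G]``) so that keeping the
central third of any optimal path yields closed contours, and the pair of
positive cost functions is

    C+ = N_[0,1](+I'''_G)        C- = N_[0,1](-I'''_G)

with ``N_[0,1]`` a min-max normalisation.  Minima of ``C+`` mark candidate
IM/AP points, minima of ``C-`` candidate MA points, and the two maps are
exact complements (``C+ + C- = 1``) because they are normalised over the
same global range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

logger = logging.getLogger(__name__)

__all__ = ["CostMaps", "gradient_image", "replicate", "build_costs",
           "compute_cost_maps", "gaussian_derivative_kernel"]


@dataclass
class CostMaps:
    I_G: np.ndarray
    I_G_rep: np.ndarray
    C_plus: np.ndarray
    C_minus: np.ndarray
    sigma_um: float
    sigma_px: float


def gaussian_derivative_kernel(sigma_px: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled first-derivative-of-Gaussian correlation kernel.

    The analytic derivative is sampled at integer offsets in
    ``[-truncate*sigma, +truncate*sigma]`` and corrected to sum to zero so
    a constant signal maps exactly to zero response.  The returned kernel
    is oriented for correlation: positive response on dark-to-bright
    transitions with increasing depth.
    """
    radius = max(1, int(np.ceil(truncate * sigma_px)))
    t = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (t / sigma_px) ** 2) / (sigma_px * np.sqrt(2 * np.pi))
    k = t / sigma_px ** 2 * g
    k -= k.mean()
    return k


def gradient_image(sub, sigma_um: float = 30.0) -> np.ndarray:
    """Column-wise derivative-of-Gaussian filtering of the sub-image.

    ``sigma_um`` is converted to pixels with the axial pixel size; depth
    boundaries use reflect padding, which avoids a spurious edge response
    at row 0 (the luminal interface).
    """
    if sigma_um <= 0:
        raise ValueError("sigma_um must be > 0")
    sigma_px = sigma_um / sub.pixel_size_axial
    if sigma_px < 0.5:
        raise ValueError("sigma below resolution: sigma_px = "
                         f"{sigma_px:.3f} < 0.5")
    k = gaussian_derivative_kernel(sigma_px)
    return correlate1d(np.asarray(sub.I, dtype=float), k, axis=0,
                       mode="reflect")


def replicate(I_G: np.ndarray) -> np.ndarray:
    """Triple horizontal replication ``[I_G, I_G, I_G]``."""
    return np.concatenate([I_G, I_G, I_G], axis=1)


def build_costs(I_G_rep: np.ndarray,
                eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalised cost pair over the replicated gradient image.

    Normalisation is global (one shared range for both signs), which makes
    the maps exact complements and preserves relative edge strength across
    columns.  A constant gradient image is degenerate: both maps are set to
    0.5 and a warning is logged.
    """
    lo, hi = float(I_G_rep.min()), float(I_G_rep.max())
    if hi - lo < eps:
        logger.warning("degenerate frame: constant gradient image, "
                       "costs set to 0.5")
        half = np.full_like(I_G_rep, 0.5, dtype=float)
        return half, half.copy()
    c_plus = (I_G_rep - lo) / (hi - lo)
    return c_plus, 1.0 - c_plus


def compute_cost_maps(sub, sigma_um: float = 30.0) -> CostMaps:
    """Gradient image, replication, cost pair, and guidewire handling.

    Columns shadowed by the guidewire carry no edge information; their
    costs are replaced by the row-wise mean cost of the unmasked columns so
    the optimal path interpolates smoothly through the shadow.
    """
    I_G = gradient_image(sub, sigma_um=sigma_um)
    I_G_rep = replicate(I_G)
    c_plus, c_minus = build_costs(I_G_rep)
    mask = getattr(sub, "guidewire_mask", None)
    if mask is not None and np.any(mask) and not np.all(mask):
        rep_mask = np.tile(np.asarray(mask, dtype=bool), 3)
        for c in (c_plus, c_minus):
            fill = c[:, ~rep_mask].mean(axis=1)
            c[:, rep_mask] = fill[:, None]
    return CostMaps(I_G=I_G, I_G_rep=I_G_rep, C_plus=c_plus, C_minus=c_minus,
                    sigma_um=sigma_um,
                    sigma_px=sigma_um / sub.pixel_size_axial)
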