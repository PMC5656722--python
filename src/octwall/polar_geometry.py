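"""Frames, lumen detection, guidewire masking, and the polar sub-image.

An intravascular OCT frame in polar form is a depth-by-angle intensity
matrix: each column is one A-line acquired along a ray from the imaging
catheter.  All downstream processing happens in a lumen-referenced
*sub-image* ``I``: the circumference is divided into ``n_angles`` (default
100) equiangular steps, and for each step the radial intensity profile is
sampled from the luminal interface down to a depth of 1 mm.  Row 0 of the
sub-image is therefore the lumen-intima interface, flattened to a
horizontal line.

The lumen contour itself is extracted with a single-contour version of the
same dynamic-programming machinery used for the wall layers (minimal-cost
path on the negated axial gradient, closed via triple replication); a
pre-computed lumen contour may be supplied instead.  The guidewire casts a
dark angular shadow over the wall, detected as a contiguous dark band in
the pullback-averaged intensity profile and masked from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .cost_maps import gaussian_derivative_kernel
from .multilayer_dp import single_contour_dp

__all__ = [
    "Frame", "LumenContour", "PolarSubImage", "LumenNotFoundError",
    "segment_lumen", "detect_guidewire", "build_subimage",
    "map_contours_to_cartesian", "pullback_intensity_profile",
    "polar_to_cartesian", "cartesian_to_polar",
]


class LumenNotFoundError(RuntimeError):
    """No lumen edge could be detected in the frame."""


@dataclass
class Frame:
    """A single OCT cross-section.

    ``pixels`` are intensities normalised to [0, 1]; ``geometry`` is
    ``"polar"`` (rows = depth along the catheter ray, columns = A-lines
    uniformly covering 360 degrees) or ``"cartesian"``.
    """

    pixels: np.ndarray
    geometry: str = "polar"
    pixel_size_axial: float = 8.8  # um / pixel
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")
        if self.pixel_size_axial <= 0:
            raise ValueError("pixel_size_axial must be > 0")
        if self.geometry not in ("polar", "cartesian"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_alines(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LumenContour:
    """Lumen boundary depth (pixels, fractional allowed) per native A-line."""

    depth_per_aline: np.ndarray

    def __post_init__(self) -> None:
        self.depth_per_aline = np.asarray(self.depth_per_aline, dtype=float)

    def __len__(self) -> int:
        return len(self.depth_per_aline)

    def interp(self, aline: np.ndarray) -> np.ndarray:
        """Circular linear interpolation at fractional A-line positions."""
        n = len(self.depth_per_aline)
        a = np.mod(aline, n)
        i0 = np.floor(a).astype(int) % n
        i1 = (i0 + 1) % n
        frac = a - np.floor(a)
        d = self.depth_per_aline
        return (1 - frac) * d[i0] + frac * d[i1]


@dataclass
class PolarSubImage:
    """Lumen-flattened depth-by-angle intensity matrix (the sub-image I)."""

    I: np.ndarray
    n_angles: int
    depth_px: int
    pixel_size_axial: float
    guidewire_mask: np.ndarray
    lumen_ref: dict = field(default_factory=dict)
    quality_mask: np.ndarray | None = None  # columns clamped at image bottom

    def __post_init__(self) -> None:
        if self.I.shape != (self.depth_px, self.n_angles):
            raise ValueError("sub-image shape mismatch")
        if len(self.guidewire_mask) != self.n_angles:
            raise ValueError("guidewire mask length mismatch")
        if self.depth_px * self.pixel_size_axial < 1000.0 - 1e-9:
            raise ValueError("sub-image must cover at least 1 mm of depth")

    @property
    def angles(self) -> np.ndarray:
        """Angle (radians) of each column; column 0 at the +x axis."""
        return np.arange(self.n_angles) * 2 * np.pi / self.n_angles


def segment_lumen(frame: Frame, sigma_px: float = 3.0,
                  kappa: float = 0.1, N: int = 3,
                  intensity_floor: float = 0.05) -> LumenContour:
    """Lumen boundary as the minimal-cost path on the negated axial gradient.

    The lumen-to-tissue transition is a rising edge with depth, so the
    strongest positive axial gradient marks the boundary.  The gradient
    image is negated and min-max normalised into a cost map, replicated
    three times horizontally, traversed by a smoothness-penalised
    single-contour DP, and the central replica is kept (closed contour).
    """
    if frame.geometry != "polar":
        raise ValueError("segment_lumen expects a polar-geometry frame")
    img = frame.pixels
    if img.max() < intensity_floor:
        raise LumenNotFoundError("no lumen detected: all-dark frame")
    k = gaussian_derivative_kernel(sigma_px)
    from scipy.ndimage import correlate1d
    grad = correlate1d(img, k, axis=0, mode="reflect")
    rng = grad.max() - grad.min()
    if rng < 1e-9:
        raise LumenNotFoundError("no lumen detected: no axial edge present")
    cost = (grad.max() - grad) / rng  # minima at strongest rising edges
    W = img.shape[1]
    cost_rep = np.concatenate([cost, cost, cost], axis=1)
    path, _ = single_contour_dp(cost_rep, kappa=kappa, N=N)
    return LumenContour(depth_per_aline=path[W:2 * W].astype(float))


def pullback_intensity_profile(frames: list[Frame]) -> np.ndarray:
    """Mean intensity per A-line over all frames of a pullback."""
    return np.mean([f.pixels.mean(axis=0) for f in frames], axis=0)


def detect_guidewire(frame: Frame, lumen: LumenContour,
                     pullback_profile: np.ndarray,
                     threshold: float = 0.5,
                     min_run: int = 3) -> np.ndarray:
    """Guidewire shadow as a contiguous dark band of the averaged profile.

    A circular run of A-lines is "dark" when its pullback-averaged
    intensity falls below ``threshold`` times the median profile value and
    it is at least ``min_run`` columns long.  If several runs qualify the
    one with the darkest mean wins; ties go to the lower start index.
    Absence of a guidewire yields an all-false mask.
    """
    profile = np.asarray(pullback_profile, dtype=float)
    n = len(profile)
    if n != frame.n_alines:
        raise ValueError("profile length must equal the A-line count")
    dark = profile < threshold * np.median(profile)
    if not dark.any():
        return np.zeros(n, dtype=bool)
    if dark.all():
        return np.ones(n, dtype=bool)
    # circular runs: rotate so position 0 is not dark
    start0 = int(np.argmin(dark))
    rolled = np.roll(dark, -start0)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.view(np.int8), [0]])))
    runs = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_run:
            idx = (np.arange(s, e) + start0) % n
            runs.append((float(profile[idx].mean()), int(idx[0]), idx))
    if not runs:
        return np.zeros(n, dtype=bool)
    runs.sort(key=lambda r: (r[0], r[1]))
    mask = np.zeros(n, dtype=bool)
    mask[runs[0][2]] = True
    return mask


def build_subimage(frame: Frame, lumen: LumenContour,
                   gw_mask: np.ndarray | None = None,
                   n_angles: int = 100,
                   depth_um: float = 1000.0) -> PolarSubImage:
    """Sample the lumen-referenced sub-image I from a polar frame.

    Column ``c`` covers the half-open angular arc starting at
    ``c * 360 / n_angles`` degrees (column 0 at the +x axis) and holds the
    radial profile from the lumen boundary down to ``depth_um``, resampled
    with bilinear interpolation; ``depth_px = ceil(depth_um / pixel_size)``
    so the sub-image always covers at least the requested depth.  Profiles
    reaching past the bottom of the frame are edge-padded and flagged in
    the quality mask.
    """
    if frame.geometry != "polar":
        raise ValueError("build_subimage expects a polar frame; convert "
                         "Cartesian input with cartesian_to_polar first")
    if n_angles < 8:
        raise ValueError("n_angles must be >= 8")
    if len(lumen) != frame.n_alines:
        raise ValueError("lumen contour length must equal the A-line count")
    img = frame.pixels
    n_rows, n_alines = img.shape
    depth_px = int(np.ceil(depth_um / frame.pixel_size_axial))

    a_c = np.arange(n_angles) * n_alines / n_angles  # fractional A-line
    lum_c = lumen.interp(a_c)
    rows = lum_c[None, :] + np.arange(depth_px)[:, None]
    cols = np.broadcast_to(a_c[None, :], rows.shape)
    # circular in angle: pad one wrapped column; edge padding in depth
    padded = np.concatenate([img, img[:, :1]], axis=1)
    I = map_coordinates(padded, [rows, cols], order=1, mode="nearest")

    quality = lum_c + depth_px - 1 > n_rows - 1
    if gw_mask is None:
        gw_cols = np.zeros(n_angles, dtype=bool)
    else:
        nearest = np.round(a_c).astype(int) % n_alines
        gw_cols = np.asarray(gw_mask, dtype=bool)[nearest]
    return PolarSubImage(
        I=np.clip(I, 0.0, 1.0), n_angles=n_angles, depth_px=depth_px,
        pixel_size_axial=frame.pixel_size_axial,
        guidewire_mask=gw_cols,
        lumen_ref={"lumen": lumen, "center": (0.0, 0.0),
                   "radius_px": lum_c, "n_alines": n_alines},
        quality_mask=quality)


def map_contours_to_cartesian(contours, sub: PolarSubImage
                              ) -> dict[str, np.ndarray]:
    """Map sub-image contours back to closed Cartesian polylines.

    Point ``k`` of interface ``n`` lies at
    ``center + (lumen_radius(theta_k) + y_n(k)) * (cos theta_k, sin theta_k)``
    in frame pixel units (the radial and axial pixel sizes coincide for the
    supported scanners).  The first point is appended last so each polyline
    is closed.
    """
    cx, cy = sub.lumen_ref.get("center", (0.0, 0.0))
    r_lum = np.asarray(sub.lumen_ref["radius_px"], dtype=float)
    theta = sub.angles
    out = {}
    for name, y in (("IM", contours.y1), ("MA", contours.y2),
                    ("AP", contours.y3)):
        r = r_lum + np.asarray(y, dtype=float)
        pts = np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)
        out[name] = np.vstack([pts, pts[:1]])
    return out


def polar_to_cartesian(frame: Frame, size: int | None = None) -> Frame:
    """Render a polar frame onto a Cartesian grid centred on the catheter."""
    if frame.geometry != "polar":
        raise ValueError("expects a polar frame")
    n_rows, n_alines = frame.pixels.shape
    if size is None:
        size = 2 * n_rows + 1
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    a = theta / (2 * np.pi) * n_alines
    padded = np.concatenate([frame.pixels, frame.pixels[:, :1]], axis=1)
    out = map_coordinates(padded, [r, a], order=1, mode="constant", cval=0.0)
    out[r > n_rows - 1] = 0.0
    return Frame(pixels=np.clip(out, 0, 1), geometry="cartesian",
                 pixel_size_axial=frame.pixel_size_axial,
                 frame_index=frame.frame_index)


def cartesian_to_polar(frame: Frame, n_alines: int = 360,
                       n_rows: int | None = None,
                       center: tuple[float, float] | None = None) -> Frame:
    """Resample a Cartesian frame onto catheter-centred polar rays."""
    if frame.geometry != "cartesian":
        raise ValueError("expects a cartesian frame")
    h, w_ = frame.pixels.shape
    if center is None:
        center = ((w_ - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center
    if n_rows is None:
        n_rows = int(min(cx, cy, w_ - 1 - cx, h - 1 - cy))
    theta = np.arange(n_alines) * 2 * np.pi / n_alines
    r = np.arange(n_rows, dtype=float)
    xx = cx + r[:, None] * np.cos(theta)[None, :]
    yy = cy + r[:, None] * np.sin(theta)[None, :]
    out = map_coordinates(frame.pixels, [yy, xx], order=1, mode="nearest")
    return Frame(pixels=np.clip(out, 0, 1), geometry="polar",
                 pixel_size_axial=frame.pixel_size_axial,
                 frame_index=frame.frame_index)
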