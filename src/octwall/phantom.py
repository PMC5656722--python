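"""Synthetic OCT-like pullbacks with known wall geometry and labels.

The generator emulates the appearance that drives the segmentation and
classification pipeline: a lumen-centred vessel wall whose healthy arcs
show the characteristic bright / dark / bright triple layer (intima,
media, adventitia) over decaying periadventitial tissue, diseased arcs
rendered as a single bright attenuating slab with no layering (only the
thickened intima is visible, the deeper layers being lost to limited
signal penetration), multiplicative speckle, and a dark guidewire shadow
sector.  Ground-truth lumen and layer contours and per-column
healthy/diseased labels are recorded before noise is applied, so every
stage of the pipeline can be validated without clinical data.

Two scanner presets mirror common polar geometries: ``terumo``
(512 x 512, 8.8 um/px) and ``sjm`` (968 x 504, 4.5 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .multilayer_dp import LayerContours
from .polar_geometry import Frame, LumenContour

__all__ = ["PhantomSpec", "GroundTruth", "generate_frame",
           "generate_pullback", "generate_cohort", "PRESETS"]

PRESETS = {
    "terumo": {"n_rows": 512, "n_alines": 512, "pixel_size_axial": 8.8},
    "sjm": {"n_rows": 968, "n_alines": 504, "pixel_size_axial": 4.5},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions of a synthetic pullback.

    Layer thicknesses default to the reference scale of healthy coronary
    walls (intima 130 um, media 95 um, adventitia 105 um); the healthy-arc
    rule (all three layers present, intima + media thickness < 500 um) is
    enforced as an invariant.  ``healthy_arcs`` lists half-open native
    A-line intervals per frame; ``None`` means fully healthy frames.
    """

    n_frames: int = 10
    n_rows: int = 512
    n_alines: int = 512
    pixel_size_axial: float = 8.8
    lumen_radius_um: float = 1600.0
    lumen_harmonic_um: float = 80.0
    lumen_harmonic_order: int = 2
    lumen_phase: float = 0.0
    intima_um: float = 130.0
    media_um: float = 95.0
    adventitia_um: float = 105.0
    thickness_variation: float = 0.08  # relative smooth angular modulation
    intensity_lumen: float = 0.04
    intensity_intima: float = 0.78
    intensity_media: float = 0.22
    intensity_adventitia: float = 0.66
    intensity_periadventitia: float = 0.45
    periadventitia_decay_um: float = 220.0
    plaque_intensity: float = 0.85
    plaque_attenuation_um: float = 260.0
    plaque_thickness_um: float = 700.0
    healthy_arcs: tuple | None = None  # per-frame tuples of (start, end)
    speckle_sigma: float = 0.2
    guidewire_center: int | None = 60
    guidewire_width: int = 24
    longitudinal_drift: float = 0.02  # relative frame-to-frame drift
    seed: int = 0

    def __post_init__(self) -> None:
        for t in (self.intima_um, self.media_um, self.adventitia_um):
            if t <= 0:
                raise ValueError("layer thicknesses must be > 0")
        if self.intima_um + self.media_um >= 500.0:
            raise ValueError("healthy wall must have intima+media < 500 um")
        if self.healthy_arcs is not None:
            for frame_arcs in self.healthy_arcs:
                for s, e in frame_arcs:
                    if not (0 <= s < e <= self.n_alines):
                        raise ValueError("arcs must lie within [0, n_alines)")

    @classmethod
    def preset(cls, name: str, **kwargs) -> "PhantomSpec":
        return cls(**{**PRESETS[name], **kwargs})


@dataclass
class GroundTruth:
    """True geometry and labels of one generated frame."""

    lumen: LumenContour
    y1_px: np.ndarray  # native pixels below the lumen, per native A-line
    y2_px: np.ndarray
    y3_px: np.ndarray
    healthy_aline: np.ndarray  # bool per native A-line
    guidewire_aline: np.ndarray
    pixel_size_axial: float

    def layer_contours(self, n_angles: int = 100) -> LayerContours:
        """Ground-truth interfaces resampled at the sub-image columns."""
        n = len(self.y1_px)
        a = np.arange(n_angles) * n / n_angles

        def interp(y):
            return LumenContour(y).interp(a)

        return LayerContours(y1=interp(self.y1_px), y2=interp(self.y2_px),
                             y3=interp(self.y3_px), n_angles=n_angles,
                             pixel_size_axial=self.pixel_size_axial)

    def labels(self, n_angles: int = 100) -> np.ndarray:
        """Per-column labels: healthy=1, diseased=0, guidewire-masked=-1."""
        n = len(self.healthy_aline)
        nearest = np.round(np.arange(n_angles) * n / n_angles).astype(int) % n
        lab = self.healthy_aline[nearest].astype(int)
        lab[self.guidewire_aline[nearest]] = -1
        return lab


def _smooth_profile(rng: np.random.Generator, n: int, n_harmonics: int = 3
                    ) -> np.ndarray:
    """Zero-mean smooth circular modulation with unit maximum amplitude."""
    theta = np.arange(n) * 2 * np.pi / n
    prof = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        prof += rng.normal() / h * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    m = np.abs(prof).max()
    return prof / m if m > 0 else prof


def _frame_arcs_mask(spec: PhantomSpec, frame_index: int) -> np.ndarray:
    healthy = np.ones(spec.n_alines, dtype=bool)
    if spec.healthy_arcs is not None:
        healthy[:] = False
        for s, e in spec.healthy_arcs[frame_index]:
            healthy[int(s):int(e)] = True
    return healthy


def generate_frame(spec: PhantomSpec, frame_index: int,
                   rng: np.random.Generator
                   ) -> tuple[Frame, GroundTruth]:
    """Render one polar frame and its ground truth.

    The wall is rendered A-line by A-line from the true geometry; speckle
    (multiplicative gamma noise of mean 1 and variance ``sigma^2``) and the
    guidewire shadow are applied afterwards, so the recorded ground truth
    is exact.
    """
    ps = spec.pixel_size_axial
    n = spec.n_alines
    theta = np.arange(n) * 2 * np.pi / n
    drift = 1.0 + spec.longitudinal_drift * np.sin(
        2 * np.pi * frame_index / max(spec.n_frames, 2))
    r_lum = (spec.lumen_radius_um + spec.lumen_harmonic_um
             * np.cos(spec.lumen_harmonic_order * theta + spec.lumen_phase)
             ) * drift / ps
    mod = 1.0 + spec.thickness_variation * _smooth_profile(rng, n)
    t1 = spec.intima_um / ps * mod * drift
    t2 = spec.media_um / ps * mod * drift
    t3 = spec.adventitia_um / ps * mod * drift
    y1, y2, y3 = t1, t1 + t2, t1 + t2 + t3

    healthy = _frame_arcs_mask(spec, frame_index)
    rows = np.arange(spec.n_rows, dtype=float)[:, None]
    depth = rows - r_lum[None, :]  # native px below the lumen
    depth_um = depth * ps

    img = np.full((spec.n_rows, n), spec.intensity_lumen)
    # healthy template: bright / dark / bright / decaying tail
    h_img = np.select(
        [depth_um < 0,
         depth_um < y1[None, :] * ps,
         depth_um < y2[None, :] * ps,
         depth_um < y3[None, :] * ps],
        [spec.intensity_lumen, spec.intensity_intima, spec.intensity_media,
         spec.intensity_adventitia],
        default=0.0)
    tail = depth_um - y3[None, :] * ps
    peri = spec.intensity_periadventitia * np.exp(
        -np.maximum(tail, 0.0) / spec.periadventitia_decay_um)
    h_img = np.where(tail >= 0, peri, h_img)
    # diseased template: single attenuating slab, no layering
    slab = np.clip(depth_um, 0.0, None)
    d_img = np.where(
        (depth_um >= 0) & (depth_um < spec.plaque_thickness_um),
        spec.plaque_intensity * np.exp(-slab / spec.plaque_attenuation_um),
        spec.intensity_lumen)
    d_img = np.where(depth_um < 0, spec.intensity_lumen, d_img)
    img = np.where(healthy[None, :], h_img, d_img)

    if spec.speckle_sigma > 0:
        shape = 1.0 / spec.speckle_sigma ** 2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    gw = np.zeros(n, dtype=bool)
    if spec.guidewire_center is not None and spec.guidewire_width > 0:
        half = spec.guidewire_width // 2
        idx = (np.arange(spec.guidewire_center - half,
                         spec.guidewire_center - half + spec.guidewire_width)
               % n)
        gw[idx] = True
        img[:, gw] = np.where(depth[:, gw] >= 0, 0.0, img[:, gw])

    frame = Frame(pixels=np.clip(img, 0.0, 1.0), geometry="polar",
                  pixel_size_axial=ps, frame_index=frame_index)
    truth = GroundTruth(lumen=LumenContour(r_lum), y1_px=y1, y2_px=y2,
                        y3_px=y3, healthy_aline=healthy, guidewire_aline=gw,
                        pixel_size_axial=ps)
    return frame, truth


def generate_pullback(spec: PhantomSpec
                      ) -> tuple[list[Frame], list[GroundTruth], dict]:
    """Generate all frames of a pullback plus a manifest of the conditions."""
    rng = np.random.default_rng(spec.seed)
    frames, truths = [], []
    for k in range(spec.n_frames):
        f, t = generate_frame(spec, k, rng)
        frames.append(f)
        truths.append(t)
    manifest = {
        "n_frames": spec.n_frames, "geometry": "polar",
        "n_rows": spec.n_rows, "n_alines": spec.n_alines,
        "pixel_size_axial_um": spec.pixel_size_axial, "seed": spec.seed,
    }
    return frames, truths, manifest


def _draw_arcs(rng: np.random.Generator, spec: PhantomSpec
               ) -> tuple | None:
    """Per-pullback wall state: fully healthy, fully diseased, or partial.

    Partial pullbacks carry one healthy arc whose centre drifts slowly
    along the pullback, so adjacent-frame majority voting is meaningful.
    """
    u = rng.uniform()
    if u < 0.2:
        return None  # fully healthy
    n = spec.n_alines
    if u < 0.4:
        return tuple(() for _ in range(spec.n_frames))  # fully diseased
    frac = rng.uniform(0.3, 0.85)
    width = int(round(frac * n))
    center = rng.uniform(0, n)
    drift = rng.normal(0, 0.01 * n)
    arcs = []
    for k in range(spec.n_frames):
        c = center + k * drift
        s = int(np.floor(c - width / 2)) % n
        e = s + width
        if e <= n:
            arcs.append(((s, e),))
        else:
            arcs.append(((s, n), (0, e - n)))
    return tuple(arcs)


def generate_cohort(n_pullbacks: int, seed: int = 0,
                    base: PhantomSpec | None = None
                    ) -> list[tuple[list[Frame], list[GroundTruth], dict]]:
    """Independent pullbacks with randomised geometry, arcs and guidewire."""
    if base is None:
        base = PhantomSpec()
    master = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_pullbacks):
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(sub_seed)
        spec = replace(
            base,
            lumen_radius_um=base.lumen_radius_um * rng.uniform(0.85, 1.15),
            lumen_harmonic_um=base.lumen_harmonic_um * rng.uniform(0.5, 1.5),
            lumen_phase=rng.uniform(0, 2 * np.pi),
            intima_um=base.intima_um * rng.uniform(0.8, 1.2),
            media_um=base.media_um * rng.uniform(0.8, 1.2),
            adventitia_um=base.adventitia_um * rng.uniform(0.8, 1.2),
            healthy_arcs=_draw_arcs(rng, base),
            guidewire_center=int(rng.integers(0, base.n_alines)),
            seed=sub_seed)
        cohort.append(generate_pullback(spec))
    return cohort
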