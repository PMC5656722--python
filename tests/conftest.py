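import numpy as np
import pytest

from octwall.config import PipelineConfig
from octwall.cost_maps import CostMaps
from octwall.phantom import PhantomSpec, generate_pullback
from octwall.polar_geometry import (build_subimage, detect_guidewire,
                                    pullback_intensity_profile, segment_lumen)


def make_cost_maps(depth: int, n_cols: int, seed: int) -> CostMaps:
    """Random complementary cost pair for DP unit tests."""
    g = np.random.default_rng(seed).standard_normal((depth, n_cols))
    cp = (g - g.min()) / (g.max() - g.min())
    return CostMaps(I_G=g, I_G_rep=g, C_plus=cp, C_minus=1.0 - cp,
                    sigma_um=30.0, sigma_px=3.0)


def uniform_cost_maps(depth: int, n_cols: int, value: float) -> CostMaps:
    c = np.full((depth, n_cols), value)
    return CostMaps(I_G=c, I_G_rep=c, C_plus=c.copy(), C_minus=c.copy(),
                    sigma_um=30.0, sigma_px=3.0)


@pytest.fixture(scope="session")
def clean_pullback():
    """Noise-free, constant-thickness healthy pullback with a guidewire."""
    spec = PhantomSpec(n_frames=3, speckle_sigma=0.0, thickness_variation=0.0,
                       seed=7)
    frames, truths, _ = generate_pullback(spec)
    return frames, truths


@pytest.fixture(scope="session")
def segmented_frame(clean_pullback):
    """Frame 0 of the clean pullback pushed through the geometry stage."""
    from octwall.cost_maps import compute_cost_maps
    from octwall.multilayer_dp import segment_layers

    frames, truths = clean_pullback
    frame, truth = frames[0], truths[0]
    lumen = segment_lumen(frame)
    gw = detect_guidewire(frame, lumen, pullback_intensity_profile(frames))
    sub = build_subimage(frame, lumen, gw)
    contours = segment_layers(sub)
    costs = compute_cost_maps(sub)
    return {"frame": frame, "truth": truth, "lumen": lumen, "sub": sub,
            "contours": contours, "costs": costs}


@pytest.fixture()
def config():
    return PipelineConfig()
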