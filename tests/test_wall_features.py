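"""The 17 per-column features of region R."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.feature import graycomatrix, graycoprops

from octwall.multilayer_dp import LayerContours
from octwall.wall_features import (FEATURE_NAMES, RELEVANT_FEATURES, RegionR,
                                   compute_feature_matrix, compute_features,
                                   extract_region_from, glcm_features,
                                   glcm_matrix, monotony_index,
                                   normalize_features)


def region(intensity, gradient=None, y1=2.0, y2=5.0, y3=8.0, ps=8.8):
    intensity = np.asarray(intensity, dtype=float)
    if gradient is None:
        gradient = np.gradient(intensity)
    return RegionR(intensity=intensity, gradient=np.asarray(gradient),
                   y1=y1, y2=y2, y3=y3, pixel_size_axial=ps)


class TestRegionExtraction:
    class Sub:
        def __init__(self, depth, n_angles, ps):
            self.I = np.random.default_rng(0).uniform(0, 1, (depth, n_angles))
            self.depth_px, self.n_angles = depth, n_angles
            self.pixel_size_axial = ps
            self.guidewire_mask = np.zeros(n_angles, dtype=bool)
            self.guidewire_mask[-1] = True

    def contours(self, y3, n, ps, y1=10, y2=30):
        return LayerContours(y1=np.full(n, float(y1)),
                             y2=np.full(n, float(y2)),
                             y3=np.full(n, float(y3)), n_angles=n,
                             pixel_size_axial=ps)

    def test_margin_arithmetic_at_high_resolution(self):
        sub = self.Sub(depth=223, n_angles=4, ps=4.5)
        regs = extract_region_from(sub, np.zeros((223, 4)),
                                   self.contours(50, 4, 4.5))
        assert len(regs[0].intensity) == 117  # rows 0..116: 50 + ceil(300/4.5)
        assert not regs[0].clamped

    def test_region_clamped_and_flagged_at_image_bottom(self):
        sub = self.Sub(depth=100, n_angles=4, ps=8.8)
        regs = extract_region_from(sub, np.zeros((100, 4)),
                                   self.contours(90, 4, 8.8, y1=20, y2=50))
        assert regs[0].clamped
        assert len(regs[0].intensity) == 100

    def test_guidewire_column_flagged_excluded(self):
        sub = self.Sub(depth=100, n_angles=4, ps=8.8)
        regs = extract_region_from(sub, np.zeros((100, 4)),
                                   self.contours(40, 4, 8.8))
        assert regs[-1].excluded and not regs[0].excluded


class TestMonotonyIndex:
    def test_monotone_decreasing_profile_scores_zero(self):
        assert monotony_index([9, 7, 5, 3, 1]) == 0.0

    def test_printed_example(self):
        # [5,3,4,1] sorts to [5,4,3,1]: displacements [0,1,1,0]
        assert monotony_index([5, 3, 4, 1]) == 0.5

    def test_reversed_profile_is_maximally_displaced(self):
        n = 8
        idx = np.arange(n)
        expected = np.median(np.abs(idx - idx[::-1]))
        assert monotony_index(np.arange(n)) == expected

    @pytest.mark.parametrize("transform", [np.exp, np.cbrt,
                                           lambda x: 3 * x + 2])
    def test_invariant_to_strictly_monotone_rescaling(self, transform):
        x = np.random.default_rng(1).uniform(0, 1, 40)
        assert monotony_index(x) == monotony_index(transform(x))

    def test_stable_under_ties(self):
        # ties keep original order, so a constant profile is "sorted"
        assert monotony_index(np.ones(11)) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                    max_size=40))
    def test_bounded_and_zero_iff_descending(self, values):
        x = np.asarray(values)
        m = monotony_index(x)
        assert 0.0 <= m <= len(x) - 1
        if np.all(np.diff(x) <= 0):
            assert m == 0.0


class TestProfileFeatures:
    def test_linear_profile_has_zero_linear_fit_mse(self):
        f = compute_features(region(np.linspace(0.9, 0.1, 50)))
        assert f[FEATURE_NAMES.index("mse_linear_fit")] == pytest.approx(0.0,
                                                                         abs=1e-20)

    def test_nonnegative_gradient_sums_to_zero(self):
        f = compute_features(region(np.linspace(0.1, 0.9, 30),
                                    gradient=np.full(30, 0.2)))
        assert f[FEATURE_NAMES.index("sum_negative_gradients")] == 0.0

    def test_negative_gradient_sum_hand_example(self):
        g = np.array([0.5, -0.25, 0.0, -0.75, 1.0])
        f = compute_features(region(np.linspace(0.9, 0.1, 5), gradient=g,
                                    y1=1, y2=2, y3=3))
        assert f[FEATURE_NAMES.index("sum_negative_gradients")] == -1.0

    def test_interface_gradients_and_distances(self):
        g = np.arange(10, dtype=float) / 10
        f = compute_features(region(np.linspace(0.9, 0.1, 10), gradient=g,
                                    y1=2, y2=5, y3=8, ps=8.8))
        named = dict(zip(FEATURE_NAMES, f))
        assert named["gradient_at_LI"] == g[0]
        assert named["gradient_at_IM"] == g[2]
        assert named["gradient_at_MA"] == g[5]
        assert named["dist_LI_IM"] == pytest.approx(2 * 8.8)
        assert named["dist_LI_MA"] == pytest.approx(5 * 8.8)
        assert named["dist_LI_AP"] == pytest.approx(8 * 8.8)

    def test_median_intensities_between_interfaces(self):
        x = np.concatenate([np.full(3, 0.8), np.full(3, 0.2), np.full(3, 0.6),
                            np.full(3, 0.4)])
        f = compute_features(region(x, y1=3, y2=6, y3=9))
        named = dict(zip(FEATURE_NAMES, f))
        assert named["median_intensity_intima"] == 0.8
        assert named["median_intensity_media"] == 0.2
        assert named["median_intensity_adventitia"] == 0.6


class TestGLCM:
    def test_matrix_matches_skimage_on_toy_region(self):
        x = np.array([0.05, 0.3, 0.55, 0.8])  # quantises to 4 levels apart
        q = np.clip((x * 16).astype(int), 0, 15)
        ours = glcm_matrix(x)
        ref = graycomatrix(q[None, :].astype(np.uint8), [1], [0], levels=16,
                           symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours, ref)

    @pytest.mark.parametrize("seed", range(4))
    def test_features_match_skimage_reference(self, seed):
        x = np.random.default_rng(seed).uniform(0, 1, 60)
        q = np.clip((x * 16).astype(int), 0, 15)
        ours = glcm_features(glcm_matrix(x))
        G = graycomatrix(q[None, :].astype(np.uint8), [1], [0], levels=16,
                         symmetric=True, normed=True)
        for name in ("contrast", "homogeneity", "correlation", "energy"):
            assert ours[name] == pytest.approx(
                float(graycoprops(G, name)[0, 0]), rel=1e-10)
        # entropy against the direct Shannon formula on the same matrix
        p = G[:, :, 0, 0]
        expected = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert ours["entropy"] == pytest.approx(expected)

    def test_constant_region_correlation_defined_as_zero(self):
        f = glcm_features(glcm_matrix(np.full(20, 0.5)))
        assert f["correlation"] == 0.0
        assert f["contrast"] == 0.0


class TestNormalization:
    def frame(self, values):
        df = pd.DataFrame(0.5, index=range(len(values)),
                          columns=FEATURE_NAMES)
        df["contrast"] = values
        return df

    def test_midpoint_maps_to_half(self):
        df = self.frame([2.0, 4.0, 6.0])
        out, stats = normalize_features(df)
        assert out["contrast"].tolist() == [0.0, 0.5, 1.0]
        assert stats["contrast"] == (2.0, 6.0)

    def test_inference_values_outside_training_range_clip(self):
        _, stats = normalize_features(self.frame([2.0, 6.0]))
        out, _ = normalize_features(self.frame([8.0, 1.0]), stats)
        assert out["contrast"].tolist() == [1.0, 0.0]

    def test_constant_feature_maps_to_half_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="octwall.wall_features"):
            out, _ = normalize_features(self.frame([3.0, 3.0]))
        assert (out["contrast"] == 0.5).all()
        assert any("constant feature" in r.message for r in caplog.records)


class TestOnPhantom:
    def test_all_features_finite_including_guidewire_columns(
            self, segmented_frame):
        df = compute_feature_matrix(segmented_frame["sub"],
                                    segmented_frame["costs"],
                                    segmented_frame["contours"])
        assert np.isfinite(df[FEATURE_NAMES].to_numpy()).all()
        assert df["excluded"].sum() > 0  # guidewire columns present

    def test_healthy_and_diseased_columns_separate(self):
        # the premise of the classification stage: contour-derived features
        # differ strongly between layered and layerless walls
        from sklearn.metrics import roc_auc_score

        from octwall.cost_maps import compute_cost_maps
        from octwall.multilayer_dp import segment_layers
        from octwall.phantom import PhantomSpec, generate_pullback
        from octwall.polar_geometry import build_subimage, segment_lumen

        spec = PhantomSpec(n_frames=1, speckle_sigma=0.0,
                           healthy_arcs=(((0, 256),),), guidewire_center=None,
                           seed=9)
        frames, truths, _ = generate_pullback(spec)
        sub = build_subimage(frames[0], segment_lumen(frames[0]))
        contours = segment_layers(sub)
        df = compute_feature_matrix(sub, compute_cost_maps(sub), contours)
        y = truths[0].labels(100)
        for name in ("contrast", "mse_linear_fit"):
            auc = roc_auc_score(y, df[name])
            assert max(auc, 1 - auc) > 0.8, name
        auc = roc_auc_score(y, df["gradient_at_IM"].abs())
        assert max(auc, 1 - auc) > 0.8
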