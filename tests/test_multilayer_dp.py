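"""The 4D front propagation: exactness, constraints, reductions."""

import numpy as np
import pytest

from octwall.multilayer_dp import (DPParams, backtrack,
                                   brute_force_oracle, path_cost,
                                   propagate_front, segment_layers,
                                   single_contour_dp, truncate_central)
from octwall.phantom import PhantomSpec, generate_pullback
from octwall.polar_geometry import build_subimage, segment_lumen

from conftest import make_cost_maps, uniform_cost_maps


class TestPropagation:
    def test_zero_weights_give_zero_cost_everywhere(self):
        costs = make_cost_maps(8, 6, 0)
        p = DPParams(omega=(0, 0, 0), kappa=0.0, N=1, gap_px=1)
        cum = propagate_front(costs, p)
        for v in cum.values:
            finite = v[np.isfinite(v)]
            assert np.all(finite == 0.0)

    def test_single_admissible_state_accumulates_forced_transitions(self):
        # depth = 2*gap + 1 forces (y1, y2, y3) = (0, gap, 2*gap)
        depth, n_cols, gap = 7, 5, 3
        costs = make_cost_maps(depth, n_cols, 3)
        p = DPParams(omega=(0.2, 1.0, 1.0), kappa=0.1, N=1, gap_px=gap)
        path, total = backtrack(propagate_front(costs, p))
        assert np.all(path[0] == 0) and np.all(path[1] == 3) and np.all(path[2] == 6)
        expected = 0.0
        cp, cm = costs.C_plus, costs.C_minus
        for x in range(1, n_cols):
            expected += 0.2 * (cp[0, x] + cp[0, x - 1])
            expected += 1.0 * (cm[3, x] + cm[3, x - 1])
            expected += 1.0 * (cp[6, x] + cp[6, x - 1])
        assert total == pytest.approx(expected, abs=1e-12)

    def test_empty_admissible_set_raises(self):
        costs = make_cost_maps(6, 5, 0)
        with pytest.raises(ValueError, match="depth too small"):
            propagate_front(costs, DPParams(gap_px=3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        costs = make_cost_maps(6, 5, seed)
        p = DPParams(N=1, gap_px=1)
        path, cost = backtrack(propagate_front(costs, p))
        oracle_path, oracle_cost = brute_force_oracle(costs, p)
        assert cost == pytest.approx(oracle_cost, abs=1e-10)
        assert path_cost(path, costs, p) == pytest.approx(cost, abs=1e-10)

    def test_matches_brute_force_with_wider_neighborhood(self):
        for seed in range(5):
            costs = make_cost_maps(5, 4, 100 + seed)
            p = DPParams(N=2, gap_px=1)
            _, cost = backtrack(propagate_front(costs, p))
            _, oracle_cost = brute_force_oracle(costs, p)
            assert cost == pytest.approx(oracle_cost, abs=1e-10)


class TestBacktrack:
    def test_uniform_costs_pick_lexicographically_smallest_endpoint(self):
        costs = uniform_cost_maps(8, 6, 0.3)
        p = DPParams(kappa=0.5, N=2, gap_px=2)
        path, _ = backtrack(propagate_front(costs, p))
        # every constant admissible path is optimal; ties resolve to the
        # lexicographically smallest state
        assert path[:, -1].tolist() == [0, 2, 4]
        assert np.all(path == path[:, :1])

    def test_uniform_costs_total_matches_closed_form(self):
        c, n_cols = 0.4, 4
        costs = uniform_cost_maps(7, n_cols, c)
        p = DPParams(omega=(0.2, 1.0, 1.0), kappa=0.1, N=1, gap_px=1)
        _, total = backtrack(propagate_front(costs, p))
        # optimal path is horizontal: per step, each interface pays w*2c
        assert total == pytest.approx((n_cols - 1) * 2 * c * (0.2 + 1 + 1))
        _, oracle_total = brute_force_oracle(costs, p)
        assert oracle_total == pytest.approx(total)

    def test_path_cost_recomputation_matches_minimum(self):
        costs = make_cost_maps(10, 9, 42)
        p = DPParams(N=2, gap_px=1)
        cum = propagate_front(costs, p)
        path, total = backtrack(cum)
        assert path_cost(path, costs, p) == pytest.approx(total, abs=1e-9)
        assert total == pytest.approx(float(np.min(cum.final_values)))


class TestOracle:
    def test_single_column_instance_costs_zero(self):
        costs = make_cost_maps(6, 1, 0)
        path, cost = brute_force_oracle(costs, DPParams(N=1, gap_px=1))
        assert cost == 0.0
        assert path[:, 0].tolist() == [0, 1, 2]  # lexicographic smallest

    def test_bound_exceeded_raises(self):
        costs = make_cost_maps(8, 6, 0)
        with pytest.raises(RuntimeError, match="oracle bound"):
            brute_force_oracle(costs, DPParams(N=2, gap_px=1),
                               max_extensions=100)


class TestTruncation:
    def test_central_third_of_constant_path(self):
        path = np.tile([[4], [10], [16]], (1, 30))
        c = truncate_central(path, 10, pixel_size_axial=8.8)
        assert c.n_angles == 10
        assert np.all(c.y1 == 4) and np.all(c.y2 == 10) and np.all(c.y3 == 16)

    def test_width_100_from_replicated_300(self):
        path = np.tile([[2], [8], [14]], (1, 300))
        assert truncate_central(path, 100).n_angles == 100

    def test_wrap_violation_warns(self):
        path = np.tile([[2], [8], [14]], (1, 9)).astype(int)
        path[0, 3] = 12  # central part spans columns 3..5
        path[0, 4] = 12
        path[0, 5] = 2
        with pytest.warns(RuntimeWarning, match="closure"):
            truncate_central(path, 3, params=DPParams(N=3, gap_px=1))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            truncate_central(np.zeros((3, 10), dtype=int), 4)


class TestReductions:
    def test_zero_weighted_interfaces_reduce_to_single_contour_dp(self):
        costs = make_cost_maps(20, 12, 5)
        p = DPParams(omega=(1.0, 0.0, 0.0), kappa=0.1, N=2, gap_px=1)
        path, total = backtrack(propagate_front(costs, p))
        single_path, single_total = single_contour_dp(costs.C_plus,
                                                      kappa=0.1, N=2)
        assert total == pytest.approx(single_total, abs=1e-9)
        assert np.array_equal(path[0], single_path)

    def test_translation_equivariance(self):
        # shifting the image content down by k rows shifts all contours by k
        class Sub:
            pass

        rng = np.random.default_rng(11)
        base = rng.uniform(0, 1, (18, 12))
        k = 4
        shifted = np.vstack([np.tile(base[:1], (k, 1)), base[:-k]])
        outs = []
        for img in (base, shifted):
            sub = Sub()
            sub.I = img
            sub.n_angles = 12
            sub.depth_px = 18
            sub.pixel_size_axial = 60.0  # keeps sigma_px >= 0.5
            sub.guidewire_mask = np.zeros(4, dtype=bool)
            outs.append(segment_layers(sub, DPParams(gap_px=1, N=3),
                                       sigma_um=60.0, downsample=1))
        # interior of the shifted solution is the translated original
        for a, b in zip(outs[0].as_array(), outs[1].as_array()):
            inside = (a + k < 18 - 1) & (a > 0)
            assert np.all(b[inside] == a[inside] + k)

    @pytest.mark.parametrize("seed", range(3))
    def test_smoothness_penalty_monotonically_reduces_roughness(self, seed):
        costs = make_cost_maps(14, 30, seed)
        rough = []
        for kappa in (0.0, 0.5, 2.0):
            p = DPParams(kappa=kappa, N=2, gap_px=1)
            path, _ = backtrack(propagate_front(costs, p))
            rough.append(int(np.abs(np.diff(path, axis=1)).sum()))
        assert rough[0] >= rough[1] >= rough[2]


class TestSegmentLayers:
    def test_noise_free_phantom_recovered_within_two_pixels(
            self, segmented_frame):
        c = segmented_frame["contours"]
        gt = segmented_frame["truth"].layer_contours(100)
        for auto, ref in zip(c.as_array(), gt.as_array()):
            assert np.mean(np.abs(auto - ref)) <= 2.0

    def test_contours_respect_constraints(self, segmented_frame):
        segmented_frame["contours"].validate()

    def test_diseased_phantom_still_returns_valid_contours(self):
        spec = PhantomSpec(n_frames=1, speckle_sigma=0.0,
                           healthy_arcs=((),), thickness_variation=0.0,
                           guidewire_center=None, seed=3)
        frames, _, _ = generate_pullback(spec)
        lumen = segment_lumen(frames[0])
        sub = build_subimage(frames[0], lumen)
        contours = segment_layers(sub)
        contours.validate()  # tentative but non-crossing, gap respected

    def test_downsampled_and_exact_dp_agree_on_small_depth(self):
        # depth small enough that the coarse path (f=1) is the exact one
        class Sub:
            pass

        rng = np.random.default_rng(2)
        sub = Sub()
        sub.I = rng.uniform(0, 1, (20, 10))
        sub.n_angles = 10
        sub.depth_px = 20
        sub.pixel_size_axial = 60.0
        sub.guidewire_mask = np.zeros(10, dtype=bool)
        a = segment_layers(sub, DPParams(gap_px=1), sigma_um=60.0,
                           downsample=1)
        b = segment_layers(sub, DPParams(gap_px=1), sigma_um=60.0,
                           downsample="auto")  # auto == 1 at this depth
        assert np.array_equal(a.as_array(), b.as_array())
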