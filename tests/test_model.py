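"""Response-model tests: distance maps, global-min pooling, RBF, rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragface.model import (
    _rescale_candidate,
    _weighted_distance_map,
    bank_min_distances,
    calibrate_sigma2,
    distance_map,
    min_over_positions_scales,
    rbf_response,
    rescale_to_spikes,
)
from fragface.types import ChannelStack, FeatureCandidate, ModelConfig


def naive_distance_map(cand_data, stim_data, weights, normalize):
    ch, h, w = cand_data.shape
    H, W = stim_data.shape[1:]
    out = np.empty((H - h + 1, W - w + 1))
    for i in range(H - h + 1):
        for j in range(W - w + 1):
            d2 = 0.0
            for c in range(ch):
                d2 += weights[c] * (
                    (cand_data[c] - stim_data[c, i : i + h, j : j + w]) ** 2
                ).sum()
            out[i, j] = d2 / (h * w) if normalize else d2
    return out


def naive_min_over_scales(cand, stim, config):
    best = np.inf
    for b in config.scale_range_b:
        sc = _rescale_candidate(cand.stack.data, b)
        if sc.shape[1] > stim.shape[0] or sc.shape[2] > stim.shape[1]:
            continue
        m = naive_distance_map(sc, stim.data, config.channel_weights, config.normalize)
        best = min(best, m.min())
    return best


def make_candidate(data, cid="c0"):
    return ChannelStack(data), FeatureCandidate(cid, ChannelStack(data), "src", (0, 0) + data.shape[1:])


class TestDistanceMap:
    def test_self_match_is_zero_at_source_offset(self, rng):
        stim = ChannelStack(rng.random((7, 14, 14)))
        cand = FeatureCandidate("c", stim.window(3, 4, 8, 8), "s", (3, 4, 8, 8))
        m = distance_map(cand, stim, alpha=0.5)
        assert m[3, 4] == pytest.approx(0.0, abs=1e-12)
        assert m.min() == pytest.approx(0.0, abs=1e-12)

    def test_scalar_toy_map_is_squared_difference(self):
        # single-channel 1x1 template: map entry (i, j) = (a - x_ij)^2
        stim = np.arange(9, dtype=float).reshape(1, 3, 3)
        cand = np.array([[[2.0]]])
        m = _weighted_distance_map(cand, stim, np.array([1.0]), normalize=True)
        assert np.allclose(m, (2.0 - stim[0]) ** 2)

    def test_matches_nested_loop_oracle(self, rng):
        stim = ChannelStack(rng.random((7, 12, 12)))
        cand = FeatureCandidate("c", ChannelStack(rng.random((7, 8, 8))), "s", (0, 0, 8, 8))
        for alpha in (0.0, 0.5, 1.0):
            m = distance_map(cand, stim, alpha=alpha)
            cfg = ModelConfig(alpha=alpha)
            oracle = naive_distance_map(
                cand.stack.data, stim.data, cfg.channel_weights, True
            )
            assert np.allclose(m, oracle, atol=1e-12)

    def test_rejects_candidate_larger_than_stimulus(self, rng):
        stim = ChannelStack(rng.random((7, 10, 10)))
        cand = FeatureCandidate("c", ChannelStack(rng.random((7, 12, 12))), "s", (0, 0, 12, 12))
        with pytest.raises(ValueError):
            distance_map(cand, stim)


class TestMinOverPositionsScales:
    def test_single_scale_equals_distance_map_minimum(self, rng):
        stim = ChannelStack(rng.random((7, 14, 14)))
        cand = FeatureCandidate("c", ChannelStack(rng.random((7, 8, 8))), "s", (0, 0, 8, 8))
        cfg = ModelConfig(scale_range_b=(1.0,))
        res = min_over_positions_scales(cand, stim, cfg)
        assert res.d2_min == pytest.approx(distance_map(cand, stim).min())
        assert res.best_scale == 1.0

    def test_planted_enlarged_candidate_found_at_its_scale(self, rng):
        cand_data = rng.random((7, 8, 8))
        scaled = _rescale_candidate(cand_data, 1.25)  # 10x10
        stim_data = np.zeros((7, 16, 16))
        stim_data[:, 3:13, 2:12] = scaled
        cand = FeatureCandidate("c", ChannelStack(cand_data), "s", (0, 0, 8, 8),
                                scale_range_b=(1.0, 1.25))
        cfg = ModelConfig(scale_range_b=(1.0, 1.25))
        res = min_over_positions_scales(cand, ChannelStack(stim_data), cfg)
        assert res.best_scale == 1.25
        assert res.best_offset == (3, 2)
        assert res.d2_min == pytest.approx(0.0, abs=1e-12)

    def test_empty_scale_range_is_rejected_at_config_level(self):
        with pytest.raises(ValueError):
            ModelConfig(scale_range_b=())

    def test_infeasible_candidate_raises(self, rng):
        stim = ChannelStack(rng.random((7, 7, 7)))
        cand = FeatureCandidate("c", ChannelStack(rng.random((7, 8, 8))), "s", (0, 0, 8, 8),
                                scale_range_b=(1.0, 1.25))
        with pytest.raises(ValueError):
            min_over_positions_scales(cand, stim, ModelConfig(scale_range_b=(1.0, 1.25)))

    def test_position_invariance_for_grid_translations(self, rng):
        cand_data = rng.random((7, 8, 8))
        cand = FeatureCandidate("c", ChannelStack(cand_data), "s", (0, 0, 8, 8))
        cfg = ModelConfig(scale_range_b=(1.0,))
        d2 = []
        for (r, c) in [(0, 0), (3, 5), (8, 2), (12, 12)]:
            stim = np.zeros((7, 20, 20))
            stim[:, r : r + 8, c : c + 8] = cand_data
            d2.append(min_over_positions_scales(cand, ChannelStack(stim), cfg).d2_min)
        assert max(d2) - min(d2) < 1e-9

    def test_alpha_one_ignores_recoloring(self, rng):
        stim_data = rng.random((7, 14, 14))
        recolored = stim_data.copy()
        recolored[4:] = rng.random((3, 14, 14))  # new colors, same edges
        cand = FeatureCandidate("c", ChannelStack(rng.random((7, 8, 8))), "s", (0, 0, 8, 8))
        cfg = ModelConfig(alpha=1.0, scale_range_b=(1.0,))
        a = min_over_positions_scales(cand, ChannelStack(stim_data), cfg)
        b = min_over_positions_scales(cand, ChannelStack(recolored), cfg)
        assert a.d2_min == pytest.approx(b.d2_min, abs=1e-12)
        assert a.best_offset == b.best_offset


class TestRbf:
    def test_closed_form_values(self):
        assert rbf_response(0.0, 1.0) == 1.0
        assert rbf_response(2.0, 1.0) == pytest.approx(np.exp(-1))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        d2a=st.floats(0, 50),
        d2b=st.floats(0, 50),
        s2=st.floats(0.5, 10),
    )
    def test_strictly_decreasing_and_bounded(self, d2a, d2b, s2):
        ra, rb = rbf_response(d2a, s2), rbf_response(d2b, s2)
        assert 0 < ra <= 1
        if d2b - d2a > 1e-6:
            assert ra > rb

    def test_rejects_invalid_arguments(self):
        with pytest.raises(ValueError):
            rbf_response(-1.0, 1.0)
        with pytest.raises(ValueError):
            rbf_response(1.0, 0.0)


class TestRescaleToSpikes:
    def test_two_point_affine_example(self):
        # predicted means 0.8 (faces) / 0.2 (non-faces), neural means 10 / 2
        ids = ["f1", "f2", "n1", "n2"]
        pred = np.array([0.9, 0.7, 0.1, 0.3])
        neural = {"f1": 12.0, "f2": 8.0, "n1": 1.0, "n2": 3.0}
        out = rescale_to_spikes(pred, ids, ["f1", "f2"], ["n1", "n2"], neural)
        assert np.allclose(out, (pred - 0.2) / 0.6 * 8 + 2)
        assert out[:2].mean() == pytest.approx(10.0)
        assert out[2:].mean() == pytest.approx(2.0)

    def test_degenerate_equal_means_raise(self):
        with pytest.raises(ValueError):
            rescale_to_spikes(
                np.array([0.5, 0.5]), ["f", "n"], ["f"], ["n"], {"f": 1.0, "n": 2.0}
            )


class TestBankFastPath:
    def test_equals_exact_per_pair_scan(self, rng):
        stims = [ChannelStack(rng.random((7, 14, 14))) for _ in range(3)]
        bank = []
        for i in range(8):
            h = int(rng.integers(8, 11))
            bank.append(
                FeatureCandidate(f"c{i}", ChannelStack(rng.random((7, h, h))), "s", (0, 0, h, h))
            )
        cfg = ModelConfig()
        D2 = bank_min_distances(bank, stims, cfg)
        for ci, cand in enumerate(bank):
            for si, stim in enumerate(stims):
                exact = min_over_positions_scales(cand, stim, cfg).d2_min
                assert D2[ci, si] == pytest.approx(exact, abs=1e-9)

    def test_sigma_calibration_is_median(self, rng):
        d2 = rng.random((4, 9))
        assert np.allclose(calibrate_sigma2(d2), np.median(d2, axis=1))
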