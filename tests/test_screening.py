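"""Screening statistics: split-half repeatability, FSI, tuning ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fragface.screening import (
    ScreeningThresholds,
    face_selectivity_index,
    repeatability,
    screen_site,
    tuning_anova,
    zscore_view_curve,
)
from fragface.experiments import screening_null_calibration
from fragface.synth import specs_to_meta
from fragface.types import ResponseTable, StimulusSpec, VIEWS_DEG


def make_table(values_by_stim, trials_per_stim, specs, site="s"):
    """values_by_stim: stimulus_id -> list of trial responses."""
    rows = []
    for sid, vals in values_by_stim.items():
        for t, v in enumerate(vals, 1):
            rows.append({"stimulus_id": sid, "trial": t, "response": v})
    return ResponseTable(site, pd.DataFrame(rows), specs_to_meta(specs))


def face_nonface_specs(n_face=4, n_nonface=4):
    return [StimulusSpec(f"f{i}", "human_face") for i in range(n_face)] + [
        StimulusSpec(f"n{i}", "nonface") for i in range(n_nonface)
    ]


class TestRepeatability:
    def test_identical_halves_give_one(self):
        specs = face_nonface_specs()
        vals = {s.stimulus_id: [i, i] for i, s in enumerate(specs)}
        assert repeatability(make_table(vals, 2, specs)) == pytest.approx(1.0)

    def test_matches_spearman_brown_of_oracle_split(self, rng):
        specs = face_nonface_specs(6, 6)
        vals = {s.stimulus_id: list(rng.normal(10, 3, size=6)) for s in specs}
        table = make_table(vals, 6, specs)
        odd = np.array([np.mean(v[0::2]) for v in vals.values()])
        even = np.array([np.mean(v[1::2]) for v in vals.values()])
        r = np.corrcoef(odd, even)[0, 1]
        assert repeatability(table) == pytest.approx(2 * r / (1 + r))

    def test_spearman_brown_boosts_intermediate_correlations(self):
        for r in (0.1, 0.5, 0.9):
            assert 2 * r / (1 + r) > r
        assert 2 * 0.5 / 1.5 == pytest.approx(2 / 3)

    def test_constant_vector_rejected(self):
        specs = face_nonface_specs()
        vals = {s.stimulus_id: [5.0, 5.0] for s in specs}
        with pytest.raises(ValueError):
            repeatability(make_table(vals, 2, specs))


class TestFsi:
    def _table(self, face_vals, nonface_vals):
        specs = face_nonface_specs(len(face_vals), len(nonface_vals))
        vals = {f"f{i}": [v, v] for i, v in enumerate(face_vals)}
        vals.update({f"n{i}": [v, v] for i, v in enumerate(nonface_vals)})
        return make_table(vals, 2, specs)

    def test_equal_means_give_zero(self):
        assert face_selectivity_index(self._table([5, 7], [6, 6])) == pytest.approx(0.0)

    def test_two_to_one_ratio_sits_exactly_at_threshold(self):
        fsi = face_selectivity_index(self._table([10.0, 10.0], [5.0, 5.0]))
        assert fsi == 1.0 / 3.0  # exact: the 2:1 boundary

    def test_zero_nonface_response_gives_one(self):
        assert face_selectivity_index(self._table([4, 4], [0, 0])) == pytest.approx(1.0)

    def test_negative_means_are_clipped_before_ratio(self):
        assert face_selectivity_index(self._table([4, 4], [-3, -3])) == pytest.approx(1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 100))
    def test_invariant_to_positive_rescaling(self, scale, seed):
        r = np.random.default_rng(seed)
        f, n = r.uniform(1, 10, 3), r.uniform(1, 10, 3)
        a = face_selectivity_index(self._table(f, n))
        b = face_selectivity_index(self._table(f * scale, n * scale))
        assert a == pytest.approx(b, abs=1e-12)


def view_table(resp_by_identity_view, n_identities, site="s"):
    specs, vals = [], {}
    for i in range(n_identities):
        for v in VIEWS_DEG:
            sid = f"vc_id{i}_{v:+04d}"
            specs.append(StimulusSpec(sid, "human_face", f"id{i}", v))
            vals[sid] = [resp_by_identity_view(i, v)] * 2
    return make_table(vals, 2, specs, site)


class TestTuningAnova:
    def test_three_group_toy_matches_hand_computed_f(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 5.0, 10.0]]
        specs, vals = [], {}
        for gi, g in enumerate(groups):
            for ri, v in enumerate(g):
                sid = f"vc_{gi}_{ri}"
                specs.append(StimulusSpec(sid, "human_face", f"id{ri}", VIEWS_DEG[gi]))
                vals[sid] = [v, v]
        table = make_table(vals, 2, specs)
        f_obs, p_obs = tuning_anova(table, "view")
        flat = np.concatenate(groups)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / (len(flat) - 3))
        assert f_obs == pytest.approx(f_hand)
        assert p_obs == pytest.approx(stats.f.sf(f_hand, 2, len(flat) - 3))

    def test_identical_group_distributions_give_f_zero(self):
        table = view_table(lambda i, v: float(i), 5)
        f, p = tuning_anova(table, "view")
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_view_shift_is_detected(self, rng):
        shift = {v: (10.0 if v == 0 else 0.0) for v in VIEWS_DEG}
        noise = {(i, v): rng.normal(0, 1) for i in range(41) for v in VIEWS_DEG}
        table = view_table(lambda i, v: 20 + shift[v] + noise[(i, v)], 41)
        _, p = tuning_anova(table, "view")
        assert p < 1e-6

    def test_identity_grouping_uses_views_as_replicates(self, rng):
        table = view_table(lambda i, v: 10.0 * i + rng.normal(0, 0.1), 4)
        _, p = tuning_anova(table, "identity")
        assert p < 1e-6

    def test_too_few_replicates_rejected(self):
        specs = [StimulusSpec("a", "human_face", "id0", 0)]
        vals = {"a": [1.0, 2.0]}
        with pytest.raises(ValueError):
            tuning_anova(make_table(vals, 2, specs), "view")


class TestZscoreCurve:
    def test_single_identity_curve_is_its_zscore(self):
        table = view_table(lambda i, v: float(v), 1)
        mean, sd, dropped = zscore_view_curve(table)
        vals = np.array(VIEWS_DEG, dtype=float)
        expect = (vals - vals.mean()) / vals.std()
        order = np.argsort(VIEWS_DEG)
        assert np.allclose(mean, expect[order])
        assert np.allclose(sd, 0.0)
        assert dropped == []

    def test_matches_brute_force_recomputation(self, rng):
        resp = {(i, v): rng.normal(10, 2) for i in range(5) for v in VIEWS_DEG}
        table = view_table(lambda i, v: resp[(i, v)], 5)
        mean, sd, _ = zscore_view_curve(table)
        z = []
        for i in range(5):
            row = np.array([resp[(i, v)] for v in sorted(VIEWS_DEG)])
            z.append((row - row.mean()) / row.std())
        z = np.array(z)
        assert np.allclose(mean, z.mean(axis=0))
        assert np.allclose(sd, z.std(axis=0))

    def test_flat_identities_are_dropped_and_reported(self):
        table = view_table(lambda i, v: float(v) if i == 0 else 7.0, 2)
        mean, sd, dropped = zscore_view_curve(table)
        assert dropped == ["id1"]
        assert np.isfinite(mean).all()


class TestScreeningCascade:
    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ScreeningThresholds(repeatability=1.1)

    def test_null_anova_p_values_are_uniform(self):
        out = screening_null_calibration(master_seed=3, n_tables=300)
        assert out["ks_p"] > 0.01

    def test_planted_face_fragment_columns_are_face_selective(
        self, ident_bundle, ident_responses
    ):
        # a column planted with a face-content fragment clears the
        # reliability and FSI gates at default gains and noise
        from fragface.synth import simulate_responses
        from fragface.types import FeatureCandidate, GroundTruthColumn

        for k, ident in enumerate(["id000", "id002", "id004", "id006"]):
            front = next(
                s for s in ident_bundle.view_ids if ident in s and "+000" in s
            )
            cand = FeatureCandidate(
                f"p{k}", ident_bundle.stacks[front].window(3, 5, 10, 10),
                front, (3, 5, 10, 10),
            )
            table = simulate_responses(
                GroundTruthColumn(f"site{k}", cand),
                ident_bundle.specs,
                ident_bundle.stacks,
                seed=100 + k,
                config=ident_responses.config,
            )
            report = screen_site(table)
            assert report.reliable
            assert report.fsi > 1 / 3

    def test_planted_view_tuned_columns_pass_the_full_cascade(
        self, ident_bundle, ident_responses
    ):
        from fragface.experiments import view_tuned_candidate_pool
        from fragface.synth import simulate_responses
        from fragface.types import GroundTruthColumn

        pool = view_tuned_candidate_pool(
            ident_responses, ident_bundle.meta.loc[ident_bundle.view_ids]
        )
        assert pool.size >= 3
        for k, ci in enumerate(pool[:3]):
            table = simulate_responses(
                GroundTruthColumn(f"s{k}", ident_responses.bank[int(ci)]),
                ident_bundle.specs,
                ident_bundle.stacks,
                seed=200 + k,
                config=ident_responses.config,
            )
            assert screen_site(table).passes_view_cascade

    def test_noise_only_columns_are_rejected(self, rng):
        # flat-rate columns: repeatability ~ 0, FSI ~ 0 -> never pass
        specs = face_nonface_specs(10, 10)
        n_pass = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            vals = {
                s.stimulus_id: list(10.0 + 3.0 * r.normal(size=6)) for s in specs
            }
            report = screen_site(make_table(vals, 6, specs))
            n_pass += report.reliable and report.face_selective
        assert n_pass == 0
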