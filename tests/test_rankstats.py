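"""Relative treatment effects, the ANOVA-type statistic, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

from countersignal import (AnalysisError, DomainError, ats_test, bh_adjust,
                           pairwise_posthoc, permutation_interaction_test,
                           relative_treatment_effects)


def make_data(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    frames = [pd.DataFrame({"group": g, "baseline": a[:, 0], "post": a[:, 1]})
              for g, a in groups.items()]
    return pd.concat(frames, ignore_index=True)


def paired_groups(rng, sizes, post_factor=None):
    """Lognormal baselines with post tracking baseline; optional group shifts."""
    groups = {}
    for i, n in enumerate(sizes):
        base = rng.lognormal(0, 1.0, n)
        post = base * rng.lognormal(0, 0.3, n)
        if post_factor is not None:
            post = post * post_factor[i]
        groups[f"g{i}"] = np.column_stack([base, post])
    return groups


class TestRelativeTreatmentEffects:
    def test_complete_ties_give_half(self):
        data = make_data({"g1": np.full((3, 2), 7.0), "g2": np.full((3, 2), 7.0)})
        rte = relative_treatment_effects(data)
        assert np.allclose(rte.values, 0.5)

    def test_hand_ranked_two_by_two(self):
        """Cells {1,2},{3,4},{5,6},{7,8}: top cell RTE = (7.5-0.5)/8."""
        data = make_data({"g1": np.array([[1.0, 3.0], [2.0, 4.0]]),
                          "g2": np.array([[5.0, 7.0], [6.0, 8.0]])})
        rte = relative_treatment_effects(data)
        expected = np.array([[0.125, 0.375], [0.625, 0.875]])
        assert np.allclose(rte.values, expected)
        flat = rte.values.ravel()
        assert np.all(np.diff(flat) > 0)

    def test_rte_in_unit_interval_and_ordered_under_shifts(self, rng):
        """RTE ordering matches cell-mean ordering for shift-only alternatives."""
        for _ in range(20):
            shifts = rng.uniform(0, 3, 4)
            base = rng.normal(10, 1, (12, 2))
            data = make_data({
                "g1": base + shifts[0], "g2": base + shifts[1],
                "g3": base + shifts[2], "g4": base + shifts[3]})
            rte = relative_treatment_effects(data)
            assert np.all((rte.values > 0) & (rte.values < 1))
            order_rte = np.argsort(rte.values.mean(axis=1))
            assert np.array_equal(order_rte, np.argsort(shifts))


class TestAtsTest:
    def test_identical_groups_give_null_interaction(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0], [2.0, 5.0]])
        res = ats_test(make_data({"g1": a, "g2": a.copy()}), "interaction")
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_doubled_post_detected_and_matches_permutation(self, rng):
        groups = paired_groups(rng, [10, 10], post_factor=[2.0, 1.0])
        data = make_data(groups)
        res = ats_test(data, "interaction")
        assert res.p_value < 0.05
        _, p_perm = permutation_interaction_test(data, n_perm=2000, seed=7)
        assert abs(res.p_value - p_perm) < 0.02

    def test_monotone_transform_invariance(self, rng):
        data = make_data(paired_groups(rng, [8, 8, 8], post_factor=[1.0, 1.5, 0.7]))
        logged = data.copy()
        logged[["baseline", "post"]] = np.log(logged[["baseline", "post"]])
        for effect in ("treatment", "time", "interaction"):
            a = ats_test(data, effect)
            b = ats_test(logged, effect)
            assert b.statistic == pytest.approx(a.statistic, rel=1e-10)
            assert b.p_value == pytest.approx(a.p_value, rel=1e-10)

    def test_singular_covariance_raises(self):
        data = make_data({"g1": np.full((4, 2), 1.0), "g2": np.full((4, 2), 1.0)})
        with pytest.raises(AnalysisError, match="singular|replicates"):
            ats_test(data, "interaction")

    def test_needs_two_subjects_per_group(self):
        data = make_data({"g1": np.array([[1.0, 2.0]]),
                          "g2": np.array([[3.0, 4.0], [5.0, 6.0]])})
        with pytest.raises(AnalysisError):
            ats_test(data, "interaction")

    def test_unknown_effect_rejected(self, rng):
        data = make_data(paired_groups(rng, [4, 4]))
        with pytest.raises(DomainError):
            ats_test(data, "nested")


class TestPermutationAgreement:
    def test_fast_two_group_path_matches_general_path(self, rng):
        """The Welch-on-rank-differences reduction equals the full ATS."""
        from countersignal.rankstats import (_ats_core, _group_arrays,
                                             _projection, _rank_rows)
        for _ in range(10):
            data = make_data(paired_groups(rng, [7, 9],
                                           post_factor=rng.uniform(0.5, 2, 2)))
            _, arrays = _group_arrays(data)
            ranked = _rank_rows(arrays)
            ats, _, _ = _ats_core(ranked, _projection("interaction", 2))
            obs, _ = permutation_interaction_test(data, n_perm=200, seed=0)
            assert obs == pytest.approx(ats, rel=1e-10)

    def test_rejection_agreement_on_null_data(self, rng):
        """Analytic and permutation interaction tests agree on reject/accept."""
        agree = 0
        n_sets = 60
        for i in range(n_sets):
            data = make_data(paired_groups(rng, [8, 8]))
            res = ats_test(data, "interaction")
            _, p_perm = permutation_interaction_test(data, n_perm=800, seed=i)
            agree += (res.p_value < 0.05) == (p_perm < 0.05)
        assert agree / n_sets >= 0.95


class TestTypeIError:
    def test_all_effects_hold_level_under_null(self):
        """Null simulation, two lognormal groups of 10: each effect's
        rejection rate at alpha = 0.05 stays within [0.03, 0.07]."""
        rng = np.random.default_rng(314159)
        reps = 5000
        rej = dict.fromkeys(("treatment", "time", "interaction"), 0)
        for _ in range(reps):
            vals = rng.lognormal(0, 1.15, (20, 2))
            data = pd.DataFrame({"group": np.repeat(["a", "b"], 10),
                                 "baseline": vals[:, 0], "post": vals[:, 1]})
            for effect in rej:
                if ats_test(data, effect).p_value < 0.05:
                    rej[effect] += 1
        for effect, hits in rej.items():
            assert 0.03 <= hits / reps <= 0.07, (effect, hits / reps)


class TestBhAdjust:
    @pytest.mark.parametrize("raw, adjusted", [
        ([0.5], [0.5]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.01, 0.04, 0.03, 0.005], [0.02, 0.04, 0.04, 0.02]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ])
    def test_step_up_hand_values(self, raw, adjusted):
        assert bh_adjust(raw) == pytest.approx(adjusted)

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


class TestPairwisePosthoc:
    def test_single_pair_unadjusted(self, rng):
        data = make_data(paired_groups(rng, [8, 8]))
        out = pairwise_posthoc(data, pairs=[("g0", "g1")])
        assert len(out) == 1
        assert out["p_bh"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_all_pairs_by_default(self, rng):
        data = make_data(paired_groups(rng, [6, 6, 6]))
        out = pairwise_posthoc(data)
        assert len(out) == 3

    def test_missing_group_rejected(self, rng):
        data = make_data(paired_groups(rng, [6, 6]))
        with pytest.raises(AnalysisError, match="unknown group"):
            pairwise_posthoc(data, pairs=[("g0", "g9")])
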