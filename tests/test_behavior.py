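"""Detect-probability, effect sizes, PCM curves, correlations, matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betaevents as be
from betaevents.behavior import (FeatureVector, UndefinedStatisticError,
                                 auroc)

from oracles import (auroc_bruteforce, friedman_chi2_formula,
                     signed_rank_left_p_enumeration)


def fv(values, labels, name="f"):
    return FeatureVector("d", name, np.asarray(values, float),
                         np.asarray(labels, bool))


class TestDetectProbability:
    def test_four_trial_worked_example_is_zero(self):
        # values 1,2,3,4 with labels +,+,-,-: every positive-class value is
        # below every negative-class value, so DP = 0
        assert auroc([1, 2, 3, 4], [True, True, False, False]) == 0.0

    def test_higher_on_negative_class_gives_dp_zero(self):
        values = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        assert auroc(values, labels) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 4, 12).astype(float)  # ties guaranteed
        labels = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        assert np.isclose(auroc(values, labels),
                          auroc_bruteforce(values, labels))

    def test_null_feature_dp_near_half(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(4000)
        labels = rng.random(4000) < 0.5
        assert abs(auroc(values, labels) - 0.5) < 0.03

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(30)
        labels = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        base = auroc(values, labels)
        assert np.isclose(auroc(np.exp(2 * values), labels), base)
        assert np.isclose(auroc(np.argsort(np.argsort(values)).astype(float),
                                labels), base)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_negated_feature_complements(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.standard_normal(24)  # continuous: no ties
        labels = rng.permutation(np.r_[np.ones(12, bool), np.zeros(12, bool)])
        assert np.isclose(auroc(values, labels) + auroc(-values, labels), 1.0)

    def test_absent_values_excluded(self):
        values = [np.nan, 1, 2, 3, 4]
        labels = [True, True, True, False, False]
        res = be.detect_probability(fv(values, labels), n_boot=50, seed=0)
        assert res.n == 4 and res.dp == 0.0

    def test_single_class_raises(self):
        with pytest.raises(UndefinedStatisticError):
            be.detect_probability(fv([1, 2], [True, True]))

    def test_bootstrap_ci_brackets_dp_and_flags_separation(self):
        rng = np.random.default_rng(2)
        values = np.r_[rng.normal(0, 1, 50), rng.normal(4, 1, 50)]
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        res = be.detect_probability(fv(values, labels), n_boot=300, seed=1)
        assert res.ci_low <= res.dp <= res.ci_high
        assert res.significant_below_half

    def test_null_significance_rate_is_nominal(self):
        # ~5% of label-independent datasets should flag a 95% CI below 0.5
        rng = np.random.default_rng(7)
        flags = []
        for _ in range(60):
            values = rng.standard_normal(80)
            labels = rng.permutation(np.r_[np.ones(40, bool),
                                           np.zeros(40, bool)])
            res = be.detect_probability(fv(values, labels), n_boot=200,
                                        seed=int(rng.integers(2**31)))
            flags.append(res.significant_below_half)
        assert np.mean(flags) < 0.15  # one-sided binomial slack around 5%


class TestGroupDPTest:
    def test_ten_values_below_half_hit_exact_floor(self):
        values = np.linspace(0.30, 0.45, 10)
        _, p, _ = be.group_dp_test(values)
        assert p == pytest.approx(9.765625e-4, abs=1e-12)

    def test_symmetric_values_not_significant(self):
        values = 0.5 + np.array([-0.1, -0.05, -0.02, 0.02, 0.05, 0.1])
        _, p, _ = be.group_dp_test(values)
        assert p > 0.4

    def test_all_at_null_degenerate(self):
        _, p, _ = be.group_dp_test(np.full(6, 0.5))
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = 0.5 + rng.uniform(-0.2, 0.2, 6)
        _, p, _ = be.group_dp_test(values)
        assert np.isclose(p, signed_rank_left_p_enumeration(values - 0.5))


class TestCohensD:
    def test_hand_computed_example(self):
        assert be.cohens_d([2, 4], [1, 3]) == pytest.approx(1 / np.sqrt(2))

    def test_identical_groups_zero(self):
        assert be.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_sign_positive_when_first_group_larger(self):
        assert be.cohens_d([5, 6, 7], [1, 2, 3]) > 0

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            be.cohens_d([1, 1], [1, 1])


class TestPooledConditionTest:
    def test_balanced_differences_give_p_half(self):
        # condition differences of equal magnitude and alternating sign:
        # t = 0, so the right-tailed p sits at the 0.5 boundary
        labs = [np.array([True, True, False, False])] * 6
        vals = [np.array([1.0, 2.0, 1.0, 2.0])
                + np.array([0, 0, s, s]) for s in (0.1, -0.1) * 3]
        res = be.pooled_condition_test(vals, labs)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(0.5)

    def test_detects_built_in_rate_difference(self):
        rng = np.random.default_rng(3)
        vals, labs = [], []
        for _ in range(10):
            pos = rng.poisson(1.0, 100).astype(float)
            neg = rng.poisson(2.5, 100).astype(float)
            vals.append(np.r_[pos, neg])
            labs.append(np.r_[np.ones(100, bool), np.zeros(100, bool)])
        res = be.pooled_condition_test(vals, labs)
        assert res["p"] < 0.05
        assert res["d"] > 0  # negative condition entered first


class TestPCM:
    def test_independent_labels_give_flat_curve(self):
        rng = np.random.default_rng(1)
        fvs = [fv(rng.standard_normal(200),
                  rng.permutation(np.r_[np.ones(100, bool),
                                        np.zeros(100, bool)]))
               for _ in range(12)]
        _, mean, _ = be.pcm_rate_curve(fvs, seed=0)
        assert np.abs(mean).max() < 30.0
        assert abs(mean.mean()) < 5.0

    def test_label_indicator_feature_is_monotone(self):
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        curve = be.pcm_rate_curve(fv(labels.astype(float), labels), seed=0)[1]
        assert curve[0] < 0 < curve[-1]
        assert curve[-1] == pytest.approx(100.0 * (1 - labels.mean())
                                          / labels.mean())

    def test_matches_enumerated_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal(43)  # continuous: no ties
        labels = rng.random(43) < 0.4
        if not labels.any():
            labels[0] = True
        _, mean, _ = be.pcm_rate_curve(fv(values, labels), seed=2)
        order = np.argsort(values)
        sl = labels[order].astype(float)
        rates = np.array([sl[i:i + 21].mean() for i in range(43 - 20)])
        pcm = 100 * (rates - labels.mean()) / labels.mean()
        oracle = np.interp(np.linspace(0, 1, 100),
                           np.linspace(0, 1, len(pcm)), pcm)
        np.testing.assert_allclose(mean, oracle, rtol=1e-10)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            be.pcm_rate_curve(fv(np.arange(21.0), [True, False] * 10 + [True]))


class TestFeatureCorrelations:
    def _fixture(self, seed=0, n_datasets=10):
        rng = np.random.default_rng(seed)
        fvs_by_ds, power_by_ds = [], []
        for _ in range(n_datasets):
            power = rng.gamma(3.0, size=60)
            feats = {
                "event_number": power + rng.normal(0, 0.5, 60),
                "event_power": power + rng.normal(0, 2.0, 60),
                "event_duration": rng.standard_normal(60),
                "event_fspan": rng.standard_normal(60),
            }
            fvs_by_ds.append({k: fv(v, rng.random(60) < 0.5, k)
                              for k, v in feats.items()})
            power_by_ds.append(power)
        return fvs_by_ds, power_by_ds

    def test_feature_identical_to_power_has_r_one(self):
        rng = np.random.default_rng(1)
        power = rng.gamma(3.0, size=50)
        fvs = [{
            "a": fv(power, rng.random(50) < 0.5),
            "b": fv(rng.standard_normal(50), rng.random(50) < 0.5),
            "c": fv(rng.standard_normal(50), rng.random(50) < 0.5),
            "d": fv(rng.standard_normal(50), rng.random(50) < 0.5),
        } for _ in range(5)]
        r, _, _ = be.feature_power_correlations(fvs, [power] * 5,
                                                reference="a")
        np.testing.assert_allclose(r["a"], 1.0, rtol=1e-12)

    def test_friedman_matches_rank_formula_oracle(self):
        fvs, power = self._fixture(seed=4)
        r, friedman, _ = be.feature_power_correlations(fvs, power)
        matrix = np.column_stack([r[k] for k in fvs[0]])
        assert friedman["chi2"] == pytest.approx(
            friedman_chi2_formula(matrix), rel=1e-9)
        assert friedman["df"] == 3

    def test_rate_beats_other_features_after_holm(self):
        fvs, power = self._fixture(seed=2)
        _, friedman, post = be.feature_power_correlations(fvs, power)
        assert friedman["p"] < 0.05
        pair = post["pairwise"]
        assert pair["event_duration"]["p_holm"] < 0.05
        for d in pair.values():
            assert d["p_holm"] >= d["p_raw"] - 1e-15

    def test_holm_adjusted_monotone_in_raw(self):
        fvs, power = self._fixture(seed=6)
        _, _, post = be.feature_power_correlations(fvs, power)
        pairs = sorted(post["pairwise"].values(), key=lambda d: d["p_raw"])
        holm = [d["p_holm"] for d in pairs]
        assert all(a <= b + 1e-15 for a, b in zip(holm, holm[1:]))


class TestOptimalCriterion:
    def test_perfect_separation_tie_breaks_to_smallest(self):
        counts = np.array([0, 0, 2, 2])
        labels = np.array([True, True, False, False])
        assert be.optimal_criterion(counts, labels)["criterion"] == 1

    def test_independent_counts_give_near_zero_performance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, 2000)
        labels = rng.random(2000) < 0.5
        best = be.optimal_criterion(counts, labels)
        assert abs(best["tpr_minus_fpr"]) < 0.08

    def test_rate_difference_prefers_criterion_two(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            pos = rng.poisson(1.0, 150)
            neg = rng.poisson(2.5, 150)
            counts = np.r_[pos, neg]
            labels = np.r_[np.ones(150, bool), np.zeros(150, bool)]
            if be.optimal_criterion(counts, labels)["criterion"] == 2:
                hits += 1
        assert hits >= 14  # criterion 2 is the mode across datasets


class TestHistogramMatching:
    def test_already_matched_keeps_everything(self):
        counts = np.array([1, 1, 2, 2, 3, 3], float)
        labels = np.array([True, False, True, False, True, False])
        kept, info = be.match_histogram_trim(counts, labels, "event_count")
        assert info["retained_fraction"] == 1.0
        assert len(kept) == 6

    def test_five_vs_three_keeps_three_per_side(self):
        counts = np.array([1.0] * 8)
        labels = np.array([True] * 5 + [False] * 3)
        kept, _ = be.match_histogram_trim(counts, labels, "event_count",
                                          seed=0)
        assert labels[kept].sum() == 3 and (~labels[kept]).sum() == 3

    @pytest.mark.parametrize("kind,seed", [("event_count", 0),
                                           ("most_recent_timing", 1)])
    def test_per_bin_counts_exactly_equal_after_matching(self, kind, seed):
        rng = np.random.default_rng(seed)
        n = 400
        labels = rng.random(n) < 0.5
        if kind == "event_count":
            key = rng.poisson(np.where(labels, 1.0, 2.5)).astype(float)
            key[key == 0] = np.nan
        else:
            key = rng.uniform(-1000, 0, n)
        kept, _ = be.match_histogram_trim(key, labels, kind, seed=seed)
        if kind == "event_count":
            bins = key[kept].astype(int)
        else:
            bins = np.floor((key[kept] + 1000.0) / 20.0).astype(int)
        for b in np.unique(bins):
            sel = kept[bins == b]
            assert labels[sel].sum() == (~labels[sel]).sum()

    def test_zero_event_trials_never_enter(self):
        counts = np.array([0.0, 0, 1, 1])
        labels = np.array([True, False, True, False])
        kept, info = be.match_histogram_trim(counts, labels, "event_count")
        assert set(kept) == {2, 3}
        assert info["n_eligible"] == 2
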