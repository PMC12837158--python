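import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eritwin import (
    ConfusionCounts,
    binary_auc,
    cohort_to_frame,
    compare_eri_groups,
    confusion_metrics,
    generate_cohort,
    propensity_match,
    smd,
)
from eritwin.synthetic import BINARY_COVARIATES, COVARIATE_COLUMNS


def auc_from_binary_pair_oracle(c):
    """Exhaustive pair counting treating the binary prediction as the score."""
    pos = [1] * c.tp + [0] * c.fn
    neg = [1] * c.fp + [0] * c.tn
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(rep, name).value == pytest.approx(100.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)

    def test_from_predictions(self):
        c = ConfusionCounts.from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)

    def test_undefined_metrics_are_none(self):
        rep = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert rep.ppv is None  # no positive predictions
        assert rep.sensitivity.value == 0.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(tp=st.integers(0, 20), fp=st.integers(0, 20),
           tn=st.integers(0, 20), fn=st.integers(0, 20))
    def test_cis_contain_point_estimates(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            tp = 1
        rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m = getattr(rep, name)
            if m is not None and m.ci is not None:
                assert m.ci[0] - 1e-9 <= m.value <= m.ci[1] + 1e-9

    def test_format_table_lists_all_statistics(self):
        text = confusion_metrics(ConfusionCounts(5, 3, 7, 0)).format_table()
        for label in ("Sensitivity", "Specificity", "Area under the curve",
                      "likelihood ratio", "predictive value", "Accuracy"):
            assert label in text


class TestBinaryAuc:
    def test_equals_sens_spec_average(self):
        c = ConfusionCounts(tp=5, fp=3, tn=7, fn=0)
        assert binary_auc(c) == pytest.approx((1.0 + 0.7) / 2)

    def test_chance_level(self):
        assert binary_auc(ConfusionCounts(tp=3, fp=4, tn=4, fn=3)) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_auc(ConfusionCounts(tp=3, fp=0, tn=0, fn=2))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tp=st.integers(0, 12), fp=st.integers(0, 12),
           tn=st.integers(0, 12), fn=st.integers(0, 12))
    def test_matches_exhaustive_pair_counting(self, tp, fp, tn, fn):
        if tp + fn == 0 or tn + fp == 0:
            tp, tn = tp + 1, tn + 1
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        assert binary_auc(c) == pytest.approx(auc_from_binary_pair_oracle(c), abs=1e-12)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        g = compare_eri_groups([0.4, 0.4, 0.4], [0.4, 0.4, 0.4])
        assert g.p_welch == 1.0
        assert g.p_mannwhitney == 1.0

    def test_complete_separation_rejects(self):
        g = compare_eri_groups([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert min(g.p_welch, g.p_mannwhitney) <= 0.1
        assert g.mean_pos > g.mean_neg

    def test_simulated_cohort_moments_reject(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0.85, 0.10, 5)
        neg = rng.normal(0.39, 0.11, 10)
        g = compare_eri_groups(pos, neg)
        assert g.p_welch < 0.05

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_eri_groups([0.5], [0.4, 0.3])


class TestSmd:
    def test_equal_distributions_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert smd(x, x) == 0.0

    def test_hand_computed_unit_difference(self):
        t = np.array([1 - 2**-0.5, 1 + 2**-0.5])  # mean 1, sd 1
        c = np.array([-(2**-0.5), 2**-0.5])  # mean 0, sd 1
        assert smd(t, c) == pytest.approx(1.0)

    def test_binary_equal_proportions(self):
        assert smd([1, 0, 1, 0], [0, 1, 0, 1], kind="binary") == 0.0

    def test_zero_variance_unequal_means_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            val = smd([1.0, 1.0], [0.0, 0.0])
        assert np.isinf(val)


@pytest.fixture(scope="module")
def null_cohort():
    recs, _ = generate_cohort(1000, confounding=0.0, seed=0)
    return cohort_to_frame(recs)


@pytest.fixture(scope="module")
def confounded_cohort():
    recs, _ = generate_cohort(1000, confounding=1.5, seed=0)
    return cohort_to_frame(recs)


class TestPropensityMatching:
    def test_null_confounding_balances(self, null_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = propensity_match(null_cohort, COVARIATE_COLUMNS,
                                   binary_covariates=BINARY_COVARIATES)
        assert res.smd_after.abs().max() < 0.1

    def test_matching_reduces_confounded_imbalance(self, confounded_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = propensity_match(confounded_cohort, COVARIATE_COLUMNS,
                                   binary_covariates=BINARY_COVARIATES)
        assert res.smd_after.abs().max() < res.smd_before.abs().max()

    def test_no_control_reuse_and_caliper_respected(self, confounded_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = propensity_match(confounded_cohort, COVARIATE_COLUMNS,
                                   binary_covariates=BINARY_COVARIATES)
        all_controls = [c for v in res.control_ids.values() for c in v]
        assert len(all_controls) == len(set(all_controls))
        logit = np.log(res.propensity / (1 - res.propensity))
        for t_id, ctrls in res.control_ids.items():
            for c_id in ctrls:
                assert abs(logit[t_id] - logit[c_id]) <= res.caliper + 1e-9

    def test_every_match_has_k_controls(self, null_cohort):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = propensity_match(null_cohort, COVARIATE_COLUMNS, ratio=3,
                                   binary_covariates=BINARY_COVARIATES)
        assert all(len(v) == 3 for v in res.control_ids.values())

    def test_insufficient_controls_drops_with_warning(self):
        recs, _ = generate_cohort(40, confounding=0.0, seed=1)
        df = cohort_to_frame(recs)
        df["group"] = 0
        df.iloc[: len(df) - 4, df.columns.get_loc("group")] = 1  # 4 controls only
        with pytest.warns(UserWarning, match="dropped"):
            res = propensity_match(df, COVARIATE_COLUMNS, ratio=3,
                                   binary_covariates=BINARY_COVARIATES)
        assert len(res.dropped_treated) >= len(res.treated_ids) - 1

    def test_single_group_rejected(self, null_cohort):
        df = null_cohort.copy()
        df["group"] = 1
        with pytest.raises(ValueError):
            propensity_match(df, COVARIATE_COLUMNS)
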