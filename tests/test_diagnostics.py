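"""Diagnostic accuracy: confusion metrics, ROC/AUC, Youden, bootstrap, U test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pji_profiler import (
    CohortTable,
    NetworkConfig,
    bootstrap_threshold_average_ci,
    confusion_metrics,
    evaluate_ensemble,
    evaluate_single_gene,
    group_test,
    roc_curve,
    train_ensemble,
    youden_threshold,
)
from pji_profiler.diagnostics import DegenerateCurveWarning, MetricError
from pji_profiler.expression import NON_PJI, PJI


# --------------------------------------------------------------------------
# brute-force oracles
# --------------------------------------------------------------------------

def auc_by_pair_counting(scores, truth):
    """Concordant-pair probability: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = conc = ties = 0
    for p in pos:
        for q in neg:
            total += 1
            conc += p > q
            ties += p == q
    return (conc + 0.5 * ties) / total


def mann_whitney_exact_enumeration(x, y):
    """Two-sided exact P by enumerating all group assignments (no ties)."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n) if i not in comb]
        us.append(sum(1 for a in xs for b in ys if a > b))
    mean_u = n1 * (n - n1) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / len(us)


class TestConfusionMetrics:
    def test_hand_computed_confusion_table(self):
        truth = [1] * 10 + [0] * 10
        pred = [1] * 9 + [0] + [0] * 8 + [1] * 2
        s = confusion_metrics(pred, truth)
        assert s.sensitivity == pytest.approx(0.90)
        assert s.specificity == pytest.approx(0.80)
        assert s.ppv == pytest.approx(9 / 11)
        assert s.npv == pytest.approx(8 / 9)
        assert s.accuracy == pytest.approx(0.85)
        assert s.lr_pos == pytest.approx(4.5)
        assert s.lr_neg == pytest.approx(0.125)

    def test_perfect_prediction_boundary_sentinels(self):
        s = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert s.sensitivity == s.specificity == s.accuracy == 1.0
        assert s.lr_neg == 0.0
        assert math.isinf(s.lr_pos)

    def test_all_positive_predictions(self):
        s = confusion_metrics([1, 1, 1, 1], [1, 1, 0, 0])
        assert s.sensitivity == 1.0
        assert s.specificity == 0.0
        assert s.lr_pos == pytest.approx(1.0)  # sens / (1 - 0)
        assert s.lr_neg == 0.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(MetricError):
            confusion_metrics([1, 0], [1, 1])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_identities_hold_exactly(self, pairs):
        pred = [p for p, _ in pairs]
        truth = [t for _, t in pairs]
        if all(truth) or not any(truth):
            return
        s = confusion_metrics(pred, truth)
        n = s.n_pos + s.n_neg
        assert s.accuracy * n == pytest.approx(
            s.sensitivity * s.n_pos + s.specificity * s.n_neg
        )
        if s.specificity < 1:
            assert s.lr_pos == pytest.approx(s.sensitivity / (1 - s.specificity))
        if s.specificity > 0:
            assert s.lr_neg == pytest.approx((1 - s.sensitivity) / s.specificity)


class TestRoc:
    def test_four_point_example(self):
        roc = roc_curve([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_label_inversion_mirrors_auc(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        assert roc_curve(scores, [1, 1, 0, 0]).auc == pytest.approx(0.25)

    def test_perfect_separation(self):
        assert roc_curve([1, 2, 10, 11], [0, 0, 1, 1]).auc == 1.0

    def test_constant_scores_degenerate(self):
        with pytest.warns(DegenerateCurveWarning):
            roc = roc_curve([1.0] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auc == 0.5

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.booleans()), min_size=2, max_size=12
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_auc_equals_pair_counting_oracle(self, pairs):
        """Trapezoidal AUC with tie grouping equals the concordance probability."""
        scores = [float(s) for s, _ in pairs]
        truth = [t for _, t in pairs]
        if all(truth) or not any(truth):
            return
        if len(set(scores)) == 1:
            with pytest.warns(DegenerateCurveWarning):
                roc = roc_curve(scores, truth)
        else:
            roc = roc_curve(scores, truth)
        assert roc.auc == pytest.approx(auc_by_pair_counting(scores, truth))

    def test_tpr_fpr_monotone_as_threshold_decreases(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.normal(size=30), rng.integers(0, 2, 30))
        assert (np.diff(roc.tpr) >= 0).all()
        assert (np.diff(roc.fpr) >= 0).all()


class TestYouden:
    def test_perfect_separation_returns_gap_midpoint(self):
        roc = roc_curve([1.0, 2.0, 10.0, 12.0], [0, 0, 1, 1])
        assert youden_threshold(roc) == pytest.approx(6.0)

    def test_degenerate_curve_returns_infinite_sentinel(self):
        with pytest.warns(DegenerateCurveWarning):
            roc = roc_curve([1.0] * 6, [1, 0, 1, 0, 1, 0])
        thr = youden_threshold(roc)
        assert math.isinf(thr)

    @given(
        st.lists(st.tuples(st.integers(0, 8), st.booleans()), min_size=4, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_maximizes_j_against_exhaustive_scan(self, pairs):
        scores = np.array([float(s) for s, _ in pairs])
        truth = np.array([t for _, t in pairs])
        if truth.all() or not truth.any() or len(set(scores)) == 1:
            return
        roc = roc_curve(scores, truth)
        thr = youden_threshold(roc)
        npos, nneg = truth.sum(), (~truth).sum()

        def j_at(t):
            pred = scores >= t
            return (pred & truth).sum() / npos - (pred & ~truth).sum() / nneg

        best_j = max(j_at(t) for t in np.concatenate([scores, [scores.max() + 1]]))
        assert j_at(thr) == pytest.approx(best_j)


class TestBootstrap:
    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        truth = np.r_[np.ones(40), np.zeros(40)].astype(bool)
        point, lo, hi = bootstrap_threshold_average_ci(
            scores, truth, metric="sensitivity", B=300, seed=0
        )
        assert lo <= point <= hi

    def test_perfect_separation_zero_width(self):
        scores = np.r_[np.ones(20) * 10, np.zeros(20)]
        truth = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        point, lo, hi = bootstrap_threshold_average_ci(
            scores, truth, metric="sensitivity", B=200, seed=0, threshold=5.0
        )
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        truth = rng.integers(0, 2, 50).astype(bool)
        a = bootstrap_threshold_average_ci(scores, truth, B=200, seed=5)
        b = bootstrap_threshold_average_ci(scores, truth, B=200, seed=5)
        assert a == b

    def test_ci_width_shrinks_with_sample_size(self):
        """Quadrupling n should roughly halve the CI width (~1/sqrt(n))."""
        widths = {}
        for n in (50, 200):
            rng = np.random.default_rng(3)
            scores = np.r_[rng.normal(1.5, 1, n), rng.normal(0, 1, n)]
            truth = np.r_[np.ones(n), np.zeros(n)].astype(bool)
            _, lo, hi = bootstrap_threshold_average_ci(
                scores, truth, metric="sensitivity", B=400, seed=4, threshold=0.75
            )
            widths[n] = hi - lo
        ratio = widths[200] / widths[50]
        assert 0.3 < ratio < 0.8

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_threshold_average_ci([1, 0], [True, False], B=10)


class TestSingleGene:
    def test_threshold_below_all_values(self, xxpress_trio_cohort):
        s, thr = evaluate_single_gene(xxpress_trio_cohort, "DEFA1", threshold=0.0,
                                      B=100, seed=0)
        assert s.sensitivity == 1.0
        assert s.specificity == 0.0

    def test_printed_threshold_rule_is_deterministic(self, xxpress_trio_cohort):
        """Applying a fixed published threshold is a pure table lookup."""
        s, thr = evaluate_single_gene(xxpress_trio_cohort, "DEFA1", threshold=0.046,
                                      B=100, seed=0)
        assert thr == 0.046
        expected = (
            (xxpress_trio_cohort.values["DEFA1"] >= 0.046)
            == (xxpress_trio_cohort.labels == PJI)
        ).mean()
        assert s.accuracy == pytest.approx(expected)

    def test_all_missing_gene_rejected(self):
        values = pd.DataFrame({"DEFA1": [np.nan, np.nan]}, index=["P1", "P2"])
        cohort = CohortTable(values, pd.Series([PJI, NON_PJI], index=values.index))
        with pytest.raises(MetricError):
            evaluate_single_gene(cohort, "DEFA1", B=100)


@pytest.fixture(scope="module")
def model(separable_cohort):
    return train_ensemble(
        separable_cohort, ("DEFA1",), n_networks=6, top_k=3,
        config=NetworkConfig(max_epochs=800), seed=0,
    )


class TestEnsembleEvaluation:

    def test_training_cohort_of_perfect_fit_scores_one(self, separable_cohort, model):
        s = evaluate_ensemble(model, separable_cohort, B=100, seed=1)
        assert s.accuracy == 1.0

    def test_patient_permutation_invariance(self, separable_cohort, model):
        perm = np.random.default_rng(4).permutation(len(separable_cohort.patients))
        shuffled = CohortTable(
            separable_cohort.values.iloc[perm], separable_cohort.labels.iloc[perm]
        )
        a = evaluate_ensemble(model, separable_cohort, B=100, seed=2)
        b = evaluate_ensemble(model, shuffled, B=100, seed=2)
        assert (a.sensitivity, a.specificity, a.accuracy) == (
            b.sensitivity, b.specificity, b.accuracy
        )

    def test_reports_per_member_and_mean(self, separable_cohort, model):
        s = evaluate_ensemble(model, separable_cohort, B=100, seed=3)
        assert len(s.per_member) == 3
        assert set(s.member_mean) >= {"sensitivity", "specificity", "accuracy"}


class TestGroupTest:
    def test_exact_enumeration_small_sample(self):
        values = pd.DataFrame({"DEFA1": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]})
        cohort = CohortTable(
            values.set_index(pd.Index([f"P{i}" for i in range(6)])),
            pd.Series([PJI] * 3 + [NON_PJI] * 3, index=[f"P{i}" for i in range(6)]),
        )
        assert group_test(cohort, "DEFA1") == pytest.approx(0.1)

    def test_completely_tied_data_gives_p_one(self):
        idx = [f"P{i}" for i in range(8)]
        cohort = CohortTable(
            pd.DataFrame({"DEFA1": [2.0] * 8}, index=idx),
            pd.Series([PJI] * 4 + [NON_PJI] * 4, index=idx),
        )
        assert group_test(cohort, "DEFA1") == 1.0

    def test_empty_group_rejected(self):
        idx = ["P0", "P1"]
        cohort = CohortTable(
            pd.DataFrame({"DEFA1": [1.0, np.nan]}, index=idx),
            pd.Series([PJI, NON_PJI], index=idx),
        )
        with pytest.raises(MetricError):
            group_test(cohort, "DEFA1")

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_matches_exact_enumeration_oracle(self, data):
        n1 = data.draw(st.integers(3, 5))
        n2 = data.draw(st.integers(3, 5))
        pooled = data.draw(
            st.lists(
                st.floats(0.01, 100), min_size=n1 + n2, max_size=n1 + n2, unique=True
            )
        )
        x, y = pooled[:n1], pooled[n1:]
        idx = [f"P{i}" for i in range(n1 + n2)]
        cohort = CohortTable(
            pd.DataFrame({"DEFA1": x + y}, index=idx),
            pd.Series([PJI] * n1 + [NON_PJI] * n2, index=idx),
        )
        assert group_test(cohort, "DEFA1") == pytest.approx(
            mann_whitney_exact_enumeration(x, y)
        )

    def test_calibrated_defa1_groups_highly_significant(self):
        """The published DEFA1 separation is so large that P < 1e-4 in
        essentially every 23/25 synthetic draw."""
        from pji_profiler import CohortSpec, generate_cohort

        hits = 0
        for seed in range(10):
            c = generate_cohort(
                CohortSpec.from_named("table1_xxpress", genes=("DEFA1",), seed=seed)
            )
            hits += group_test(c, "DEFA1") < 1e-4
        assert hits >= 9
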