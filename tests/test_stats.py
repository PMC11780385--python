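from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from gistmon import (
    ConfusionTable,
    ResponseStatus,
    UndefinedMetricError,
    binarize_response,
    cohens_kappa,
    fisher_exact,
    icc_absolute_agreement,
    kappa_from_counts,
    mann_whitney_u,
    performance,
    performance_report,
    reconstruct_table,
    round_half_away,
)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(2.5, 3), (-2.5, -3), (81.8, 82), (95.45, 95), (0.4, 0)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected

    def test_one_decimal(self):
        assert round_half_away(95.45, 1) == 95.5


class TestBinarize:
    @pytest.mark.parametrize(
        "status,expected",
        [
            (ResponseStatus.CR, True),
            (ResponseStatus.PR, True),
            (ResponseStatus.SD, False),
            (ResponseStatus.PD, False),
        ],
    )
    def test_responders_are_cr_and_pr(self, status, expected):
        assert binarize_response(status) is expected


class TestPerformance:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ConfusionTable(18, 0, 4, 17), (90, 82, 100)),
            (ConfusionTable(20, 0, 2, 17), (95, 91, 100)),
            (ConfusionTable(21, 13, 1, 4), (64, 95, 24)),
            (ConfusionTable(14, 0, 5, 11), (83, 74, 100)),
            (ConfusionTable(10, 0, 0, 10), (100, 100, 100)),
        ],
    )
    def test_whole_percent_triples(self, table, expected):
        triple = performance(table)
        assert (triple.accuracy, triple.sensitivity, triple.specificity) == expected

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            performance(ConfusionTable(0, 3, 0, 4))  # no benefit patients

    def test_report_emits_both_orientations(self):
        report = performance_report(ConfusionTable(18, 0, 4, 17))
        assert report["standard"]["sensitivity"] == 82
        assert report["transposed"]["sensitivity"] == 100
        assert report["confusion"] == [18, 0, 4, 17]


class TestReconstructTable:
    def test_forced_zero_cell_pins_unique_table(self):
        tables = reconstruct_table((22, 17), (18, 21), [("fp", 0)])
        assert [t.as_tuple() for t in tables] == [(18, 0, 4, 17)]

    def test_volumetric_marginals(self):
        tables = reconstruct_table((22, 17), (20, 19), [("fp", 0)])
        assert [t.as_tuple() for t in tables] == [(20, 0, 2, 17)]

    def test_choi_metric_constraints_pin_unique_table(self):
        # six feasible tables with these marginals; the printed companion
        # metrics select exactly one
        unconstrained = reconstruct_table((22, 17), (34, 5))
        assert len(unconstrained) == 6
        tables = reconstruct_table(
            (22, 17), (34, 5), [("sensitivity", 96), ("specificity", 24)]
        )
        assert [t.as_tuple() for t in tables] == [(21, 13, 1, 4)]

    def test_early_prediction_marginals(self):
        tables = reconstruct_table((19, 11), (14, 16), [("fp", 0)])
        assert [t.as_tuple() for t in tables] == [(14, 0, 5, 11)]

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ValueError):
            reconstruct_table((22, 17), (18, 20))

    def test_enumeration_preserves_marginals(self):
        for t in reconstruct_table((9, 6), (7, 8)):
            assert t.n_benefit == 9 and t.n_nonbenefit == 6 and t.n_responders == 7


class TestKappa:
    def test_perfect_agreement(self):
        labels = [True, False, True, True, False]
        assert cohens_kappa(labels, labels) == 1.0

    def test_surgeon_agreement_witness_table(self):
        # 30/39 initial agreement with these marginals gives kappa 0.54
        assert round_half_away(kappa_from_counts(16, 6, 3, 14), 2) == 0.54

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.random(4000) < 0.5
        b = rng.random(4000) < 0.5
        assert abs(cohens_kappa(list(a), list(b))) < 0.05

    def test_matches_direct_contingency_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            a = list(rng.random(n) < rng.uniform(0.2, 0.8))
            b = list(rng.random(n) < rng.uniform(0.2, 0.8))
            both = sum(x and y for x, y in zip(a, b))
            a_only = sum(x and not y for x, y in zip(a, b))
            b_only = sum((not x) and y for x, y in zip(a, b))
            neither = n - both - a_only - b_only
            expected = kappa_from_counts(both, a_only, b_only, neither)
            assert cohens_kappa(a, b) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(10)
        a = list(rng.integers(0, 2, 50))
        b = list(rng.integers(0, 2, 50))
        assert cohens_kappa(a, b) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(a, b), abs=1e-10
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([True, False], [True])


def icc2_anova_oracle(a, b):
    """From-scratch two-way ANOVA decomposition, written independently."""
    y = np.column_stack([a, b]).astype(float)
    n, k = y.shape
    subj = y.mean(axis=1, keepdims=True)
    rater = y.mean(axis=0, keepdims=True)
    grand = y.mean()
    msr = (k * ((subj - grand) ** 2).sum()) / (n - 1)
    msc = (n * ((rater - grand) ** 2).sum()) / (k - 1)
    mse = ((y - subj - rater + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_exact_duplicate_is_one(self):
        a = [1.0, 2.0, 5.0, 9.0]
        assert icc_absolute_agreement(a, a) == pytest.approx(1.0)

    def test_large_offset_penalized(self):
        rng = np.random.default_rng(12)
        a = rng.normal(100, 10, 20)
        assert icc_absolute_agreement(a, a + 50.0) < 0.2

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            a = rng.normal(50, 20, 20)
            b = a + rng.normal(0, 5, 20)
            assert icc_absolute_agreement(a, b) == pytest.approx(
                icc2_anova_oracle(a, b), abs=1e-10
            )

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(14)
        a = rng.normal(100, 30, 15)
        b = a + rng.normal(2, 8, 15)
        df = pd.DataFrame(
            {
                "subject": list(range(15)) * 2,
                "rater": ["a"] * 15 + ["b"] * 15,
                "score": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        # absolute-agreement single-rater row; labelled ICC2 or ICC(A,1)
        # depending on the pingouin version
        row = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[row, "ICC"].iloc[0])
        assert icc_absolute_agreement(a, b) == pytest.approx(icc2, abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


def exact_mw_p_by_value_enumeration(x, y):
    """Oracle: enumerate value splits and count U by direct pair comparison."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if xv > yv else (0.5 if xv == yv else 0.0) for xv in xs for yv in ys
        )

    mu = nx * len(y) / 2
    dev = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0 and res.p_value == pytest.approx(0.1)

    def test_identical_single_values(self):
        assert mann_whitney_u([5.0], [5.0]).p_value == 1.0

    def test_exact_equals_value_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(8):
            x = list(rng.integers(0, 6, 5))  # ties likely
            y = list(rng.integers(0, 6, 5))
            res = mann_whitney_u(x, y, method="exact")
            assert res.p_value == pytest.approx(
                exact_mw_p_by_value_enumeration(x, y), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(16)
        x = list(rng.normal(size=6))
        y = list(rng.normal(size=6))
        res = mann_whitney_u(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n12(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = list(rng.normal(size=6))
            y = list(rng.normal(0.5, 1, size=6))
            exact = mann_whitney_u(x, y, method="exact").p_value
            approx = mann_whitney_u(x, y, method="asymptotic").p_value
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def fisher_enumeration_oracle(tp, fp, fn, tn):
    """Oracle: explicit hypergeometric point probabilities via factorials."""
    from math import comb

    n = tp + fp + fn + tn
    row = tp + fn
    col = tp + fp
    denom = comb(n, col)

    def pmf(k):
        return comb(row, k) * comb(n - row, col - k) / denom

    p_obs = pmf(tp)
    return sum(
        pmf(k)
        for k in range(max(0, col - (n - row)), min(row, col) + 1)
        if pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestFisherExact:
    def test_reference_table(self):
        assert fisher_exact(ConfusionTable(3, 1, 1, 3)) == pytest.approx(17 / 35)

    def test_zero_row_gives_one(self):
        assert fisher_exact(ConfusionTable(0, 0, 5, 7)) == 1.0

    def test_symmetric_table_gives_one(self):
        assert fisher_exact(ConfusionTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 12, 4))
            if tp + fp + fn + tn == 0:
                continue
            p1 = fisher_exact(ConfusionTable(tp, fp, fn, tn))
            p2 = fisher_exact(ConfusionTable(tp, fn, fp, tn))  # swap rows/cols
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_enumeration_oracle_and_scipy(self):
        rng = np.random.default_rng(19)
        for _ in range(15):
            tp, fp, fn, tn = (int(v) for v in rng.integers(0, 15, 4))
            if tp + fp + fn + tn == 0:
                continue
            p = fisher_exact(ConfusionTable(tp, fp, fn, tn))
            assert p == pytest.approx(fisher_enumeration_oracle(tp, fp, fn, tn), abs=1e-10)
            ref = sps.fisher_exact([[tp, fn], [fp, tn]], alternative="two-sided")[1]
            assert p == pytest.approx(ref, abs=1e-9)
        assert 0 < p <= 1


@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_confusion_table_marginals_recompute(tp, fp, fn, tn):
    t = ConfusionTable(tp, fp, fn, tn)
    assert t.total == tp + fp + fn + tn
    assert t.n_benefit + t.n_nonbenefit == t.total
    assert t.n_responders == tp + fp


def test_confusion_table_rejects_negative_cells():
    with pytest.raises(ValueError):
        ConfusionTable(-1, 0, 0, 0)
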