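"""Cohort-level statistics for diagnostic evaluation and agreement.

Covers the diagnostic comparison of binarized response (CR or PR) against
the surgical-benefit reference label (confusion tables, accuracy /
sensitivity / specificity), exhaustive reconstruction of 2x2 tables from
published marginal counts, Cohen's kappa, the two-way random-effects
absolute-agreement single-rater ICC, an exact/approximate Mann-Whitney U
test, and Fisher's exact test (point-probability two-sided method).

Reported percentages are rounded half away from zero to whole percent,
mirroring how clinical papers print them; nothing is rounded inside a
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .criteria import ResponseStatus

__all__ = [
    "ConfusionTable",
    "PerformanceTriple",
    "BenefitLabel",
    "UndefinedMetricError",
    "round_half_away",
    "binarize_response",
    "performance",
    "performance_report",
    "reconstruct_table",
    "cohens_kappa",
    "kappa_from_counts",
    "icc_absolute_agreement",
    "mann_whitney_u",
    "fisher_exact",
]


class UndefinedMetricError(ValueError):
    """A performance metric's denominator is zero."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class BenefitLabel:
    """Surgical-benefit reference label for one patient.

    ``benefit`` is the consensus adjudication; ``observer_labels`` optionally
    carries the two surgeons' independent pre-consensus calls.
    """

    patient_id: str
    benefit: bool
    observer_labels: tuple[bool, bool] | None = None


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of predicted response vs. surgical benefit.

    Rows are the reference (benefit yes / no), columns the prediction
    (responder yes / no): ``tp`` responders with benefit, ``fp`` responders
    without benefit, ``fn`` non-responders with benefit, ``tn``
    non-responders without benefit.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_benefit(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonbenefit(self) -> int:
        return self.fp + self.tn

    @property
    def n_responders(self) -> int:
        return self.tp + self.fp

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class PerformanceTriple:
    """Accuracy / sensitivity / specificity in percent.

    Sensitivity is the detection rate among benefit patients,
    tp / (tp + fn); specificity is tn / (tn + fp) among non-benefit
    patients.
    """

    accuracy: float
    sensitivity: float
    specificity: float


def binarize_response(status: ResponseStatus) -> bool:
    """True for the responder categories CR and PR."""
    return status in (ResponseStatus.CR, ResponseStatus.PR)


def _raw_metrics(table: ConfusionTable) -> dict[str, float]:
    if table.total == 0:
        raise UndefinedMetricError("accuracy is undefined for an empty table")
    out = {"accuracy": 100.0 * (table.tp + table.tn) / table.total}
    if table.n_benefit > 0:
        out["sensitivity"] = 100.0 * table.tp / table.n_benefit
    if table.n_nonbenefit > 0:
        out["specificity"] = 100.0 * table.tn / table.n_nonbenefit
    return out


def performance(table: ConfusionTable, rounded: bool = True) -> PerformanceTriple:
    """Accuracy, sensitivity, specificity of a confusion table, in percent.

    With ``rounded=True`` (the reporting convention) values are rounded half
    away from zero to whole percent.  Raises :class:`UndefinedMetricError`
    when a denominator is zero.
    """
    raw = _raw_metrics(table)
    for name in ("sensitivity", "specificity"):
        if name not in raw:
            raise UndefinedMetricError(f"{name} has a zero denominator")
    if rounded:
        raw = {k: round_half_away(v) for k, v in raw.items()}
    return PerformanceTriple(raw["accuracy"], raw["sensitivity"], raw["specificity"])


def performance_report(table: ConfusionTable) -> dict:
    """Performance in both label orientations.

    ``standard`` uses sensitivity = detection of benefit.  ``transposed``
    swaps the sensitivity/specificity labels; published triples sometimes
    follow this orientation, so both are emitted rather than guessed.
    """
    triple = performance(table)
    return {
        "confusion": list(table.as_tuple()),
        "standard": {
            "accuracy": triple.accuracy,
            "sensitivity": triple.sensitivity,
            "specificity": triple.specificity,
        },
        "transposed": {
            "accuracy": triple.accuracy,
            "sensitivity": triple.specificity,
            "specificity": triple.sensitivity,
        },
        "orientation_note": (
            "standard: sensitivity = responder rate among surgical-benefit patients; "
            "transposed swaps the sensitivity/specificity labels"
        ),
    }


def _matches_printed(metric_pct: float, printed: float) -> bool:
    # A printed whole percent may come from direct rounding or from rounding
    # an already once-rounded decimal (95.45 -> 95.5 -> 96), both seen in
    # clinical reporting; accept either.
    return round_half_away(metric_pct) == printed or round_half_away(
        round_half_away(metric_pct, 1)
    ) == printed


def reconstruct_table(
    benefit_marginals: tuple[int, int],
    responder_marginals: tuple[int, int],
    constraints: Iterable[tuple[str, float]] = (),
) -> list[ConfusionTable]:
    """All 2x2 tables with the given marginals satisfying every constraint.

    ``benefit_marginals`` is (n benefit, n non-benefit); ``responder_marginals``
    is (n responders, n non-responders).  A constraint is a ``(name, value)``
    pair: a cell name (``"tp"``, ``"fp"``, ``"fn"``, ``"tn"``) with an exact
    count, or a metric name (``"accuracy"``, ``"sensitivity"``,
    ``"specificity"``) with its printed whole-percent value.  Enumeration is
    exhaustive over the (at most min(marginal)+1) feasible tables; published
    performance triples plus marginal counts typically pin a unique table.
    """
    n_pos, n_neg = benefit_marginals
    n_resp, n_nonresp = responder_marginals
    if n_pos + n_neg != n_resp + n_nonresp:
        raise ValueError(
            f"inconsistent marginals: {n_pos}+{n_neg} != {n_resp}+{n_nonresp}"
        )
    constraints = list(constraints)
    out = []
    for tp in range(min(n_pos, n_resp) + 1):
        fn = n_pos - tp
        fp = n_resp - tp
        tn = n_neg - fp
        if min(fn, fp, tn) < 0:
            continue
        table = ConfusionTable(tp, fp, fn, tn)
        if all(_satisfies(table, name, value) for name, value in constraints):
            out.append(table)
    return out


def _satisfies(table: ConfusionTable, name: str, value: float) -> bool:
    if name in ("tp", "fp", "fn", "tn"):
        return getattr(table, name) == value
    raw = _raw_metrics(table)
    if name not in raw:
        return False
    return _matches_printed(raw[name], value)


def kappa_from_counts(
    both_pos: int, a_only: int, b_only: int, both_neg: int
) -> float:
    """Cohen's kappa from the cells of a 2x2 rater-agreement table."""
    n = both_pos + a_only + b_only + both_neg
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (both_pos + both_neg) / n
    pa_pos = (both_pos + a_only) / n
    pb_pos = (both_pos + b_only) / n
    p_e = pa_pos * pb_pos + (1 - pa_pos) * (1 - pb_pos)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters' label vectors.

    Uses marginal-product expected agreement; works for any hashable label
    set.  Returns 1.0 in the degenerate case of two identical constant
    vectors (perfect agreement with no room for chance correction).
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    n = len(labels_a)
    if n < 2:
        raise ValueError("kappa needs at least two rated items")
    labels = sorted(set(labels_a) | set(labels_b), key=repr)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    counts_a = {lab: 0 for lab in labels}
    counts_b = {lab: 0 for lab in labels}
    for a in labels_a:
        counts_a[a] += 1
    for b in labels_b:
        counts_b[b] += 1
    p_e = sum(counts_a[lab] * counts_b[lab] for lab in labels) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def icc_absolute_agreement(
    meas_a: Sequence[float], meas_b: Sequence[float]
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-rater ANOVA mean squares

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 raters and n subjects.  Absolute agreement penalizes a
    systematic offset between raters, unlike a consistency ICC.
    """
    a = np.asarray(meas_a, dtype=float)
    b = np.asarray(meas_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("measurements must be equal-length 1-D sequences")
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least three subjects")
    data = np.column_stack([a, b])
    if np.ptp(data) == 0:
        raise ValueError("ICC is undefined for constant measurements")
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``method="exact"`` enumerates every assignment of the pooled values'
    ranks to the two groups (ties handled by mid-ranks), so the p-value is
    the exact permutation probability of a U at least as far from its null
    mean as observed.  ``method="asymptotic"`` uses the tie-corrected normal
    approximation with continuity correction.  ``"auto"`` picks exact for
    n_x + n_y <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0
    if method == "auto":
        method = "exact" if n <= 12 else "asymptotic"
    if method == "exact":
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        min_rank_sum = nx * (nx + 1) / 2
        for idx in combinations(range(n), nx):
            u = ranks[list(idx)].sum() - min_rank_sum
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
    elif method == "asymptotic":
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return MannWhitneyResult(u=u_obs, p_value=float(p), method=method)


def fisher_exact(table: ConfusionTable) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums the hypergeometric probabilities of every table with the observed
    marginals whose point probability does not exceed that of the observed
    table (within a small relative tolerance for float safety).
    """
    n = table.total
    if n == 0:
        raise ValueError("empty table")
    k_row = table.n_benefit
    k_col = table.n_responders
    rv = sps.hypergeom(n, k_row, k_col)
    lo = max(0, k_col - (n - k_row))
    hi = min(k_row, k_col)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(table.tp)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)
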