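"""Longitudinal tumour-size analysis over the neoadjuvant course.

Works on per-patient timelines of lesion observations (baseline at month 0,
interim scans, final preoperative scan).  Provides baseline-referenced
percentage-change series, time to a shrinkage threshold, the shrinkage-
stagnation summary (how little tumours change after an early deep
response), first-interim prediction of surgical benefit, and between-group
summaries with a Mann-Whitney comparison.

Patients whose timeline has only a baseline and a preoperative scan carry
no interim information and are excluded from trajectory analyses by the
callers (see :func:`with_interim`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .criteria import (
    CriteriaThresholds,
    DEFAULT_THRESHOLDS,
    recist_classify,
    volumetric_classify,
)
from .metrics import LesionObservation, percent_change
from .stats import BenefitLabel, ConfusionTable, binarize_response, mann_whitney_u

__all__ = [
    "PatientTimeline",
    "GroupTrajectorySummary",
    "CohortTrajectorySummary",
    "with_interim",
    "change_series",
    "time_to_threshold",
    "stagnation_summary",
    "early_prediction",
    "group_medians",
]

DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class PatientTimeline:
    """Ordered scans of one patient plus the surgical-benefit label.

    Scans must have strictly increasing month offsets with the baseline at
    month 0, and the baseline lesion must be present.
    """

    patient_id: str
    scans: tuple[LesionObservation, ...]
    benefit: BenefitLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans", tuple(self.scans))
        if len(self.scans) < 2:
            raise ValueError(f"{self.patient_id}: a timeline needs >= 2 scans")
        months = [s.month for s in self.scans]
        if months[0] != 0:
            raise ValueError(f"{self.patient_id}: baseline scan must be at month 0")
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError(f"{self.patient_id}: months must strictly increase")
        if not self.scans[0].present:
            raise ValueError(f"{self.patient_id}: baseline lesion must be present")

    @property
    def baseline(self) -> LesionObservation:
        return self.scans[0]

    @property
    def final(self) -> LesionObservation:
        return self.scans[-1]

    @property
    def has_interim(self) -> bool:
        """True when at least one scan lies between baseline and the final scan."""
        return len(self.scans) >= 3

    @property
    def first_interim(self) -> LesionObservation:
        if not self.has_interim:
            raise ValueError(f"{self.patient_id}: no interim scan")
        return self.scans[1]


def with_interim(timelines: Iterable[PatientTimeline]) -> list[PatientTimeline]:
    """The subset of timelines carrying at least one interim scan."""
    return [t for t in timelines if t.has_interim]


def change_series(
    timeline: PatientTimeline, metric: str = "volume"
) -> list[tuple[float, float]]:
    """Baseline-referenced percentage-change series for one patient.

    Returns ``(month, % change from baseline)`` pairs, including the
    baseline entry ``(0, 0)``.  Changes are always referenced to baseline,
    never chained scan-to-scan.  A disappeared lesion contributes -100 %.
    """
    attr = {"volume": "volume_mm3", "diameter": "diameter_mm"}[metric]
    base = getattr(timeline.baseline, attr)
    if base <= 0:
        raise ValueError(f"zero baseline {metric}")
    return [(s.month, percent_change(base, getattr(s, attr))) for s in timeline.scans]


def time_to_threshold(
    series: Sequence[tuple[float, float]], threshold: float
) -> float | None:
    """Month of the first scan at or beyond a (negative) change threshold.

    Inclusive at the boundary; returns ``None`` when the threshold is never
    reached.  No interpolation between scans: the answer is always an
    observed scan month.
    """
    for month, change in series:
        if change <= threshold:
            return month
    return None


def _iqr(values: Sequence[float]) -> tuple[float, float]:
    return (
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


@dataclass(frozen=True)
class StagnationSummary:
    """Residual volume change after an early threshold crossing."""

    median_pct: float
    iqr_pct: tuple[float, float]
    n: int


def stagnation_summary(
    timelines: Iterable[PatientTimeline],
    threshold: float = -66.0,
    reference: str = "interim",
) -> StagnationSummary:
    """Median residual shrinkage of early deep responders.

    For every patient whose *first interim* scan crosses ``threshold``
    (volume change from baseline), computes the additional volume change
    between the first and second post-baseline scans.  With
    ``reference="interim"`` (default) the residual is a percentage of the
    first-interim volume — the change of the already-shrunken tumour; with
    ``reference="baseline"`` it is a percentage of baseline volume.  The
    summary is the median and IQR of the residual magnitudes.
    """
    if reference not in ("interim", "baseline"):
        raise ValueError(f"unknown reference {reference!r}")
    residuals = []
    for t in timelines:
        if len(t.scans) < 3:
            continue
        base = t.baseline.volume_mm3
        v1 = t.scans[1].volume_mm3
        v2 = t.scans[2].volume_mm3
        if percent_change(base, v1) > threshold:
            continue
        if reference == "interim":
            if v1 <= 0:
                continue
            residuals.append(abs(percent_change(v1, v2)))
        else:
            residuals.append(abs(100.0 * (v2 - v1) / base))
    if not residuals:
        raise ValueError("no patient crosses the threshold at the first interim scan")
    return StagnationSummary(
        median_pct=float(np.median(residuals)), iqr_pct=_iqr(residuals), n=len(residuals)
    )


def early_prediction(
    timelines: Iterable[PatientTimeline],
    criterion: str = "volumetric",
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> ConfusionTable:
    """Predict surgical benefit from the first interim scan alone.

    Classifies baseline vs. first interim under the chosen criterion,
    binarizes (CR or PR = responder), and cross-tabulates against the
    consensus benefit labels.  Every timeline must carry an interim scan.
    """
    classify = {"recist": recist_classify, "volumetric": volumetric_classify}[criterion]
    tp = fp = fn = tn = 0
    timelines = list(timelines)
    if not timelines:
        raise ValueError("no timelines")
    for t in timelines:
        status = classify(t.baseline, t.first_interim, thresholds)
        predicted = binarize_response(status)
        if t.benefit.benefit:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return ConfusionTable(tp, fp, fn, tn)


@dataclass(frozen=True)
class GroupTrajectorySummary:
    """Per-group summary of first-interim response and threshold crossing."""

    n: int
    median_first_interim_change_pct: float
    iqr_first_interim_change_pct: tuple[float, float]
    median_first_interim_month: float
    iqr_first_interim_month: tuple[float, float]
    n_cross_first_interim: int
    n_cross_ever: int
    median_residual_pct: float | None


@dataclass(frozen=True)
class CohortTrajectorySummary:
    benefit: GroupTrajectorySummary
    non_benefit: GroupTrajectorySummary
    threshold_pct: float
    mann_whitney_p: float


def _group_summary(
    group: list[PatientTimeline], threshold: float
) -> GroupTrajectorySummary:
    changes = [change_series(t, "volume")[1][1] for t in group]
    months = [t.first_interim.month for t in group]
    cross_first = sum(c <= threshold for c in changes)
    cross_ever = sum(
        time_to_threshold(change_series(t, "volume"), threshold) is not None
        for t in group
    )
    try:
        residual = stagnation_summary(group, threshold).median_pct
    except ValueError:
        residual = None
    return GroupTrajectorySummary(
        n=len(group),
        median_first_interim_change_pct=float(np.median(changes)),
        iqr_first_interim_change_pct=_iqr(changes),
        median_first_interim_month=float(np.median(months)),
        iqr_first_interim_month=_iqr(months),
        n_cross_first_interim=cross_first,
        n_cross_ever=cross_ever,
        median_residual_pct=residual,
    )


def group_medians(
    timelines: Iterable[PatientTimeline], threshold: float = -66.0
) -> CohortTrajectorySummary:
    """Benefit vs. non-benefit trajectory summaries plus a Mann-Whitney p.

    Quantiles use linear interpolation (numpy's default percentile method).
    The p-value compares the groups' first-interim volume changes.
    """
    timelines = [t for t in timelines if t.has_interim]
    benefit = [t for t in timelines if t.benefit.benefit]
    non_benefit = [t for t in timelines if not t.benefit.benefit]
    if not benefit or not non_benefit:
        raise ValueError("both benefit groups must be non-empty")
    changes_b = [change_series(t, "volume")[1][1] for t in benefit]
    changes_n = [change_series(t, "volume")[1][1] for t in non_benefit]
    p = mann_whitney_u(changes_b, changes_n).p_value
    return CohortTrajectorySummary(
        benefit=_group_summary(benefit, threshold),
        non_benefit=_group_summary(non_benefit, threshold),
        threshold_pct=threshold,
        mann_whitney_p=p,
    )
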