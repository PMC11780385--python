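"""Response classification under RECIST 1.1, volumetric, and Choi criteria.

All three criteria partition a baseline -> follow-up change into exactly one
of CR / PR / SD / PD:

* RECIST 1.1 (single target lesion): CR on disappearance, PR at >=30 %
  diameter reduction, PD at >=20 % diameter increase, SD otherwise.
* Volumetric: PR at >=66 % volume reduction and PD at >=73 % increase.
  These thresholds are the RECIST diameter thresholds mapped through the
  isotropic sphere relation ``(1+d)^3 - 1`` and rounded to whole percent.
* Choi: PR at >=10 % diameter reduction OR >=15 % density (mean HU)
  reduction; PD at >=10 % diameter increase AND a density reduction of
  less than 15 %; the PR clause is evaluated first, so a density responder
  with a growing diameter is PR.

Changes are referenced to baseline (not nadir): the monitoring question is
what the whole neoadjuvant course achieved relative to the pre-treatment
scan.  All threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .metrics import LesionObservation, percent_change

__all__ = [
    "ResponseStatus",
    "CriteriaThresholds",
    "DEFAULT_THRESHOLDS",
    "IncompleteObservationError",
    "recist_classify",
    "volumetric_classify",
    "choi_classify",
    "volume_threshold_from_diameter",
    "classify_all",
    "CRITERIA",
]


class ResponseStatus(str, Enum):
    CR = "CR"  # complete response: disappearance of the primary tumour
    PR = "PR"  # partial response
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease


class IncompleteObservationError(ValueError):
    """A criterion needs a metric (e.g. density) missing from an observation."""


@dataclass(frozen=True)
class CriteriaThresholds:
    """Percentage-change thresholds; comparisons are inclusive.

    PR thresholds are negative (reductions), PD thresholds positive.
    """

    recist_pr: float = -30.0
    recist_pd: float = 20.0
    vol_pr: float = -66.0
    vol_pd: float = 73.0
    choi_diam_pr: float = -10.0
    choi_dens_pr: float = -15.0
    choi_diam_pd: float = 10.0

    def __post_init__(self) -> None:
        for name in ("recist_pr", "vol_pr", "choi_diam_pr", "choi_dens_pr"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative (a reduction threshold)")
        for name in ("recist_pd", "vol_pd", "choi_diam_pd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (an increase threshold)")


DEFAULT_THRESHOLDS = CriteriaThresholds()


def _require_baseline(baseline: LesionObservation, metric: str) -> None:
    if not baseline.present or getattr(baseline, metric) <= 0:
        raise ValueError(f"baseline lesion must be present with positive {metric}")


def recist_classify(
    baseline: LesionObservation,
    follow: LesionObservation,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> ResponseStatus:
    """RECIST 1.1 on the longest transaxial diameter of the single target lesion."""
    _require_baseline(baseline, "diameter_mm")
    if not follow.present:
        return ResponseStatus.CR
    change = percent_change(baseline.diameter_mm, follow.diameter_mm)
    if change <= thresholds.recist_pr:
        return ResponseStatus.PR
    if change >= thresholds.recist_pd:
        return ResponseStatus.PD
    return ResponseStatus.SD


def volumetric_classify(
    baseline: LesionObservation,
    follow: LesionObservation,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> ResponseStatus:
    """Volumetric response on the 3-D VOI volume."""
    _require_baseline(baseline, "volume_mm3")
    if not follow.present:
        return ResponseStatus.CR
    change = percent_change(baseline.volume_mm3, follow.volume_mm3)
    if change <= thresholds.vol_pr:
        return ResponseStatus.PR
    if change >= thresholds.vol_pd:
        return ResponseStatus.PD
    return ResponseStatus.SD


def choi_classify(
    baseline: LesionObservation,
    follow: LesionObservation,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> ResponseStatus:
    """Choi criteria combining diameter and mean-density change.

    PR is evaluated before PD: a lesion whose density drops >=15 % is PR
    even if its diameter grows, honouring the ``<15 % density reduction``
    conjunct of the PD clause.
    """
    _require_baseline(baseline, "diameter_mm")
    if not follow.present:
        return ResponseStatus.CR
    if baseline.density_hu is None or follow.density_hu is None:
        raise IncompleteObservationError(
            "Choi classification needs mean density on both scans"
        )
    d_diam = percent_change(baseline.diameter_mm, follow.diameter_mm)
    d_dens = percent_change(baseline.density_hu, follow.density_hu)
    if d_diam <= thresholds.choi_diam_pr or d_dens <= thresholds.choi_dens_pr:
        return ResponseStatus.PR
    if d_diam >= thresholds.choi_diam_pd and d_dens > thresholds.choi_dens_pr:
        return ResponseStatus.PD
    return ResponseStatus.SD


def volume_threshold_from_diameter(diameter_change: float) -> float:
    """Isotropic volume change equivalent to a fractional diameter change.

    For a sphere shrinking or growing isotropically by a diameter factor
    ``1 + d``, the volume changes by ``(1 + d)^3 - 1``.  This maps the
    RECIST PR/PD diameter thresholds (-0.30 / +0.20) to the volumetric
    thresholds (-0.657 / +0.728, i.e. -66 % / +73 % at whole-percent
    rounding).
    """
    if diameter_change <= -1:
        raise ValueError("diameter change must exceed -1 (total disappearance)")
    return (1.0 + diameter_change) ** 3 - 1.0


CRITERIA = {
    "recist": recist_classify,
    "volumetric": volumetric_classify,
    "choi": choi_classify,
}


def classify_all(
    timeline,
    reference: int | None = None,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> dict[str, ResponseStatus]:
    """Classify baseline vs. a referenced scan under all three criteria.

    ``reference`` indexes into the timeline's scans and defaults to the last
    (preoperative) scan.  Requires at least two scans.
    """
    scans = timeline.scans
    if len(scans) < 2:
        raise ValueError("classification needs a baseline and at least one follow-up")
    follow = scans[-1 if reference is None else reference]
    baseline = scans[0]
    return {name: fn(baseline, follow, thresholds) for name, fn in CRITERIA.items()}
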