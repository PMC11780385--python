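"""End-to-end orchestration: manifest of scans in, analysis reports out.

``run_assess`` reads a manifest CSV (one row per patient/scan/observer)
plus a benefit-label CSV, extracts per-scan lesion metrics from the NIfTI
pairs, classifies every patient under the three criteria, evaluates the
criteria against the benefit labels, runs the trajectory analysis on the
subset with interim scans, and computes interobserver agreement where
duplicate delineations exist.  ``run_simulate`` wraps the synthetic cohort
generator.  All outputs are plain CSV/JSON with stable keys.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import criteria as crit
from . import metrics as met
from . import stats as st
from . import trajectory as traj
from .imaging import read_mask, read_volume
from .simulate import CohortSpec, SyntheticCohort, generate_cohort, write_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_assess", "run_simulate", "load_cohort"]

DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an assessment run."""

    manifest: Path
    labels: Path
    out_dir: Path
    thresholds: crit.CriteriaThresholds = field(default_factory=crit.CriteriaThresholds)
    reference: str | int = "last"  # which scan response is measured against
    trajectory_threshold_pct: float = -66.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        thr = crit.CriteriaThresholds(**d.pop("thresholds", {}))
        return cls(
            manifest=Path(d["manifest"]),
            labels=Path(d["labels"]),
            out_dir=Path(d["out_dir"]),
            thresholds=thr,
            reference=d.get("reference", "last"),
            trajectory_threshold_pct=float(d.get("trajectory_threshold_pct", -66.0)),
            seed=int(d.get("seed", 0)),
        )


def _months_column(df: pd.DataFrame) -> pd.Series:
    """Month offsets from either a numeric ``month`` or a ``scan_date`` column."""
    if "month" in df.columns:
        return df["month"].astype(float)
    if "scan_date" in df.columns:
        dates = pd.to_datetime(df["scan_date"])
        base = dates.groupby(df["patient_id"]).transform("min")
        return (dates - base).dt.days / DAYS_PER_MONTH
    raise ValueError("manifest needs a 'month' or 'scan_date' column")


def _read_labels(path: Path) -> dict[str, st.BenefitLabel]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        observers = None
        if "rater_a" in df.columns and "rater_b" in df.columns:
            observers = (bool(int(row["rater_a"])), bool(int(row["rater_b"])))
        out[str(row["patient_id"])] = st.BenefitLabel(
            str(row["patient_id"]), bool(int(row["benefit"])), observers
        )
    return out


def load_cohort(
    manifest_path: Path, labels_path: Path
) -> tuple[list[traj.PatientTimeline], pd.DataFrame, pd.DataFrame]:
    """Read a manifest of NIfTI scans into patient timelines.

    The primary observer per patient is the lexicographically smallest
    ``observer_id``; rows from other observers are kept aside for agreement
    analysis.  Returns (timelines, per-scan metrics table, agreement table
    of duplicate-observer measurements including Dice per scan pair).
    """
    mdf = pd.read_csv(manifest_path)
    if mdf.empty:
        raise ValueError(f"manifest {manifest_path} is empty")
    mdf = mdf.copy()
    mdf["month"] = _months_column(mdf)
    mdf["patient_id"] = mdf["patient_id"].astype(str)
    labels = _read_labels(labels_path)
    root = manifest_path.parent
    metric_rows = []
    agreement_rows = []
    timelines = []
    for pid, pdf in mdf.groupby("patient_id", sort=True):
        if pid not in labels:
            raise ValueError(f"patient {pid} missing from labels file")
        primary = sorted(pdf["observer_id"].astype(str).unique())[0]
        scans = []
        for month, sdf in pdf.groupby("month", sort=True):
            obs_by_id = {}
            for _, row in sdf.iterrows():
                ct = read_volume(root / str(row["volume_path"]))
                mask = read_mask(root / str(row["mask_path"]), reference=ct.grid)
                obs_by_id[str(row["observer_id"])] = (mask, ct)
            mask, ct = obs_by_id[primary]
            obs = met.observe(mask, ct, month=float(month))
            scans.append(obs)
            metric_rows.append(
                {
                    "patient_id": pid,
                    "month": float(month),
                    "present": obs.present,
                    "volume_mm3": obs.volume_mm3,
                    "diameter_mm": obs.diameter_mm,
                    "density_hu": obs.density_hu,
                }
            )
            for other_id, (other_mask, other_ct) in obs_by_id.items():
                if other_id == primary:
                    continue
                other_obs = met.observe(other_mask, other_ct, month=float(month))
                agreement_rows.append(
                    {
                        "patient_id": pid,
                        "month": float(month),
                        "observer_id": other_id,
                        "dice": met.dice(mask, other_mask),
                        "volume_a": obs.volume_mm3,
                        "volume_b": other_obs.volume_mm3,
                        "diameter_a": obs.diameter_mm,
                        "diameter_b": other_obs.diameter_mm,
                        "density_a": obs.density_hu,
                        "density_b": other_obs.density_hu,
                    }
                )
        timelines.append(traj.PatientTimeline(pid, tuple(scans), labels[pid]))
    return timelines, pd.DataFrame(metric_rows), pd.DataFrame(agreement_rows)


def _classification_rows(
    timelines: list[traj.PatientTimeline],
    thresholds: crit.CriteriaThresholds,
    reference: str | int,
) -> pd.DataFrame:
    ref = None if reference == "last" else int(reference)
    rows = []
    for t in timelines:
        follow = t.scans[-1 if ref is None else ref]
        base = t.baseline
        d_diam = met.percent_change(base.diameter_mm, follow.diameter_mm)
        d_vol = met.percent_change(base.volume_mm3, follow.volume_mm3)
        d_dens = (
            met.percent_change(base.density_hu, follow.density_hu)
            if base.density_hu is not None and follow.density_hu is not None
            else None
        )
        statuses = crit.classify_all(t, ref, thresholds)
        for criterion, status in statuses.items():
            rows.append(
                {
                    "patient_id": t.patient_id,
                    "criterion": criterion,
                    "percent_change_diameter": d_diam,
                    "percent_change_volume": d_vol,
                    "percent_change_density": d_dens,
                    "status": status.value,
                }
            )
    return pd.DataFrame(rows)


def _confusion(
    timelines: list[traj.PatientTimeline], statuses: dict[str, crit.ResponseStatus]
) -> st.ConfusionTable:
    tp = fp = fn = tn = 0
    for t in timelines:
        predicted = st.binarize_response(statuses[t.patient_id])
        if t.benefit.benefit:
            tp += predicted
            fn += not predicted
        else:
            fp += predicted
            tn += not predicted
    return st.ConfusionTable(tp, fp, fn, tn)


def _agreement_report(
    adf: pd.DataFrame, labels: list[st.BenefitLabel]
) -> dict:
    report: dict = {}
    if not adf.empty:
        report["dice_mean"] = float(adf["dice"].mean())
        report["dice_sd"] = float(adf["dice"].std(ddof=1)) if len(adf) > 1 else 0.0
        report["n_duplicate_scans"] = int(len(adf))
        for name in ("volume", "diameter", "density"):
            a = adf[f"{name}_a"].astype(float)
            b = adf[f"{name}_b"].astype(float)
            ok = a.notna() & b.notna()
            if ok.sum() >= 3 and np.ptp(np.concatenate([a[ok], b[ok]])) > 0:
                report[f"icc_{name}"] = st.icc_absolute_agreement(a[ok], b[ok])
            else:
                report[f"icc_{name}"] = None
    rated = [l for l in labels if l.observer_labels is not None]
    if len(rated) >= 2:
        report["kappa_surgical_benefit"] = st.cohens_kappa(
            [l.observer_labels[0] for l in rated],
            [l.observer_labels[1] for l in rated],
        )
    return report


def run_assess(config: RunConfig) -> dict[str, Path]:
    """Run the full assessment; returns the paths of the written reports."""
    timelines, metrics_df, agreement_df = load_cohort(config.manifest, config.labels)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["metrics"] = out / "metrics.csv"
    metrics_df.to_csv(paths["metrics"], index=False)

    cls_df = _classification_rows(timelines, config.thresholds, config.reference)
    paths["classifications"] = out / "classifications.csv"
    cls_df.to_csv(paths["classifications"], index=False)

    performance = {}
    for criterion in ("recist", "volumetric", "choi"):
        sub = cls_df[cls_df["criterion"] == criterion]
        statuses = {
            row["patient_id"]: crit.ResponseStatus(row["status"])
            for _, row in sub.iterrows()
        }
        table = _confusion(timelines, statuses)
        performance[criterion] = st.performance_report(table)
    paths["performance"] = out / "performance.json"
    paths["performance"].write_text(json.dumps(performance, indent=2))

    agreement = _agreement_report(agreement_df, [t.benefit for t in timelines])
    paths["agreement"] = out / "agreement.json"
    paths["agreement"].write_text(json.dumps(agreement, indent=2))

    subset = traj.with_interim(timelines)
    trajectory_report: dict = {"n_with_interim": len(subset)}
    if subset:
        long_rows = []
        for t in subset:
            for metric in ("volume", "diameter"):
                for month, change in traj.change_series(t, metric):
                    long_rows.append(
                        {
                            "patient_id": t.patient_id,
                            "month": month,
                            "metric": metric,
                            "percent_change": change,
                            "benefit": t.benefit.benefit,
                        }
                    )
        paths["trajectory_long"] = out / "trajectory_long.csv"
        pd.DataFrame(long_rows).to_csv(paths["trajectory_long"], index=False)
        groups = {t.benefit.benefit for t in subset}
        if groups == {True, False}:
            summary = traj.group_medians(subset, config.trajectory_threshold_pct)
            trajectory_report["group_summary"] = dataclasses.asdict(summary)
            for criterion in ("recist", "volumetric"):
                table = traj.early_prediction(subset, criterion, config.thresholds)
                trajectory_report[f"early_{criterion}"] = st.performance_report(table)
    paths["trajectory_summary"] = out / "trajectory_summary.json"
    paths["trajectory_summary"].write_text(json.dumps(trajectory_report, indent=2))
    log.info("assessment complete: %d patients, reports in %s", len(timelines), out)
    return paths


def run_simulate(
    spec: CohortSpec, out_dir: Path, render: bool = True
) -> tuple[SyntheticCohort, dict[str, Path]]:
    """Generate a synthetic cohort and write its artifacts."""
    cohort = generate_cohort(spec)
    paths = write_cohort(cohort, out_dir, render=render)
    log.info(
        "simulated %d patients (%d benefit / %d non-benefit) into %s",
        len(cohort.patients),
        spec.n_benefit,
        spec.n_nonbenefit,
        out_dir,
    )
    return cohort, paths
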