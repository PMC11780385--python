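"""Synthetic voxelized GIST cohorts with plateauing shrinkage trajectories.

The generator emulates the statistical structure the analysis assumes, so
every downstream module is testable without clinical data:

* Tumour volume follows a plateauing exponential decay
  ``v(t) = v0 * (p + (1 - p) exp(-t / tau))`` — a fast initial response
  that stagnates at a residual fraction ``p`` of baseline.  Surgical-benefit
  patients draw ``p`` from a deep-response range (final reduction beyond the
  66 % volumetric PR threshold), non-benefit patients from a shallow range.
* Lesions are ellipsoids rendered on a voxel grid by a centre-inside test;
  anisotropy exponents distribute the volume shrinkage unevenly over the
  three semi-axes (all-axial shrinkage reproduces the discordance where
  volume collapses while the transaxial diameter is unchanged).
* Mean density declines by a patient-specific asymptotic fraction; the
  per-group probability of being a density responder governs Choi
  behaviour.
* Observer-duplicate masks perturb the boundary by thresholding the signed
  distance plus a smooth random field, calibrated to a target Dice score.

Everything is reproducible from a single integer seed; per-patient streams
are split with spawned seed sequences so patients are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import CTVolume, ImageGrid, LesionMask, write_mask, write_volume
from .metrics import EmptyMaskError, LesionObservation, dice
from .stats import BenefitLabel
from .trajectory import PatientTimeline

__all__ = [
    "TrajectoryParams",
    "CohortSpec",
    "PatientRecord",
    "SyntheticCohort",
    "volume_at",
    "density_at",
    "remaining_fraction",
    "base_semi_axes",
    "semi_axes_at",
    "render_lesion",
    "perturb_mask",
    "calibrate_perturbation",
    "generate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Ground-truth trajectory of one synthetic tumour.

    ``plateau_fraction`` is the asymptotic remaining-volume fraction,
    ``tau_months`` the decay time constant, ``density_drop_frac`` the
    asymptotic fractional decrease in mean HU, ``anisotropy`` the per-axis
    shrink exponents (non-negative, summing to 1: semi-axis i scales with
    the remaining fraction to the power ``anisotropy[i]``), and
    ``axis_ratios`` the baseline semi-axis shape ratios.
    """

    v0_mm3: float
    plateau_fraction: float
    tau_months: float
    density0_hu: float = 60.0
    density_drop_frac: float = 0.3
    anisotropy: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.v0_mm3 <= 0:
            raise ValueError("baseline volume must be positive")
        if not (0 < self.plateau_fraction <= 1):
            raise ValueError("plateau fraction must lie in (0, 1]")
        if self.tau_months <= 0:
            raise ValueError("decay time constant must be positive")
        if any(a < 0 for a in self.anisotropy) or not math.isclose(
            sum(self.anisotropy), 1.0, abs_tol=1e-9
        ):
            raise ValueError("anisotropy exponents must be >= 0 and sum to 1")
        if any(r <= 0 for r in self.axis_ratios):
            raise ValueError("axis ratios must be positive")


def remaining_fraction(params: TrajectoryParams, month: float) -> float:
    """v(t)/v0 under the plateauing exponential decay model."""
    if month < 0:
        raise ValueError("month must be non-negative")
    p = params.plateau_fraction
    return p + (1.0 - p) * math.exp(-month / params.tau_months)


def volume_at(params: TrajectoryParams, month: float) -> float:
    """Tumour volume in mm^3 at a given month; v0 at month 0, v0*p as t -> inf."""
    return params.v0_mm3 * remaining_fraction(params, month)


def density_at(params: TrajectoryParams, month: float) -> float:
    """Mean HU at a given month: the density declines on the same time scale."""
    if month < 0:
        raise ValueError("month must be non-negative")
    decline = params.density_drop_frac * (1.0 - math.exp(-month / params.tau_months))
    return params.density0_hu * (1.0 - decline)


def base_semi_axes(
    volume_mm3: float, axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> np.ndarray:
    """Ellipsoid semi-axes (mm) with the given shape ratios and analytic volume."""
    k = np.asarray(axis_ratios, dtype=float)
    r = (3.0 * volume_mm3 / (4.0 * math.pi * float(np.prod(k)))) ** (1.0 / 3.0)
    return r * k


def semi_axes_at(
    params: TrajectoryParams, month: float, fraction: float | None = None
) -> np.ndarray:
    """Semi-axes at a given month (or explicit remaining fraction).

    Each axis scales as fraction**anisotropy[i]; since the exponents sum to
    1 the ellipsoid volume scales exactly with the fraction.
    """
    f = remaining_fraction(params, month) if fraction is None else fraction
    base = base_semi_axes(params.v0_mm3, params.axis_ratios)
    return base * f ** np.asarray(params.anisotropy)


def render_lesion(
    volume_mm3: float,
    grid: ImageGrid,
    center_voxel: tuple[float, float, float] | None = None,
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0),
    density_hu: float = 60.0,
    background_hu: float = 0.0,
) -> tuple[LesionMask, CTVolume]:
    """Voxelize an ellipsoid of the requested analytic volume.

    The mask contains every voxel whose centre lies inside the ellipsoid;
    the paired CT volume has uniform interior HU ``density_hu`` on the
    background.  A zero volume yields an empty mask.  Raises when the
    ellipsoid does not fit inside the grid.
    """
    shape = grid.shape
    spacing = np.asarray(grid.spacing)
    if center_voxel is None:
        center_voxel = tuple((s - 1) / 2.0 for s in shape)
    center = np.asarray(center_voxel, dtype=float) * spacing
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    if volume_mm3 == 0:
        mask = LesionMask(grid, np.zeros(shape, dtype=np.uint8))
        ct = CTVolume(grid, np.full(shape, background_hu, dtype=float))
        return mask, ct
    semi = base_semi_axes(volume_mm3, axis_ratios)
    extent_lo = center - semi
    extent_hi = center + semi
    grid_hi = (np.asarray(shape) - 1) * spacing
    if np.any(extent_lo < -spacing / 2) or np.any(extent_hi > grid_hi + spacing / 2):
        raise ValueError(
            f"lesion with semi-axes {np.round(semi, 1)} mm at centre "
            f"{np.round(center, 1)} mm exceeds grid extent {np.round(grid_hi, 1)} mm"
        )
    axes = [
        ((np.arange(shape[i]) * spacing[i] - center[i]) / semi[i]) ** 2
        for i in range(3)
    ]
    q = (
        axes[0][:, None, None]
        + axes[1][None, :, None]
        + axes[2][None, None, :]
    )
    inside = q <= 1.0
    mask = LesionMask(grid, inside.astype(np.uint8))
    ct_values = np.where(inside, density_hu, background_hu).astype(float)
    return mask, CTVolume(grid, ct_values)


def _signed_distance_mm(mask: LesionMask) -> np.ndarray:
    """Distance to the boundary in mm, positive inside the lesion."""
    inside = ndimage.distance_transform_edt(mask.values, sampling=mask.grid.spacing)
    outside = ndimage.distance_transform_edt(
        1 - mask.values, sampling=mask.grid.spacing
    )
    return inside - outside


def perturb_mask(
    mask: LesionMask,
    amplitude_mm: float,
    seed: int | np.random.Generator,
    correlation_mm: float = 3.0,
) -> LesionMask:
    """Observer-style boundary perturbation of a mask.

    Adds a smooth unit-variance random field, scaled by ``amplitude_mm``,
    to the signed boundary distance and re-thresholds at zero.  Amplitude 0
    reproduces the mask exactly; the expected Dice overlap with the
    original decreases monotonically with amplitude.  Deterministic given
    the seed.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot perturb an empty mask")
    if amplitude_mm < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude_mm == 0:
        return LesionMask(mask.grid, mask.values.copy())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sigma_vox = [correlation_mm / s for s in mask.grid.spacing]
    noise = ndimage.gaussian_filter(
        rng.standard_normal(mask.grid.shape), sigma=sigma_vox
    )
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    perturbed = (_signed_distance_mm(mask) + amplitude_mm * noise) > 0
    return LesionMask(mask.grid, perturbed.astype(np.uint8))


def calibrate_perturbation(
    mask: LesionMask,
    target_dice: float,
    n_seeds: int = 8,
    seed: int = 0,
    max_amplitude_mm: float = 8.0,
    iterations: int = 14,
) -> float:
    """Amplitude (mm) whose mean Dice vs. the original hits ``target_dice``.

    Bisection on the empirical calibration curve (mean Dice over
    ``n_seeds`` perturbation seeds as a function of amplitude), which is
    monotone decreasing in expectation.
    """
    if not (0 < target_dice < 1):
        raise ValueError("target Dice must lie in (0, 1)")

    def mean_dice(amp: float) -> float:
        return float(
            np.mean(
                [dice(mask, perturb_mask(mask, amp, seed + k)) for k in range(n_seeds)]
            )
        )

    lo, hi = 0.0, max_amplitude_mm
    if mean_dice(hi) > target_dice:
        return hi
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if mean_dice(mid) > target_dice:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults mirror the monitored trajectory subset of a neoadjuvant GIST
    cohort: 19 surgical-benefit and 11 non-benefit patients, baseline
    volumes log-uniform over 50-2000 mL (tumours of roughly 5-16 cm),
    deep-response plateaus for the benefit group (final reduction 68-85 %)
    and shallow plateaus for the non-benefit group (10-45 %), a first
    interim scan around 2-3.5 months (slightly later in the benefit group),
    later scans at 6.6 and 9 months, and most patients responding in
    density so the Choi criteria call far more PRs than the size criteria.

    Decay time constants are drawn log-uniformly: most tumours finish
    shrinking within the first interim interval (hence the stagnation
    pattern), while a slow minority crosses the 66 % threshold only later.
    """

    n_benefit: int = 19
    n_nonbenefit: int = 11
    benefit_plateau: tuple[float, float] = (0.15, 0.32)
    nonbenefit_plateau: tuple[float, float] = (0.55, 0.90)
    tau_range_months: tuple[float, float] = (0.35, 2.2)
    benefit_interim_month: tuple[float, float] = (2.6, 3.5)
    nonbenefit_interim_month: tuple[float, float] = (2.0, 2.8)
    later_months: tuple[float, ...] = (6.6, 9.0)
    v0_range_mm3: tuple[float, float] = (5e4, 2e6)
    density0_range_hu: tuple[float, float] = (40.0, 80.0)
    benefit_density_responder_p: float = 0.95
    nonbenefit_density_responder_p: float = 0.76
    responder_density_drop: tuple[float, float] = (0.20, 0.50)
    nonresponder_density_drop: tuple[float, float] = (0.0, 0.10)
    axis_ratio_range: tuple[float, float] = (0.8, 1.25)
    anisotropy: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    volume_noise_sigma: float = 0.0
    observer_amplitude_mm: float = 1.0
    observer_label_flip_p: float = 0.0
    spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benefit < 0 or self.n_nonbenefit < 0:
            raise ValueError("group sizes must be non-negative")
        for name in ("benefit_plateau", "nonbenefit_plateau"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi <= 1")
        if self.later_months and sorted(self.later_months) != list(self.later_months):
            raise ValueError("later_months must be increasing")
        if self.volume_noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: ground truth plus the derived timeline."""

    patient_id: str
    benefit: bool
    params: TrajectoryParams
    months: tuple[float, ...]
    measured_fractions: tuple[float, ...]
    timeline: PatientTimeline


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    patients: tuple[PatientRecord, ...]

    @property
    def timelines(self) -> list[PatientTimeline]:
        return [p.timeline for p in self.patients]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "benefit": p.benefit,
                    "v0_mm3": p.params.v0_mm3,
                    "plateau_fraction": p.params.plateau_fraction,
                    "tau_months": p.params.tau_months,
                    "density0_hu": p.params.density0_hu,
                    "density_drop_frac": p.params.density_drop_frac,
                }
            )
        return pd.DataFrame(rows)


def _draw_patient(
    rng: np.random.Generator, spec: CohortSpec, benefit: bool, patient_id: str
) -> PatientRecord:
    v0 = float(
        np.exp(rng.uniform(*np.log(spec.v0_range_mm3)))
    )
    plateau = float(rng.uniform(*(spec.benefit_plateau if benefit else spec.nonbenefit_plateau)))
    tau = float(np.exp(rng.uniform(*np.log(spec.tau_range_months))))
    m1 = float(
        rng.uniform(
            *(spec.benefit_interim_month if benefit else spec.nonbenefit_interim_month)
        )
    )
    density0 = float(rng.uniform(*spec.density0_range_hu))
    responder_p = (
        spec.benefit_density_responder_p if benefit else spec.nonbenefit_density_responder_p
    )
    is_density_responder = bool(rng.random() < responder_p)
    drop = float(
        rng.uniform(
            *(
                spec.responder_density_drop
                if is_density_responder
                else spec.nonresponder_density_drop
            )
        )
    )
    ratios = tuple(float(r) for r in rng.uniform(*spec.axis_ratio_range, size=3))
    params = TrajectoryParams(
        v0_mm3=v0,
        plateau_fraction=plateau,
        tau_months=tau,
        density0_hu=density0,
        density_drop_frac=drop,
        anisotropy=spec.anisotropy,
        axis_ratios=ratios,
    )
    months = (0.0, m1, *spec.later_months)
    fractions = []
    scans = []
    in_plane = (0, 1)  # rendered grids use axial axis 2
    for month in months:
        f = remaining_fraction(params, month)
        if spec.volume_noise_sigma > 0 and month > 0:
            f *= float(np.exp(spec.volume_noise_sigma * rng.standard_normal()))
        fractions.append(f)
        semi = semi_axes_at(params, month, fraction=f)
        scans.append(
            LesionObservation(
                present=True,
                volume_mm3=v0 * f,
                diameter_mm=2.0 * float(max(semi[list(in_plane)])),
                density_hu=density_at(params, month),
                month=month,
            )
        )
    flip = rng.random(2) < spec.observer_label_flip_p
    observer_labels = (bool(benefit ^ flip[0]), bool(benefit ^ flip[1]))
    label = BenefitLabel(patient_id, benefit, observer_labels)
    timeline = PatientTimeline(patient_id, tuple(scans), label)
    return PatientRecord(
        patient_id=patient_id,
        benefit=benefit,
        params=params,
        months=months,
        measured_fractions=tuple(fractions),
        timeline=timeline,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort, reproducible from ``spec.seed``.

    Benefit patients draw shrinkage plateaus from the deep-response range
    so their final volumetric status is PR; non-benefit patients from the
    shallow range so theirs is SD (at zero measurement noise).
    """
    n_total = spec.n_benefit + spec.n_nonbenefit
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    patients = []
    for i in range(n_total):
        benefit = i < spec.n_benefit
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        patients.append(_draw_patient(rng, spec, benefit, pid))
    return SyntheticCohort(spec=spec, patients=tuple(patients))


def _patient_grid(record: PatientRecord, spacing: float) -> ImageGrid:
    """Auto-sized grid fitting the baseline lesion with a safety margin."""
    semi = base_semi_axes(record.params.v0_mm3, record.params.axis_ratios)
    shape = tuple(int(math.ceil(2 * (s + 4 * spacing) / spacing)) | 1 for s in semi)
    return ImageGrid(shape=shape, spacing=(spacing,) * 3, axial_axis=2)


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    render: bool = True,
    n_observer_pairs: int = 10,
) -> dict[str, Path]:
    """Write cohort artifacts: manifest + labels + truth CSVs, NIfTI pairs.

    With ``render=True``, every scan is voxelized on a per-patient grid and
    written as a (CT volume, mask) NIfTI pair; the first
    ``n_observer_pairs`` patients additionally get an observer-perturbed
    duplicate of their baseline mask (observer id ``obs2``) for
    interobserver analysis.  Without rendering only the tabular ground
    truth and analytic metrics are written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    manifest_rows = []
    metric_rows = []
    obs_seed = np.random.SeedSequence((spec.seed, 0xD1CE)).generate_state(1)[0]
    for idx, rec in enumerate(cohort.patients):
        grid = _patient_grid(rec, spec.spacing_mm) if render else None
        for j, (month, f) in enumerate(zip(rec.months, rec.measured_fractions)):
            obs = rec.timeline.scans[j]
            metric_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "month": month,
                    "present": obs.present,
                    "volume_mm3": obs.volume_mm3,
                    "diameter_mm": obs.diameter_mm,
                    "density_hu": obs.density_hu,
                }
            )
            if not render:
                continue
            semi = semi_axes_at(rec.params, month, fraction=f)
            ratios = tuple(semi / float(np.max(semi)))
            mask, ct = render_lesion(
                rec.params.v0_mm3 * f,
                grid,
                axis_ratios=ratios,
                density_hu=density_at(rec.params, month),
            )
            vol_path = out / f"{rec.patient_id}_m{j}_ct.nii.gz"
            mask_path = out / f"{rec.patient_id}_m{j}_mask_obs1.nii.gz"
            write_volume(ct, vol_path)
            write_mask(mask, mask_path)
            manifest_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "month": month,
                    "volume_path": vol_path.name,
                    "mask_path": mask_path.name,
                    "observer_id": "obs1",
                }
            )
            if j == 0 and idx < n_observer_pairs and spec.observer_amplitude_mm > 0:
                dup = perturb_mask(
                    mask, spec.observer_amplitude_mm, seed=int(obs_seed) + idx
                )
                dup_path = out / f"{rec.patient_id}_m{j}_mask_obs2.nii.gz"
                write_mask(dup, dup_path)
                manifest_rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "month": month,
                        "volume_path": vol_path.name,
                        "mask_path": dup_path.name,
                        "observer_id": "obs2",
                    }
                )
    paths = {}
    paths["truth"] = out / "truth.csv"
    cohort.truth_frame().to_csv(paths["truth"], index=False)
    paths["labels"] = out / "labels.csv"
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "benefit": int(p.benefit),
                "rater_a": int(p.timeline.benefit.observer_labels[0]),
                "rater_b": int(p.timeline.benefit.observer_labels[1]),
            }
            for p in cohort.patients
        ]
    ).to_csv(paths["labels"], index=False)
    paths["metrics"] = out / "analytic_metrics.csv"
    pd.DataFrame(metric_rows).to_csv(paths["metrics"], index=False)
    if render:
        paths["manifest"] = out / "manifest.csv"
        pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    return paths
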