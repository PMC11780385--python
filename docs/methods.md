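# Methods

## Measurement model

All metrics derive from a voxel grid with per-axis physical spacing (mm)
and a designated *axial* axis (anatomical inferior–superior; inferred from
the NIfTI affine, falling back to array axis 2 with a logged warning when
orientation metadata is unusable). Physical positions are voxel centres at
`index × spacing`, 0-based. Masks are strictly binary; any nonzero voxel
read from file is binarized to 1. Two images must agree in shape and in
spacing to 1 mdm (1e-3 mm) to share a grid — loose enough to absorb header
round-trip noise, tight enough to catch genuine mismatches. Measurements
are taken on the native grid; no resampling or registration is performed
(grids of different geometry are rejected, not interpolated).

* **Volume** = tumour-voxel count × voxel volume. Exact for the binary
  model; the voxelization error of a rendered ellipsoid is O(spacing/r).
* **Longest transaxial diameter** = the maximum Euclidean distance between
  tumour-voxel *centres* within any single transaxial slice, using the
  in-plane spacing. No half-voxel edge correction and no 3-D chord: the
  convention is unambiguous and oracle-checkable, is applied identically
  to baseline and follow-up (percentage changes are therefore insensitive
  to it), and keeps the measurement in the axial plane as the RECIST
  recommendation requires. The implementation restricts the all-pairs
  search to 2-D convex-hull vertices for slices with more than 16 points
  (the diameter endpoints are hull vertices); degenerate collinear slices
  fall back to the direct search. Empty and single-voxel masks have zero
  extent between centres and return 0.
* **Mean density** = arithmetic mean HU over all VOI voxels; no trimming,
  erosion, or partial-volume exclusion. Undefined (an error) for an empty
  mask.
* **Dice** = 2|A∩B| / (|A|+|B|), defined as 1 when both masks are empty
  (agreement on absence).

## Response criteria

Each criterion is a total function onto {CR, PR, SD, PD}; all threshold
comparisons are inclusive (≥/≤). Changes are percentage changes from
*baseline*, not from the nadir: the monitoring question is what the whole
neoadjuvant course achieved relative to the pre-treatment scan, and the
single-lesion, no-new-metastasis setting removes the need for RECIST's
non-target and new-lesion machinery. CR is disappearance of the lesion.

The volumetric PR/PD thresholds are not free parameters: they are the
RECIST diameter thresholds pushed through the isotropic sphere relation
Δv = (1 + Δd)³ − 1, giving −65.7 % → −66 % and +72.8 % → +73 % at
whole-percent rounding. A consequence tested as an invariant: for an
isotropically rescaled lesion the RECIST and volumetric categories agree
away from the rounding boundaries.

In the Choi criteria the PR clause (diameter −10 % **or** density −15 %)
is evaluated before the PD clause (diameter +10 % **and** density reduction
< 15 %), honouring the conjunction literally: a density responder whose
diameter grows is PR, not PD. Choi's original intratumoral-nodule PD
clause is out of scope. Rounding (half away from zero, whole percent) is
applied only to *reported* values, never inside a classification.

## Diagnostic evaluation

A patient is a predicted *responder* when the final status is CR or PR;
the reference label is adjudicated surgical benefit. Sensitivity is the
responder rate among benefit patients, specificity the non-responder rate
among non-benefit patients. Published triples are sometimes printed with
these two labels transposed, and the orientation cannot be recovered from
a printed triple alone — reports therefore emit both orientations with an
explanatory note rather than guessing.

**Marginal reconstruction.** Given the benefit split and a criterion's
responder count, every feasible integer 2×2 table is enumerated (there are
at most min(marginal)+1). Constraints — a structural cell value such as
`fp = 0` (forced whenever a 100 % metric is printed for a criterion whose
responder count is below the benefit count), or a printed whole-percent
metric — filter the set, typically to a single table. A printed metric
matches if it equals the metric rounded half away from zero directly *or*
after first rounding to one decimal (double rounding, e.g. 95.45 → 95.5 →
96, occurs in clinical reporting; accepting either form is required for
one published Choi companion metric and never admits a second table in
the cases exercised here).

**Agreement statistics.** Cohen's κ uses marginal-product expected
agreement (κ defined as 1 for two identical constant vectors). The ICC is
ICC(2,1) — two-way random effects, absolute agreement, single rater — from
the two-rater mean-squares decomposition; absolute agreement is the right
form when a systematic offset between observers must count against
reliability. The form is a package choice; cross-checked in tests against
an independent ANOVA oracle and pingouin.

**Hypothesis tests.** Mann–Whitney U is exact (full enumeration of rank
assignments, midranks for ties) for n₁+n₂ ≤ 12 and a tie-corrected normal
approximation with continuity correction beyond; the cutoff keeps the
exact path under C(12,6) = 924 enumerations. Fisher's exact test uses the
point-probability two-sided method (sum of hypergeometric probabilities no
larger than the observed table's), the dominant convention in statistics
references; scipy's implementation serves as an independent cross-check in
tests, never as the implementation.

## Trajectory analysis

Change series are baseline-referenced (appending scans never alters
earlier entries). Time-to-threshold is the month of the first scan at or
beyond the threshold, with no interpolation — the answer is always an
observed scan. The *first interim* scan is the first scan after baseline
that is not the final preoperative scan; patients with only baseline and
preoperative scans carry no interim information and are excluded from
trajectory analyses. Quantiles use linear interpolation (numpy default).

The stagnation summary takes, for each patient whose first interim scan
crosses the threshold, the additional volume change between the first and
second post-baseline scans. By default the residual is expressed relative
to the *first-interim* volume — "reduced only slightly" describes the
subsequent change of the already-shrunken tumour — with the
baseline-referenced alternative available as a flag, since either reading
of a published residual is defensible. When a patient's second
post-baseline scan is the final scan, that scan plays the role of the
second interim.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a monitored
neoadjuvant cohort, not CT appearance. Defaults (a `CohortSpec`):

| parameter | default | rationale |
|---|---|---|
| group sizes | 19 benefit / 11 non-benefit | monitored-subset split |
| baseline volume v₀ | log-uniform 50–2000 mL | ~5–16 cm tumours |
| plateau fraction p (benefit) | uniform 0.15–0.32 | final reduction 68–85 %, safely beyond the −66 % PR threshold |
| plateau fraction p (non-benefit) | uniform 0.55–0.90 | final reduction 10–45 %, SD |
| decay constant τ | log-uniform 0.35–2.2 months | most tumours finish shrinking before the first interim scan (small residual change afterwards) while a slow minority crosses the threshold only later; the log-uniform spread jointly reproduces a ~72 %/~25 % group-median early reduction, roughly 14/19 first-scan crossers, and a few-percent stagnation residual |
| first interim scan | uniform 2.6–3.5 mo (benefit), 2.0–2.8 mo (non-benefit) | typical interim intervals, slightly later in the benefit group |
| later scans | 6.6 and 9.0 months | second interim and preoperative |
| baseline density | uniform 40–80 HU | portal-venous soft-tissue range; only relative change matters |
| density responders | 95 % (benefit) / 76 % (non-benefit) | drives Choi PR counts far above the size criteria's |
| density drop | 20–50 % (responders), 0–10 % (non-) | clear of the −15 % Choi threshold on both sides |
| axis ratios | uniform 0.8–1.25 per axis | mildly non-spherical lesions |
| anisotropy exponents | (⅓, ⅓, ⅓) | isotropic shrinkage unless a discordance case is requested |
| volume noise σ | 0 | lognormal multiplicative measurement noise, off by default |

Volume follows v(t) = v₀·(p + (1−p)·e^(−t/τ)) — the minimal plateauing
form consistent with a fast-then-stagnant response; it is generator-only
and never used for inference. Lesion semi-axes scale as f^aᵢ with the
remaining fraction f and exponents aᵢ summing to 1, so the analytic volume
scales exactly with f; concentrating the exponents on the axial axis
reproduces the discordance where volume collapses while the transaxial
diameter is unchanged. Measurement noise multiplies f (so measured volume
and diameter stay mutually consistent). Density declines on the same time
scale toward its asymptotic drop.

Rendering voxelizes the ellipsoid by a centre-inside test on an
auto-sized per-patient grid (baseline extent plus a 4-voxel margin) at
1 mm isotropic spacing by default. Observer-duplicate masks threshold the
signed boundary distance plus a smooth (3 mm correlation) unit-variance
Gaussian field scaled by an amplitude in mm; amplitude 0 is the identity,
expected Dice decreases monotonically with amplitude, and
`calibrate_perturbation` bisects the empirical calibration curve to hit a
target Dice (≈1 mm amplitude yields Dice ≈ 0.92 on a 10 mm sphere).
Per-patient randomness comes from spawned seed sequences, so patients are
independent and cohorts bit-reproducible from one integer seed.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: CT texture, organs, contrast phases, partial
volume at real boundaries, inter-scanner attenuation variability (a known
confounder of Choi density measurements), multi-lesion disease, irregular
scan schedules, and genuinely progressing tumours (volumes only shrink
under the default model). Results on synthetic cohorts validate the
*computational* pipeline, not the clinical performance of the criteria.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately compact
problems: rendered grids up to ~140³ voxels at 0.5–1 mm spacing, cohorts
of 30 analytic timelines, 200 replicate cohorts for parameter-recovery
checks, and 20–25 perturbation seeds for Dice calibration — sizes at which
every check completes in seconds while voxelization tolerances (volume
within 2–3 %, diameter within one in-plane voxel diagonal) are
comfortably met. Hypothesis-based property tests run derandomized. All
stochastic computations are seeded; the acceptance script derives every
stream from its `--seed` argument.

## Known limitations

* Diameters are measured between voxel centres, so a rendered sphere's
  measured diameter is biased low by up to one voxel; conclusions rest on
  percentage changes, which cancel the convention.
* The exact Mann–Whitney path is O(C(n, n₁)) and restricted to n ≤ 12;
  larger samples use the tie-corrected approximation (within 0.02 of exact
  at the crossover in tests).
* `reconstruct_table` assumes the printed marginals are themselves exact
  counts; it cannot repair internally inconsistent published triples (one
  published early-prediction triple admits no integer table at its stated
  n and is deliberately not reconstructed).
* Nadir-referenced RECIST progression, non-target/new-lesion rules, and
  multi-lesion sums of diameters are out of scope for this single-lesion
  setting.
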