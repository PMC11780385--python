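# gistmon

CT-based response monitoring for neoadjuvant-treated gastrointestinal
stromal tumours (GIST).

Patients with localised GIST often receive tyrosine kinase inhibitors
(TKIs, e.g. imatinib) before surgery to shrink the tumour and de-escalate
the operation. Whether that *surgical benefit* materialises is monitored on
serial contrast-enhanced CT with competing response criteria. `gistmon`
implements that monitoring pipeline as a tested, reusable library plus CLI:

* **Lesion morphometry** from 3-D binary volumes of interest (VOIs) on CT:
  tumour volume, longest transaxial diameter, mean attenuation (HU), and
  the Dice similarity coefficient between duplicate delineations.
* **Response classification** of a baseline → follow-up change into
  CR/PR/SD/PD under three criteria (inclusive thresholds, changes
  referenced to baseline):
  * RECIST 1.1 (single target lesion): PR at Δd ≤ −30 %, PD at Δd ≥ +20 %;
  * Volumetric: PR at Δv ≤ −66 %, PD at Δv ≥ +73 %, the RECIST thresholds
    mapped through the isotropic sphere relation Δv = (1 + Δd)³ − 1;
  * Choi: PR at Δd ≤ −10 % **or** ΔHU ≤ −15 %; PD at Δd ≥ +10 % **and**
    ΔHU > −15 %.
* **Diagnostic evaluation** of binarized response (CR∪PR) against
  surgical-benefit labels: confusion tables, accuracy/sensitivity/
  specificity (both label orientations), exhaustive reconstruction of 2×2
  tables from published marginal counts, Cohen's κ, ICC(2,1), exact
  Mann–Whitney U, and Fisher's exact test.
* **Trajectory analysis** of shrinkage over the treatment course:
  baseline-referenced change series, time-to-threshold, shrinkage
  stagnation after an early deep response, and prediction of surgical
  benefit from the first interim scan alone.
* **Synthetic cohorts**: voxelized ellipsoidal lesions following a
  plateauing exponential decay v(t) = v₀·(p + (1−p)·e^(−t/τ)), with
  anisotropic-shrinkage cases, density decline, observer-perturbed
  duplicate masks, and benefit labels — so the whole pipeline runs and is
  validated without any clinical data.

Volumes and masks are NIfTI (via nibabel); tabular inputs and reports are
CSV/JSON.

## Worked example

```python
from gistmon import CohortSpec, generate_cohort, classify_all
from gistmon.trajectory import group_medians, stagnation_summary

cohort = generate_cohort(CohortSpec(seed=1))   # 19 benefit / 11 non-benefit
statuses = [classify_all(t) for t in cohort.timelines]
n_pr = sum(s["volumetric"].value == "PR" for s in statuses)
print(f"volumetric PR: {n_pr}/{len(statuses)}")

summary = group_medians(cohort.timelines)
b, n = summary.benefit, summary.non_benefit
print(f"benefit group   : median first-interim volume change {b.median_first_interim_change_pct:.1f} % "
      f"(IQR {b.iqr_first_interim_change_pct[0]:.1f} to {b.iqr_first_interim_change_pct[1]:.1f})")
print(f"non-benefit     : median first-interim volume change {n.median_first_interim_change_pct:.1f} %")
print(f"crossed -66 % at first interim: {b.n_cross_first_interim}/{b.n} (ever: {b.n_cross_ever}/{b.n})")
print(f"Mann-Whitney p  : {summary.mann_whitney_p:.2e}")
stag = stagnation_summary(cohort.timelines)
print(f"post-crossing residual shrinkage: median {stag.median_pct:.1f} % "
      f"(IQR {stag.iqr_pct[0]:.1f}-{stag.iqr_pct[1]:.1f}, n={stag.n})")
```

prints:

```
volumetric PR: 19/30
benefit group   : median first-interim volume change -75.4 % (IQR -78.3 to -69.4)
non-benefit     : median first-interim volume change -23.4 %
crossed -66 % at first interim: 16/19 (ever: 19/19)
Mann-Whitney p  : 7.61e-06
post-crossing residual shrinkage: median 8.8 % (IQR 2.7-12.2, n=16)
```

Every benefit patient ends as a volumetric PR and every non-benefit
patient as SD (that is the generator's construction); the benefit group
collapses by ~75 % within its first interim scan versus ~23 % in the
non-benefit group, most benefit patients cross the −66 % threshold at that
first scan, and afterwards the already-shrunken tumours change little —
the stagnation pattern that motivates asking whether neoadjuvant treatment
could stop earlier.

The same analysis runs from the shell on rendered NIfTI data:

```sh
gistmon simulate --spec cohort.yaml --out cohort/        # NIfTI + manifest
gistmon assess --manifest cohort/manifest.csv \
               --labels cohort/labels.csv --out report/  # CSV/JSON reports
```

`report/performance.json` holds the per-criterion confusion tables and
performance triples (in both sensitivity/specificity label orientations),
`agreement.json` the interobserver Dice/ICC/κ, and
`trajectory_summary.json` the group medians and first-interim prediction.

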