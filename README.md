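# ctbca — CT body composition and survival analysis

`ctbca` is a Python library for relating CT-derived body composition to
overall survival in interstitial lung disease cohorts. Given chest CT
volumes and per-organ segmentation masks (NIfTI), it quantifies tissue
volumes and *fat-isodense attenuation volumes* by HU thresholding, derives
five body-composition indices, and runs the full cohort statistics
workflow: median-split stratification, group comparison, Kaplan–Meier /
log-rank survival analysis and multivariate Cox regression. A synthetic
phantom and cohort generator makes every stage testable without clinical
data.

It is written for imaging researchers who already have segmentations (for
example from an automated body-composition network) and want a tested,
reproducible quantification-to-statistics pipeline.

## The quantities

Raw volumes (mL) per subject: bone, muscle, subcutaneous (SAT), visceral
(VAT), inter-/intra-muscular (IMAT), epicardial (EAT) and mediastinal
(MAT) adipose tissue, lung, and two HU-window quantities:

* **CTpfav** — pulmonary fat attenuation volume: voxels in [−200, −60] HU
  inside the lung mask;
* **IMAT** — voxels in [−190, −30] HU inside the muscle mask.

The five indices:

```
sarcopenia index      = muscle / bone
fat index             = TAT / bone          TAT = SAT+VAT+IMAT+EAT+MAT
myosteatosis index    = 100 · IMAT / TAT    [%]
mediastinal fat index = MAT / bone
pulmonary fat index   = 100 · CTpfav / lung [%]
```

For survival, each index is dichotomised at the cohort median
(< median = low, ≥ median = high), compared by Kaplan–Meier with a
log-rank test, and entered (as the high-vs-low group indicator) into its
own multivariate Cox model alongside the clinical covariates, all in a
single step. The survival engines — product-limit estimator, log-rank,
and Newton–Raphson Cox with Efron tie handling — are implemented in the
package and cross-checked against independent references in the tests.

## Worked example

```python
from ctbca import PhantomSpec, make_phantom, quantify_subject, compute_indices

spec = PhantomSpec(shape=(64, 64, 32), spacing=(1.0, 1.0, 1.0),
                   counts={"lung_parenchyma": 97940, "lung_fat": 2060})
ct, masks, truth = make_phantom(spec)
vols = quantify_subject(ct, masks)
print(vols.lung_ml, vols.ctpfav_ml)          # 100.0 2.06
print(compute_indices(vols).pulmonary_fat_index)  # 2.06
```

2060 fat-isodense voxels planted in a 100 000-voxel lung at 1 mm³ give a
lung volume of 100.0 mL, a CTpfav of 2.06 mL, and hence a pulmonary fat
index of 2.06% — recovered exactly, because quantification on phantoms is
bit-exact by construction.

On the statistics side (`examples/survival_analysis.py`, simulated cohort
of 500 with a true high-PFI hazard ratio of 2.37 and age hazard ratio of
1.05/year):

```
24-month survival: low PFI 90% vs high PFI 75%
60-month survival: low PFI 73% vs high PFI 55%
log-rank: chi2 = 27.43, p = 1.6e-07

               covariate    hr  ci95_low  ci95_high     p
pulmonary_fat_index_high 2.259     1.756      2.907 0.000
                     age 1.050     1.042      1.058 0.000
```

The fitted hazard ratios recover the simulated ground truth (2.37 and
1.05) within sampling error; the other covariates are survival-neutral in
the simulation and test as such.

Each script in `examples/` demonstrates one capability end to end:
phantom quantification, index computation, cohort group characterisation,
survival analysis, and the full pipeline (`run_pipeline`) that emits the
report tables (cohort description, index medians, per-split group
characterisation, per-index Cox results, KM curves and horizon survival
rates) as deterministic CSVs.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch: it generates a synthetic fixture
bundle (phantom NIfTIs, masks, simulated cohort), quantifies the phantoms,
and runs every statistics stage through to the report tables, writing the
result file to `--out`.

## Layout

```
src/ctbca/
  imaging.py    CT/mask I/O, slice resampling, HU-threshold volumetry
  indices.py    the five body-composition indices
  cohort.py     median/horizon splits; normality-routed t / Mann-Whitney;
                Fisher exact; group characterisation
  survival.py   Kaplan-Meier, log-rank, Cox PH (Newton-Raphson, Efron/Breslow)
  synth.py      phantom generator, cohort simulator, fixture bundles
  pipeline.py   end-to-end orchestration and report tables
docs/methods.md the models, defaults and design choices in detail
```
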