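# Methods

`ctbca` quantifies CT body composition from segmentation masks and relates
the derived indices to overall survival. This note documents the models,
the defaults, and the design choices that were genuinely open.

## Imaging quantification

A subject is a 3-D CT volume in Hounsfield units (HU) plus binary masks for
lung, bone, muscle, and the subcutaneous, visceral, epicardial and
mediastinal adipose compartments. All quantities are sums over voxels, so
axis orientation is irrelevant; only the voxel spacing (mm) matters. A
compartment volume is `count x (sx*sy*sz / 1000)` mL, written with exactly
that association so phantom ground truths are reproduced bit-for-bit.

Two quantities are defined by HU windows rather than masks alone:

* **CTpfav** (pulmonary fat attenuation volume): voxels inside the lung
  mask with HU in **[-200, -60]**. A wider [-200, -40] variant used in
  some of the pulmonary-fat literature is available through `QuantConfig`;
  the narrower window is the default because it is the one the
  quantification method itself is stated with.
* **IMAT** (inter-/intra-muscular adipose tissue): voxels inside the muscle
  mask with HU in **[-190, -30]**.

Both windows are closed intervals (a voxel at exactly -200 HU counts) and
no morphological post-processing is applied to the selected voxels.

Quantification runs at native spacing by default. Normalising slice
thickness (5 mm for body composition, 1.5 mm for organ volumetry, the
convention of the segmentation networks this pipeline consumes masks from)
is an explicit opt-in: interpolation perturbs volumes, and the package's
contract is exactness on known inputs. When enabled, resampling acts along
the slice axis only — linear interpolation for HU, nearest-neighbour for
masks — because the normalisation being emulated is of slice thickness,
not in-plane resolution. Non-finite HU values are rejected at load time
rather than silently excluded.

## Body-composition indices

| index | formula | unit |
|---|---|---|
| sarcopenia index | muscle / bone | ratio |
| fat index | TAT / bone | ratio |
| myosteatosis index | 100 · IMAT / TAT | % |
| mediastinal fat index | MAT / bone | ratio |
| pulmonary fat index (PFI) | 100 · CTpfav / lung volume | % |

**TAT composition.** "Total adipose tissue" is not universally defined; the
default here is SAT + VAT + IMAT + EAT + MAT — every extracted adipose
compartment — configurable via `QuantConfig.tat_components`. With IMAT
included, the myosteatosis index is bounded by 100%. Epicardial adipose
tissue is quantified as a raw volume but enters no index; it is kept in the
output because downstream users may want it.

Indices are computed and stored unrounded; the report layer rounds
(volumes 3 decimals, indices 2, HR/CI 2, p-values 3).

## Cohort statistics

* **Median split**: low iff value < cohort median, high iff ≥ median (ties
  at the cutoff are high). The median of an even-sized sample is the mean
  of the two middle order statistics. For 71 distinct values this yields
  the 35/36 split the group tables assume.
* **Survival-horizon split** (default 60 months): deaths before the
  horizon vs subjects observed past it. Subjects censored before the
  horizon have unknown 5-year status and are excluded, with the exclusion
  count reported. (In a fully-followed cohort no exclusions occur.)
* **Normality routing**: each group is tested with the D'Agostino–Pearson
  K² omnibus test (skewness and kurtosis transforms summed, χ²(2) tail);
  the two-sample t-test is used only if *both* groups pass at α = 0.05,
  otherwise Mann–Whitney U. Whether routing should be per-group or pooled
  was an open choice; per-group is the stricter and more common reading.
  Groups below n = 20 (the validity floor of the kurtosis transform)
  route directly to Mann–Whitney.
* **t-test**: pooled-variance by default — the classical "two-tailed
  t-test" — with Welch as an option.
* **Mann–Whitney U**: exact two-sided p by enumerating the null U
  distribution (Gaussian-binomial recurrence) when the samples are untied
  and n₁·n₂ ≤ 400; otherwise a normal approximation with midrank tie
  correction and 0.5 continuity correction. Two-sided p is twice the
  smaller tail, capped at 1.
* **Fisher's exact test**: two-sided by the sum-of-small-probabilities
  convention (all tables with the observed margins whose hypergeometric
  probability is ≤ the observed one, within relative tolerance 1e-7) —
  the definition used by common statistical software.

No multiple-testing correction is applied across the covariate table; the
workflow this reproduces applies none.

## Survival analysis

* **Kaplan–Meier**: product-limit estimator; right-continuous step
  function with S(0) = 1; a subject censored exactly at an event time is
  still at risk for that event. Survival rates at a horizon are read off
  the step function; requesting a time beyond follow-up is an error, not
  an extrapolation.
* **Log-rank**: observed-minus-expected events over hypergeometric
  variance summed over distinct event times, referred to χ²(1).
* **Cox proportional hazards**: partial likelihood maximised by
  Newton–Raphson from β = 0 with step-halving on likelihood decrease;
  convergence when max |gradient| < 1e-9 or relative log-likelihood change
  < 1e-12, at most 100 iterations. **Efron** tie handling by default (more
  accurate when event times tie; the Breslow option coincides with Efron
  when none do). Covariates are centred internally for conditioning; the
  estimates are invariant to this. Standard errors come from the inverse
  observed information; CIs are exp(β ± 1.96·SE) and p-values are Wald —
  no likelihood-ratio option in v1. Complete separation surfaces as
  non-convergence (or as divergent coefficients) and raises.
* **Per-index models**: each index enters its own multivariate model as
  the median-split group indicator (1 = high, so the reported HR is
  high-vs-low), alongside age, sex, BMI, smoking, GAP index, fibrotic
  status, FVC%, cardiovascular disease and diabetes, all entered in a
  single step. DLCO is excluded: it is missing for a substantial fraction
  of subjects and would shrink the complete-case set. The indices share
  volumes (bone, TAT) and are therefore never fitted jointly.

The published table this reproduces labels the index rows "(reference
high)" while its text reports the hazard ratio for high-versus-low; the
coding here follows the text's substance — the indicator is 1 for the
high group and the HR is the high group's risk relative to low.

## Synthetic data

**Phantoms** plant known voxel counts per tissue at fixed HU levels in an
air background (-1000 HU), at seed-deterministic positions with pairwise
disjoint regions. Fat-isodense levels sit strictly inside their windows
(-100 HU), other tissues strictly outside, so quantified volumes equal
planted counts times voxel volume exactly. Phantoms have no noise, no
partial-volume mixing and no anatomy — a green phantom test establishes
the counting arithmetic, not robustness to real CT texture.

**Cohorts** emulate a fibrotic-predominant NSIP population of 71 subjects:
age median 65 (IQR 21.5) years, 55% female, BMI median 29, 48% smokers,
GAP median 4, 86% fibrotic, FVC median 62%, DLCO median 41 with ~28%
missingness, 68% cardiovascular disease, 31% diabetes; index medians
(e.g. PFI 2.06%, sarcopenia 1.84) match the published cohort. Skewed
continuous variables are log-normal matched to median and IQR width
(σ = asinh(IQR/2m)/z₀.₇₅, μ = ln m) — a two-parameter fit to the only two
published moments. Covariates are independent by default; any joint
structure beyond that would be guesswork, so none is imposed.

Survival times are exponential proportional hazards with linear predictor
Σ βᵢxᵢ. Ground-truth effects: log 2.37 for the high-PFI group indicator
(computed after drawing the index values, mirroring how the Cox models
code indices) and log 1.05 per year of age; all other covariates are
neutral. The baseline rate is calibrated by log-scale bisection so the
expected event fraction at the censoring horizon equals 54%, the observed
death fraction. Administrative censoring defaults to 120 months (the
middle of the published follow-up span); an optional dropout fraction
censors uniformly before the horizon. An infeasible calibration target
warns with the achieved fraction instead of failing.

Because covariates are independent, a green simulation test establishes
effect recovery and error calibration under the stated model — not
robustness to confounding, non-proportional hazards, or informative
censoring, none of which the generator produces.

## Numerical and degenerate-input choices

* Volumes use one fixed multiplication order (above) so exactness tests
  are meaningful at machine precision.
* Empty lung or muscle masks raise (the dependent index is undefined)
  rather than returning 0/0.
* Zero denominators in index formulas raise naming the denominator.
* A covariate with zero variance raises before the Cox iteration starts.
* p-values are floored at the smallest positive double so reported values
  are always in (0, 1].
* Exact Mann–Whitney enumeration is capped at n₁·n₂ = 400; beyond that
  the corrected normal approximation is used.

## Known limitations

* Masks are inputs: the package quantifies within segmentations, it does
  not produce them, and it does not model partial-volume averaging at the
  lung–fibrosis interface (a recognised source of bias for pulmonary fat
  measurement on thick slices).
* The cohort simulator's independence assumption means group tables on
  synthetic data show only type-I behaviour; the age imbalances real
  median splits produce can be emulated via a correlation knob but are
  off by default.
* Report tables reproduce structure and statistics of the clinical
  workflow; the clinical numbers themselves are not reproducible without
  the patient data.
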