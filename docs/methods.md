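# Methods

## Trajectory summaries

A feature trajectory is a short irregular time series v(t₀ = 0), …, v(t_K)
in months from the baseline scan to progressive disease. Three scalar
summaries are computed grid-natively (no interpolation to a common grid,
no smoothing):

- **AUC1**: sum of trapezoid areas (vᵢ + vᵢ₊₁)/2 · Δtᵢ, feature-units ×
  months.
- **beta**: OLS slope of value on time, feature-units / month.
- **AUC2**: the same trapezoid areas with sign sᵢ = +1 if the segment
  rises, −1 otherwise. The "otherwise" is deliberate: a perfectly flat
  segment *subtracts* its area under the default rule
  (`zero_increment="subtract"`), so a constant trajectory of value 1 over
  [0, 4] has AUC2 = −4. A configuration switch (`"drop"`) makes zero
  increments contribute nothing instead. The default was chosen because
  the sign rule is stated as a strict positivity test on the increment;
  in continuous data the distinction is immaterial.

Values are baseline-normalized ratios by default before summarization
(`values / values[0]`); negative cutoffs on volume AUC2 only make sense on
a relative scale, and normalization makes summaries comparable across
patients with very different absolute tumor burdens. A raw-scale mode
exists for features where the absolute level matters.

Missing feature values drop only the affected time point for that feature,
never the patient; a trajectory left with fewer than two usable points
yields an all-NaN summary with a warning rather than an error.

For nonnegative trajectories |AUC2| ≤ AUC1, with equality exactly when all
area-carrying segments move in one direction; AUC1 − |AUC2| equals twice
the smaller of the rising and falling area masses. These invariants are
property-tested.

## Six-pattern classification

Volume trajectories are assigned to an ordinal taxonomy: (1) reduction
only, (2) slow progression after rapid response, (3) rapid progression
after rapid response, (4) slow progression after slight reduction,
(5) rapid progression after slight reduction, (6) sequential progression.
The original taxonomy was applied visually; the implementation
operationalizes it with two thresholds on the normalized trajectory:
nadir depth d = 1 − min v and the OLS slope m of the post-nadir segment.
No post-nadir rise → 1; d ≤ 0 → 6; otherwise deep (d ≥ 0.30) vs shallow
crossed with fast (m ≥ 0.10/month) vs slow. Both thresholds are
configurable (`PatternThresholds`); the defaults separate the synthetic
templates cleanly and are stated choices, not literature values.

## Survival modeling

- **Optimal cutpoint**: candidates are midpoints between consecutive
  distinct marker values with both groups ≥ 10% of the sample (the floor
  prevents degenerate 1-vs-(n−1) splits); the returned cutoff minimizes
  the two-group log-rank p, ties resolving to the smaller cutoff. The
  log-rank statistic is computed directly (pooled tied events,
  hypergeometric variance) with a vectorized scan over all candidate
  splits sharing one pass over the risk sets. *Caveat*: minimum-p
  selection makes the reported p anti-conservative; an optional
  permutation-adjusted p re-runs the full scan on label-permuted data.
  The acceptance suite demonstrates the inflation on null data rather
  than hiding it.
- **Kaplan–Meier**: product-limit estimator with Greenwood variance;
  median = first time S(t) ≤ 0.5 (NaN if never reached). Implemented
  in-house because the censoring-weighted ROC needs left limits of the
  censoring-distribution KM; equality with lifelines is unit-tested.
- **Cox fits**: lifelines `CoxPHFitter` (Efron tie handling) behind a
  thin adapter returning coefficients, HRs, Wald 95% CIs/p-values and
  AIC = −2·logPL + 2k. Constant columns and designs with fewer events
  than covariates are rejected; convergence/separation warnings are
  surfaced as flags. An independent Efron partial-log-likelihood
  evaluator confirms fitted maxima by grid search in tests.
- **Screening/selection**: univariate Cox per dichotomized marker
  (keep p < 0.05); VIFⱼ = 1/(1 − R²ⱼ) from an intercept-including OLS of
  each feature on the rest, dropping the worst feature iteratively while
  any VIF > 10; bidirectional stepwise AIC starting from the full
  candidate set, applying the single best add/remove move until no move
  lowers AIC (deterministic given column order, full path logged, AIC
  monotone along the path by construction).
- **Time-dependent ROC**: cumulative-case / dynamic-control AUC at each
  horizon t — cases have an observed event by t, controls are still under
  observation after t — with cases weighted by 1/Ĝ(Tᵢ⁻), the inverse
  censoring-survival left limit (Uno-type IPCW); tied scores count ½.
  Under no censoring this reduces exactly to the concordant-pair
  proportion. Horizons with no cases or no controls return NaN with a
  flag. Agreement with scikit-survival's `cumulative_dynamic_auc` is
  unit-tested.

## Radiomic features

Inputs are 3-D HU blocks with binary masks and voxel spacing; all outputs
are in physical units so anisotropy is handled once.

- **volume**: voxel count × voxel volume.
- **surface area**: marching-cubes mesh at the 0.5 level of the
  zero-padded mask, Gaussian-smoothed (σ = 0.8 voxels) first — the
  staircase mesh of a raw binary sphere overestimates the analytic area
  by ~9%, smoothing brings it within ~1%. Masks thinner than four voxels
  in any direction use exposed-face counting instead (a unit voxel gives
  6 mm²).
- **density**: mean HU over the mask. The mass-like alternative reading
  was rejected; mean attenuation is the standard convention.
- **skewness/kurtosis of positive pixel values**: standardized third and
  fourth moments of in-mask voxels with HU strictly > 0 (post-contrast
  soft-tissue convention). Kurtosis is non-excess (normal = 3) by
  default, switchable. Fewer than three distinct positive voxels → NaN
  with a warning.
- **entropy**: Shannon entropy (bits) of the intensity histogram with
  fixed 10-HU bins over [−1000, 400], clipping outliers into edge bins;
  bin width and range are configurable since no canonical binning exists.
- **entropy at inner portion**: the same entropy over the mask voxels
  whose Euclidean distance to the boundary is ≥ 2 mm (configurable);
  "inner" has no standard definition, so a distance-erosion margin is the
  package's operationalization. If erosion empties the mask the full-mask
  value is returned with a fallback flag.
- **aggregation**: per RECIST up to five target lesions; total volume is
  the sum, every other feature the volume-weighted average.
- A registry (`register_feature`) lets users plug in additional
  per-lesion features; the prognostic machinery is feature-agnostic.

Phantoms (spheres/ellipsoids with constant, Gaussian or core-rim texture)
carry analytic ground truth for verification; the ellipsoid area truth
uses the Knud Thomsen approximation (<1.1% error).

## Synthetic cohort generator

The generator emulates the data structure of a serial-CT EGFR-TKI cohort:
~2-month scan spacing, trajectories ending at progressive disease, six
response patterns, secondary features co-varying with volume, and
overall survival tied to the realized trajectory shape.

- **Templates** are piecewise exponential: decay from ratio 1 to a nadir
  (deep 0.30, shallow 0.85) at min(4 months, T/2), then saturating
  exponential regrowth toward a per-pattern ceiling (pattern 2: 0.8 at
  initial slope 0.015/month; 3: 2.2 at 0.40; 4: 1.4 at 0.035; 5: 3.5 at
  0.50; pattern 1 decays to plateau 0.5 at 0.35/month; pattern 6 grows
  toward 4.5 at 0.40/month). The ceiling models the tumor burden at which
  progressive disease ends follow-up; unbounded exponential regrowth
  would imply 10–1000× volume ratios no PD-terminated series contains.
- **Follow-up couples to pattern** — aggressive patterns progress sooner:
  time-point counts 1:(6–8), 2:(5–7), 3:(4–5), 4:(6–8), 5:(4–5), 6:(3–4),
  clipped to the cohort-level range (default (3, 8)). This coupling is
  what makes the signed area track the taxonomy: at equal follow-up a
  deep-responder that regrows to its ceiling accrues as much positive
  area as a shallow slow progressor.
- **Noise**: unit-mean multiplicative lognormal with CV 0.10 per
  measurement (baseline ratio stays exactly 1).
- **Secondary features** are linear transforms a + b·ratio + N(0, sd) per
  scan — density (35, 15, 5 HU), positive-pixel skewness (0.4, 0.6,
  0.25), kurtosis (2.5, 1.0, 0.5), entropy (3.5, 1.0, 0.35), inner
  entropy (3.0, 1.2, 0.45) — and surface area = baseline area ·
  ratio^(2/3) with CV-0.10 noise. The noise floors make every secondary
  feature a decidedly noisier proxy of the volume signal (amplitude/noise
  ~2–3 vs ~10), as serial-CT texture features are relative to volumetry,
  so each has a known but weaker association with outcome.
- **Survival**: exponential proportional hazards with log-hazard
  Σ coefₖ · summaryₖ computed from the *realized* (noisy, normalized)
  trajectories; default coefficient 0.15 per unit volume AUC2, baseline
  hazard 0.02/month. Censoring is uniform dropout on (0, 2·horizon)
  truncated administratively at the 60-month horizon, giving ~45–50%
  censoring, comparable to a cohort with half the patients alive at
  analysis. Baseline absolute volumes are lognormal (median 4000 mm³,
  log-sd 0.8) and stored separately from the ratio scale.

What the generator does *not* emulate: informative censoring, correlated
multi-lesion structure, scan-interval irregularity, non-proportional
hazards, and any CT acquisition physics (voxel-level synthesis lives in
the phantom generator). Passing tests therefore demonstrate the
statistical machinery is correct and recovers planted signal under clean
proportional-hazards conditions — not that the pipeline's selected
features or AUROC would replicate on clinical data.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 200 patients (matching a
plausible single-center scale while keeping dozens of replicate runs
cheap), 100 replicates for CI-coverage checks, 500 for the type-I-rate
check, and n = 2000 for the null-AUC calibration. Determinism: one
`numpy` Generator seeded from the run seed drives every draw in a fixed
order, so identical configurations reproduce byte-identical CSVs.
Degenerate inputs are handled explicitly: constant markers refuse a
cutpoint; zero-variance designs refuse a Cox fit; an all-censored horizon
flags NaN rather than guessing.

## Known limitations

- The stepwise-AIC + minimum-p-cutpoint pipeline is honest to common
  practice but statistically aggressive; selected models overfit at
  n ≈ 50–200 and the raw cutpoint p-values are anti-conservative. Use the
  permutation-adjusted p and treat AUROC values as in-sample.
- The pattern classifier's thresholds (0.30 depth, 0.10/month slope) are
  calibrated to the synthetic templates; clinical use would require
  re-calibration against visual consensus labels.
- First-order features only; no GLCM/texture matrices unless registered
  by the user.
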