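# Methods

This note documents the models, conventions and numerical choices behind
`psma_percist`, and what the synthetic data do and do not establish.

## Coordinate and measurement conventions

Arrays are indexed (z, y, x), 0-based; voxel *i* along an axis of spacing
*s* mm has its center at (*i* + 0.5)·*s* mm. A voxel belongs to an analytic
shape (lesion ellipsoid, aortic cylinder, SUVpeak sphere) iff its **center**
lies inside the shape, boundary inclusive. This single rule makes every
geometric quantity exactly reproducible by enumeration, which is how the
test oracles verify them. Lengths are mm, volumes mL, SUV dimensionless
(lean-body-mass normalized where applicable).

## Quantification

* **Blood-pool reference.** A cylindrical VOI (default length 30 mm,
  diameter 10 mm, axis along z) in the aorta provides mean, SD (n−1
  denominator) and SUVpeak. The segmentation threshold is
  T = 1.5·SUVpeak + 2·SD.
* **SUVpeak.** The maximal mean SUV over spheres of 1.2 cm diameter
  (~1 cm³, the PERCIST convention) whose centers are voxel centers inside
  the query mask. The sphere may extend beyond the mask but not beyond the
  grid; ties are broken toward the lowest (z, y, x) center. If a mask lies
  entirely within the boundary margin (no admissible full sphere), spheres
  clipped at the grid edge are used — a documented edge rule, exercised in
  tests. Implementation is a normalized spherical-kernel correlation
  (`scipy.ndimage.correlate`); an exhaustive brute-force search is the test
  oracle.
* **Segmentation.** Voxels with SUV strictly greater than T, minus an
  exclusion mask (the blood-pool VOI by default, or any user-supplied
  physiological-uptake labels — the package's stand-in for manual VOI
  editing), grouped by 26-connectivity. Components smaller than 0.3 mL are
  disregarded; surviving components must additionally satisfy
  SUVpeak(component) > T. Labels are assigned by decreasing volume (ties by
  first voxel in scan order) so output is deterministic.
* **Burden metrics.** PSMA-TV is the summed component volume;
  TL-PSMA = Σ SUVpeak_l · volume_l per patient. The alternative reading
  (global SUVpeak × total PSMA-TV) is available via
  `QuantConfig(tl_mode="global")`; the summation form is the default
  because the metric is defined by analogy to total lesion glycolysis,
  which sums per-lesion contributions.
* **LBM.** Janmahasatian male formula, LBM = 9270·W/(6680 + 216·BMI). The
  study population is male; the female coefficients are deliberately not
  offered. Pre-normalized SUV_lbm volumes bypass this entirely.
* **Lesion sampling.** `select_extreme_lesions` takes the k most- and
  least-avid lesions (default k = 2) per metastasis category (lymph node,
  bone, visceral), all lesions when a category holds ≤ 2k, plus prostate
  lesions — reproducing the avidity-spread sampling scheme of the
  lesion-level analysis.

## Response classification

Lesion level (SUVpeak): follow-up 0 → iCR; change ≤ −30% → iPR; ≥ +30% →
iPD; else iSD. Both ±30% boundaries are inclusive. Patient level (TL-PSMA):
same boundaries; **any new lesion is sufficient for iPD** and takes
precedence over a concurrent TL-PSMA reduction (the conservative,
PERCIST-consistent reading of "and/or"); patient-level complete response is
not defined. Biochemical: change < −50% → bPR (a reduction of exactly 50%
is still bSD); ≥ +25% → bPD; else bSD. All classifications are invariant
under rescaling of both timepoints, verified by property tests away from
the exact boundaries (where floating-point rounding of the percent change
can tip the label — boundary behavior itself is pinned by exact tests).

Cross-timepoint matching is greedy nearest-centroid within 15 mm and the
same site (both configurable); unmatched baseline lesions are treated as
resolved (follow-up SUVpeak 0), unmatched follow-up lesions flagged new.
The tolerance is an artifact convention — clinically lesions were matched
by a reader — and is therefore explicit rather than implicit.

## Statistics

All SUV analyses use natural logs (SUV is right-skewed). Significance is
two-sided at α = 0.05; no multiplicity correction is applied across the
univariate screens, a deliberate mirror of the screening design and a known
limitation.

* **ROC.** Empirical, all observed thresholds plus a sentinel; score ≥
  cutoff predicts responder. Youden cutoff maximizes sens + spec − 1, ties
  resolved toward higher specificity and then the larger cutoff (the
  intended clinical use emphasizes specificity). The minimum-specificity
  cutoff is the smallest threshold reaching specificity 0.80. AUC is the
  trapezoidal area (sklearn's concordance). Optimism correction follows
  Harrell: apparent AUC of the univariate logistic score minus the mean
  bootstrap optimism over B resamples (default 1000; resampling at lesion
  or cluster/patient level as appropriate; single-class resamples are
  redrawn under a cap).
* **Mixed models.** log SUVpeak (or SUVmax) ~ response + PSMA-TV + site,
  random intercept per patient, fitted by **ML, not REML**, so the reported
  likelihood-ratio test against the model without the response terms is
  valid. Response enters dichotomized (responder = iCR∪iPR) or as the
  four-level category with iPD as reference; a site×response interaction is
  optional. Wald 95% CIs; exponentiated coefficients are multiplicative SUV
  ratios. τ² is the random-intercept variance, σ² the residual variance,
  ICC = τ²/(τ²+σ²). The modeled direction (log SUV as outcome, response as
  fixed effect) matches the coefficient-table layout this analysis reports;
  the inverse phrasing sometimes used in prose descriptions is noted but
  not implemented.
* **Logistic screens.** outcome ~ variable + baseline PSMA-TV versus
  outcome ~ PSMA-TV, LRT with 1 df. Quasi-complete separation (diverging
  coefficient, |β| > 10, or a separation warning) is flagged while the LRT
  p is still reported: the likelihood difference is well-defined at the
  boundary even when the Wald CI is not (this is how the screens behave
  when imaging and biochemical response nearly coincide).
* **Survival.** Kaplan–Meier product-limit per group; median OS is the
  first time S(t) ≤ 0.5, +inf ("not reached") when never attained;
  two-sided log-rank across groups; univariate Cox with Efron tie handling,
  categorical covariates reference-coded against the first listed level.
  Monotone partial likelihood is detected and flagged rather than reported
  as a finite estimate.

## Synthetic data: what it emulates and what it does not

`generate_phantom` renders truncated-normal background, a normal blood-pool
cylinder and plateau-intensity ellipsoids; Gaussian smoothing (FWHM in mm)
is available to mimic scanner resolution but **off by default** so that
segmentation oracles remain exact — partial-volume effects are represented
only by this optional blur. There is no attenuation, scatter,
reconstruction noise texture, or respiratory motion; passing phantom tests
shows the measurement chain is correct, not that it is robust to real
acquisition physics.

`simulate_cohort` draws, for patient *i* and lesion *j*,

    log SUVpeak_ij = site_mean(site_ij) + b_i + β·R_ij + ε_ij,
    b_i ~ N(0, τ²), ε_ij ~ N(0, σ²),

with defaults chosen to resemble a salvage-therapy mCRPC cohort: 32
patients, ≈7.4 lesions/patient (1 + Poisson), site mix 36/50/7/6%
(lymph node/bone/visceral/prostate), site means at the log of typical
median SUVpeak values (13.7 prostate, 7.4 lymph node, 6.8 bone, 7.3
visceral), τ = 0.4, σ = 0.5, β = ln 1.80, lesion response rate 0.63.
The response label is Bernoulli and, by default, independent of the latent
intensity (`link_slope = 0`): a non-zero slope would make the marginal
contrast recovered by the mixed model differ from β through selection on
the latent, breaking the generative contract. SUVmax is SUVpeak × 1.35 — a
pure artifact convention (any factor > 1 serves), since the joint
distribution of the two statistics is not specified by the analysis being
mirrored. Follow-up SUVpeak ratios are drawn per category inside the
corresponding classification bands, so labels and trajectories are
consistent by construction. PSA follows a lognormal (median 210 ng/mL,
log-SD 1.52 from the reported IQR) with its change coupled to the TL-PSMA
log-ratio plus noise; survival is exponential (median 8 months for
non-responders, hazard ratio 0.457 for imaging responders, ≈10 months
marginal) with uniform censoring on 6–40 months giving a high event
fraction. These are stylized: no informative censoring, no
treatment-cycle structure, no correlation between lesion count and
survival beyond the response pathway.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately modest sizes chosen as
the smallest that make the statistical assertions sharp: phantoms of
48×64×64 voxels at 2 mm, oracle grids of 20³–30³, cohorts of 200 patients ×
~8 lesions with 100 replicates for parameter recovery, 200 replicates at
n = 100 for null calibration, bootstrap B = 50–200 in tests (B = 1000 is
the library default). Random streams derive from a single root seed via
`numpy.random.SeedSequence` spawning, so sub-stages are independently
reproducible. Sphere/cylinder membership comparisons carry a 1e-9 epsilon
to keep voxels exactly on analytic boundaries stable across platforms.

## Known limitations

* Segmentation assumes lesions are resolvable as distinct components at
  threshold T; abutting lesions merge (clinically handled by reader
  editing, here only by an explicit exclusion/label volume).
* SUVpeak of lesions smaller than the 1.2 cm sphere is diluted by
  background, so TL-PSMA from per-lesion SUVpeak under-represents the
  plateau burden of sub-sphere lesions; this is inherent to the peak
  statistic, not an implementation artifact.
* The Youden cutoff is reported without a confidence interval, and no
  multivariable model selection is performed — both out of scope by
  design.
* Wald CIs for mixed-model contrasts ignore the uncertainty of the
  variance components; coverage is verified by simulation under the
  generator's own conditions only.
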