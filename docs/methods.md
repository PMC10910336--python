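# Methods

This note documents the models, numerical conventions and design choices
behind `pfradiomics`, in the order the pipeline applies them.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not photorealistic radiographs. Each subject draws a latent
patellofemoral severity `s ~ Uniform(0, 1)` which simultaneously drives:

* **Patella shape.** A rotated superellipse (exponent 2.5; rotation
  U(−12°, 12°)) with vertical semi-axis 14 mm × elongation, where
  elongation interpolates `patella_elongation_range` (default 1.0–1.12)
  by `s`, plus an inferior-pole protrusion of length
  `inferior_osteophyte_range` (default 0–3 mm) × `s`. An independent
  global size factor U(0.90, 1.10) models body-size variation; it is
  deliberately larger than the severity-driven elongation so that
  ROI *area* is a poor severity proxy and the planted signal stays
  localised rather than leaking into every ROI through the geometry.
* **Peri-trochlear texture.** A Gaussian random field (correlation
  length U(2, 6) px) multiplied by a Gaussian band centred
  posterior-inferior to the patella and by a sigmoid gate that keeps it
  strictly posterior to the patella boundary. Gating matters twice: the
  normalisation statistics are computed over the patella bounding box and
  must stay severity-independent, and the informative region must lie
  (as intended) partly outside the bone, where the inferior ROI reaches.
  The amplitude interpolates `texture_contrast_range` (default
  0.02–0.25 intensity units) by `s` — the primary planted image signal.
* **KLG.** `digitize(s + N(0, 0.45²))` against frozen cutpoints
  (0.4316, 0.6756, 0.9110, 1.2746), Monte-Carlo calibrated so the grade
  mix is ≈ 45/18/15/15/7 % for grades 0–4. The mapping noise is
  deliberately large: KLG grades the *tibiofemoral* joint, a correlated
  but distinct structure, and the noise is what gives the image-derived
  RadScore independent prognostic content next to KLG.
* **Outcome.** Weibull proportional hazards with shape k = 2 and
  log-hazard `α + severity_effect·s + klg_effect·KLG`
  (defaults `severity_effect = 3.0`, `klg_effect = 1.0`,
  `α = −15.2315`). Shape 2 (rather than exponential) makes event *timing*
  track hazard: under a memoryless model, fast (≤30-month) and slow
  (30–84-month) progressors have nearly identical risk-score
  distributions, the two Youden cutpoints coincide and the medium
  stratum degenerates — shape 2 restores the three-class structure the
  stratification targets. `α` is recalibrated by Monte-Carlo bisection
  (2×10⁶ subjects) whenever the effect sizes change, to hit a 10.5 %
  84-month event fraction. Censoring is per-subject administrative
  U(84, 101) months plus, with probability 0.05, an early dropout
  U(1, 84); observed time is the minimum.
* **Demographics.** Age N(62.4, 8²) clipped to 50–79, 60 % male,
  BMI N(30.5, 5²); all independent of the hazard so they calibrate the
  covariate-selection false-positive rate. PFOA is a noisy threshold on
  `s` (≈15 % positive, 6.8 % missing).

Effect sizes were fixed once by a power-style design study on the tabular
model (a severity proxy with measurement noise 0.25–0.30 at n = 1000):
they are the smallest round values at which the multivariate Cox stage
retains the severity proxy and the stratification produces three ordered
strata in ≥ 7/8 replicates. The per-SD severity hazard ratio (e^{3·0.289}
≈ 2.4) matches the magnitude reported for univariate radiomic scores in
knee-replacement cohorts; `klg_effect = 1.0` (HR 2.7/grade) is somewhat
above published multivariate estimates (~1.9/grade) and was accepted to
keep the discrete KLG term dominant in the fused score, which is what
separates the two Youden cutpoints.

Images carry a dark collimation border and an overexposed side marker.
Both clip at ±6 SD after normalisation, pinning every processed image's
intensity range to exactly [−6, 6]; without them the global min/max — and
through them the intensity-transform scaling constants — would inherit a
severity dependence from the texture amplitude.

What passing tests do **not** show: the phantoms have none of the
projection overlap, exposure variation, soft-tissue shadowing or
segmentation error of real lateral radiographs, so end-to-end recovery
here demonstrates the pipeline's correctness and sensitivity to a planted
signal, not clinical performance.

## Preprocessing

Order: align → resample → normalise → filter → discretise. Filtering
precedes gray-level reduction; alignment precedes resampling so the image
is interpolated only twice (rotation, zoom) with linear interpolation for
intensities, nearest-neighbour for masks, out-of-bounds filled with the
image minimum.

* **Alignment** maximises bounding-box height/width of the rotated mask
  over an exhaustive −30°…+30° grid (step 0.5°), ties to the smallest
  |angle|. The search rotates the mask's convex-hull pixel coordinates
  analytically. Pixel quantisation leaves the raw ratio argmax with
  1–2° of wobble (the ratio curve's curvature near the peak,
  ~3×10⁻⁴ per deg², is below the ~1 % extent noise), so a quadratic is
  fitted to the ratio over a ±10° window and its vertex, snapped back to
  the grid, is used.
* **Resampling** to 0.5 mm isotropic (`scipy.ndimage.zoom`, grid mode).
* **Normalisation**: z-score with mean/SD over the patella bounding box,
  clipped at ±6; a zero in-bbox SD is an error.
* **Discretisation**: fixed bin number,
  `level = min(32, 1 + floor(32·(x−min)/(max−min)))`, with min/max taken
  per ROI per image type at extraction time, so every ROI uses its full
  1–32 range on every image type.

**ROI geometry.** The posterior one-third vertical strip of the patella
bbox is split into three equal-height parts, each extended posteriorly by
twice the strip width; a ROI is exactly `bbox_width` wide and
`floor(bbox_height/3)` tall. Column remainders join the posterior
extension; row remainders fall off the superior edge so the stack stays
anchored inferiorly (all three boxes are always congruent — the inferior
region the analysis cares about is never truncated). For a left knee,
posterior = higher column indices; right knees mirror.

## Filter bank

Ten congruent image types: original; LL/LH/HL/HH of a single-level
undecimated Coiflet-1 wavelet transform (mirror boundary, realised by
symmetric padding around pywt's periodic SWT); Laplacian-of-Gaussian at
σ = 1 mm (kernel truncated at 8σ — the default 4σ kernel's weights do
not sum exactly to zero and leave a ~10⁻⁴ DC residual); and four
monotone intensity transforms of the min-shifted image `x̂ = x − min(x)`
with range `R`:

    square      = (x̂/√R)²            squareroot = √R·√x̂
    logarithm   = R·log1p(x̂)/log1p(R) exponential = expm1(x̂·log1p(R)/R)

Each maps [0, R] onto [0, R]; a constant image passes through unchanged.
The undecimated transform keeps one ROI grid valid across the stack.

## Features (93 per image type)

18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM,
native implementations with these conventions:

* distance 1, four 2-D directions (0/45/90/135°) for GLCM and GLRLM,
  features computed per direction then averaged; 8-connected GLSZM zones
  and GLDM/NGTDM neighbourhoods; GLDM α = 0 with dependence size
  = 1 + dependent-neighbour count (sizes start at 1);
* entropies in log base 2 with 0·log 0 = 0; kurtosis is Pearson
  (non-excess); variance is the population variance; percentiles use
  linear interpolation; first-order entropy/uniformity use the same
  32-bin fixed-bin-number histogram as the texture matrices;
* energy and total energy are sums (total energy × pixel area in mm²),
  hence ROI-size dependent — intentional, as in standard toolkits;
* degenerate single-level regions (reachable only with
  `allow_constant=True`; the default is an error naming the image type)
  use skewness = kurtosis = 0, GLCM correlation = 1, IMC1 = IMC2 = 0,
  MCC = 1, NGTDM contrast = 0;
* all pixels in the rectangular ROI are used — the ROI, not the patella
  mask, is the analysis region.

Implementation notes: symmetric GLCMs make the marginals equal, collapse
the cross entropies to HXY1 = HXY2 = 2·HX, and reduce all (i±j)
statistics to moments of the sum/difference marginals; MCC uses the
symmetric similar matrix G Gᵀ (G = D^{-1/2} P D^{-1/2}) so a symmetric
eigensolver applies, absent levels contributing only zero eigenvalues.
GLSZM zones for all 32 levels are found in one labelling pass over a
level-indexed boolean volume whose structuring element does not connect
across levels. Every feature is verified against a second, independently
written literal-formula implementation (explicit Python loops) to 10⁻⁹
relative tolerance on frozen fixtures.

## RadScore

* **Mutual information**: discrete MI (natural log) after equal-frequency
  binning into 8 bins; discrete variables with ≤8 distinct values are
  used as-is; for all-distinct continuous values the binning is
  rank-based (exactly balanced); constant input → 0.
* **mRMR**: greedy MID — first pick maximises I(x;y); step j maximises
  I(x;y) − mean over selected of I(x;x_s); ties break lexicographically;
  zero-variance features are dropped first.
* **Easy-ensemble**: the 60-month label is KR event with time ≤ 60;
  subjects censored before 60 months without an event are excluded from
  fitting (counts logged in the report). Each of 500 submodels (100 in
  the end-to-end tests, a pure runtime scale-down) trains on all
  minority-class subjects plus an equal-size majority subsample drawn
  without replacement (fresh seeded draw per submodel). A submodel is an
  L2-penalised logistic regression (λ = 1 on z-scored features, penalty
  excluding the intercept) fitted by full Newton iterations to 10⁻⁸.
  "Ridge regression" for a binary endpoint is implemented as penalised
  logistic because the ensemble must emit probabilities; a
  least-squares-on-0/1 variant would not change the ranking-based
  metrics. RadScore = mean submodel probability ∈ [0, 1].
* **Best ROI**: highest training 60-month AUC (Mann–Whitney, tie-corrected,
  the same routine the survival metrics use); ties go to the inferior ROI.

## Survival machinery

* **Cox**: Breslow tie handling, Newton–Raphson on the partial likelihood
  with analytic gradient/Hessian, step-halving (the likelihood never
  decreases), tolerance 10⁻⁹, ≤100 iterations; SEs from the inverse
  observed information; Wald p-values, 95 % CIs as exp(β ± 1.96·SE).
  Non-convergence and |β| > 50 (separation) raise rather than return
  silently. Cross-checked against lifelines on tie-free fixtures (Efron
  and Breslow coincide there) to 10⁻⁶.
* **C-index**: Harrell's — comparable pairs are those where the shorter
  observed time ended in an event (strictly shorter; equal-time pairs are
  not comparable), score ties count ½. Bootstrap CI: percentile
  2.5/97.5 over subject-level resamples. Model comparison: one-sided
  permutation test, statistic C(A) − C(B), null built by swapping each
  subject's pair of scores with probability ½, add-one p-value.
* **Time-dependent ROC**: cumulative cases (event, time ≤ t), dynamic
  controls (time > t); subjects censored at or before t without an event
  are excluded and counted (no IPCW — exclusion counts are reported
  instead). AUC by Mann–Whitney with tie correction.
* **Kaplan–Meier**: product-limit; right-continuous step lookup.

## Risk score and stratification

Two-stage covariate handling mirrors a univariate/multivariate reporting
workflow: multivariate Cox on {RadScore (standardised by training
mean/SD, so its HR is per-SD), age, gender, BMI, KLG, PFOA}; covariates
with p < 0.05 are retained and refitted; if nothing survives, the model
falls back to {RadScore, KLG} with a flag. Subjects with missing PFOA
are excluded from the selection stage only; if PFOA is retained, missing
values take the training mean at scoring time. The KR risk score is the
refit's linear predictor (no baseline hazard is needed for ranking,
thresholds or KM grouping).

Thresholds: candidate cutpoints are midpoints of sorted unique training
scores. `t_low` maximises Youden's J for (slow ∪ fast) vs non;
`t_high` maximises J for fast vs (slow ∪ non); ties prefer the lower
cutpoint; if `t_high ≤ t_low` the upper threshold moves to the next
candidate above `t_low` (logged). Classification sends boundary scores
upward (= t_low → medium, = t_high → high). Subjects censored before 84
months without an event are "indeterminate": excluded (and counted) in
threshold fitting and confusion matrices, retained in Cox and KM. When a
training cohort lacks one of the three classes (possible in small null
cohorts) the pipeline reports stratification as unavailable instead of
aborting the whole analysis.

A structural observation, documented because it shapes expectations: with
a purely continuous risk score, the fast-vs-rest Youden cut tends to
coincide with the any-progression cut (the specificity gain per passed
non-case, 1/n_rest, cannot offset the sensitivity loss 1/n_fast when
fast cases are few and distributed like slow ones). Separated cutpoints
require the score to separate fast from slow — in this design the
discrete KLG term and the Weibull timing provide that, and an occasional
cohort still collapses to a thin medium stratum (the end-to-end checks
therefore require their properties in ≥ 4 of 5 seeds, not all).

## Problem sizes and determinism

End-to-end recovery runs use n = 1500 subjects × 5 seeds with 100
submodels; null-calibration runs use 20 cohorts of n = 260 with 25
submodels; Cox recovery uses 200 replicates at n = 1000; the
reproduction script uses one n = 900 cohort. All randomness flows from
integer seeds through `numpy.random.Generator` (`SeedSequence` spawning
for per-subject streams), and fixed seed ⇒ byte-identical cohort tables
and reports.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute metric
  values on synthetic cohorts do not transfer to clinical data.
* td-ROC uses exclusion rather than IPCW weighting, which is biased when
  censoring is heavy and informative; synthetic censoring here is light
  and independent.
* The Breslow tie approximation degrades with heavily tied times;
  synthetic times are continuous.
* Patella segmentation is assumed given (synthetic masks are exact);
  there is no automatic segmentation.
* The alignment criterion has ~1.5° irreducible wobble from pixel
  quantisation; features are insensitive to rotations of that size.
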