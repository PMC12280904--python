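# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `pathomil`.

## Preprocessing

**Tissue masking.** Otsu's threshold is computed on the 256-level histogram
of grayscale luminance (0.299R + 0.587G + 0.114B). The implementation
compares between-class variances with exact integer arithmetic
(σ²_B(t) ∝ (S₀N₁ − S₁N₀)²/(N₀N₁) over the split {< t} vs {≥ t}), so plateau
ties are resolved deterministically toward the smaller threshold instead of
depending on floating-point round-off. Tissue = luminance strictly below the
threshold. Masking can run on a configurable downsample of the slide; the
mask is stored at that resolution.

**Tiling.** Tiles are non-overlapping, axis-aligned, and exactly square
(512 px in production, 64 px mini-tiles for desk-scale studies); partial
edge tiles are dropped rather than padded so the shape invariant is exact.
A tile is retained iff its tissue fraction is ≥ 0.5 (configurable); every
candidate tile's fraction is recorded in the manifest.

**Stain normalization (Macenko).** Optical density OD = −log₁₀(I/255),
stained pixels = any channel above the OD floor 0.15. The any-channel
criterion matters: pure eosin transmits red, so an all-channel floor would
discard exactly the pink stroma the normalization is meant to align. Stain
directions are the 1st/99th-percentile angles of the OD cloud projected on
its top-2 eigenplane; hematoxylin is the column with the larger red OD;
concentrations come from least squares, clipped at zero, scaled at the 99th
percentile. Normalization transfers the in-plane stain component to the
reference basis and **keeps the off-plane OD residual**, which makes
self-normalization an exact fixed point and preserves texture detail that a
pure rank-2 reconstruction would blur away. Near-white tiles raise
`StainEstimationError`; the pipeline skips them un-normalized.

**Augmentation.** Flips, mirror, Gaussian blur (σ = 1 px), per-channel
affine color jitter (±5% by default), and "progressive sprinkling"
implemented as seeded square occlusions (side = tile/16, fill 127) whose
count grows linearly with a `progress` parameter in [0,1] — intended to be
driven by the training-epoch fraction. The literature gives no canonical
definition of progressive sprinkling; this cutout-style reading is a
documented interpretation. Each tile draws from its own child RNG stream
(seed, slide hash, row, col), so augmentation is order-independent.

## Patch model

The patch classifier is a compact CNN: stride-2 3×3 conv/ReLU blocks
(default channels 8-16-32[-32]) followed by global average pooling and a
linear 2-class head, trained with softmax cross-entropy and SGD
(momentum 0.9, batch 32). All arithmetic is float64 numpy with manual
backprop; a fixed seed reproduces parameters and loss traces bitwise on one
thread. The architecture is deliberately size-configurable: the pipeline's
contribution is the training contract, not a specific backbone, and the
same interface (backbone/head parameter split, last-conv activations and
gradients) holds at any width.

Two learning-rate schedules drive the two parameter groups, per epoch:

* head: η(t) = η_min + ½(η_max − η_min)(1 + cos(π t/T_i)), η_min = 0,
  η_max = 0.01, T_i = 30;
* backbone: 0 for t ≤ T_i/2, the same cosine value afterwards — the
  frozen-then-fine-tune recipe used with transferred weights. Updates are
  epoch-granular; there is no per-step warmup.

**Weak labels.** Death on/before 60 months → 1; follow-up past 60 months →
0 (including deaths after the horizon); censored before 60 months →
excluded from patch training, because the 5-year label is undefined for
them. The positive class (index 1) is death-within-5-years everywhere;
"likelihood" downstream always means that class's probability.

## MIL encodings

Bins: 101 centers at 0.00 … 1.00 step 0.01; bin i covers
[cᵢ − 0.005, cᵢ + 0.005), last bin closed. This scheme is forced by the
published feature names, which carry two-decimal centers.

* PALHI: count-normalized histogram (so the encoding is invariant to bag
  size) + the two predicted-class fractions.
* BoW: tf = bin count / bag size; idf = ln((1+N)/(1+df)) + 1 (smoothed,
  the common modern default — the TF-IDF variant is otherwise unspecified);
  the 101-block is L2-normalized; the label pair is a majority-vote one-hot
  with ties to class 0.

Early fusion concatenates PALHI (103) then BoW (103) in a fixed canonical
order of 206 unique names. Published formulas spell some features
differently (`HistogramBoWProb_0.15`, `BoWProb_008`, `BoWProb_06`); an
explicit alias table maps each spelling to its canonical name, reading the
digit-run forms as decimals (008 → 0.08, 06 → 0.60, 063 → 0.63,
068 → 0.68). The table is data, editable without code changes.

## Signature

**Fitting.** L1-penalized Cox regression solved by cyclic coordinate
descent (tolerance 1e-7) over a 100-value λ path. The default path spans
two decades below λ_max (the smallest λ at which all coefficients vanish):
on representative synthetic cohorts (n = 300, p = 206) the CV-optimal λ
sits well inside two decades, while deeper path segments only produce
near-saturated dense fits at several times the runtime; a deeper path
remains available via `alpha_min_ratio`. Features are standardized
internally and coefficients returned on the original scale. λ is selected
by 10-fold cross-validation minimizing the partial-likelihood deviance
−2(ℓ_all(β₋ₖ) − ℓ_train(β₋ₖ)) (Verweij–van Houwelingen) with Breslow-tie
log partial likelihood; folds are stratified on event status by seeded
permutation so rare events spread across folds. Constant columns are
dropped with a warning. `ensure_nonzero` optionally falls back to the
largest λ with an active feature when the CV minimum is the empty model —
useful for very small pilot cohorts.

**Cutoff.** Candidates are midpoints between adjacent distinct scores
leaving ≥ 10% of samples on each side; the selected cutoff maximizes the
absolute standardized log-rank statistic (O−E over the hypergeometric
variance), ties breaking toward the smaller cutoff. The scan equals an
exhaustive O(n²) search by construction and is tested against an
independent implementation. Group assignment: high iff score strictly
exceeds the cutoff, so a score equal to the cutoff is low-risk.

**Published model.** The printed 8-coefficient formula and its cutoff
0.1139008 are frozen as an immutable `SignatureModel`; the package makes no
claim about the λ that produced it (not reported with the formula).

## Survival evaluation

Times are months throughout; year horizons convert as 12·years. OS and DFS
run through identical code paths (endpoint = column selection).

* Kaplan–Meier with Greenwood variance; log-rank via lifelines.
* Cox: Efron ties by default (month-resolution data has many ties);
  Breslow available via the statsmodels PHReg backend.
* RMST(τ): area under the KM step function; variance
  Σ_{tᵢ<τ} A(tᵢ)² dᵢ/(nᵢ(nᵢ−dᵢ)) with A(t) the remaining area to τ;
  differences reported high − low with normal-approximation CI.
* Time-dependent AUROC: cumulative-case / dynamic-control with KM-based
  IPCW (scikit-survival).
* Calibration: prediction-quantile bins, KM-observed vs mean-predicted
  survival at the horizon; bins merge with a warning when predictions have
  too few distinct values.
* Decision curves: NB(p) = TP/n − p/(1−p)·FP/n with event status at the
  horizon estimated by KM inside the predicted-positive stratum
  (censoring-adjusted counts).
* NRI/IDI: category-free, with IPCW weights — cases (event, t ≤ h) weighted
  1/G(t⁻), controls (t > h) weighted 1/G(h), censored-before-h excluded;
  bootstrap percentile CIs. Identical risk vectors return exactly 0; model
  swap flips both signs exactly.
* Brier: IPCW prediction-error curve (scikit-survival).
* E-value: E = RR + √(RR(RR−1)) with RR = HR (inverted when < 1) — the
  rate-ratio approximation, documented as approximate when the outcome is
  common. CI E-value uses the bound closer to 1; CIs crossing 1 give 1.
* Interaction: Cox with main effects + product term, Wald test on the
  product; every factor cell must be populated.

## Interpretability

SHAP for the linear signature is exact and closed-form:
φⱼ = βⱼ(xⱼ − mean_background(xⱼ)), base value = score of the background
mean; efficiency (base + Σφ = score) holds to 1e-10 and is verified against
full coalition enumeration in tests. Grad-CAM weights the last
convolution's channels by spatially averaged class-score gradients,
rectifies, min-max normalizes (all-zero maps pass through, no division by
zero) and upsamples bilinearly. Patch influence = positive-class likelihood
× mean CAM intensity. The top-ranked patches are embedded with
totally-random-tree leaf indicators (a random-forest proximity space) and
agglomerated with Ward linkage into k = 4 clusters (k-means fallback);
patches are canonically ordered before embedding so clustering is
permutation-invariant up to label renaming. Descriptors default to the
classifier's pooled last-conv features; the descriptor space for this kind
of morphology clustering is a genuinely open choice.

## Synthetic data

The generator encodes the statistical structure the pipeline assumes:

* latent risk r ~ N(0,1) per patient;
* patch likelihoods i.i.d. Beta(a(r), b(r)) with a(r) = exp(0.8r),
  b(r) = exp(−0.8r), both clipped to [0.2, 20] — mean strictly increasing
  in r without degenerate bags;
* survival exponential with hazard 0.004·e^{β·r} per month (≈ 79% 5-year
  survival at average risk, a realistic CRC figure), censoring
  Uniform(0, 120) months (10-year accrual);
* optional treatment arm: log-hazard offset for treated patients plus an
  interaction term confined to one risk stratum, for effect-modification
  studies;
* imaging studies: each slide is a mosaic whose tumor-tile fraction is
  sigmoid(1.5r), mixed with stroma tiles and one background tile; textures
  use H&E-like colors (dark purple nuclei, pink fibrous stroma, white
  adipocytes) so masking, stain estimation and the CNN all have real signal.

Everything is a pure function of (parameters, seed).

**What the synthetic data does not emulate:** scanner noise and stain batch
effects, spatial correlation between neighboring tiles, non-proportional
hazards, informative censoring, and the morphological complexity of real
H&E. Passing tests therefore demonstrate that the pipeline's machinery is
correct and recovers planted signal under its own assumptions — not that
the published clinical effect sizes replicate on real cohorts, which would
require the original slides and follow-up.

## Problem sizes

Test and demonstration runs are sized for a single CPU: mini-tile studies
use 40 slides of 5×5 64-px tiles with a (8,16,32)-channel CNN trained
30 epochs; signature-recovery suites use n = 300, p = 206 over 10 seeds;
simulation-calibration suites use 200–1000 replicates. The same code paths
scale to 512-px tiles and deeper CNNs unchanged.

## Known limitations

* The CNN is a desk-scale stand-in honoring the training contract; no
  pretrained ImageNet weights are bundled (transfer initialization is
  supported through checkpoint loading).
* The E-value uses the rare-outcome HR→RR approximation.
* DCA/NRI/IDI censoring adjustments (KM within strata / IPCW) are
  documented choices; other published variants exist.
* `fit_lasso_cox` does not attempt to reproduce the published λ or
  coefficients — those depend on the original cohort data.
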