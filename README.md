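# pathomil

Weakly-supervised pathomics for colorectal-cancer (CRC) prognosis from
H&E-stained whole-slide images, runnable end to end on synthetic slides and
cohorts with known ground truth.

## Who this is for

Researchers building or auditing slide-level prognostic models from routine
histology: the package implements the full chain from raw RGB slides to a
validated survival signature, with every statistical step exposed as a plain
Python function and every stage reproducible from a single seed.

## The method

1. **Preprocessing** — Otsu thresholding on grayscale luminance removes white
   background; the tissue region is cut into non-overlapping 512 × 512 tiles
   (64 px "mini-tiles" at desk scale); Macenko stain normalization aligns each
   tile's hematoxylin/eosin optical-density basis to a reference; per-channel
   z-scoring standardizes intensities.
2. **Patch model** — a small CNN is trained under weak supervision: every
   patch inherits its patient's 5-year survival status (death within 60
   months → 1). Training uses softmax cross-entropy and SGD (momentum 0.9,
   batch 32) with a cosine-annealed learning rate
   η(t) = η_min + ½(η_max − η_min)(1 + cos(π t / T_i)), η_max = 0.01,
   T_i = 30; the backbone stays frozen for the first T_i/2 epochs and then
   joins the same schedule.
3. **MIL features** — each slide's bag of patch likelihoods p ∈ [0,1] is
   encoded twice: **PALHI**, the histogram over 101 bins centered at 0.00,
   0.01, …, 1.00 plus the two predicted-class fractions; and **BoW**, TF-IDF
   over the same 101 "words" (idf = ln((1+N)/(1+df)) + 1, L2-normalized) plus
   a majority-vote one-hot pair. Early fusion concatenates both into a
   206-dimensional slide vector.
4. **Signature** — LASSO-Cox on the fused features; λ chosen by 10-fold
   cross-validated partial-likelihood deviance (minimum criterion). The risk
   score is the sparse linear predictor Σ βⱼ xⱼ. Patients split into
   high/low risk at the cutoff maximizing the standardized log-rank statistic
   (maximally selected rank statistics). The published 8-term formula

   PS = 0.464259187·HistogramBoWProb_0.15 + 0.516838374·HistogramBoWProb_0.66
      + 0.76054024·HistogramBoWProb_0.72 + 0.000727042·BoWProb_008
      − 0.379252147·BoWProb_06 − 0.475519653·BoWProb_063
      − 0.090370453·BoWProb_068 + 0.050898359·BoWPred_0,  cutoff 0.1139008

   ships as a frozen model (`published_signature()`), with the alias table
   mapping the published feature spellings onto canonical names.
5. **Evaluation** — Kaplan–Meier + log-rank, Cox regression (Efron ties),
   RMST differences, Harrell's C, time-dependent (IPCW) AUROC, calibration,
   decision curves, continuous NRI/IDI, Brier prediction-error curves,
   E-values, and treatment-interaction tests.
6. **Interpretability** — exact closed-form SHAP for the linear signature
   (φⱼ = βⱼ(xⱼ − x̄ⱼ)), Grad-CAM on the CNN's last convolution, slide
   likelihood heatmaps, and random-forest-proximity clustering of the most
   influential patches.

A synthetic-data module generates the full study: class-textured tiles
(tumor/stroma/mucosa/adipose/background in H&E-like colors), composite
slides whose tumor-tile fraction follows a latent risk r ~ N(0,1), patch
likelihood bags p ~ Beta(a(r), b(r)), and exponential survival with hazard
h·exp(β·r) under uniform censoring.

## Worked example

```python
import numpy as np
from pathomil.synthetic import SimCohortParams, simulate_cohort
from pathomil.mil import encode_cohort
from pathomil.signature import fit_lasso_cox, score_slides, select_cutoff, stratify
from pathomil.surv_eval import logrank_test, harrell_c

bags, cohort, truth = simulate_cohort(SimCohortParams(n_patients=120, beta=1.0, seed=1))
X, vocab = encode_cohort(bags)                      # (120, 206) feature matrix
model = fit_lasso_cox(X, cohort["time"].to_numpy(), cohort["event"].to_numpy(),
                      seed=1, ensure_nonzero=True)
scores = score_slides(model, X)
cut = select_cutoff(scores, cohort["time"].to_numpy(), cohort["event"].to_numpy())
groups = stratify(scores, cut)
stat, p = logrank_test(cohort["time"].to_numpy(), cohort["event"].to_numpy(),
                       groups.to_numpy())
print(X.shape, model.n_nonzero, round(cut, 3), p)
```

prints

```
(120, 206) 12 1.817 1.0696185300693783e-32
```

i.e. the encoder produced the 206-feature matrix, cross-validation kept 12
features, the optimal cutoff landed at 1.82 on the risk-score scale, and the
resulting high/low groups differ overwhelmingly in survival (log-rank
p ≈ 10⁻³²) — as they should, since the simulated effect is strong (β = 1).

The full imaging pipeline (tile → train → infer → encode → fit → score →
stratify → evaluate → explain) runs from the CLI:

```bash
pathomil simulate --out study --n-slides 40 --tile-size 64 --seed 3
pathomil run --slides study/slides --cohort study/cohort.csv --out results --seed 3
```

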