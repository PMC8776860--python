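# Methods

## Problem setting

`mxproximity` quantifies how tumor cells and immune cells are arranged on a
stained tissue section, and what that arrangement implies for patient
outcome. The inputs are the centroid tables produced by upstream single-cell
segmentation of multiplexed immunohistochemistry (MxIHC) slides: one row per
cell with micrometre coordinates, a nucleated flag, and binary calls for a
marker panel (here SOX10 for melanoma lineage, CD8 for cytotoxic T cells,
plus CD11c/CD40/CD80). Two analysis layers sit on top:

1. **Paired-slide spatial layer.** For each patient a pre-treatment slide
   and an at-progression slide are quantified (tumor-cell density per mm²,
   marker frequency among nucleated cells, and the proximity pairing
   statistic), per-metric log2 fold-changes are formed, changes are tested
   with the Wilcoxon matched-pairs signed-rank test, and each fold-change
   metric is correlated with progression-free survival (PFS) by Spearman
   rank correlation, visualized with a quadratic fit and its pointwise 95%
   confidence band.
2. **Cohort survival layer.** On a TCGA-style expression/survival cohort:
   exclusion filtering, Kaplan–Meier curves and log-rank tests on
   median-split groups, univariable Cox hazard ratios reported per
   interquartile range (IQR), stage-stratified Cox models testing an
   immune-score × tumor-marker interaction via the likelihood-ratio (LR)
   test, Harrell's c-index with bootstrap optimism correction, four-subgroup
   (marker^hi/lo × CD8^hi/lo) Wilcoxon rank-sum comparisons of downstream
   gene expression with Bonferroni correction, and a linear interaction
   model of log2 gene expression on the marker z-score × log2 CD8.

## The pairing statistic

A target (SOX10⁺) cell is *paired* when at least one reference (CD8⁺) cell
lies within a Euclidean centroid-to-centroid distance r (default r = 45 μm,
the scale of juxtacrine/short-range paracrine interaction; r = "any"
degenerates to mere co-occurrence). The slide-level statistic is

    pair_statistic(r) = #{distinct paired target cells} / #{reference cells}

Counting *distinct cells* rather than (target, reference) edges is the
default because the statistic normalizes a cell population size; an
all-edges variant is available via `mode="pairs"`. The comparison is
boundary-inclusive (d ≤ r) and performed on squared distances, so the
KD-tree accelerated search returns exactly the brute-force answer even when
a distance ties r to the last bit; this equivalence is a release gate tested
on 100 random slides. When a slide has no reference cells the statistic is
flagged undefined (`None`), propagated, and excluded pairwise from
correlations with the exclusion count logged; fold-changes with a zero on
either side are likewise flagged rather than patched with a silent
pseudocount (an explicit, logged pseudocount is opt-in).

The density denominator is the declared tissue region area; when absent it
falls back to the bounding box of nucleated cells, with a warning, since
centroid tables rarely ship a tissue mask.

## Synthetic data: what it emulates, and what it does not

The generators provide ground-truth-bearing stand-ins for both layers so
every stage runs and is testable without any data download.

**Slides** are marked point processes on a rectangular window (default
1000×1000 μm): reference cells homogeneous Poisson at `lambda_ref`
(default 2×10⁻⁴/μm² = 200/mm²), target cells Poisson at `lambda_target`
(default 3×10⁻⁴/μm²) with a fraction `attract_frac` placed as isotropic
Gaussian displacements (sd `attract_sigma_um`, default 20 μm) from uniformly
chosen reference cells — the generative analogue of spatial attraction
between interacting cell types — plus unlabeled nucleated background cells
at `lambda_other` (default 1.5×10⁻³/μm², so labeled cells are a realistic
minority of nuclei). The torus boundary is the default because it makes the
Poisson void probability exact: with no attraction, the expected paired
fraction is 1 − exp(−λ_ref·π·r²) ≈ 0.720 at the defaults, which the test
suite checks by Monte Carlo within 3 standard errors. Bounded mode clips
displacements at the window edge and is provided for realism; closed-form
checks are run on the torus only. The generator does not emulate cell
shapes, segmentation error, staining artefacts, or non-Poisson clustering
beyond the attraction construct — so green tests certify the statistics and
their implementation, not robustness to segmentation noise.

**Paired cohorts** (default n = 11 patients, PFS uniform on 1.5–30 months,
matching the scale of a progression cohort on targeted therapy) program a
per-patient log2 fold-change of the target intensity as
`slope · z(−PFS) + Normal(0, noise_sd)` (defaults slope 1.2, noise 0.4),
i.e. shorter PFS ⇒ greater tumor-cell expansion, the direction observed
clinically. The programmed fold-changes are returned as ground truth so
end-to-end tests can compare the pipeline's estimate against the construct.

**Survival cohorts** (default n = 445, early-stage fraction 0.53, echoing
the reference melanoma cohort after exclusions) draw exponential event
times under a proportional-hazards model `h(t|x) = h₀·exp(Σβₖxₖ)` with
independent exponential censoring (defaults h₀ = 0.012/month, censor rate
0.010/month, giving a median OS of a few years and a realistic event
fraction). Default covariates are a standardized immune score (β = −0.55,
protective), SOX10/MLANA z-scores (β = 0.20/0.15, adverse), a late-stage
indicator (β = 0.9), and log2 CD8A expression; downstream response genes
(PDCD1, CD274, IFNG, GZMB) track CD8A positively and the tumor marker
negatively on the log2 scale with a mild negative interaction. Exponential
baselines are a simplification: real cohort hazards are not constant, so
parametric-shape questions are out of scope for these tests.

## Statistical conventions

* **Wilcoxon signed-rank:** zero differences discarded; with ≤ 25 nonzero
  differences the two-sided p is exact over all 2ⁿ sign assignments
  (computed by subset-sum convolution over doubled midranks, which handles
  tied magnitudes); beyond that, a normal approximation with tie
  correction and no continuity correction. The statistic is W⁺.
* **Spearman:** midranks; p from the t approximation with n − 2 df (method
  recorded in the result); an exact permutation option exists for n ≤ 10.
* **Quadratic fit:** OLS on (1, x, x²); the band is the t-based pointwise
  95% CI of the conditional mean with n − 3 residual df.
* **Cox:** lifelines partial likelihood with Efron tie handling. Continuous
  effects are reported as HR per IQR: exp(β·IQR) with CI endpoints
  transformed identically; the IQR uses linear-interpolation (type-7)
  quantiles on the analysis sample, which makes the report invariant to
  affine rescaling of the covariate.
* **Stage** enters stratified Cox models as stratum-specific baseline
  hazards, not a covariate (disease stage is the classic proportionality
  violator).
* **Median splits** send ties to "low" (value ≤ median), logged.
* **LR test:** 2(ℓ_full − ℓ_reduced) against χ² with df = number of added
  terms; a negative statistic beyond −10⁻⁶ raises a convergence error.
* **c-index:** Harrell's c with risk-score ties scored 0.5. Optimism is the
  bootstrap mean of (c of the refit model on its resample) − (that model's
  c on the original data); corrected = apparent − optimism; B = 200 by
  default under one documented seed (B = 50 in the heavier simulations
  below). Bootstrap refits that fail to converge are skipped and counted.
* **Subgroup tests:** two median splits → four subgroups; all 6 pairwise
  Wilcoxon rank-sum tests per response gene; Bonferroni p_adj = min(1, 6p);
  subgroups of size < 2 are flagged, not tested.
* **Cohort filter:** drop OS < 0, missing OS or status, and stage mapping
  to `excluded` (stage 0, "NOS", unparseable); idempotent, counts logged.
  Complete cases are required downstream — multiple imputation and
  penalized variable selection are out of scope.

## Validation design and problem sizes

The validation suite (and `scripts/acceptance.py`, which recomputes the
same quantities from scratch at a user-supplied seed) uses these problem
sizes, chosen as the smallest at which each property is sharp:

* search-oracle equivalence: 100 random slides of 200+200 cells;
* torus paired fraction vs closed form: 50 slides at λ = 2×10⁻⁴/μm²,
  agreement within 3 Monte-Carlo SEs;
* signed-rank exactness: random fixtures with 3–12 nonzero differences
  against literal 2ⁿ enumeration;
* per-IQR HR recovery: programmed HR 2.0, n = 2000 (tolerance 1.8–2.2);
  CI coverage of the null over 500 replicates of n = 150 (≈95%);
* null calibration: 1000 replicates each for the log-rank test (100 per
  arm — large enough that the asymptotic chi-square approximation itself is
  accurate, so the check isolates the implementation) and the stratified LR
  interaction test (n = 100, two strata), compared to U(0,1) by
  Kolmogorov–Smirnov at α = 0.01;
* optimism: 10 noise covariates at n = 60, B = 50, 20 seeds, corrected <
  apparent in ≥ 95%;
* end to end: a 40-patient paired cohort with slope 1.5, noise 0.3, seed
  11, requiring the reported Spearman(density fold-change, PFS) < −0.5 and
  within 0.15 of the Spearman computed on the programmed truth.

## Numerical and degenerate-input choices

Exact-tie safety via squared distances (above); undefined statistics are
explicit flags, never NaN arithmetic; all-zero paired differences, constant
vectors, zero nucleated cells, zero events, empty strata, and collinear
designs raise typed errors (`DegenerateStatisticError`, `ValidationError`)
that the pipeline catches and reports instead of aborting the run (CLI exit
code 3). Simulators derive named substreams from one integer seed
(`numpy.random.SeedSequence`), so identical seeds give byte-identical
outputs and per-patient pieces are reproducible in isolation. Pipeline
reports serialize with sorted keys and carry a SHA-256 digest; a rerun on
identical inputs is byte-identical.

## Known limitations

Whole-slide vs tissue-masked area is the caller's responsibility (the
bounding-box fallback is a crude mask). The pairing statistic ignores edge
effects on bounded windows. The nucleated-cell denominator is taken from
the input flag; whether that flag means hematoxylin-positive nuclei or all
segmented objects is an upstream decision. Survival simulations use
exponential baselines and independent censoring. ESTIMATE-style immune
scores are consumed as a column, never computed.
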