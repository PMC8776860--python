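# mxproximity

Spatial proximity analysis of multiplexed-immunohistochemistry (MxIHC) cell
centroids, paired pre/post-treatment fold-change statistics, and cohort
survival modelling — built for studies of the tumor–immune microenvironment
where the question is whether tumor cells sitting *close to* immune cells,
and the expansion of tumor cells under therapy, track patient outcome.

The package takes segmentation output (per-cell centroid tables with binary
marker calls, e.g. SOX10 for melanoma cells and CD8 for cytotoxic T cells)
and clinical linkage tables; it never touches images. A synthetic-data
module generates marked point patterns and survival cohorts with known
ground truth, so the entire pipeline runs and validates with no download.

## The statistics at the core

**Pairing statistic.** A target cell is *paired* when at least one
reference cell lies within Euclidean centroid distance r (default 45 μm):

    pair_statistic(r) = #{distinct SOX10⁺ cells with a CD8⁺ cell ≤ r} / #{CD8⁺ cells}

computed by an exact-tie-safe KD-tree search that provably matches brute
force. Per-slide metrics also include density (cells/mm²) and frequency
(% of nucleated cells).

**Paired-slide layer.** Per patient, log2 FC = log2(post/pre) of each
metric; Wilcoxon matched-pairs signed-rank test (exact p for ≤ 25 nonzero
differences) for pre-vs-post shifts; Spearman rank correlation of each FC
metric with progression-free survival; quadratic fit with pointwise 95% CI
for visualization.

**Cohort survival layer.** Exclusion filtering; Kaplan–Meier and log-rank
on median-split groups; univariable Cox with hazard ratios per
interquartile range, HR = exp(β·IQR); stage-stratified Cox models testing
an immune-score × marker interaction by likelihood-ratio test; Harrell's
c-index with bootstrap optimism correction; four-subgroup
(marker^hi/lo × CD8^hi/lo) rank-sum expression comparisons with Bonferroni
adjustment; linear interaction models on log2 expression.

## Worked example

`examples/02_paired_cohort_foldchange.py` simulates an 11-patient paired
cohort in which tumor-cell expansion is programmed to be stronger in
patients who progress sooner, then runs the full pipeline:

```
metric            Wilcoxon p  Spearman rho        p
density:SOX10         0.2783        -0.964   0.0000
frequency:SOX10       0.4648        -0.982   0.0000
pairstat:45           0.3652        -0.982   0.0000
pairstat:any          0.3203        -0.955   0.0000

report digest: dd34af939bcf02ad (rerun-identical)
```

The strongly negative Spearman rho for every fold-change metric recovers
the programmed direction — greater tumor-cell expansion (and more tumor
cells within 45 μm of a CD8⁺ cell) in patients with shorter PFS — while the
Wilcoxon column shows that with n = 11 the paired pre/post shift itself is
not individually significant at this effect size. The digest line is the
report's SHA-256: reruns on identical inputs are byte-identical.

`examples/03_survival_cohort_analysis.py` runs the survival layer on a
simulated 445-patient cohort (protective immune score, adverse SOX10):

```
cohort after exclusions: n=445, events=273
early  sox10_z       HR/IQR 1.052 (95% CI 0.853-1.298, IQR 1.28, n=230)
early  immune_score  HR/IQR 0.633 (95% CI 0.488-0.820, IQR 1.42, n=230)
late   sox10_z       HR/IQR 1.160 (95% CI 0.939-1.433, IQR 1.21, n=215)
late   immune_score  HR/IQR 0.503 (95% CI 0.401-0.631, IQR 1.31, n=215)
...
c-index: apparent=0.635, optimism=0.0015, corrected=0.633
```

An HR/IQR of 0.503 means one interquartile step in immune score halves the
mortality hazard in late-stage patients of this simulated cohort.

## Command line

A thin CLI wraps the library:

```sh
mxproximity simulate --kind paired --n 11 --seed 1 --out-dir sim/
mxproximity quantify --cells sim/cells.csv --panel SOX10,CD8 --out metrics.tsv
mxproximity foldchange --cells sim/cells.csv --clinical sim/clinical.csv \
    --panel SOX10,CD8 --out fc.tsv
mxproximity correlate --foldchange fc.tsv --clinical sim/clinical.csv --out corr.tsv
mxproximity survival --cohort cohort.tsv --out survival.json
mxproximity run --config pipeline.yaml --out-dir report/
```

Exit codes: 0 success, 2 validation error, 3 statistical degeneracy
(reported, not fatal).

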