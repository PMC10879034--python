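# progdecon

Gene-program decomposition of expression matrices, fixed-basis projection,
and cohort-level GLM statistics.

`progdecon` is for transcriptomics researchers who want to describe a cell
population not as a hard partition into clusters but as a combination of
**gene programs** — nonnegative weighted gene sets discovered by
non-negative matrix factorization (NMF) — and then reuse those programs to
interpret new bulk or single-cell datasets and to quantify how programs and
cell frequencies shift across disease cohorts. The motivating use case is
gradual populations such as peripheral CD4⁺ T cells, where cluster
boundaries are arbitrary but program activity varies smoothly.

## The model

A normalized, nonnegative genes × columns expression matrix `X` is
factorized as

```
X ≈ W · H,      W ≥ 0 (genes × k),   H ≥ 0 (k × columns)
```

under squared Frobenius loss. Fit quality is summarized by explained
variance derived from residual sums of squares:

```
RSS_c   = Σ_ij (x_ij − w_ic h_cj)²          Evar_c   = 1 − RSS_c / Σ_ij x_ij²
RSS_all = Σ_ij (x_ij − (W·H)_ij)²           Evar_all = 1 − RSS_all / Σ_ij x_ij²
```

The component number k is chosen from a scan using two diagnostics: the
elbow of `Evar_all(k)` and the maximum pairwise Spearman correlation
between columns of `W`, which jumps sharply once components become
redundant; the advisory k is the rank just before that jump.

**Fixed-basis projection.** Given a pre-computed basis `W` (possibly
converted across species through a homolog table), a new dataset is
projected by solving, for each column `x`,

```
min_{h ≥ 0} ‖x − W h‖²
```

exactly by active-set nonnegative least squares, after restricting both
`W` and the query to their shared genes. Two QC metrics accompany each
projection: **POH**, the proportion of the query's highly variable genes
(top 500 by binned normalized dispersion, TCR/IG VDJ genes excluded)
contained in the basis gene set — below 0.1 the query carries variability
the basis cannot represent — and the projection's `Evar_all`.

**Cohort statistics.** With samples grouped into cohorts, per-cluster
frequency change is modeled by a binomial GLM with logit link,

```
(n_cat, n_total − n_cat) ~ Disease + Age/25 + Gender + Project
```

with healthy as the disease baseline, and per-cluster program change by
OLS of the per-sample mean activity on the same predictors. p-values are
Wald tests, corrected by Benjamini–Hochberg FDR across clusters. Samples
whose metadata sex conflicts with XIST-inferred sex (mean raw count
> 0.05 ⇒ female) are removed first.

## Worked example

Simulate data with 4 planted programs, scan ranks, fit, and project:

```bash
progdecon simulate basis --n-genes 300 --k 4 --seed 1 --out W_true.tsv
progdecon simulate expression --basis W_true.tsv --n-columns 400 \
    --noise-scale 0.05 --seed 1 --out X.tsv
progdecon scan-k --matrix X.tsv --k-min 2 --k-max 8 --seed 1 --out scan.json
progdecon fit --matrix X.tsv --k 4 --seed 1 \
    --out-basis W_fit.tsv --out-activity H_fit.tsv --out-diagnostics diag.json
progdecon project --matrix X.tsv --basis W_fit.tsv --out H_proj.tsv --qc qc.json
```

prints

```
advisory k = 4 (elbow at 4)
k=4 evar_all=1.0000 converged=True
POH=1.000 Evar_all=1.000 overlap=300 genes
```

The scan recovers the planted rank (the Spearman redundancy diagnostic
jumps going from 4 to 5 components while the explained-variance curve has
its elbow at 4); the k = 4 fit explains essentially all of the signal
(noise sd was 0.05); and projecting the data back onto the fitted basis
gives POH = 1.0 (every query HVG is a basis gene — the query *is* the
training distribution) and Evar_all ≈ 1.0 (near-perfect reconstruction).
On real queries from other tissues or platforms, POH and Evar_all drop,
and the 0.1 POH threshold flags queries the basis cannot represent.

The same steps are available as library calls (`fit_nmf`,
`scan_components`, `project_expression`, `fit_cohort_models`), and the
sklearn-style estimators `ProgramNMF` and `FixedBasisProjector` compose
with scikit-learn pipelines.

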