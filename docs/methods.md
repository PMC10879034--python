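# Methods

## Decomposition

The factorization minimizes `‖X − WH‖²_F` with `W, H ≥ 0` and no
regularization, solved by coordinate descent (scikit-learn's NMF solver).
Initialization is a nonnegative double SVD with zeros replaced by the
matrix mean (NNDSVDa), followed by a small multiplicative perturbation
(±1%) seeded by `random_state`. This makes every fit a pure function of
the data and the seed — two runs with the same seed are bit-identical —
while the perturbation lets restarts explore distinct local optima.
Defaults: `max_iter = 1000`, `tol = 1e-6`; `converged` in the diagnostics
records whether the tolerance was reached before the iteration cap.

Per-component explained variance `Evar_c` uses the rank-1 slice
`w_·c h_c·` of the *joint* fit, not a per-component refit; this is what
the RSS_c formula states and keeps components comparable within one
decomposition. Because the slices overlap, `Σ_c Evar_c` need not equal
`Evar_all`. Components are relabeled `NMF0…NMF{k−1}` in decreasing
`Evar_c` order for presentation stability.

The inter-component redundancy diagnostic is the maximum pairwise
Spearman correlation computed on the **gene-feature columns of W** (not
on H): the criterion asks whether two *gene programs* rank genes the same
way. Ties receive average ranks; constant columns are excluded from the
statistic with a warning.

### Rank selection

`scan_components` fits each rank in the scan and derives:

* the **elbow** — the scanned k with the most negative discrete second
  difference of `Evar_all(k)`, i.e. where the curve stops gaining;
* the **advisory k** — the first scanned k at or beyond the elbow whose
  successor jumps by more than 0.1 (default) in maximum Spearman
  correlation. Once the true rank is exceeded, the factorization splits a
  real program into correlated copies, so the first jump marks the rank
  just before redundancy sets in.

The advisory value is a suggestion and is never auto-applied; the
diagnostics always carry the full curves. On synthetic data with 4
well-separated planted programs (300 genes, 400 columns, clipped-Gaussian
noise sd 0.05, scan k = 2…8) the advisory rank equals 4 in 8–9 of 10
seeds; the failures are fits where a rank-4 local optimum already splits
a block.

## HVG selection

Statistics follow the classical dispersion recipe: back-transform the
log1p-normalized matrix with `expm1`; per gene compute the mean `m` and
sample variance `v` (N−1 denominator) and report `mean = log1p(m)`,
`dispersion = log(v/m)`; cut genes into 20 equal-width bins of the
reported mean; the normalized dispersion is the within-bin z-score
(ddof = 1). A gene is flagged when `min_mean < mean < max_mean` and
`z > min_disp`.

Pinned edge cases: a nonpositive dispersion (zero variance or zero mean)
reports NaN log-dispersion, receives z = 0 and is never flagged; bins
with ≤ 1 gene or zero spread assign z = 0 (conservative — prevents NaN
propagation and single-gene bins from self-certifying); a mean range at
floating-point noise level collapses to a single bin. Selection applies
thresholds first, then ranks the flagged genes by z descending with
lexicographic gene-id tie-breaks (deterministic across platforms), and
clamps to `n_top` with a logged warning when fewer genes are available.

Two presets: `reference` (min_disp = 0.5, no clamp) for fitting a basis
and `query` (min_disp = 0.1, top 500) for projection QC. Both exclude
VDJ-segment genes of the TCR/IG loci by symbol prefix
(TRAV/TRAJ/TRBV/…/IGLJ) because their variance reflects clonal structure
rather than transcriptional state; constant-region genes (TRBC1, IGHM…)
are retained. Normalization (`normalize_and_log`) rescales each nonzero
column to 10⁴ counts (CP10K) and optionally applies log1p; all-zero
columns pass through unchanged.

## Projection (NMFproj)

Basis and query are first restricted to their gene intersection, in query
gene order; `W` is **not** renormalized after subsetting (consequence:
absolute activity scales are comparable only at similar overlap, which
the QC fields expose). Fewer overlapping genes than components is a hard
error; overlap below 50% of basis genes warns. Cross-species transfer
renames each basis gene to the *first* homolog in table order; unmapped
genes are dropped and target collisions keep the first source in basis
order.

Each query column is solved by exact Lawson–Hanson active-set NNLS —
deterministic and identical to iterative fixed-W multiplicative updates
at convergence. KKT residuals are verified against a 1e-8 relative
tolerance; rank-deficient bases produce a warning and a valid (but
non-unique) solution. The query scale is caller-controlled (raw counts
and TPM both make sense, matching how the basis was fit); an opt-in
CP10K+log mode is provided.

POH uses the retained basis rows as the reference set by default; the
basis's fit-time HVG universe can be used instead via a flag. The 0.1
low-quality threshold is shipped as a constant. POH needs at least two
query columns (variance is undefined otherwise) and is reported as NaN
with a notice for single-column queries.

## Cohort GLMs

The frequency model is a plain binomial GLM (no overdispersion
correction; beta-binomial is out of scope). Design encodings are fixed
for reproducibility: disease one-hot with `healthy` as reference (first
observed level when healthy is absent, with a note), age divided by 25
years so a typical adult contributes an O(1) covariate, gender with male
as reference, project one-hot with the first observed level as reference.
Terms without variation are dropped with a warning; aliased columns of a
rank-deficient design are removed greedily (first independent set kept);
perfect separation yields flagged NaN estimates, never silent ones.

The feature model takes the **per-sample mean** activity per cluster as
the observation — samples, not cells, are the independent unit, which
avoids pseudoreplication and is the conservative reading.

FDR families: BH is applied across clusters within one term for the
frequency model and across clusters within one (term, component) pair
for the feature model; the family choice is recorded in the output.
"Scaled intercepts" min–max scale feature-model intercepts across
clusters within a component to [0, 1] as a baseline activity profile;
raw intercepts are kept alongside, and a degenerate range scales to 0
with a warning.

Sex QC precedes fitting: mean raw XIST count > 0.05 infers female;
conflicts with metadata remove the sample; samples without XIST pass with
a notice.

## Synthetic data

Generators are pure functions of their arguments and seed. The basis
generator assigns each component `⌊n_genes/k⌋` dominant genes with
gamma(2, 1) + 1 weights; `overlap ∈ [0, 1]` scales gamma-distributed
cross-component bleed (0 ⇒ disjoint supports). Activities are
gamma(shape 2, scale 1): nonnegative, right-skewed, occasionally near
zero — mimicking sparse program usage. Noise is clipped-Gaussian (fast,
analytic-style tests) or Poisson counts around `W·H` (single-cell-like;
an optional target column sum emulates library size). Gene identifiers
are `G000001…` with a configurable fraction of `TRBV…` decoys to exercise
the VDJ filter.

The cohort generator draws disease (uniform over declared levels), age
(uniform 20–70 y), sex (fair coin), and project (uniform), pushes them
through the same logit/linear models the statistics layer fits, and
embeds the true coefficients. XIST means are drawn consistent with the
drawn sex. What it does **not** emulate: dropout, batch/library-size
gradients beyond Poisson, overdispersed (beta-binomial) counts, and
correlated covariates — so passing recovery tests demonstrates
correctness of the estimators under their own assumptions, not
robustness to real-data violations of them.

## Problem sizes and numerical choices

Validation workloads are sized for interactive runs: rank-scan recovery
uses 300 genes × 400 columns over 10 seeds; GLM recovery uses 100
cohorts of 400 samples × 1000 cells (plus 500 null fits); projection
exactness uses 100 genes × 5 components × 50 columns. Tolerances: 1e-12
for closed-form identities, 1e-9/1e-6 for NNLS and recovery (float64
accumulation), 0.01 slack on Evar monotonicity across ranks (local
optima), ±0.05 on simulation means.

## Known limitations

* Evar can be negative for a poor or mismatched factorization; only the
  upper bound of 1 is structural.
* The advisory rank assumes programs of roughly comparable magnitude;
  heavily imbalanced programs can move the elbow below the true rank.
* Projection transfers no information about genes absent from the basis;
  POH flags this but nothing corrects it.
* The binomial GLM understates uncertainty when counts are overdispersed
  relative to binomial sampling; q-values on real cohorts should be read
  with that in mind.
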