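# Methods

This note documents the models implemented in `crossde`, the assumptions
behind the synthetic data, the numerical choices, and what the test suite
does and does not establish about real data.

## Pipeline model

The package implements a **two-step** cross-platform meta-analysis: each
study is analyzed separately on its own scale, and only the per-gene
p-values and directions are combined. The ComBat-merged matrix is *not*
the source of the meta p-values; it serves the PCA batch diagnostics and
an optional merged-analysis mode. This ordering is a deliberate design
choice: combining p-values avoids putting intensities and counts on a
common scale for inference, while the merged matrix is still useful to
verify that the between-study effect is removable.

### Harmonization (`crossde.io`)

Platform features are collapsed to gene ids by keeping, per gene, the
feature with the highest mean expression (ties broken lexicographically
by feature id). This rule is common practice where no annotation-quality
information is available; it is deterministic and idempotent. Studies are
then restricted to the lexicographically sorted intersection of their
gene universes — Fisher combination is only defined for genes measured in
both studies; genes private to one study are dropped and counted in the
log.

The absence filter pools **all samples of both studies** and removes a
gene when the fraction of samples in which it is absent is strictly
greater than the threshold (default 0.8). "Absent" means a zero count for
RNA-seq; for continuous intensities, a value at or below the study-wide
matrix minimum (the platform's effective detection floor — "absence" has
no canonical definition for continuous data, so the floor is used).
Fully-absent genes are always removed regardless of the threshold, which
keeps a threshold of 1.0 meaningful.

### Normalization (`crossde.normalize`)

Microarray intensities: generalized log, glog2(y) = log2((y + √(y²+c²))/2),
followed by quantile normalization across samples. The glog behaves as
log2(y) for y ≫ c and compresses variance near zero; c defaults to the
5th percentile of positive intensities ("auto"). This is a closed-form
stand-in for model-based variance-stabilizing normalization: it captures
the variance-stabilizing intent with reproducible arithmetic, and a plain
`log2(y + offset)` path is provided for sensitivity analysis. Quantile
normalization replaces each column's sorted values by the rank-wise mean
of all sorted columns; tied values receive the mean of the reference
values their tied ranks would occupy, so the transform stays monotone and
well defined.

RNA-seq counts: log2-CPM, `log2((count + c0) / (lib + 2·c0) × 1e6)` with
prior count c0 = 0.5 and the library size as the column sum. The doubled
prior in the denominator keeps the transform bounded and scale-invariant
for proportional columns.

### Moderated t (`crossde.de`)

Two-group model only (case vs. control within one region): effect = mean
difference, s² = pooled within-group variance, df = n₁ + n₂ − 2. The
variance prior (d₀, s₀²) is estimated by moment matching: with
z = log s², the scaled-F model implies E[z] and Var[z] in digamma/
trigamma closed forms; Var[z] in excess of trigamma(df/2) determines d₀
via the trigamma inverse (Newton iteration), and E[z] then gives s₀².
When the empirical spread of log s² does not exceed pure chi-square
sampling noise the prior is degenerate: d₀ = ∞ with s₀² the mean sample
variance (this makes the estimator exact for a point mass of variances,
and reduces the test to a z-test). The closed-form moment fit was chosen
over the full marginal-likelihood fit because it is reproducible and
oracle-testable; on 300-gene matrices it agrees with the reference R
implementation to a fraction of a percent (see `tests/test_r_oracles.py`).

Zero effects map to direction "down" with a logged warning — an arbitrary
but deterministic tie rule that in practice occurs only on degenerate
synthetic input.

BH adjustment is the standard step-up: q₍ᵢ₎ = min over j ≥ i of m·p₍ⱼ₎/j,
capped at one, returned in input order.

### ComBat (`crossde.batch`)

Parametric empirical Bayes location/scale adjustment. Each gene is
standardized against a grand mean (batch-size-weighted) plus the
protected covariate fit — the case/control label is always in the
standardization design so disease signal is not absorbed into the batch
estimate; a batch fully confounded with the covariate is rejected with an
explanatory error. Per batch, gene-wise additive effects get a normal
prior (moments of the raw estimates) and multiplicative effects an
inverse-gamma prior (method of moments); the posterior point estimates
are solved by the standard fixed-point iteration to max |Δ| < 1e−6
(cap 500 iterations). Only the parametric variant is implemented. The
implementation matches the reference R implementation to < 5e−3 in the
adjusted values on test matrices.

PCA diagnostics: genes are centered, sample scores come from the SVD of
the centered matrix, and batch mixing is summarized as the silhouette of
the batch labels in (PC1, PC2) — near zero or negative means mixed.

### Fisher meta-analysis (`crossde.meta`)

F_g = −2 Σ ln P_gs referred to χ²(2S); for S = 2 the upper tail is
(1 + F/2)e^(−F/2) (the generic and closed forms agree to 1e−12 over
F ∈ [0, 200]). Per-study p-values are floored at 1e−300 before taking
logs, with a logged warning. Direction disagreements are resolved in
favor of the study with the smaller raw p and flagged `concordant=False`;
exactly tied opposite evidence is marked ambiguous and excluded from the
pathway/network stages. The reported F_g is negative for up-regulated
genes and positive for down-regulated ones, matching the reporting
convention of the reference table.

The significance filter defaults to **BH-adjusted** combined p < 0.05.
The published table's printed combined p-values are demonstrably
BH-adjusted: the raw χ²(4) tails of the printed |F_g| values are orders
of magnitude smaller than the printed p's, and a single effective test
count m ≈ 18,100 reconciles every printed (rank, |F_g|, p) triple under
step-up with running minimum (`crossde.reference`; 39 of 40 rows match to
the printed precision, the one exception being a last-rank row whose
value is set by a gene just below the printed cut, which the step-up
upper bound accommodates). A config flag (`use_adjusted=false`) preserves
the literal raw-p reading.

The effective-test-count inference itself uses the one-sided structure of
step-up: each printed row implies a hard lower bound on m (its value can
only have been pulled *down* by unprinted neighbors), the rows compatible
with the resulting envelope are the ones at which the running minimum is
attained, and m is a precision-weighted least-squares fit over those rows.

### ORA (`crossde.ora`)

Exact upper hypergeometric tail P(X ≥ k) per gene set, BH across all
tested sets. The background universe defaults to all genes that entered
the meta-analysis (configurable); sets are intersected with the universe
and filtered to 5–2,000 members *before* adjustment, which determines the
test count. One-sided over-representation only.

### PPI hubs (`crossde.network`)

The reference network is a plain two-column edge list (an optional third
column is a confidence score filterable with `--min-score`); self-loops
and duplicate edges are dropped. Zero order = subgraph induced on the
seed genes with isolated nodes removed; first order = seeds plus direct
neighbors. Hub ranking is by degree, ties by betweenness (exact,
unnormalized pair counts), then lexicographic — "high centrality" is
operationalized as betweenness since no specific centrality is canonical
here. The random-walk-with-restart score is the stationary distribution
of a walker restarting to the uniform seed vector with probability 0.5
(default), computed by power iteration on the column-normalized adjacency
to max |Δ| < 1e−10; mass on degree-0 nodes is redistributed to the
restart vector so scores always sum to one.

## Synthetic data (`crossde.simulate`)

The generator's defaults are the study conditions used throughout the
tests: 18,000 shared genes; group sizes (41, 50) array and (26, 105)
RNA-seq; 5% DE genes with |log2 FC| ~ |N(1.0, 0.4)| and random sign; 5%
of DE genes direction-discordant between platforms; array noise sd 0.8
log2 units (typical inter-sample variability of single-channel arrays);
negative-binomial dispersion 0.1 (bulk-tissue scale); gene-wise
between-study shift sd 0.5 log2 units applied to the RNA-seq study (the
additive structure ComBat removes); 1% dropout genes zeroed in ~90% of
the samples of both studies to exercise the absence filter.

Array intensities are generated on the natural scale, 2^(baseline +
effect + noise) with baselines log-uniform over [4, 14] log2 units, so
the normalization stage has real work to do. RNA-seq means are
2^(baseline + shift + effect) scaled by per-sample library factors drawn
log-uniformly over [1/3, 3]; counts are NB with constant dispersion
(mean–dispersion parameterization; var = μ + φμ²). Dropout genes are
drawn from the non-DE pool so ground-truth bookkeeping stays exact.

What the generator does **not** emulate: probe-level microarray
structure, paired-eye or within-donor correlation, disease-stage strata,
gene–gene correlation, mean-variance trends beyond the NB form, and
platform-specific coverage biases. Passing tests therefore establish the
*arithmetic and calibration* of the pipeline under a clean two-platform
model, not its behavior under every pathology of real GEO data.

## Test design and problem sizes

Oracle tests freeze hand-computed or brute-force values: BH against the
quadratic-time definition, the hypergeometric tail against exhaustive
enumeration of all draws (N ≤ 12), betweenness against shortest-path
enumeration (≤ 8 nodes), and the moderated-t/ComBat stack against the
reference R implementations on small matrices. Calibration and recovery
tests run at reduced but representative sizes chosen to keep the default
suite fast: null calibration at 10,000 genes, ComBat recovery at 2,000
genes × 40 samples (residual noise sd 0.15 so that shift-recovery error
is dominated by the prior, not by sampling noise), silhouette decrease at
1,000 genes × 30 samples over 20 replicates, and the power-dominance
experiment at the full default conditions over 20 seeds.

## Known limitations

* Two studies, two groups: no covariates, no multi-factor designs, no
  precision weights; S > 2 is supported by the combination formula but
  not exercised against a reference.
* The glog+quantile path is a stand-in for model-based VSN; absolute
  normalized values differ from VSN even though downstream inference is
  rank-driven and robust to this.
* ComBat is parametric-prior only; no reference-batch or count-level
  variant.
* The hypergeometric ORA ignores gene-set overlap and topology.
* The effective test count m of the published table is inferred, not
  printed; conclusions that depend on it are internal-consistency checks,
  not reproductions of the original universe size.
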