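# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and the limitations of `coexsig`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator produces gene-by-sample matrices from a Gaussian latent-factor
model. For gene *g* in sample *s*:

    x[g,s] = u_g · f_{m(g)}(s) + b_{g,fam(s)} + ε[g,s]

- `m(g)` is the planted module of *g*; background genes have no factor term.
- Factors `f_m` are standard normal per sample. With
  `family_factor_corr = ρ > 0` they decompose as
  `√ρ·g_family + √(1−ρ)·e_sample` (unit marginal variance), modelling
  family-shared baseline module activity — shared genetics, environment and
  processing batch. The default is ρ = 0, i.e. fully independent samples.
- Loadings `u_g ~ Normal(loading_mean, loading_sd)` truncated to (0, 1].
- Disease: in affected samples the factors of `disease_modules` are shifted
  by `disease_effect`, expressed in factor SD units. The signal therefore
  lives at the module-eigengene level, not in individual genes.
- Family offsets `b ~ Normal(0, family_offsets_sd²)` are constant within a
  (gene, family) pair, so family-control normalization cancels them exactly.
- Noise `ε ~ Normal(0, noise_sd²)`.

The marginal variance of a member gene is `u²·var(f) + family_offsets_sd² +
noise_sd²`, which the test suite checks against the closed form. All draws
come from one `numpy` generator seeded by `config.seed`; every dataset is
bit-reproducible.

What the generator does **not** emulate: count-level sampling noise (data
are Gaussian at the log scale), probe effects, gene–gene correlation beyond
the block-factor structure, heavy-tailed expression distributions, and
outlying samples unless constructed explicitly. Passing tests demonstrate
that the algorithms recover the structure this model plants; they do not
certify performance on real cohorts, where module structure is weaker and
overlapping.

Default study designs used in the tests and acceptance script, chosen to
mirror a small rare-disease program: a detection benchmark of 2000 genes
with three 100-gene modules, loadings 0.8, noise SD 0.6, 50 samples; an
association cohort of 30 samples (balanced) with a 1.5-SD disease effect;
a reference-signature cohort of 10 cases / 40 controls (rare-disease
cohorts are control-heavy); and singleton-classification cohorts of four
two-member families (one candidate family, three control families),
matching a one-patient-versus-three-controls comparison design.

## Expression input and QC

Matrices are TSV, genes in rows (a transposed orientation flag is
provided). Counts convert to `log2(RPKM + 1)`:
`RPKM = counts / ((length/1e3) · (libsize/1e6))`. Base 2 with a +1
pseudocount is a convention choice — zero counts map to exactly 0 — and is
isolated in one function should a different convention be needed.

Sample outliers are flagged by standardized mean inter-sample correlation:
a sample whose z-scored mean Pearson correlation with all other samples
falls below −2.5 is removed, and the criterion is re-evaluated until no
sample is flagged. The rule needs at least 4 samples and removes one sample
per iteration (the worst), which makes the outcome order-independent.

## Preprocessing

- **Covariate removal** is per-gene ordinary-least-squares residualization
  (categoricals one-hot encoded, one level dropped; the grand mean added
  back). Empirical-Bayes shrinkage of covariate effects is deliberately not
  reproduced: no shrinkage hyper-parameters are available to match, and OLS
  residualization is idempotent and transparent. The trait of interest must
  never be included as a covariate.
- **Family-control normalization** subtracts, per gene, the expression of
  each family's single designated control (metadata column
  `family_control`, falling back to `status == 0`); control columns are
  dropped. Subtraction (not a ratio) is correct because inputs are
  log-scale. The pipeline default order is family normalization before any
  remaining covariate removal, switchable via
  `preprocess.covariates_before_family_norm`.
- **Differential expression** is a per-gene Welch t-test with
  Benjamini–Hochberg FDR; a gene "passes" when `fdr < 0.05` and
  `|log2FC| > 0.3`. This replaces a negative-binomial count model by
  design: the DE stage only feeds the threshold filter, and inputs are
  log-scale values, not counts. Note that the empirical FDR of a single
  simulated replicate fluctuates widely around its controlled expectation
  (BH controls the mean, not each draw); tests therefore average over
  replicates.

## Network and modules

- Correlation: Pearson. Biweight midcorrelation would be more robust to
  single-sample outliers but is not implemented; the correlation function
  is one swappable call site.
- Adjacency: unsigned by default (`|r|^β`); signed available.
- Soft-threshold choice: connectivity `k_i = Σ_j a_ij` is discretized into
  10 equal-width bins; the signed scale-free fit index is the R² of
  log10(frequency) on log10(mean bin k), negated when the slope is
  positive. The chosen β is the smallest candidate (grid 1..20) with fit
  ≥ 0.8, else the maximizer. **Guard:** when that choice leaves the network
  with mean connectivity below 1 per gene — which happens on small gene
  sets where the fit first succeeds only at β ≥ 12, a regime in which the
  adjacency is annihilated and no module can survive a static-height cut —
  the pipeline falls back to the conventional sample-size defaults
  (unsigned: 9/8/7/6 for < 20, < 30, < 40, ≥ 40 samples; signed doubled).
  The selection rule itself is unchanged and reported in
  `soft_threshold.tsv`.
- TOM and clustering: the exact TOM formula is in the code and README;
  clustering is average linkage on `1 − TOM`.
- Tree cut: the deterministic "tree" variant — cut all merges above
  0.99 × the tallest merge; branches with ≥ `min_module_size` (default 30)
  leaves become modules, labelled by decreasing size; the rest is label 0.
  This variant is reproducible and easy to reason about, but it is fuzzier
  at module boundaries than the hybrid PAM-stage algorithm: background
  genes that merge below the cut height attach to a module branch. At
  moderate powers this adds roughly 10–40 % extra genes per module on
  planted-truth data (visible in the signature sizes the tests report),
  which is why detection quality is evaluated with membership-overlap
  statistics (ARI, Jaccard) rather than exact set equality.
- Eigengenes: member genes are standardized, the first right singular
  vector of the member × sample block is rescaled to unit variance and
  oriented to correlate nonnegatively with the module mean profile (exact
  ties break toward the first member gene). `variance_explained` is the
  leading eigenvalue share.
- Merging: iteratively merge the closest module pair with eigengene
  dissimilarity `1 − cor` below 0.25, recomputing after each merge.
- Hubs: intramodular connectivity kIM (summed adjacency to module
  co-members) and kME (correlation with the module eigengene); ties break
  by gene order.

## Association and selection

Point-biserial Pearson correlation of each eigengene with the 0/1 trait;
two-sided p from `t = r√((n−2)/(1−r²))` with n−2 df; `|r| = 1` maps to
p = 0. Disease modules are those with raw p < α (default 0.05), ordered by
p; BH-adjusted values are reported alongside but do not gate selection.
Consequence: with k modules tested, a null cohort yields a non-empty
signature with probability ≈ 1 − 0.95^k (≈ 14 % at k = 3). This is the
intended behaviour of raw-α selection and is measured, not hidden, by the
type-I calibration in the acceptance script.

## Cross-dataset comparison

- Overlap: exact upper-tail hypergeometric `P(X ≥ overlap)` via the
  survival function. For cross-dataset tests the universe is the set of
  genes present in both datasets through the one-to-one ortholog map —
  the most conservative defensible universe; label-0 pools are excluded;
  BH correction runs across the whole module-pair matrix.
- Preservation: for each reference module, the observed statistics are
  (i) mean within-module adjacency in the *test* data and (ii) the
  correlation between intramodular connectivity vectors computed in
  reference vs test data, each z-scored against ≥ 20 (default 100) random
  same-size gene sets drawn from the shared genes. `Z_summary` is their
  mean. This is a two-statistic distillation of the published ~7-statistic
  composite; the conventional reading (Z > 10 strong, 2–10 moderate, < 2
  none) is used in tests, not hard-coded into decisions. A numerically
  degenerate null (e.g. test data identical to reference, where every
  permutation scores alike to machine precision) is reported as Z = 0 for
  that statistic rather than as noise.
- Enrichment: per (module, gene set) hypergeometric tests against a GMT
  collection, BH within module, universe either all genes or assigned
  genes.

## Signature classification

`derive_signature` runs the full chain (optional covariate removal →
network → modules → association) and records provenance (power, cut
parameters, α, cohort sizes, the association table).

`classify_variant` has two modes because standard network analysis does not
define modules from a single normalized sample:

- `module_overlap` (≥ 8 effective samples): detect modules in the
  family-normalized patient data and hypergeometric-test every patient
  module against each signature module; BH across the full test matrix.
- `deviation_set` (default for singletons): the candidate's deviation gene
  set is every gene whose family-normalized value deviates from the
  normalized controls by more than 2 robust SD (median/MAD, scaled by
  1.4826); that set is hypergeometric-tested against each signature module.

The decision statistic is the minimum BH-adjusted p; `supported` means it
falls below α = 0.05. The call expresses evidence of signature association
only — it is explicitly not a clinical variant classification.

**When singleton classification can work at all.** The deviation-set test
treats genes as independent, but module genes deviate *coherently*: a
single large fluctuation of normal module activity between the candidate
and their family control mimics a disease perturbation. The package's own
analysis of this (reproducible from the generator) shows that with module
activity independent across family members (ρ = 0), the null
false-positive rate is ≈ 25 % — singleton diagnosis is then impossible in
principle. Family normalization is meaningful precisely because family
members share baseline module activity; the classifier demonstrations
therefore use ρ = 0.9. On the sensitivity side, a design-time power curve
(50 replicates per point, 3-control design) gave supported rates of
2/50, 4/50, 12/50, 30/50, 43/50, 49/50 and 50/50 at effects 0, 0.5, 1.0,
1.5, 2.0, 2.5 and 3.0: the few-control MAD estimate is noisy, so reliable
single-sample detection requires a perturbation several residual SDs
strong. The demonstration effect is fixed at 3.0 — the severe-perturbation
regime in which near-complete separation of affected and benign singletons
is attainable — and the acceptance script reports the measured
sensitivity, specificity and median p of both arms.

## Numerical conventions and degenerate inputs

- All hypergeometric p-values are floored at the smallest positive double
  and capped at 1; `P(X ≥ 0)` is exactly 1.
- Zero-variance genes are dropped with a warning before correlation;
  passing them to `pairwise_correlation` directly is an error.
- Ties: module labels by decreasing size then lowest member index; hub
  rankings and edge exports by gene order; eigengene sign by mean-profile
  orientation, then first member gene.
- Sub-seeds for permutation and simulation streams are derived
  deterministically from the user seed; every output records the seed used.

## Known limitations

- Desk-scale target is ≤ 5000 genes: full dense correlation/TOM matrices,
  no block-wise decomposition.
- The static-height tree cut's boundary fuzz (above) makes exact module
  sizes sensitive to the chosen power.
- The scale-free fit index is unstable on small gene sets (< ~1000 genes),
  where the connectivity histogram is strongly bimodal; the sample-size
  fallback mitigates but does not remove this.
- The hypergeometric classifier p-values assume gene-level independence
  and are anti-conservative under coherent module fluctuations; calls near
  the threshold should be treated as qualitative evidence.
- No quantitative-trait association, no GO service integration (gene sets
  are flat GMT inputs), no count-level DE model.
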