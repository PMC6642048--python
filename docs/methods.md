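# Methods

This note documents the statistical model behind `tmetargets`, the
conventions and defaults each stage uses, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Co-expression profiling

For each cancer-type cohort (a genes × samples matrix of bulk expression
values), every gene is correlated with the pan T-cell marker (*CD3E* by
default) using the Pearson product-moment coefficient restricted to
**pairwise-complete** samples: only tumors with non-missing values for both
the gene and the marker contribute. A cell of the resulting gene ×
cancer-type profile is reported missing when fewer than `min_samples`
complete pairs remain (default 10 — two- or three-point correlations are
numerically legal but scientifically meaningless) or when either restricted
vector has zero variance. Pearson correlation is invariant to per-gene
positive affine transforms, so the profile is identical whether cohorts are
supplied as raw TPM-like values or per-gene z-scores; `zscore_normalize`
is provided for symmetry with typical public-cohort exports.

Cohorts can be excluded by label before profiling. The motivating use is
thymoma: thymic tumors arise in the organ where T cells mature, so their
bulk expression confounds the infiltration signal the marker is meant to
proxy.

Genes are summarized by the **median** correlation across cancer types
(even counts average the two central values; a gene with no observable
cells has a missing median) and ranked descending. Ties are broken by
ascending gene symbol — a deterministic convention; genes with missing
medians sort last with missing rank. Signed correlations are stored and
ranked throughout; absolute values appear only inside the complementarity
scores, which define them explicitly.

## Complementarity scores

With ρ_TC, ρ_TP, ρ_TA the per-cohort correlations of a target gene with
*CD3E*, *PDCD1* and *CTLA4*:

- PDCD1 complementarity: `|ρ_TC| (|ρ_TC| − |ρ_TP|)`
- joint complementarity: `|ρ_TC| min{|ρ_TC| − |ρ_TP|, |ρ_TC| − |ρ_TA|}`

Both scores lie in [−1, 1]; the joint score equals the PDCD1 score exactly
when |ρ_TA| ≤ |ρ_TP| and never exceeds it. Scores are computed **per
cancer type and then medianed** across types — not evaluated once on the
median correlations; the two orders differ and the per-type-first order is
the one that matches a score defined cohort-wise. A (gene, type) cell
missing in any required profile is excluded from that gene's median rather
than zero-filled, consistent with the pairwise-complete philosophy. The
positive-score filter (`filter_positive_scores`) is a reporting view; the
full table is always produced.

A checkpoint gene can never top its own complementarity ranking: its
self-correlation is 1, so its own score is `|ρ_TC|(|ρ_TC| − 1) ≤ 0`.

## Preranked enrichment

`enrichment` re-implements weighted-KS preranked gene-set enrichment.
Walking the descending ranking, the running sum gains
`|s_i|^p / Σ_hits |s_j|^p` at set members and loses `1/(N − N_hits)` at
non-members; the enrichment score (ES) is the running-sum value of largest
magnitude, signed. Conventions:

- `weight_exponent` p defaults to 1 (the standard "weighted" scheme);
  p = 0 recovers the classic unweighted KS statistic.
- Hit increments use |score|^p even for negative scores (standard
  preranked behavior).
- If every hit score is exactly 0 the hit weights fall back to 1/N_hits.
- Sign ties in peak selection (|max| = |min|) resolve toward the positive
  side, for determinism; cumulative float error is clamped so |ES| ≤ 1
  exactly.

The null is **gene-tag permutation**: ES of uniformly random subsets of
the ranked universe at the observed (restricted) set size, `n_perm`
defaulting to 1000. Nulls are generated per distinct set size with a seed
derived from (master seed, size), so equal-size sets share a null and
results are invariant to GMT line order. NES divides ES by the mean |ES|
of same-sign null values (NES of an ES equal to its same-sign null mean is
1; ES = 0 maps to NES = 0). The nominal p is the fraction of same-sign
null ES at least as extreme, floored at 1/(n_perm + 1); a null with no
same-sign draws is flagged `degenerate_null`. The FDR q is the signed-NES
ratio statistic — fraction of pooled normalized null NES at least as
extreme over fraction of observed NES at least as extreme, per sign,
clamped to [0, 1] — made monotone so a more extreme NES never receives a
larger q. With a permutation null of size n_perm, q-values below
~1/n_perm are not resolvable; the implementation reports 0 rather than
extrapolating the null tail.

Set-size bounds default to [15, 500] after restriction to the ranked
universe (the synthetic pipeline lowers the floor to 5 because its toy
collections are small); dropped sets are logged.

## Responder analysis

Each response group (responder / non-responder) gets its own ordinary
least-squares regression. The orientation is **PDCD1 regressed on CD3E**:
the T-cell marker is the natural predictor of per-sample checkpoint
expression. It is an argument (`predictor` / `response`), not a hard-coded
choice. R² is computed as 1 − SSres/SStot, which for simple regression
with an intercept equals r²; the identity is asserted in tests at 1e-9
relative tolerance. Groups need ≥ 3 samples and a non-constant predictor.

The two groups' squared residuals — each from its own fit — are compared
with a **two-sided** Mann–Whitney U test (no direction is presupposed; the
direction actually observed is reported alongside). The p-value is exact
by full enumeration when both groups have ≤ 8 tie-free observations, and
otherwise uses the normal approximation with midrank tie correction and
continuity correction. Outlier exclusion is by explicit sample ID, with
both the full and the reduced analyses reported side by side; a
Q3 + 3·IQR flag per group is provided as a convenience heuristic only.

Two caveats worth knowing: (i) squared residuals within a group are mildly
dependent through the shared fit (they sum to zero against the design), so
the U test runs slightly above nominal level — about 5.4% at α = 0.05 for
groups of 14 and 12 in our calibration; (ii) if checkpoint expression is
forced non-negative while the coupling noise is large relative to the
intercept, the clamp creates a point mass at zero that violates the linear
coupling model and inflates the test further (to ~12% in the default
preset's noise regime). The type-I calibration test therefore runs in the
clamp-free regime; power statements about the default preset are
unaffected.

## The synthetic-data generator

### Bulk cohorts

Expression is a two-factor linear-Gaussian model: per sample, a latent
T-cell infiltration level f and an independent latent PD-1 program level g
are standard normal, and gene *j* has

    x_j = λ_j f + κ_j g + ε_j,   ε_j ~ N(0, σ_j²)

The marker gene is the noiseless factor itself (λ = 1, κ = 0, σ = 0,
enforced at config validation), so every gene's population correlation
with the marker is exactly `λ / sqrt(λ² + κ² + σ²)` — the recovery target
for the ranking. A *PDCD1* stand-in is a gene with both λ and κ large: it
tracks infiltration *and* carries the second axis, precisely the pattern
the complementarity score penalizes. Units are irrelevant (Pearson
invariance), which is why a unit-variance latent scale suffices.

Defaults mirror the emulated study scale: 31 cancer types × 310 samples
(≈ 9.6k tumors). The default panel (`default_gene_specs`) plants signal
genes with population marker correlations evenly spaced in [0.5, 0.95],
checkpoint stand-ins PDCD1 = (λ 0.80, κ 0.55, σ 0.30) and CTLA4 = (0.70,
0.35, 0.50), and pure-noise null genes. Missing values can be injected
completely at random at a configurable rate to exercise the
pairwise-complete path. Per-type seeds derive from
`SeedSequence((master_seed, index_in_sorted_labels))`, making cohorts
independent of iteration order and bit-reproducible.

What the generator does **not** emulate: tumor purity, copy-number
contamination, batch effects, count-distribution (negative-binomial)
noise, or correlated gene modules beyond the two factors. Passing recovery
tests therefore demonstrates that the statistics do what they claim under
their own assumptions — not that real cohorts satisfy those assumptions.

### Responder cohorts

Default sizes are 14 responders vs 12 non-responders. Marker expression is
log-normal (meanlog 3, sdlog 1 — TPM-like, strictly positive, median
≈ 20); checkpoint expression is `1 + 0.6·CD3E + noise` with group noise SD
1 (responders) vs 25 (non-responders), clamped at zero because TPM is
non-negative. One responder outlier with ≥ 5× both column maxima is
planted by default; it is placed **on** the coupling line so a noiseless
responder group remains exactly linear. The noise SDs were chosen so the
per-group correlations fall in the regime the analysis targets (responder
r ≈ 1, non-responder r ≈ 0.7) given the log-normal marker scale.

## Problem sizes used in the acceptance computations

Recovery and calibration numbers reported by `scripts/acceptance.py` and
asserted in `tests/test_acceptance.py` use: 8 cancer types × 500 samples
with 500 null genes (co-expression recovery, 100 replicates); the same
scale with 100 nulls for the complementarity outranking check (100
replicates) and with 600 coupled genes (λ ∈ [0.3, 0.9]) + 400 nulls for
the top-600 positivity scan (10 replicates); a 1000-gene ranking with
2000 permutations for enrichment p-uniformity; 200 replicates of the
default responder preset for power and 1000 clamp-free replicates for
type-I error; and one full 31 × 310 pipeline run with 1000 permutations
for the end-to-end quantities. These sizes were chosen to make the
Monte-Carlo standard errors small relative to the asserted margins.

## Known limitations

- The enrichment q-value is permutation-resolution-limited (no tail
  extrapolation), so very small q's saturate at 0.
- The published top-co-expression table prints medians to three decimals;
  within tied printed values the original ordering is unrecoverable, and
  the deterministic symbol tie-break may permute genes inside a tie group.
- The responder U test's mild anti-conservatism under within-group residual
  dependence is documented above rather than corrected; a
  permutation-of-labels test would fix it but is not what the analysis
  this package reproduces used.
- Correlation-based screening is deliberately coarse: it cannot separate
  "expressed by T cells" from "expressed by cells that co-occur with
  T cells", and marker choice (CD4/CD8 partitioning, other CD3 chains) is
  supported via the `marker` argument but not systematically compared.
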