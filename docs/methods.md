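# Methods

This document states the models the package implements, their assumptions,
the default parameters and why, the numerical choices made, and known
limitations. Symbols: a feature table has counts `x_ij` for taxon `i` in
sample `j`; `p_ij = x_ij / Σ_i x_ij` is relative abundance.

## Preprocessing

* **Low-count filter** (`filter_low_count_taxa`): drop taxa with total
  reads `< min_total` across all samples. Default `min_total = 10`, a
  common denoising floor for amplicon tables; taxa below it are dominated
  by index hopping and PCR error.
* **Rarefaction** (`rarefy`): subsample each column to a common `depth`
  **without replacement** — one `multivariate_hypergeometric` draw per
  sample (numpy Generator), not repeated Bernoulli thinning. Columns
  already exactly at `depth` are left untouched (making rarefaction
  idempotent); columns below `depth` are dropped and reported. Default
  `depth = 86,235`, sized for deep multi-habitat surveys; for desk-scale
  or synthetic data pass an explicit smaller depth. Per-taxon expectation
  is `depth × p_ij`, which the tests verify by Monte-Carlo over 200 seeds.

## Diversity primitives

* **Richness**: count of taxa with nonzero reads.
* **Faith PD**: total branch length of the union of root-to-tip paths over
  the taxa present in a sample, on a rooted tree. Implemented as a single
  postorder pass with per-node presence masks (O(nodes × samples));
  verified against a brute-force path-union oracle on random trees.
  Missing branch lengths are treated as 0 with a warning; negative lengths
  are rejected.
* **Levins niche breadth**: `B = 1 / Σ_j q_j²` where `q_j` is the taxon's
  abundance distribution over the samples of a group; `B = 1` for a
  point mass, `B = n` for perfect evenness. `community_breadth` averages
  `B` over the taxa present in each sample.
* **Bray–Curtis**: `1 − 2 Σ min(x_i, y_i) / (Σ x_i + Σ y_i)` on counts.
* **Baselga partition**: with `a` shared and `b`, `c` unique species,
  `β_sor = (b+c)/(2a+b+c)` splits exactly into turnover
  `β_sim = min(b,c)/(a+min(b,c))` and nestedness `β_sne = β_sor − β_sim`.
  The identity is enforced to 1e-12 at construction time.
* **Matrix rank correlation**: Spearman correlation of the condensed
  (lower-triangle) entries of two dissimilarity matrices, with a seeded
  permutation test over sample relabelings; `p = (hits + 1)/(n_perm + 1)`.

## Sloan neutral community model

For a local community of size `N` receiving immigrants at rate `m` from a
source pool where taxon `i` has abundance `p_i`, the stationary occurrence
frequency above a detection limit `d` is

```
f_pred(p) = 1 − BetaCDF(d; N m p, N m (1 − p))
```

Implementation: `d = 1/N` by default (one read at the common depth —
rarefied input is therefore assumed); `m` is fitted by bounded scalar
minimization of the sum of squared residuals on `log10 m ∈ [−6, 1]`
(tolerance 1e-10, avoiding the flat plateaus at extreme `m`);
`R² = 1 − SSE/SST` against the observed frequencies; the confidence
interval on `m` comes from bootstrap resampling taxa (default 1000
replicates). `ncm_r2_by_habitat_count` refits on every non-empty habitat
subset (2^H − 1 combinations) and reports the Spearman trend of `R²`
against subset size — declining `R²` with more pooled habitats indicates
habitat-level selection. Recovery is verified on `simulate_sloan` output
(independent Beta draws per taxon, the model's own marginal).

Assumptions: equal sampling depth across samples (enforced), a single
shared source pool per fitted group, independence across taxa (the Sloan
approximation), ≥ 6 taxa with intermediate frequencies to constrain `m`.

## EM source tracking with an unknown source

Each sink sample's reads are modeled as a multinomial mixture over K known
source profiles `γ_k` (pooled per-habitat relative abundances, excluding
the sink itself; by default the sink's own habitat is excluded entirely)
plus one free "unknown" profile:

* E-step: `r_jk = m_k γ_kj / Σ_k' m_k' γ_k'j`
* M-step: `m_k = Σ_j x_j r_jk / Σ_j x_j`, and the unknown profile
  `γ_unknown,j ∝ x_j r_j,unknown`.

The log-likelihood is non-decreasing every iteration (asserted in tests).
A pseudocount of 1e-10 keeps profiles strictly positive.

**Identifiability.** With a free unknown profile the likelihood has a flat
ridge: the unknown can absorb mass that known sources explain equally
well, so the EM point estimate of the unknown fraction is biased upward
even on noise-free data. The default estimator therefore applies a
*minimal-unknown* resolution after EM: the sink composition is projected
onto the known profiles by bounded non-negative least squares
(`scipy.optimize.lsq_linear`, coefficients in [0, 1]) and the unknown
fraction is the unexplained remainder. This picks, among the ridge's
near-equivalent solutions, the one attributing as much as possible to
known sources — the conventional reading of "unknown = what no known
source can explain". Pass `resolve_unknown="em"` for the raw EM point.

`habitat_contribution_summary` averages per-sink mixtures within each sink
habitat into a (sink habitat) × (source habitat + unknown) matrix with
zero diagonal and unit row sums.

Limitation: when source habitats are strongly correlated — e.g. habitat B
itself contains half of habitat A's pool — attribution between them is
genuinely ambiguous, and a sink from A can be attributed to B (which
"contains" A). This is inherent to mixture-based source tracking, not an
implementation artifact; the ground-truth recovery tests therefore use
scenarios where the attribution is identifiable (partially or fully
disjoint pools).

## Migrant calling

Per unordered habitat pair (10 pairs for 5 habitats):

1. **Screen**: keep taxa present in strictly more than `prevalence`
   (default 0.5) of the samples on *each* side.
2. **Breadth shift**: Wilcoxon signed-rank test, paired by taxon, of
   Levins breadth on side A vs side B — evidence that the two
   environments select differently on the shared taxa.
3. **Call**: per screened taxon, a two-sided Wilcoxon rank-sum test of
   relative abundances across the two sides; the taxon is a *potential
   migrant* iff `p ≥ alpha` (default 0.05).

Note the inversion: non-significance declares migration, so raising
`alpha` makes calling stricter, and multiple-testing correction *inflates*
migrant counts — hence no correction by default (`correction="bh"` is
available and its effect is tested). The rank-sum p-value is exact when
there are no ties and ≤ 25 samples per side, otherwise the normal
approximation with continuity correction is used (`scipy.stats
.mannwhitneyu`). Under a pure null the non-migrant call fraction equals
`alpha` (verified to ±0.02); with 50 planted equal-mean migrants against
450 four-fold-shifted taxa at 18 samples/side, sensitivity and specificity
both exceed 0.9 over 20 seeds.

`summarize_migrants_by_supergroup` and `summarize_migrant_guilds` roll
migrant calls up to eukaryotic supergroups and (for fungi, via a
genus → trophic-mode guild database) to pathotroph / saprotroph /
symbiotroph classes; taxa without an assignment are binned as
"unassigned", never dropped.

## Synthetic metacommunity generator

`generate_metacommunity(ScenarioConfig(...))` emulates a multi-habitat
survey so that every pipeline stage has a ground-truth oracle. Defaults
mirror the survey design the package targets: 6 parks × 5 habitats × 3
replicates = 90 samples, 2000 taxa, depth 86,235.

* **Pools**: taxa split into a shared core (`habitat_overlap`, default
  0.3) plus one unique block per habitat (plus a hidden block for the
  unknown source when the mixing matrix uses it). Within-pool abundances
  are log-normal with `pool_sigma = 1.5` — the heavy-tailed rank-abundance
  shape amplicon tables show.
* **Mixing**: each habitat's expected composition is a convex combination
  of pools given by `mixing_matrix` rows (identity by default); the matrix
  is recorded in the `GroundTruth`.
* **Park effect**: a multiplicative log-normal perturbation
  (`park_sigma = 0.3`), deliberately the smallest variance component.
* **Sampling**: one multinomial draw per sample at `depth`; optionally
  Sloan-neutral Beta draws first (`neutral=True`).
* **Companions**: a random bifurcating tree with exponential branch
  lengths, PR2-style eight-rank lineages (about half Opisthokonta, a
  `fungal_fraction` of which are fungi with genus-level guild entries).
* **Oracles**: `plant_migrants` equalizes chosen shared taxa's pooled mean
  proportions across a pair (redrawing columns at their original depths);
  `simulate_sink_mixture` builds one sink from known + hidden sources;
  `simulate_migration_pair` plants equal-mean migrants next to
  fold-shifted taxa (the shifted block's total mass is preserved so the
  migrants stay equal-mean after normalization).

What the generator does **not** emulate: sequencing error and chimeras,
compositional correlations between taxa, within-habitat spatial structure,
or differences between amplicon regions beyond a metadata label.

## Determinism and numerics

All randomness flows from explicit integer seeds (< 2³¹) through
`numpy.random.default_rng`; the CLI derives one substream per stage from
the root seed via SHA-256, so stage outputs are independent of stage
order. Identical seeds reproduce byte-identical outputs (asserted
end-to-end). Beta CDFs use `scipy.special.betainc`; EM works in
log-likelihood space with pseudocounts; dissimilarity and breadth code is
vectorized numpy with no per-element Python loops on the hot paths.
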