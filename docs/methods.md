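# Methods

This note records the models, conventions, and design choices behind each
stage, the parameters that matter, and what the synthetic-data tests do and
do not establish about real data.

## Data model and preprocessing

An `OtuTable` is an OTUs × samples matrix of non-negative counts (or
relative abundances) with unique, ordered identifiers. TSV is the canonical
interchange format; a minimal reader for the BIOM 1.0 JSON layout is
included.

Preprocessing runs control-first:

1. **Control-OTU removal.** Any OTU with a non-zero count in the
   negative-control extraction sample is removed entirely (treated as
   ambient contamination), and the control column is dropped. Removal is
   all-or-nothing per OTU, regardless of how abundant the OTU is elsewhere.
2. **Low-abundance filter.** An OTU is kept iff its row sum is at least
   `threshold_fraction` (default 5×10⁻⁵, i.e. 0.005 %) of the grand total
   of the table — all samples pooled, inclusive threshold. Pooling is used
   because the fraction refers to "all sequences" of a dataset, not to any
   single sample. With threshold 0 every row is kept, including all-zero
   rows (0 ≥ 0).
3. **Rarefaction.** Each sample is subsampled to a fixed depth *without*
   replacement (one multivariate hypergeometric draw per sample), so output
   column sums equal the depth exactly and no OTU can gain reads. A single
   draw is used (no averaging over repeated rarefactions); the seed is a
   required, recorded parameter. Samples below the target depth raise an
   error rather than being silently dropped.

Whether the abundance filter should run before or after control-OTU removal
is underdetermined in practice; this package fixes control-first, which is
the order in which the artifacts arise (contamination is a property of the
extraction, not of the biology).

## Diversity conventions

* Shannon *H* uses natural logarithms. For soil prokaryote communities with
  ~1,100 observed taxa, printed values near 6 are only consistent with nats
  (the maximum ln S ≈ 7), not bits.
* Simpson diversity is 1 − Σp² (probability that two randomly drawn reads
  differ in taxon).
* Evenness is the Hill ratio e^H / S — the effective number of
  equally-abundant taxa over observed richness — not Pielou's H/ln S.
  For the summary values this package is validated against, e^H/S lands in
  the printed 0.1–0.5 range while Pielou's index would sit near 0.9;
  `evenness_from_summary` applies the same convention to condition-level
  means when per-sample vectors are unavailable.
* Chao1 is the bias-corrected estimator S_obs + F1(F1−1)/(2(F2+1)),
  applied uniformly so F2 = 0 needs no special case. It requires integer
  counts and is reported as missing on relative tables.
* Bray–Curtis D = Σ|x−y| / Σ(x+y) ∈ [0,1]; a pair of all-zero samples is
  assigned 0 by convention (logged). Bray–Curtis is a semimetric (no
  triangle inequality), which PERMANOVA does not require.
* Presence of an OTU in a condition (for shared/specific partitions) means
  count > 0 in at least one replicate; a stricter all-replicates mode is
  available.

## PERMANOVA

The squared distance matrix is Gower-centered, G = −½ J D² J; trace(G) is
the total sum of squares. Terms enter sequentially (Type-I), each term's SS
being the increment tr(H_k G) − tr(H_{k−1} G) of the cumulative design's
projection matrix; this matches the behavior of the standard `adonis`-style
sequential decomposition and makes R² values (terms + residual) sum to 1 by
construction. Factors are treatment-coded; interaction columns are products
of the parents' dummies, and parents must precede interactions in the
formula. Rank increments are computed from a pivoted QR with tolerance
1e-8·max(n,p)·|R₁₁|; a term adding no rank is reported as aliased.

Significance uses unrestricted permutation of sample labels of D (no
strata), with the +1 convention p = (1 + #{F* ≥ F}) / (1 + n_perm), so the
smallest attainable p is 1/(n_perm+1) — e.g. 0.001 at 999 permutations. A
tie tolerance of 1e-12·(1+|F|) makes relabelings equivalent to the observed
one count as ties regardless of floating-point noise; without it, exact
enumeration and the Monte-Carlo p disagree by half the tied mass on small
designs.

## Co-occurrence network

**Correlation.** Pearson r between OTU rows across samples, computed on
whatever abundance scale the caller provides. When combining marker
datasets rarefied to different depths, `merge_domains` converts each table
to per-sample relative abundance before concatenation (so the merged matrix
encodes composition, not depth); the per-sample column sum is then the
number of domains, a constant that leaves Pearson across samples unchanged.
Zero-variance OTUs are flagged undefined and excluded from testing. Fewer
than 5 samples triggers a warning: Pearson estimates on n = 3 replicates
are not stable, and the caller must decide which sample set feeds each
network.

**Permutation null.** Each of B replicates shuffles every OTU row's sample
order independently, destroying exactly the inter-OTU dependence under test
while preserving all marginals, then recomputes the full correlation
matrix. p_raw = count/B without pseudo-count, so p = 0 is attainable. This
is deliberate: with B = 100 the smallest pseudo-counted p is ≈ 0.0099, and
a BH threshold of 0.01 over ~10⁶ pairs would then retain almost nothing —
incompatible with networks of several thousand links at that permutation
budget. The conservative (count+1)/(B+1) variant is available via
`pseudocount=True` (CLI `--pseudocount`). The flip side of the
zero-attainable convention is a per-pair false-edge floor: each null pair
lands at p = 0 with probability ≈ 1/(B+1), and those pairs survive BH at
any α. Error control should therefore be read as a per-pair false-edge
rate (≈ 0.005 at B = 200, comfortably within 1.5α for α = 0.01), not as a
discovery-FDR, which is dominated by the p = 0 atom whenever true pairs
are scarce.

**Edges and nodes.** Edge iff BH-adjusted p ≤ α (default 0.01) and
|r| ≥ r_min (default 0; no published magnitude cutoff to adopt). Nodes are
OTUs with at least one retained edge; isolated OTUs are excluded (node
counts below the OTU inventory imply this convention), with a flag to keep
them.

**Hubs.** Kleinberg hub score: for an undirected graph, the principal
eigenvector of the adjacency matrix, |·|-normalized to max 1 (computed by
dense symmetric eigendecomposition; on a disconnected graph the score
concentrates on the dominant component, matching igraph's `hub_score`).
Top-k ranking rounds scores to 10 decimals and breaks ties by node id, so
output order is deterministic.

**Global metrics.** Density 2m/(n(n−1)); transitivity 3·triangles/connected
triples; diameter = largest finite shortest-path length; average path
length = mean over connected (reachable) pairs only. The reachable-pairs
conventions for disconnected graphs follow the igraph defaults and are
logged when a graph has multiple components.

## Synthetic-data generator

Counts are drawn through a Gaussian copula: per sample, a latent
multivariate normal z with unit variances and a planted correlation matrix;
per OTU, abundance exp(μ + σz) with μ = 0, σ = 1 (log-normal marginals,
realistically heavy-tailed); multiplicative group effects exp(LFC) applied
to chosen OTUs in samples at a chosen factor level; per-sample
normalization; and a multinomial draw at the target depth. Columns
therefore sum exactly to the depth, like a rarefied table.

Planted structures:

* **Blocks** — equicorrelated OTU sets (pairwise latent ρ).
* **Hubs** — a latent factor model: spoke = ρ·hub + √(1−ρ²)·noise, giving
  hub–spoke correlation ρ and spoke–spoke correlation ρ². A literal star
  correlation matrix (spokes mutually uncorrelated) is not positive
  semi-definite once kρ² > 1 — e.g. 15 spokes at ρ = 0.9 — so the factor
  construction is the honest way to plant a high-ρ hub, at the cost that
  spokes also correlate with one another.
* The implied correlation matrix is PSD-checked (min eigenvalue ≥ −1e-8)
  before Cholesky; violations raise an error suggesting a smaller ρ.

The default study-shaped preset is 2 soils × {bulk, planted,
planted+amended} × 3 replicates = 18 samples, with 1,600 (prokaryote) or
430 (fungal) OTUs at depths 7,541 / 32,983.

**Attenuation, and what passing tests show.** Correlation planted on the
latent scale is attenuated on the abundance scale twice: by the exponential
map (latent ρ = 0.95 → abundance-scale r ≈ (e^ρ−1)/(e−1) ≈ 0.92 at σ = 1)
and by compositional closure (severe when the planted block is a large
fraction of the table — a 5-OTU table of one block realizes *negative*
pairwise correlations; minor when the block is ≲ 15 % of OTUs). The
generator stores the realized latent matrix in the truth object so recovery
thresholds can be set against what was actually planted. Because the
log-normal marginals are heavy-tailed, the permutation null also has
heavier tails than a Gaussian-theory calculation suggests: a block edge
survives BH at α = 0.01 essentially only when its permutation count is 0,
and per-pair P(count = 0) plateaus near 0.99 at B = 200, n = 20 — so
recovering *all* 10 edges of a planted block succeeds in roughly 90 % of
runs, not ~100 %. Recovery test sizes here use the planted structure plus
30 background OTUs, n = 20 samples, depth 10,000, B = 200, 50 seeds —
small enough to run in seconds, large enough that calibration fractions
concentrate.

What these tests do **not** show about real data: the generator has no
taxonomic signal, no sparsity/zero-inflation beyond what log-normal ×
multinomial produces, no depth variation between samples, and no
compositionality-aware correction (the Pearson-on-proportions approach
itself is naive to closure, which is a property of the method being
implemented, not of the generator).

## Numerical and degenerate-input conventions

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical tables, p-values, edge lists, and metrics.
* Relative-abundance validation tolerates 1e-9 on column sums; round-trip
  serialization uses 17 significant digits.
* Diversity indices raise on all-zero vectors; Bray–Curtis on a pair of
  all-zero samples returns 0 (logged); single-node networks report density
  and APL as missing (NaN); an empty network raises on hub scoring.
* The permutation comparison |r*| ≥ |r| is taken at face value (no
  tolerance): ties have measure zero for continuous data, and the identity
  permutation legitimately counts when drawn.

## Known limitations

* Pearson on relative abundances is sensitive to compositional effects; no
  SparCC/SPIEC-EASI-style correction is attempted (out of scope).
* No dispersion test accompanies PERMANOVA, and permutations are
  unrestricted (no strata).
* Networks built from n = 3 replicates per condition are statistically
  fragile; the package warns below n = 5 and leaves the sample-set choice
  to the caller.
* No statistical test is provided for comparing average path lengths
  between two networks.
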