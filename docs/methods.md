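# Methods

This note documents the models and procedures implemented in coralfam, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Similarity graph

Two construction routes share one graph contract (simple, undirected,
positive weights, every input gene present as a node so singleton families
survive clustering):

* **Internal scorer** — Jaccard similarity of the distinct k-mer sets of
  two protein sequences (k = 4 by default); an edge is kept when the score
  reaches `min_score` (default 0.2) and the score is the weight. k-mers
  containing X (the collapse target for all non-standard residues) are
  skipped so the k-mer space stays at the 20 standard letters. Candidate
  pairs come from a shared-k-mer inverted index; pairs sharing no k-mer
  have Jaccard 0 and can never reach a positive threshold, which keeps the
  construction near-linear in practice at desk scale. Within-taxon edges
  are included deliberately: paralogs must be able to co-cluster into one
  family.
* **Ingested hits** — 12-column tabular alignment rows, self-hits dropped,
  E-values above 10⁻⁵ dropped, weight −log₁₀(max(E, 10⁻²⁰⁰)) (the floor
  keeps weights finite at E = 0), reciprocal pairs symmetrised by the
  maximum (the common choice in MCL orthology pipelines; the mean is the
  obvious alternative and would differ only for asymmetric hit pairs).

The defaults k = 4 and `min_score` = 0.2 were fixed once against the
generator's default divergence (below): at those settings within-family
pairs stay connected across the deepest simulated splits while
between-family pairs (random 20-letter sequences, expected 4-mer Jaccard
≈ 10⁻⁴) essentially never pass. Both are exposed on the CLI.

## Markov clustering

The flow matrix starts from the weighted adjacency with self-loops; the
loop weight is the node's maximum incident edge weight (1 for isolated
nodes), a standard stabilisation that stops small clusters from
evaporating. Iteration alternates expansion (matrix squaring) and
inflation (entrywise power, default 2.0, then column renormalisation);
entries below 10⁻⁵ are pruned (each column's maximum is always retained)
and columns renormalised, until the largest entrywise change drops below
10⁻⁸ or 100 iterations. Clusters are read from the limit matrix as
connected components of its nonzero pattern — this merges overlapping
attractor systems, guaranteeing a partition, which we prefer to
assigning overlap rows to their heaviest attractor because the latter is
unstable near ties. The matrix is stored sparse throughout; pruning keeps
the iteration sparse even after expansion. Inflation is the granularity
dial: the family count is checked (and asserted in tests) to be
non-decreasing in inflation on the default dataset.

Clustering quality against known truth is scored with the adjusted Rand
index of the two partitions.

## Gene-set definitions

Presence means count ≥ 1 — family membership, not copy number, decides
presence everywhere (Venn regions, core, specificity). With focal clade F,
comparison clade C, outgroups O and focal species s ∈ F:

* core = families present in every taxon of F;
* clade-specific = core families absent from every taxon of C ∪ O
  (a subset of core by construction, asserted at run time);
* clade-diversified and species-expanded are the significant outcomes of
  the two statistical tests below;
* focal-specific genes = genes of s whose family contains no gene of any
  other taxon (singletons included). This is a gene set, matching how
  species-private content is usually reported; the family-level view is
  kept alongside.

The core gene fraction of taxon t is Σ_{f∈core} n_{f,t} / N_t with N_t the
proteome size. Family-size histograms use exponential binning with
intervals (0,1], (1,3], (3,7], …, open on the left, so size 1 is alone in
the first bin and sizes 2–3 share the second.

The shared-gene-content dendrogram uses
d(A,B) = 1 − |fam(A) ∩ fam(B)| / min(|fam(A)|, |fam(B)|), the gene-content
phylogeny convention (dividing by the mean is available as a config
alternative; min makes a strict subset relationship a zero distance),
clustered by UPGMA since the display target is a rooted ultrametric
dendrogram.

## Expansion statistics

Both tests condition on total gene content by treating a family's member
count in a taxon as a binomial draw from that proteome's total.

**Clade diversification.** For each family with at least one member in
F ∪ C (outgroups excluded from the contrast), the grouped-binomial
likelihood-ratio test compares a single shared proportion against separate
pooled proportions per clade. Pooled MLEs are count/total within each
group; log-likelihoods use the binomial kernel with 0·log 0 = 0; the
statistic 2(ℓ₁−ℓ₀) is referred to χ²₁. Because group is a two-level
factor, this is algebraically identical to the deviance test of a binomial
GLM with a clade covariate — no iterative fitting is needed. A
one-sided Fisher variant on the pooled 2×2 table is available by config.
Significance requires BH-FDR q < 0.01 across all tested families *and* a
positive direction (focal larger); a family that is significantly
*smaller* in the focal clade is never called diversified.

**Species expansion.** For each family present in ≥ 2 focal taxa, every
ordered pair (X, Y) of occupied focal taxa is tested with the one-sided
Fisher exact test (hypergeometric upper tail, margins fixed). BH runs over
all pairwise tests of the sweep jointly — pooling is the more conservative
choice for a sweep whose tests share families. A family is declared
expanded in X under the default all-pairs rule only if its test against
every other occupied focal taxon is individually significant; an any-pair
rule is available by config. The all-pairs reading reproduces the
qualitative pattern that a species can hold many families yet few
*expanded* ones.

One-sided tests are used throughout because both definitions ask for
"larger", never for change in either direction. Proteome totals (not
clustered-gene totals) are the denominators, matching the idea of
conditioning on total gene content.

## FFP phylogeny

Feature frequency profiles count overlapping length-8 amino-acid windows
within proteins (never across protein boundaries; X-containing windows
skipped). Profiles are stored as hash maps — the 20⁸ feature space is far
too sparse for dense arrays. Divergence is Jensen–Shannon in bits over the
union support; in bits it is bounded by [0,1], symmetric, and zero iff the
frequency vectors coincide. JSD itself (not its square root) is the
distance; the square root — a metric — is available by config, and at the
tree-building level the choice rarely changes topology since NJ is
invariant to monotone, locally near-affine distortions only approximately;
we simply fix one convention and record it.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion.
Determinism is pinned down: Q-ties break toward the lowest taxon-index
pair, and a negative branch length is clamped to zero with the deficit
moved to its sister branch so the pair sum is preserved. On additive
matrices the algorithm is exact (verified to 10⁻⁹ on random additive
matrices in the tests). Output is unrooted with a trifurcating seed node.

Bootstrap support resamples the union feature set with replacement at the
same cardinality, B = 100 pseudoreplicates by default; each replicate's
resampled counts yield a JSD matrix and NJ tree, and every internal
bipartition of the point estimate is labelled with the percentage of
replicates containing it. This is the standard profile (column) bootstrap;
block resampling of sequences would model within-protein correlation but
needs choices (block length) the profile bootstrap avoids.

## GO enrichment

Classic hypergeometric ("Fisher one-sided") enrichment: universe = genes
with ≥ 1 annotation, N its size; for a term with K annotated universe
genes and k hits among the n annotated set genes, p = P(X ≥ k) and
expected = nK/N. Rows with k = 0 are omitted; output is sorted by p. Raw
p-values are the primary output (mirroring the Observed/Expected/p table
convention); a clearly labelled BH column is added. topGO-style
decorrelation (weight01) is deliberately not reproduced — it is a property
of that tool's algorithm rather than of the hypergeometric model, which is
why p-values from such tools are not expected to be bit-identical.
When an is_a graph is supplied, annotations are first closed under
ancestry (true-path rule); propagation is idempotent and rejects cycles.

## Synthetic data generator

The generator is the pipeline's ground-truth instrument. It emulates:

* a known species tree (default: 8 taxa — a 4-taxon focal clade, a
  2-taxon comparison clade, two outgroups — with branch lengths scaled so
  the deepest pairs sit near 20–25% amino-acid divergence);
* gene-family birth/death: each family starts as one copy at the root; on
  a branch of length t each copy is lost with probability 1−exp(−μt) and,
  surviving, duplicates (at most once per branch) with probability
  1−exp(−λt); defaults λ = 0.1, μ = 0.05 give mostly-single-copy families
  with occasional paralogs;
* planted expansions: (family, taxon-or-clade, fold) multiplies the copy
  count entering the named stem branch, so planted copies diverge along
  the stem and remain co-clusterable; the pre-fold count is recorded as
  the expansion's baseline in the truth object;
* sequences: i.i.d.-uniform ancestral proteins of geometric length (mean
  150 aa, floor 30), evolved by per-site substitution with probability
  s·t per branch (default s = 0.15) to a uniformly chosen different
  residue; duplicates evolve independently after their duplication point;
* GO annotations: background terms at 5% frequency, planted terms at
  configurable in/out frequencies over target family sets.

Gene ids are `<taxon>_g<serial>` and never encode the family, so no stage
can leak truth. All outputs are byte-deterministic given the seed; counts,
sequences and annotations draw from separate named substreams of the root
seed.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: amino-acid exchangeability structure
(no BLOSUM-like rate matrix), indels, domain shuffling and chimeric genes,
codon-level effects, horizontal transfer, annotation errors and fragmented
gene models, and compositional biases of real proteomes. Recovery numbers
on synthetic data are upper bounds on what identical settings would
achieve on real proteomes.

## Validation experiment sizes

The benchmark module fixes the study conditions once:

* clustering recovery: 8 taxa × 200 families (≈ 1,700 genes), one seed,
  scored by ARI against truth;
* expansion recovery: 20 seeds × 120 families on a deeper 8-taxon tree
  (birth-rich regime λ = 8.0, μ = 0.5 — the at-most-one-duplication-per-
  branch model needs many short branches for families to reach realistic
  baseline sizes); 15 planted 5-fold single-taxon expansions per seed;
  sensitivity measured over planted families whose realized baseline is
  ≥ 10;
* null calibration: 20 seeds × 1,000 families, nothing planted, false-call
  rates of both sweeps at q < 0.01;
* NJ exactness: 100 random additive 6-taxon matrices (random merge trees,
  branch lengths U(0.1, 1));
* FFP recovery: 4 taxa × 100 families, s = 0.2, B = 100, l = 8.

## Numerical conventions and degenerate inputs

* 0·log 0 = 0 throughout (entropy and binomial kernels, via `xlogy`).
* Fisher p-values are hypergeometric survival values, memoised on the
  table; clamped to [0, 1].
* All-zero families: the LRT degenerates to (statistic 0, p 1,
  direction 0) rather than erroring.
* E-value 0 floors at 10⁻²⁰⁰ before the log transform.
* BH is the step-up procedure (via statsmodels), capped at 1, stable under
  input permutation.
* MCL pruning never empties a column (the column maximum survives), so
  column stochasticity is preserved.
* Pipeline reports contain no timestamps; stage timings go to the log.
  Rerunning any configuration with the same seed reproduces every output
  file byte-for-byte.

## Known limitations

* The internal similarity scorer is a k-mer Jaccard, not an alignment;
  it is blind to domain-level partial homology, so multi-domain families
  may over-merge at permissive thresholds.
* Dense all-pairs behaviour of MCL limits practical graph sizes to a few
  tens of thousands of genes; the implementation is sparse but not
  out-of-core.
* The clade test treats taxa within a group as exchangeable binomial
  pools; phylogenetic non-independence within clades is not modelled
  (a birth–death likelihood across the tree, CAFE-style, is out of
  scope).
* Enrichment p-values are raw hypergeometric; users comparing against
  decorrelating tools should expect rank, not value, agreement.
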