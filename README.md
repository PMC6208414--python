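# coralfam

Comparative gene-family analysis across whole proteomes, built for the kind
of multi-genome study done on scleractinian corals and their anthozoan and
basal-metazoan relatives: given one predicted proteome per genome, identify
ortholog groups, partition them into biologically meaningful gene sets,
test for lineage-specific gene-family expansion, build an alignment-free
whole-proteome phylogeny, and profile gene sets for GO-term enrichment.
Every stage can also be exercised end-to-end on synthetic proteomes with
planted ground truth, so the whole pipeline is testable without any real
genome.

## What it computes

**Ortholog groups (gene families).** Genes from all taxa are connected into
a weighted similarity graph — either from an internal alignment-free k-mer
Jaccard scorer or from ingested all-vs-all alignment hits (12-column
tabular format, E-value cutoff 10⁻⁵, edge weight −log₁₀ E) — and clustered
with the Markov Cluster algorithm (MCL): the column-stochastic flow matrix
is alternately squared (expansion) and raised entrywise to the inflation
power *r* (default 2.0) with column renormalisation, until convergence;
attractor systems become families, singletons included.

**Gene sets.** With the taxa split into a focal clade, a comparison clade
and outgroups, families are partitioned into: *core* (present in every
focal-clade taxon), *clade-specific* (core and absent outside the focal
clade), *clade-diversified* (significantly larger in the focal clade than
the comparison clade), *species-expanded* (significantly larger in one
focal species than in every other), and *focal-species-specific genes*
(genes whose family occurs in no other taxon). Summaries include the core
gene fraction of a proteome, Venn region counts of family presence across
up to four taxa, exponentially binned family-size distributions (intervals
(0,1], (1,3], (3,7], … open on the left), and a UPGMA dendrogram on the
shared-gene-content distance d(A,B) = 1 − |shared| / min(|A|, |B|).

**Expansion statistics.** The clade contrast is a grouped-binomial
likelihood-ratio test (the two-level binomial GLM in closed form): under
H₀ one shared proportion π of the proteome belongs to the family, under H₁
separate pooled proportions π_focal and π_comp; 2(ℓ₁−ℓ₀) ~ χ²₁. The
species contrast is a one-sided Fisher exact test per ordered pair of
focal taxa on [[k_X, N_X−k_X], [k_Y, N_Y−k_Y]], conditioning on total gene
content. Each sweep is Benjamini–Hochberg corrected and called at
FDR-adjusted p < 0.01, in the direction "larger" only.

**Alignment-free phylogeny.** Each proteome is summarised by its length-8
amino-acid feature frequency profile (FFP); profiles are compared by
Jensen–Shannon divergence in bits, JSD(P,Q) = H(M) − (H(P)+H(Q))/2 with
M = (P+Q)/2, which lies in [0,1]; the divergence matrix is resolved by
canonical neighbor joining, and internal-node support comes from 100
bootstrap pseudoreplicates of the feature set.

**GO enrichment.** Classic hypergeometric upper-tail enrichment of a gene
set against the annotated whole-genome universe, reporting observed and
expected (nK/N) counts and raw p per term (plus a labelled BH column),
with optional true-path propagation of is_a ancestry.

## Worked example

Simulate 120 gene families on an 8-taxon species tree (focal clade F1–F4,
comparison clade C1–C2, outgroups O1–O2), with one 6-fold expansion planted
in F1 and one GO term planted at 80% frequency in four families, then run
the full pipeline:

```yaml
# config.yaml
outdir: out
seed: 7
bootstrap: 50
simulate:
  n_families: 120
  planted_expansions:
    - [fam010, F1, 6]
  planted_go:
    - [GO:0009000, [fam000, fam001, fam002, fam003], 0.8, 0.05]
grouping:
  focal_clade: [F1, F2, F3, F4]
  comparison_clade: [C1, C2]
  outgroups: [O1, O2]
  focal_species: F1
```

```bash
$ coralfam all --config config.yaml
report written to out/report.json (148 families)
```

`out/report.json` then contains (excerpt):

```
n_families          148
set_sizes           {'clade_diversified': 0, 'clade_specific': 3,
                     'core': 111, 'focal_specific_genes': 0}
core_gene_fraction  0.983871
clustering_ari      0.947869
```

148 inferred families against 120 true ones (a few deep families split at
this divergence, adjusted Rand index 0.948 against the generator's truth);
111 families are core to F1–F4 and those account for 98.4% of F1's genes.
The FFP tree in the same report recovers the simulated topology with 100%
bootstrap support at every node:

```
(((C1,C2)100,(O1,O2)100)100,(F1,F2)100,(F3,F4)100);
```

Stage TSVs (`graph.abc.tsv`, `families.tsv`, `family_counts.tsv`,
`clade_diversified.tsv`, `species_expansion.tsv`, `gene_sets.tsv`,
`venn.tsv`, `size_bins.tsv`, `enrichment_*.tsv`) and newicks are written
alongside, and each stage is also runnable standalone — see
`coralfam --help` for the `simulate | graph | cluster | classify | expand |
phylo | enrich | all` subcommands.

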