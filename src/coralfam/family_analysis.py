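"""Family x taxon count matrix and descriptive comparative outputs.

From an ortholog clustering this module builds the copy-number matrix and
derives the comparative summaries: the five gene sets of interest (core
families shared by the whole focal clade; clade-specific families absent
outside it; clade-diversified and species-expanded families from the
statistical tests; focal-species-specific genes), Venn region counts of
family presence across up to four taxa, the core-gene fraction of a
proteome, exponentially binned family-size distributions, and a
shared-gene-content dendrogram (UPGMA on a presence-overlap distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .mcl_clustering import OrthologGroupSet

__all__ = [
    "FamilyCountMatrix",
    "TaxonGrouping",
    "GeneSetPartition",
    "build_count_matrix",
    "classify_gene_sets",
    "core_gene_fraction",
    "venn_counts",
    "exponential_bins",
    "gene_content_dendrogram",
]


@dataclass
class FamilyCountMatrix:
    """Ortholog-family x taxon gene counts plus per-taxon proteome totals."""

    counts: pd.DataFrame  # index = family_id, columns = taxon_id, int >= 0
    taxon_totals: dict[str, int]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative family counts")
        for taxon in self.counts.columns:
            if taxon not in self.taxon_totals:
                raise ValueError(f"no proteome total for taxon {taxon!r}")
            clustered = int(self.counts[taxon].sum())
            if clustered > self.taxon_totals[taxon]:
                raise ValueError(
                    f"clustered genes ({clustered}) exceed proteome total "
                    f"({self.taxon_totals[taxon]}) for {taxon!r}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    def families_of_taxon(self, taxon: str) -> set[str]:
        return set(self.counts.index[self.counts[taxon] >= 1])


@dataclass
class TaxonGrouping:
    """Focal clade vs comparison clade vs outgroups, plus the focal species."""

    focal_clade: set[str]
    comparison_clade: set[str]
    outgroups: set[str]
    focal_species: str

    def __post_init__(self) -> None:
        sets = [self.focal_clade, self.comparison_clade, self.outgroups]
        for a, b in combinations(sets, 2):
            if a & b:
                raise ValueError(f"taxon groups overlap: {sorted(a & b)}")
        if self.focal_species not in self.focal_clade:
            raise ValueError("focal_species must belong to the focal clade")

    @property
    def all_taxa(self) -> set[str]:
        return self.focal_clade | self.comparison_clade | self.outgroups

    @property
    def non_focal(self) -> set[str]:
        return self.comparison_clade | self.outgroups


@dataclass
class GeneSetPartition:
    """The five comparative gene sets."""

    core: set[str]
    clade_specific: set[str]
    clade_diversified: set[str]
    species_expanded: dict[str, set[str]]
    focal_specific: set[str]          # gene ids of the focal species
    focal_specific_families: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.clade_specific <= self.core:
            raise ValueError("clade_specific must be a subset of core")


def build_count_matrix(
    groups: OrthologGroupSet,
    gene_taxon: Mapping[str, str],
    taxon_totals: Mapping[str, int] | None = None,
) -> FamilyCountMatrix:
    """Count members of each family per taxon.

    ``taxon_totals`` defaults to the clustered gene counts (valid when the
    clustering covers every gene of every proteome, as MCL with retained
    isolated nodes does).
    """
    taxa: set[str] = set()
    for fam_id, members in groups.families.items():
        for gene in members:
            if gene not in gene_taxon:
                raise ValueError(f"gene {gene!r} has no taxon assignment")
            taxa.add(gene_taxon[gene])
    fam_ids = sorted(groups.families)
    cols = sorted(taxa)
    counts = pd.DataFrame(0, index=pd.Index(fam_ids, name="family_id"),
                          columns=cols, dtype=np.int64)
    for fam_id in fam_ids:
        for gene in groups.families[fam_id]:
            counts.loc[fam_id, gene_taxon[gene]] += 1
    if taxon_totals is None:
        taxon_totals = {t: int(counts[t].sum()) for t in cols}
    return FamilyCountMatrix(counts=counts, taxon_totals=dict(taxon_totals))


def classify_gene_sets(
    matrix: FamilyCountMatrix,
    grouping: TaxonGrouping,
    diversified: Iterable[str] = (),
    expanded: Mapping[str, Iterable[str]] | None = None,
    groups: OrthologGroupSet | None = None,
    gene_taxon: Mapping[str, str] | None = None,
) -> GeneSetPartition:
    """Partition families/genes into the five comparative sets.

    * core: families with >= 1 member in every focal-clade taxon;
    * clade-specific: core families with 0 members in every non-focal taxon;
    * clade-diversified / species-expanded: copied from significant test
      results (see the expansion statistics module);
    * focal-specific: genes of the focal species whose family has members
      in no other taxon (singletons included) — a gene set, not a family
      set; the family-level view is reported alongside.
    """
    missing = grouping.all_taxa - set(matrix.taxa)
    if missing:
        raise ValueError(f"grouping taxa absent from matrix: {sorted(missing)}")
    pres = matrix.presence()
    focal = sorted(grouping.focal_clade)
    non_focal = sorted(grouping.non_focal)

    core = set(pres.index[pres[focal].all(axis=1)])
    if non_focal:
        absent_outside = set(pres.index[~pres[non_focal].any(axis=1)])
    else:
        absent_outside = set(pres.index)
    clade_specific = core & absent_outside

    other_than_focal_sp = [t for t in matrix.taxa
                           if t != grouping.focal_species]
    only_focal_sp = pres[grouping.focal_species] & ~pres[
        other_than_focal_sp].any(axis=1)
    focal_specific_families = set(pres.index[only_focal_sp])

    focal_specific_genes: set[str] = set()
    if groups is not None and gene_taxon is not None:
        for fam in focal_specific_families:
            for gene in groups.families.get(fam, ()):
                if gene_taxon[gene] == grouping.focal_species:
                    focal_specific_genes.add(gene)

    return GeneSetPartition(
        core=core,
        clade_specific=clade_specific,
        clade_diversified=set(diversified),
        species_expanded={t: set(v) for t, v in (expanded or {}).items()},
        focal_specific=focal_specific_genes,
        focal_specific_families=focal_specific_families,
    )


def core_gene_fraction(matrix: FamilyCountMatrix,
                       partition: GeneSetPartition,
                       taxon: str) -> float:
    """Fraction of a proteome's genes belonging to core families."""
    if taxon not in matrix.taxa:
        raise ValueError(f"unknown taxon {taxon!r}")
    core = sorted(partition.core)
    in_core = int(matrix.counts.loc[core, taxon].sum()) if core else 0
    return in_core / matrix.taxon_totals[taxon]


def venn_counts(matrix: FamilyCountMatrix,
                taxa: Sequence[str]) -> dict[frozenset[str], int]:
    """Family counts per presence/absence region among up to 4 taxa.

    Every family present in >= 1 of the listed taxa lands in exactly one
    of the 2^k - 1 regions keyed by the subset of taxa it occurs in; both
    single-copy genes and multi-copy families count once.
    """
    if len(taxa) > 4:
        raise ValueError("venn regions supported for at most 4 taxa")
    unknown = set(taxa) - set(matrix.taxa)
    if unknown:
        raise ValueError(f"taxa absent from matrix: {sorted(unknown)}")
    pres = matrix.presence()
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(taxa) + 1):
        for combo in combinations(taxa, r):
            regions[frozenset(combo)] = 0
    for _, row in pres[list(taxa)].iterrows():
        present = frozenset(t for t in taxa if row[t])
        if present:
            regions[present] += 1
    return regions


def exponential_bins(sizes: Iterable[int]
                     ) -> list[tuple[tuple[int, int], int]]:
    """Histogram of family sizes in intervals (2^(i-1), 2^i], open on the
    left: size 1 alone in the first interval, sizes 2–3 in the second,
    4–7 in the third, and so on.  Trailing empty intervals are trimmed.
    """
    sizes = list(sizes)
    if not sizes:
        return []
    if any(s < 1 for s in sizes):
        raise ValueError("family sizes must be >= 1")
    n_bins = max(int(np.ceil(np.log2(max(sizes) + 1))), 1)
    bins: list[tuple[tuple[int, int], int]] = []
    for i in range(1, n_bins + 1):
        lo = 2 ** (i - 1) - 1   # (0,1], (1,3], (3,7], ... open on the left
        hi = 2 ** i - 1
        count = sum(1 for s in sizes if lo < s <= hi)
        bins.append(((lo, hi), count))
    while bins and bins[-1][1] == 0:
        bins.pop()
    return bins


def gene_content_dendrogram(matrix: FamilyCountMatrix,
                            taxa: Sequence[str] | None = None,
                            formula: str = "min") -> dendropy.Tree:
    """UPGMA dendrogram on shared-gene-content distance.

    d(A,B) = 1 - |families present in both| / min(|A|, |B|) (the
    gene-content phylogeny convention); ``formula='mean'`` divides by the
    mean instead.  Output is a rooted ultrametric tree.
    """
    taxa = list(taxa) if taxa is not None else matrix.taxa
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for a dendrogram")
    fam_sets = {t: matrix.families_of_taxon(t) for t in taxa}
    for t, fams in fam_sets.items():
        if not fams:
            raise ValueError(f"taxon {t!r} has zero families")
    n = len(taxa)
    dmat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = fam_sets[taxa[i]], fam_sets[taxa[j]]
        shared = len(a & b)
        denom = min(len(a), len(b)) if formula == "min" else (
            (len(a) + len(b)) / 2.0)
        d = 1.0 - shared / denom
        dmat[i, j] = dmat[j, i] = max(d, 0.0)
    z = linkage(squareform(dmat, checks=False), method="average")
    return _linkage_to_tree(z, taxa)


def _linkage_to_tree(z: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Convert a scipy linkage matrix into a rooted ultrametric tree."""
    ns = dendropy.TaxonNamespace(list(labels))
    n = len(labels)
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        nodes[i] = (node, 0.0)
    for k, (a, b, dist, _cnt) in enumerate(z):
        parent = dendropy.Node()
        height = dist / 2.0  # ultrametric: merge height is half the distance
        for child_id in (int(a), int(b)):
            child, child_h = nodes[child_id]
            child.edge.length = max(height - child_h, 0.0)
            parent.add_child(child)
        nodes[n + k] = (parent, height)
    root, _ = nodes[n + len(z) - 1]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree
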