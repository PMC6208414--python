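"""Markov clustering (MCL) of the gene-similarity graph into ortholog groups.

The flow matrix alternates expansion (matrix squaring) with inflation
(entrywise power and column renormalisation); small entries are pruned to
keep the matrix sparse.  At convergence the nonzero pattern decomposes
into attractor systems, read out as connected components; overlapping
attractors are merged so the result is always a partition.  Isolated
genes become singleton families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from .similarity_graph import SimilarityGraph

__all__ = ["OrthologGroupSet", "mcl", "cluster_quality",
           "write_families_tsv", "read_families_tsv"]


@dataclass
class OrthologGroupSet:
    """A partition of the gene universe into families (clusters)."""

    families: dict[str, set[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam_id, members in self.families.items():
            if not members:
                raise ValueError(f"empty family {fam_id}")
            overlap = seen & members
            if overlap:
                raise ValueError(f"families overlap on {sorted(overlap)[:3]}")
            seen |= members

    @property
    def gene_universe(self) -> set[str]:
        return set().union(*self.families.values()) if self.families else set()

    def family_of(self) -> dict[str, str]:
        return {g: fid for fid, members in self.families.items()
                for g in members}

    def sizes(self) -> list[int]:
        return [len(m) for m in self.families.values()]


def _column_normalize(m: sp.csr_matrix) -> sp.csr_matrix:
    colsums = np.asarray(m.sum(axis=0)).ravel()
    colsums[colsums == 0] = 1.0
    return (m @ sp.diags(1.0 / colsums)).tocsr()


def _prune(m: sp.csr_matrix, prune_below: float) -> sp.csr_matrix:
    if m.nnz == 0:
        return m
    m = m.tocsc()
    # never empty a column: keep each column's max even below threshold
    keep = m.data >= prune_below
    for j in range(m.shape[1]):
        lo, hi = m.indptr[j], m.indptr[j + 1]
        if lo == hi:
            continue
        if not keep[lo:hi].any():
            keep[lo + int(np.argmax(m.data[lo:hi]))] = True
    m.data[~keep] = 0.0
    m.eliminate_zeros()
    return m.tocsr()


def mcl(
    sg: SimilarityGraph,
    inflation: float = 2.0,
    max_iter: int = 100,
    prune_below: float = 1e-5,
    tol: float = 1e-8,
) -> OrthologGroupSet:
    """Cluster a similarity graph into ortholog groups by Markov clustering.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight (1 for isolated nodes) before column normalisation.
    Higher ``inflation`` yields finer clusters; ``inflation`` must exceed 1.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(sg.graph.nodes)
    n = len(nodes)
    if n == 0:
        return OrthologGroupSet(families={}, provenance={
            "inflation": inflation, "prune_below": prune_below,
            "max_iter": max_iter, "tol": tol, "iterations": 0})
    idx = {g: i for i, g in enumerate(nodes)}

    rows, cols, vals = [], [], []
    loop = np.ones(n)
    for u, v, w in sg.graph.edges.data("weight"):
        iu, iv = idx[u], idx[v]
        rows += [iu, iv]
        cols += [iv, iu]
        vals += [w, w]
        loop[iu] = max(loop[iu], w)
        loop[iv] = max(loop[iv], w)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    m = _column_normalize(m)

    iterations = 0
    for iterations in range(1, max_iter + 1):
        expanded = (m @ m).tocsr()
        expanded.data = np.power(expanded.data, inflation)
        expanded = _column_normalize(expanded)
        expanded = _prune(expanded, prune_below)
        expanded = _column_normalize(expanded)
        diff = abs(expanded - m)
        change = diff.max() if diff.nnz else 0.0
        m = expanded
        if change < tol:
            break

    # attractor systems = connected components of the limit nonzero pattern
    pattern = ((m + m.T) > 0).astype(np.int8)
    n_comp, labels = connected_components(pattern, directed=False)
    clusters: dict[int, set[str]] = {}
    for gene, i in idx.items():
        clusters.setdefault(int(labels[i]), set()).add(gene)
    ordered = sorted(clusters.values(), key=lambda s: (-len(s), min(s)))
    width = max(6, len(str(len(ordered))))
    families = {f"OG{str(i).zfill(width)}": members
                for i, members in enumerate(ordered)}
    return OrthologGroupSet(
        families=families,
        provenance={"inflation": inflation, "prune_below": prune_below,
                    "max_iter": max_iter, "tol": tol,
                    "iterations": iterations},
    )


def cluster_quality(groups: OrthologGroupSet, truth) -> float:
    """Adjusted Rand index between a clustering and the true partition.

    ``truth`` is either a ``SyntheticTruth`` or a plain gene->family map
    over the same gene universe.
    """
    gene_to_family = getattr(truth, "gene_to_family", truth)
    genes = sorted(groups.gene_universe)
    if set(genes) != set(gene_to_family):
        raise ValueError("gene universe mismatch between clustering and truth")
    fam_of = groups.family_of()
    return float(adjusted_rand_score(
        [gene_to_family[g] for g in genes],
        [fam_of[g] for g in genes],
    ))


def write_families_tsv(groups: OrthologGroupSet,
                       gene_taxon: dict[str, str],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("family_id\ttaxon\tgene_id\n")
        for fam_id in sorted(groups.families):
            for gene in sorted(groups.families[fam_id]):
                fh.write(f"{fam_id}\t{gene_taxon.get(gene, '')}\t{gene}\n")


def read_families_tsv(path: str | Path
                      ) -> tuple[OrthologGroupSet, dict[str, str]]:
    families: dict[str, set[str]] = {}
    gene_taxon: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("family_id"):
            raise ValueError(f"{path}: missing family_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fam_id, taxon, gene = line.split("\t")
            families.setdefault(fam_id, set()).add(gene)
            gene_taxon[gene] = taxon
    return OrthologGroupSet(families=families), gene_taxon
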