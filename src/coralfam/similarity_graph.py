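"""Weighted gene-similarity graph for ortholog clustering.

Two sources: an internal alignment-free k-mer Jaccard scorer over the
proteomes, or ingested tabular alignment hits thresholded at an E-value
cutoff (default 1e-5) with weight ``-log10(evalue)``.  Either way the
result is a simple undirected graph whose node set is the full gene
universe — isolated genes are retained so singleton families survive
clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import ProteinRecord, TabularHit

__all__ = [
    "SimilarityGraph",
    "kmer_set",
    "kmer_jaccard",
    "build_graph_internal",
    "build_graph_from_hits",
    "write_abc",
    "read_abc",
]

EVALUE_FLOOR = 1e-200  # E-value 0 floored here so -log10 weights stay finite


@dataclass
class SimilarityGraph:
    """Simple undirected weighted graph over gene ids with taxon tags."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges.data("weight"):
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if w is None or w <= 0:
                raise ValueError(f"non-positive weight on ({u},{v})")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def taxon_of(self, gene: str) -> str:
        return self.graph.nodes[gene].get("taxon", "")


def kmer_set(sequence: str, k: int) -> frozenset[str]:
    """Distinct k-mers of a sequence; windows containing X are skipped."""
    return frozenset(
        sequence[i:i + k]
        for i in range(len(sequence) - k + 1)
        if "X" not in sequence[i:i + k]
    )


def kmer_jaccard(a: ProteinRecord, b: ProteinRecord, k: int = 4) -> float:
    """Jaccard similarity of the distinct k-mer sets of two proteins."""
    if len(a.sequence) < k or len(b.sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    sa, sb = kmer_set(a.sequence, k), kmer_set(b.sequence, k)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def build_graph_internal(
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    k: int = 4,
    min_score: float = 0.2,
) -> SimilarityGraph:
    """All-vs-all k-mer Jaccard graph over >= 2 proteomes.

    An edge joins genes a != b iff their Jaccard >= ``min_score``; the
    Jaccard value is the edge weight.  Within-taxon edges are included so
    paralogs co-cluster into one family.  Candidate pairs are generated
    through a shared-k-mer inverted index: pairs sharing no k-mer have
    Jaccard 0 and can never pass a positive threshold.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    g = nx.Graph()
    records: list[ProteinRecord] = []
    for taxon, recs in proteomes.items():
        for rec in recs:
            g.add_node(rec.gene_id, taxon=taxon)
            records.append(rec)

    sets = [kmer_set(r.sequence, k) for r in records]
    index: dict[str, list[int]] = {}
    for i, s in enumerate(sets):
        for mer in s:
            index.setdefault(mer, []).append(i)

    candidates: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                candidates.add((members[ai], members[bi]))

    for i, j in candidates:
        si, sj = sets[i], sets[j]
        union = len(si | sj)
        if union == 0:
            continue
        jac = len(si & sj) / union
        if jac >= min_score:
            g.add_edge(records[i].gene_id, records[j].gene_id, weight=jac)
    return SimilarityGraph(graph=g)


def build_graph_from_hits(
    hits: Sequence[TabularHit],
    evalue_cutoff: float = 1e-5,
    gene_taxon: Mapping[str, str] | None = None,
    all_genes: Iterable[str] | None = None,
) -> SimilarityGraph:
    """Similarity graph from tabular alignment hits.

    Self-hits and hits with E-value above the cutoff are dropped; edge
    weight is ``-log10(max(evalue, 1e-200))``; reciprocal hits are
    symmetrized by keeping the maximum weight.  ``all_genes`` (or the
    hits' own id universe) fixes the node set so unconnected genes remain
    isolated nodes.  Output is invariant to hit order.
    """
    g = nx.Graph()
    universe = set(all_genes) if all_genes is not None else set()
    for h in hits:
        universe.add(h.query_id)
        universe.add(h.subject_id)
    for gene in sorted(universe):
        g.add_node(gene, taxon=(gene_taxon or {}).get(gene, ""))
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue > evalue_cutoff:
            continue
        w = -math.log10(max(h.evalue, EVALUE_FLOOR))
        if w <= 0:
            continue
        prev = g.get_edge_data(h.query_id, h.subject_id)
        if prev is None or prev["weight"] < w:
            g.add_edge(h.query_id, h.subject_id, weight=w)
    return SimilarityGraph(graph=g)


def write_abc(sg: SimilarityGraph, path: str | Path) -> None:
    """Dump edges as 3-column TSV (the ABC dialect of MCL pipelines)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for u, v, w in sorted(sg.graph.edges.data("weight")):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_abc(path: str | Path) -> SimilarityGraph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            u, v, w = parts[0], parts[1], float(parts[2])
            if u != v:
                g.add_edge(u, v, weight=w)
    return SimilarityGraph(graph=g)
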