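"""Classic hypergeometric GO-term enrichment of gene sets.

A gene set of interest is compared against the whole-genome universe,
where the universe is restricted to genes carrying at least one GO
annotation.  For each term, the observed member count is referred to the
hypergeometric upper tail; the expected count under the null is
n*K/N.  Output rows mirror the (term, name, observed, expected, p)
enrichment-table schema; raw p-values are reported, with a clearly
labelled BH-adjusted column alongside.  When an is_a parent graph is
available, annotations are first propagated to all ancestors (true-path
rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .expansion_stats import bh_fdr
from .io_formats import GOAnnotationMap

__all__ = ["EnrichmentRow", "propagate_annotations", "enrich",
           "write_enrichment_tsv"]


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    observed: int
    expected: float
    p_value: float
    q_value: float = float("nan")
    term_name: str = ""


def propagate_annotations(annotations: GOAnnotationMap) -> GOAnnotationMap:
    """Close each gene's term set under is_a ancestry (true-path rule).

    With no parent map, annotations pass through unchanged.  Idempotent;
    a cyclic parent graph raises ``ValueError``.
    """
    if annotations.term_parents is None:
        return annotations
    g = nx.DiGraph()
    for term, parents in annotations.term_parents.items():
        g.add_node(term)
        for p in parents:
            g.add_edge(term, p)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cyclic is_a graph")
    ancestors = {t: nx.descendants(g, t) for t in g}  # edges point child->parent
    gene_to_terms = {
        gene: set().union(terms, *(ancestors.get(t, set()) for t in terms))
        for gene, terms in annotations.gene_to_terms.items()
    }
    return GOAnnotationMap(gene_to_terms=gene_to_terms,
                           term_parents=annotations.term_parents)


def enrich(
    set_genes: Iterable[str],
    universe_genes: Iterable[str],
    annotations: GOAnnotationMap,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment of a gene set vs the universe.

    The universe is restricted to annotated genes (N); for each term with
    K annotated universe genes and k observed among the n annotated set
    genes, p = P(X >= k) and expected = n*K/N.  Terms with k = 0 are
    omitted; rows are sorted by ascending p (ties by term id).
    """
    set_genes = set(set_genes)
    universe_genes = set(universe_genes)
    if not set_genes <= universe_genes:
        raise ValueError("gene set is not a subset of the universe")

    annotated = annotations.annotated_genes()
    universe = universe_genes & annotated
    in_set = set_genes & annotated
    N, n = len(universe), len(in_set)

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.gene_to_terms[gene]:
            term_genes.setdefault(term, set()).add(gene)

    rows: list[EnrichmentRow] = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & in_set)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(
            term=term,
            observed=k,
            expected=n * K / N,
            p_value=min(p, 1.0),
            term_name=(term_names or {}).get(term, ""),
        ))
    rows.sort(key=lambda r: (r.p_value, r.term))
    qs = bh_fdr([r.p_value for r in rows])
    return [EnrichmentRow(term=r.term, observed=r.observed,
                          expected=r.expected, p_value=r.p_value,
                          q_value=q, term_name=r.term_name)
            for r, q in zip(rows, qs)]


def write_enrichment_tsv(rows: Iterable[EnrichmentRow],
                         path: str | Path) -> None:
    """TSV with GO accession, name, Observed, Expected, p and BH q."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GO\tTerm Name\tObserved\tExpected\tp\tq_BH\n")
        for r in rows:
            fh.write(f"{r.term}\t{r.term_name}\t{r.observed}\t"
                     f"{r.expected:.4g}\t{r.p_value:.4g}\t{r.q_value:.4g}\n")
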