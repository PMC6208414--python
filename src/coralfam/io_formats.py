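"""Readers and writers for the standard formats the pipeline touches.

Protein FASTA, BLAST tabular (outfmt-6 dialect), two-column id2go TSV,
minimal OBO (``id:``/``is_a:`` stanza lines only) and newick, plus the
scaffold decontamination filter applied to raw alignment hits.

All writers emit UTF-8 with LF line endings.  FASTA identifiers follow the
dominant convention: the token before the first whitespace is the gene id,
the remainder of the header is a description that is retained but unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "TabularHit",
    "GOAnnotationMap",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "filter_contaminant_scaffolds",
    "read_id2go",
    "write_id2go",
    "read_obo_lite",
    "write_obo_lite",
    "read_newick",
    "write_newick",
]

# Residues outside the 20-letter standard alphabet are collapsed to X on
# read; X-containing k-mers are skipped downstream, keeping the k-mer
# space at 20 letters.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header, empty sequence, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single predicted protein: unique gene id, source taxon, sequence."""

    gene_id: str
    taxon_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")


@dataclass(frozen=True)
class TabularHit:
    """One row of a 12-column tabular alignment report."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass
class GOAnnotationMap:
    """Gene -> GO term sets, with an optional acyclic is_a parent graph."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_parents: dict[str, set[str]] | None = None

    def __post_init__(self) -> None:
        if self.term_parents is not None:
            _check_parent_graph(self.term_parents)

    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if ts}


def _check_parent_graph(term_parents: Mapping[str, set[str]]) -> None:
    g = nx.DiGraph()
    for term, parents in term_parents.items():
        for p in parents:
            if p == term:
                raise ValueError(f"term {term} is its own parent")
            g.add_edge(term, p)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"cyclic is_a graph: {cycle}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _clean_sequence(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in STANDARD_AA else "X" for c in seq)


def read_fasta(path: str | Path, taxon_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the gene id; the
    rest is kept as the description.  Records preserve file order.  Raises
    :class:`FastaParseError` naming the offending line for empty sequences,
    empty headers and duplicate ids.
    """
    path = Path(path)
    # map record index -> 1-based line number of its header, for error text
    header_lines: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines.append(lineno)

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for idx, rec in enumerate(SeqIO.parse(fh, "fasta")):
            lineno = header_lines[idx] if idx < len(header_lines) else -1
            if not rec.id:
                raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
            if len(rec.seq) == 0:
                raise FastaParseError(
                    f"{path}:{lineno}: empty sequence for record {rec.id!r}"
                )
            if rec.id in seen:
                raise FastaParseError(
                    f"{path}:{lineno}: duplicate gene id {rec.id!r} "
                    f"(first seen at line {seen[rec.id]})"
                )
            seen[rec.id] = lineno
            records.append(
                ProteinRecord(
                    gene_id=rec.id,
                    taxon_id=taxon_id,
                    sequence=_clean_sequence(str(rec.seq)),
                    description=rec.description[len(rec.id):].strip(),
                )
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            header = rec.gene_id
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[TabularHit]:
    """Read a 12-column tabular hit file (the standard outfmt-6 dialect).

    Columns 1, 2, 3, 11, 12 are query, subject, percent identity, e-value
    and bitscore; extra columns are ignored.  Rows with fewer than 12
    columns or non-numeric e-value/bitscore raise ``ValueError``.
    """
    hits: list[TabularHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric field: {exc}"
                ) from None
            if not math.isfinite(evalue) or not math.isfinite(bitscore):
                raise ValueError(f"{path}:{lineno}: non-finite evalue/bitscore")
            hits.append(TabularHit(cols[0], cols[1], pident, evalue, bitscore))
    return hits


def filter_contaminant_scaffolds(
    hits: Sequence[TabularHit],
    evalue_max: float = 1e-20,
    bitscore_min: float = 1000.0,
) -> tuple[set[str], set[str]]:
    """Partition query scaffolds into (kept, removed) by contaminant hits.

    A scaffold is flagged as contaminant (removed) iff at least one of its
    hits satisfies ``evalue < evalue_max`` AND ``bitscore > bitscore_min``
    — strict inequalities, matching the decontamination rule applied to
    assembly scaffolds screened against symbiont/bacterial/viral databases.
    """
    queries = {h.query_id for h in hits}
    removed = {
        h.query_id
        for h in hits
        if h.evalue < evalue_max and h.bitscore > bitscore_min
    }
    return queries - removed, removed


# ---------------------------------------------------------------------------
# id2go TSV
# ---------------------------------------------------------------------------

def read_id2go(path: str | Path,
               term_parents: dict[str, set[str]] | None = None
               ) -> GOAnnotationMap:
    """Read a two-column TSV mapping gene id to comma-separated GO ids."""
    gene_to_terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            gene, terms = parts
            gene_to_terms[gene] = {
                t for t in (x.strip() for x in terms.split(",")) if t
            }
    return GOAnnotationMap(gene_to_terms=gene_to_terms,
                           term_parents=term_parents)


def write_id2go(annotations: GOAnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in sorted(annotations.gene_to_terms):
            terms = ",".join(sorted(annotations.gene_to_terms[gene]))
            fh.write(f"{gene}\t{terms}\n")


# ---------------------------------------------------------------------------
# minimal OBO
# ---------------------------------------------------------------------------

def read_obo_lite(path: str | Path) -> dict[str, set[str]]:
    """Parse only ``id:``/``is_a:`` lines of [Term] stanzas into a parent map.

    Obsolete terms are dropped.  Full OBO semantics (relationships,
    intersections, imports) are deliberately out of scope.  A cyclic is_a
    graph raises ``ValueError``.
    """
    term_parents: dict[str, set[str]] = {}
    current: str | None = None
    in_term = False
    obsolete = False
    pending: dict[str, set[str]] = {}

    def flush() -> None:
        nonlocal current, obsolete
        if current is not None and not obsolete:
            term_parents.setdefault(current, set()).update(
                pending.get(current, set())
            )
        current = None
        obsolete = False
        pending.clear()

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line:
                continue
            if line.startswith("id:"):
                current = line[3:].strip()
            elif line.startswith("is_a:") and current is not None:
                parent = line[5:].strip().split("!")[0].strip()
                pending.setdefault(current, set()).add(parent)
            elif line.startswith("is_obsolete:") and "true" in line:
                obsolete = True
    flush()
    _check_parent_graph(term_parents)
    return term_parents


def write_obo_lite(term_parents: Mapping[str, set[str]],
                   path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(term_parents):
            fh.write(f"\n[Term]\nid: {term}\n")
            for parent in sorted(term_parents[term]):
                fh.write(f"is_a: {parent}\n")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick, internal-node labels carrying supports."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def read_newick(source: str) -> dendropy.Tree:
    """Parse a newick string (internal node labels preserved)."""
    return dendropy.Tree.get(
        data=source,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
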