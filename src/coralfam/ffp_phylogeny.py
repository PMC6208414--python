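"""Alignment-free whole-proteome phylogeny from feature frequency profiles.

Each proteome is summarised by its length-l amino-acid k-mer counts
(default l = 8; windows never cross protein boundaries and windows
containing X are skipped).  Profiles are compared by Jensen–Shannon
divergence in bits — symmetric, bounded in [0, 1] — and the divergence
matrix is turned into an unrooted tree by canonical neighbor joining
(Saitou–Nei with the Studier–Keppler Q-criterion), which is exact on
additive matrices.  Bootstrap support resamples the union feature set
with replacement and reports, for each internal bipartition of the point
estimate, the percentage of pseudoreplicate trees containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import xlogy

from .io_formats import ProteinRecord

__all__ = [
    "FFPProfile",
    "DistanceMatrix",
    "ffp_profile",
    "jsd",
    "distance_matrix",
    "nj_tree",
    "bootstrap_tree",
]

LOG2 = float(np.log(2.0))


@dataclass
class FFPProfile:
    """Feature (l-mer) frequency profile of one proteome."""

    taxon_id: str
    l: int
    feature_counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.feature_counts.values()):
            raise ValueError("feature counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.feature_counts.values())


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for i, t in enumerate(self.taxa):
                row = "\t".join(f"{x:.10g}" for x in self.d[i])
                fh.write(f"{t}\t{row}\n")


def ffp_profile(proteome: Sequence[ProteinRecord], l: int = 8) -> FFPProfile:
    """Count overlapping l-mers across all proteins of one proteome.

    Windows are taken within each protein only; l-mers containing X are
    skipped.  Raises if no countable window exists.
    """
    counts: dict[str, int] = {}
    for rec in proteome:
        seq = rec.sequence
        for i in range(len(seq) - l + 1):
            mer = seq[i:i + l]
            if "X" in mer:
                continue
            counts[mer] = counts.get(mer, 0) + 1
    if not counts:
        raise ValueError(f"no countable window of length {l}")
    taxon = proteome[0].taxon_id if proteome else ""
    return FFPProfile(taxon_id=taxon, l=l, feature_counts=counts)


def _jsd_freq(p: np.ndarray, q: np.ndarray) -> float:
    """JSD in bits of two frequency vectors over the same support."""
    m = 0.5 * (p + q)

    def h(v: np.ndarray) -> float:
        return float(-xlogy(v, v).sum() / LOG2)

    val = h(m) - 0.5 * (h(p) + h(q))
    return float(min(max(val, 0.0), 1.0))


def jsd(p: FFPProfile, q: FFPProfile) -> float:
    """Jensen–Shannon divergence (bits) between two profiles of equal l."""
    if p.l != q.l:
        raise ValueError(f"feature length mismatch: {p.l} vs {q.l}")
    union = sorted(set(p.feature_counts) | set(q.feature_counts))
    pv = np.array([p.feature_counts.get(f, 0) for f in union], dtype=float)
    qv = np.array([q.feature_counts.get(f, 0) for f in union], dtype=float)
    return _jsd_freq(pv / pv.sum(), qv / qv.sum())


def distance_matrix(profiles: Sequence[FFPProfile]) -> DistanceMatrix:
    taxa = [p.taxon_id for p in profiles]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jsd(profiles[i], profiles[j])
    return DistanceMatrix(taxa=taxa, d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining; exact on additive distance matrices.

    Ties in the Q-criterion break toward the lowest taxon-index pair, and
    a negative branch length is clamped to zero with the deficit moved to
    its sister so the pair's total length is preserved.  The result is
    unrooted (trifurcating seed node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa for neighbor joining")
    ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))  # indices into rows of d / nodes list

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                qv = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or qv < best[0] - 1e-15:
                    best = (qv, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)

        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - dij)
            d[new_idx, k] = d[k, new_idx] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # join the last three around a trifurcating seed node
    i, j, k = active
    root = dendropy.Node()
    lij, lik, ljk = d[i, j], d[i, k], d[j, k]
    li = 0.5 * (lij + lik - ljk)
    lj = 0.5 * (lij + ljk - lik)
    lk = 0.5 * (lik + ljk - lij)
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = max(ln, 0.0)
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as canonical leaf sets.

    Each internal edge induces a split; the side not containing the
    lexicographically smallest leaf is the canonical representative.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = leaves - side
        splits.add(frozenset(side))
    return splits


def _count_matrix(profiles: Sequence[FFPProfile]
                  ) -> tuple[list[str], np.ndarray]:
    union = sorted(set().union(*(p.feature_counts for p in profiles)))
    counts = np.zeros((len(profiles), len(union)))
    for i, p in enumerate(profiles):
        for j, f in enumerate(union):
            c = p.feature_counts.get(f)
            if c:
                counts[i, j] = c
    return union, counts


def _nj_from_counts(counts: np.ndarray, taxa: list[str]) -> dendropy.Tree:
    freqs = counts / counts.sum(axis=1, keepdims=True)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _jsd_freq(freqs[i], freqs[j])
    return nj_tree(DistanceMatrix(taxa=taxa, d=d))


def bootstrap_tree(
    profiles: Sequence[FFPProfile],
    B: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ point-estimate tree with feature-bootstrap supports.

    The union feature set is resampled with replacement (same cardinality)
    B times; each pseudoreplicate yields a JSD matrix and NJ tree, and
    every internal node of the point estimate is labelled with the
    percentage of pseudoreplicates containing its bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ls = {p.l for p in profiles}
    if len(ls) != 1:
        raise ValueError("profiles have mixed feature lengths")
    taxa = [p.taxon_id for p in profiles]
    _, counts = _count_matrix(profiles)

    point = _nj_from_counts(counts, taxa)
    target = {s: 0 for s in tree_splits(point)}

    rng = np.random.default_rng(seed)
    n_feat = counts.shape[1]
    for _ in range(B):
        idx = rng.integers(0, n_feat, size=n_feat)
        boot = counts[:, idx]
        keep = boot.sum(axis=1) > 0
        if not keep.all():        # degenerate resample: skip taxon-less reps
            continue
        rep = _nj_from_counts(boot, taxa)
        for s in tree_splits(rep):
            if s in target:
                target[s] += 1

    leaves = set(taxa)
    anchor = min(leaves)
    for node in point.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        key = frozenset(leaves - side if anchor in side else side)
        node.label = str(int(round(100.0 * target[key] / B)))
    return point
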