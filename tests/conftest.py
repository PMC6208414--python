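"""Shared fixtures: small synthetic datasets and a hand-built toy matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import coralfam as cf


@pytest.fixture(scope="session")
def small_dataset():
    """40-family, 8-taxon dataset with sequences and annotations."""
    cfg = cf.SimulationConfig(n_families=40, seed=11)
    proteomes, truth, annotations = cf.simulate_dataset(cfg)
    return cfg, proteomes, truth, annotations


@pytest.fixture(scope="session")
def default_grouping():
    return cf.TaxonGrouping(
        focal_clade={"F1", "F2", "F3", "F4"},
        comparison_clade={"C1", "C2"},
        outgroups={"O1", "O2"},
        focal_species="F1",
    )


@pytest.fixture()
def toy_matrix():
    """Hand-built 6-taxon, 8-family matrix with hand-derived gene sets.

    Focal clade F1-F4 (focal species F1), comparison C1, outgroup O1:
      famA all six taxa            -> core only
      famB focal clade only        -> core AND clade-specific
      famC focal + C1              -> core only
      famD missing F2              -> not core
      famE only F1, two copies     -> focal-specific genes
      famF only C1                 -> none
      famG focal + O1              -> core only
      famH only F1, singleton      -> focal-specific gene
    """
    taxa = ["F1", "F2", "F3", "F4", "C1", "O1"]
    rows = {
        "famA": [1, 1, 1, 1, 1, 1],
        "famB": [2, 1, 1, 1, 0, 0],
        "famC": [1, 1, 1, 1, 1, 0],
        "famD": [1, 0, 1, 1, 1, 1],
        "famE": [2, 0, 0, 0, 0, 0],
        "famF": [0, 0, 0, 0, 1, 0],
        "famG": [1, 2, 1, 1, 0, 1],
        "famH": [1, 0, 0, 0, 0, 0],
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    counts.index.name = "family_id"
    totals = {t: int(counts[t].sum()) for t in taxa}
    matrix = cf.FamilyCountMatrix(counts=counts, taxon_totals=totals)

    families: dict[str, set[str]] = {}
    gene_taxon: dict[str, str] = {}
    for fam, row in counts.iterrows():
        members = set()
        for t in taxa:
            for i in range(int(row[t])):
                g = f"{t}_{fam}_{i}"
                members.add(g)
                gene_taxon[g] = t
        if members:
            families[fam] = members
    groups = cf.OrthologGroupSet(families=families)
    grouping = cf.TaxonGrouping(
        focal_clade={"F1", "F2", "F3", "F4"},
        comparison_clade={"C1"},
        outgroups={"O1"},
        focal_species="F1",
    )
    return matrix, groups, gene_taxon, grouping


def random_additive_matrix(rng: np.random.Generator, n_taxa: int = 6):
    """Random additive distance matrix plus its true unrooted splits."""
    labels = [f"T{i}" for i in range(n_taxa)]
    active: list[tuple[set[str], dict[str, float]]] = [
        ({lab}, {lab: 0.0}) for lab in labels
    ]
    dist: dict[frozenset[str], float] = {}
    splits: set[frozenset[str]] = set()
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        leaves_j, d_j = active.pop(j)
        leaves_i, d_i = active.pop(i)
        bi, bj = rng.uniform(0.1, 1.0, size=2)
        for a, da in d_i.items():
            for b, db in d_j.items():
                dist[frozenset((a, b))] = da + bi + db + bj
        merged_leaves = leaves_i | leaves_j
        merged = {lab: d + bi for lab, d in d_i.items()}
        merged.update({lab: d + bj for lab, d in d_j.items()})
        active.append((merged_leaves, merged))
        if 2 <= len(merged_leaves) <= n_taxa - 2:
            splits.add(frozenset(merged_leaves))
    full = set(labels)
    anchor = min(full)
    canon = {frozenset(full - s) if anchor in s else s for s in splits}
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            d[a, b] = d[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, d, canon
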