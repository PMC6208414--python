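"""Parameter-recovery benchmarks on synthetic data with planted truth.

Each function simulates a dataset under fixed study conditions, runs the
relevant pipeline stage, and scores the result against the generator's
ground truth.  These are the package's own validation experiments; the
test suite asserts thresholds on their outputs and the acceptance script
reports them.
"""

from __future__ import annotations

import numpy as np

from . import ffp_phylogeny, mcl_clustering, similarity_graph
from .expansion_stats import (significant_families, test_clade_diversified,
                              test_species_expansion)
from .family_analysis import FamilyCountMatrix, TaxonGrouping
from .synthetic_data import (SimulationConfig, simulate_dataset,
                             simulate_family_counts)

__all__ = [
    "DEFAULT_GROUPING",
    "random_additive_matrix",
    "clustering_recovery",
    "expansion_recovery",
    "expansion_null_calibration",
    "nj_exactness",
    "ffp_recovery",
]

DEFAULT_GROUPING = TaxonGrouping(
    focal_clade={"F1", "F2", "F3", "F4"},
    comparison_clade={"C1", "C2"},
    outgroups={"O1", "O2"},
    focal_species="F1",
)

FOUR_TAXON_TREE = "((A:0.3,B:0.3)AB:0.15,(C:0.3,D:0.3)CD:0.15)R;"


def random_additive_matrix(rng: np.random.Generator, n_taxa: int = 6):
    """Random additive distance matrix with its true unrooted splits.

    A random binary tree is built by repeated random merges with branch
    lengths uniform on [0.1, 1]; pairwise distances are accumulated as
    path sums during merging, independent of any tree-reconstruction code.
    """
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


def clustering_recovery(seed: int = 0, n_families: int = 200) -> dict:
    """ARI of MCL ortholog groups vs truth on the default 8-taxon dataset."""
    cfg = SimulationConfig(n_families=n_families, seed=seed)
    proteomes, truth, _ = simulate_dataset(cfg)
    sg = similarity_graph.build_graph_internal(proteomes)
    groups = mcl_clustering.mcl(sg)
    return {
        "ari": mcl_clustering.cluster_quality(groups, truth),
        "n_genes": len(truth.gene_to_family),
        "n_true_families": n_families,
        "n_inferred_families": len(groups.families),
    }


#: Deep 8-taxon tree for the expansion experiment: copies duplicate at
#: most once per copy per branch, so many short branches are needed for
#: families to grow to realistic baseline sizes (>= 10) before the
#: planted expansion multiplies them.
EXPANSION_TREE = (
    "((((((F1:0.2,F2:0.2)a:0.2,(F3:0.2,F4:0.2)b:0.2)c:0.2,C1:0.4)d:0.2,"
    "C2:0.4)e:0.2,O1:0.5)f:0.2,O2:0.5)ROOT;"
)


def _expansion_config(seed: int, n_families: int, planted: bool
                      ) -> SimulationConfig:
    # birth-rich regime so planted families reach baseline sizes >= 10
    expansions = []
    if planted:
        focal = sorted(DEFAULT_GROUPING.focal_clade)
        expansions = [(f"fam{i:03d}", focal[i % len(focal)], 5)
                      for i in range(15)]
    return SimulationConfig(
        species_tree=EXPANSION_TREE,
        n_families=n_families,
        duplication_rate=8.0,
        loss_rate=0.5,
        planted_expansions=expansions,
        seed=seed,
    )


def _matrix_from_truth_counts(counts) -> FamilyCountMatrix:
    totals = {t: int(counts[t].sum()) for t in counts.columns}
    return FamilyCountMatrix(counts=counts, taxon_totals=totals)


def expansion_recovery(n_seeds: int = 20, seed0: int = 0,
                       n_families: int = 120, q: float = 0.01) -> dict:
    """Sensitivity for planted 5-fold single-taxon expansions.

    Counts evolve under a birth-rich regime; sensitivity is measured over
    planted families whose realized copy number entering the expanded
    stem branch (the baseline) is >= 10, at FDR q with the all-pairs rule.
    """
    detected = qualifying = 0
    for s in range(n_seeds):
        cfg = _expansion_config(seed0 + s, n_families, planted=True)
        sim = simulate_family_counts(cfg)
        matrix = _matrix_from_truth_counts(sim.counts)
        _, expanded = test_species_expansion(matrix, DEFAULT_GROUPING,
                                             q_threshold=q, rule="all")
        for fam, target, _fold in cfg.planted_expansions:
            if sim.expansion_baselines[(fam, target)] >= 10:
                qualifying += 1
                if fam in expanded[target]:
                    detected += 1
    return {
        "sensitivity": detected / qualifying if qualifying else float("nan"),
        "n_qualifying": qualifying,
        "n_detected": detected,
        "n_seeds": n_seeds,
    }


def expansion_null_calibration(n_seeds: int = 20, seed0: int = 1000,
                               n_families: int = 1000,
                               q: float = 0.01) -> dict:
    """False-call rates of both expansion tests with nothing planted."""
    pair_called = pair_tested = 0
    clade_called = clade_tested = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_families=n_families, duplication_rate=0.5,
                               loss_rate=0.3, seed=seed0 + s)
        sim = simulate_family_counts(cfg)
        matrix = _matrix_from_truth_counts(sim.counts)
        _, expanded = test_species_expansion(matrix, DEFAULT_GROUPING,
                                             q_threshold=q, rule="all")
        called = set().union(*expanded.values())
        pair_called += len(called)
        pair_tested += n_families
        div = test_clade_diversified(matrix, DEFAULT_GROUPING, q_threshold=q)
        clade_called += len(significant_families(div))
        clade_tested += len(div)
    return {
        "pairwise_false_call_rate": pair_called / pair_tested,
        "clade_false_call_rate": clade_called / clade_tested,
        "n_pairwise_families": pair_tested,
        "n_clade_tests": clade_tested,
    }


def nj_exactness(n_matrices: int = 100, seed: int = 0,
                 n_taxa: int = 6) -> dict:
    """Topology and branch-length recovery on random additive matrices."""
    rng = np.random.default_rng(seed)
    topo_ok = 0
    max_err = 0.0
    for _ in range(n_matrices):
        labels, d, true_splits = random_additive_matrix(rng, n_taxa=n_taxa)
        tree = ffp_phylogeny.nj_tree(
            ffp_phylogeny.DistanceMatrix(taxa=labels, d=d))
        if ffp_phylogeny.tree_splits(tree) == true_splits:
            topo_ok += 1
        pdm = tree.phylogenetic_distance_matrix()
        ns = tree.taxon_namespace
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    err = abs(pdm.distance(ns.get_taxon(a),
                                           ns.get_taxon(b)) - d[i, j])
                    max_err = max(max_err, err)
    return {
        "topology_accuracy": topo_ok / n_matrices,
        "max_patristic_error": max_err,
        "n_matrices": n_matrices,
    }


def ffp_recovery(seed: int = 0, B: int = 100, l: int = 8,
                 n_families: int = 100) -> dict:
    """FFP/JSD/NJ recovery of a 4-taxon tree with well-separated branches."""
    cfg = SimulationConfig(species_tree=FOUR_TAXON_TREE,
                           n_families=n_families, seed=seed,
                           substitution_prob_per_unit=0.2)
    proteomes, _, _ = simulate_dataset(cfg)
    profiles = [ffp_phylogeny.ffp_profile(proteomes[t], l=l)
                for t in sorted(proteomes)]
    tree = ffp_phylogeny.bootstrap_tree(profiles, B=B, seed=seed)
    splits = ffp_phylogeny.tree_splits(tree)
    want = frozenset({"C", "D"})  # canonical form of the AB|CD split
    support = 0
    if want in splits:
        leaves = frozenset("ABCD")
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            canon = frozenset(leaves - side) if "A" in side else side
            if canon == want:
                support = int(node.label)
    return {
        "topology_correct": int(want in splits),
        "true_split_support": support,
        "B": B,
    }
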