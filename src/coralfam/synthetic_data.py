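"""Synthetic multi-taxon proteomes with known gene-family ground truth.

Gene families evolve along a user-supplied species tree under a per-copy
birth/death process; amino-acid sequences evolve by i.i.d. per-site
substitution, so every duplicate diverges independently after its
duplication point.  Lineage-specific expansions are planted by multiplying
a family's copy number on the stem branch of a named taxon or clade, and
GO-term enrichment is planted by annotating target families at an elevated
frequency.  The resulting ground truth (family membership, expansion
baselines, enriched terms) lets every downstream stage — similarity graph,
MCL clustering, expansion tests, FFP phylogeny, GO enrichment — be scored
against a known answer.

The model is deliberately minimal: a uniform substitution model (no rate
matrix), no indels, no codon structure, no horizontal transfer.  That is
sufficient to create the k-mer similarity and divergence structure the
pipeline consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GOAnnotationMap, ProteinRecord, write_fasta, write_id2go

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CountSimulation",
    "simulate_family_counts",
    "simulate_sequences",
    "assign_go_annotations",
    "simulate_dataset",
    "write_dataset",
    "DEFAULT_SPECIES_TREE",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
MIN_FAMILY_LENGTH = 30

#: Default 8-taxon species tree: a focal clade of four taxa (F1–F4), a
#: two-taxon comparison clade (C1, C2) and two outgroups (O1, O2).
#: Branch lengths are in expected substitutions per unit, scaled so the
#: deepest leaf-to-leaf path stays clusterable by 4-mer similarity.
DEFAULT_SPECIES_TREE = (
    "((((F1:0.2,F2:0.2)F12:0.1,(F3:0.2,F4:0.2)F34:0.1)FOCAL:0.3,"
    "(C1:0.25,C2:0.25)COMP:0.35)ANTH:0.2,(O1:0.4,O2:0.4)OUT:0.2)ROOT;"
)


@dataclass
class SimulationConfig:
    """Parameters of the proteome simulator.

    Rates are per family copy per unit branch length; ``fold`` of a planted
    expansion multiplies the copy count entering the stem branch of the
    named taxon or clade (internal-node label of the species tree).
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 200
    family_length_mean: int = 150
    duplication_rate: float = 0.1
    loss_rate: float = 0.05
    planted_expansions: list[tuple[str, str, int]] = field(default_factory=list)
    substitution_prob_per_unit: float = 0.15
    go_terms: int = 50
    go_base_frequency: float = 0.05
    planted_go: list[tuple[str, tuple[str, ...], float, float]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if not 0 < self.substitution_prob_per_unit < 1:
            raise ValueError("substitution_prob_per_unit must be in (0,1)")
        for fam, target, fold in self.planted_expansions:
            if fold < 2:
                raise ValueError(f"fold must be >= 2 for {fam}/{target}")
        for term, fams, f_in, f_out in self.planted_go:
            if not (0 <= f_in <= 1 and 0 <= f_out <= 1):
                raise ValueError(f"GO frequencies for {term} must be in [0,1]")

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.species_tree,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree().leaf_node_iter()]

    def family_ids(self) -> list[str]:
        width = len(str(self.n_families - 1))
        return [f"fam{str(i).zfill(width)}" for i in range(self.n_families)]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    gene_to_family: dict[str, str]
    family_counts: pd.DataFrame  # families x taxa, integer copy numbers
    taxon_totals: dict[str, int]
    planted_expansions: list[tuple[str, str, int]]
    expansion_baselines: dict[tuple[str, str], int]  # (family, target) -> copies entering stem
    planted_go: list[tuple[str, tuple[str, ...], float, float]]
    seed: int

    def partition_labels(self, genes: list[str]) -> list[str]:
        return [self.gene_to_family[g] for g in genes]


@dataclass
class CountSimulation:
    """Copy-number table plus the per-branch genealogy that produced it.

    ``genealogy[node_label][f]`` lists, for each copy of family ``f``
    present at that tree node, the index of its parent copy at the parent
    node — enough to replay sequence evolution consistently with counts.
    """

    counts: pd.DataFrame
    genealogy: dict[str, list[list[int]]]
    tree: dendropy.Tree
    expansion_baselines: dict[tuple[str, str], int]
    config: SimulationConfig


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"__internal{id(node)}"


def _resolve_targets(tree: dendropy.Tree,
                     config: SimulationConfig) -> dict[str, set[str]]:
    """Map planted-expansion target names to tree node labels; validate."""
    labels = {_node_label(n) for n in tree.preorder_node_iter()}
    targets: dict[str, set[str]] = {}
    for fam, target, _fold in config.planted_expansions:
        if target not in labels:
            raise ValueError(
                f"planted expansion target {target!r} is not a taxon or "
                f"labelled clade of the species tree"
            )
        targets.setdefault(target, set()).add(fam)
    fam_ids = set(config.family_ids())
    for fams in targets.values():
        unknown = fams - fam_ids
        if unknown:
            raise ValueError(f"planted expansion names unknown families {unknown}")
    return targets


def simulate_family_counts(config: SimulationConfig,
                           rng: np.random.Generator | None = None
                           ) -> CountSimulation:
    """Evolve per-family copy numbers along the species tree.

    Each family starts with one copy at the root.  On a branch of length
    ``t`` every copy is lost with probability ``1 - exp(-loss_rate * t)``
    and, if it survives, duplicates with probability
    ``1 - exp(-duplication_rate * t)``.  A planted (family, target, fold)
    expansion replicates each copy entering the target's stem branch
    ``fold`` times before the branch's birth/death events, so all planted
    copies diverge along the stem and remain co-clusterable.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    tree = config.tree()
    fam_ids = config.family_ids()
    n_fam = config.n_families
    targets = _resolve_targets(tree, config)
    fold_of: dict[tuple[str, str], int] = {
        (fam, target): fold for fam, target, fold in config.planted_expansions
    }

    genealogy: dict[str, list[list[int]]] = {}
    counts_at: dict[dendropy.Node, np.ndarray] = {}
    baselines: dict[tuple[str, str], int] = {}

    for node in tree.preorder_node_iter():
        label = _node_label(node)
        if node.parent_node is None:
            counts_at[node] = np.ones(n_fam, dtype=np.int64)
            genealogy[label] = [[0] for _ in range(n_fam)]
            continue
        parent_counts = counts_at[node.parent_node]
        t = node.edge.length or 0.0
        p_loss = 1.0 - np.exp(-config.loss_rate * t)
        p_dup = 1.0 - np.exp(-config.duplication_rate * t)

        folds = np.ones(n_fam, dtype=np.int64)
        for fam in sorted(targets.get(label, ())):
            fi = fam_ids.index(fam)
            folds[fi] = fold_of[(fam, label)]
            baselines[(fam, label)] = int(parent_counts[fi])

        node_parents: list[list[int]] = []
        new_counts = np.zeros(n_fam, dtype=np.int64)
        for fi in range(n_fam):
            entering: list[int] = []
            for ci in range(parent_counts[fi]):
                entering.extend([ci] * folds[fi])
            kept: list[int] = []
            if entering:
                lost = rng.random(len(entering)) < p_loss
                dup = rng.random(len(entering)) < p_dup
                for j, parent_idx in enumerate(entering):
                    if lost[j]:
                        continue
                    kept.append(parent_idx)
                    if dup[j]:
                        kept.append(parent_idx)
            node_parents.append(kept)
            new_counts[fi] = len(kept)
        counts_at[node] = new_counts
        genealogy[label] = node_parents

    taxa = config.taxa()
    table = pd.DataFrame(
        {tx: counts_at[node]
         for node in tree.leaf_node_iter()
         for tx in [node.taxon.label]},
        index=pd.Index(fam_ids, name="family_id"),
    )[taxa]
    return CountSimulation(counts=table, genealogy=genealogy, tree=tree,
                           expansion_baselines=baselines, config=config)


def _evolve(seq: np.ndarray, p_sub: float, rng: np.random.Generator
            ) -> np.ndarray:
    """One branch of i.i.d. per-site substitution to a different residue."""
    if p_sub <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < min(p_sub, 0.95)
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the 19 non-identical residues
        shift = rng.integers(1, len(AMINO_ACIDS), size=n_hit)
        out[hit] = (out[hit] + shift) % len(AMINO_ACIDS)
    return out


def simulate_sequences(sim: CountSimulation,
                       config: SimulationConfig | None = None
                       ) -> tuple[dict[str, list[ProteinRecord]], SyntheticTruth]:
    """Evolve protein sequences down the genealogy of a count simulation.

    Each family draws an i.i.d.-uniform ancestral sequence of geometric
    length (mean ``family_length_mean``, floor 30 aa).  Gene ids are
    ``<taxon>_g<serial>`` and never encode the family.
    """
    config = config or sim.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    tree = sim.tree
    fam_ids = config.family_ids()
    n_fam = config.n_families
    s = config.substitution_prob_per_unit

    lengths = np.maximum(
        rng.geometric(1.0 / config.family_length_mean, size=n_fam),
        MIN_FAMILY_LENGTH,
    )
    root_seqs = [rng.integers(0, len(AMINO_ACIDS), size=int(L))
                 for L in lengths]

    # seqs_at[node][f] = list of integer-encoded copy sequences
    seqs_at: dict[dendropy.Node, list[list[np.ndarray]]] = {}
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        if node.parent_node is None:
            seqs_at[node] = [[seq] for seq in root_seqs]
            continue
        t = node.edge.length or 0.0
        p_sub = s * t
        parent_seqs = seqs_at[node.parent_node]
        node_seqs: list[list[np.ndarray]] = []
        for fi in range(n_fam):
            node_seqs.append([
                _evolve(parent_seqs[fi][pi], p_sub, rng)
                for pi in sim.genealogy[label][fi]
            ])
        seqs_at[node] = node_seqs

    proteomes: dict[str, list[ProteinRecord]] = {}
    gene_to_family: dict[str, str] = {}
    for node in tree.leaf_node_iter():
        taxon = node.taxon.label
        records: list[ProteinRecord] = []
        serial = 0
        for fi in range(n_fam):
            for seq in seqs_at[node][fi]:
                gene_id = f"{taxon}_g{serial:05d}"
                serial += 1
                records.append(ProteinRecord(
                    gene_id=gene_id,
                    taxon_id=taxon,
                    sequence="".join(AMINO_ACIDS[seq]),
                ))
                gene_to_family[gene_id] = fam_ids[fi]
        proteomes[taxon] = records

    truth = SyntheticTruth(
        gene_to_family=gene_to_family,
        family_counts=sim.counts,
        taxon_totals={tx: len(recs) for tx, recs in proteomes.items()},
        planted_expansions=list(config.planted_expansions),
        expansion_baselines=dict(sim.expansion_baselines),
        planted_go=list(config.planted_go),
        seed=config.seed,
    )
    return proteomes, truth


def assign_go_annotations(truth: SyntheticTruth,
                          config: SimulationConfig) -> GOAnnotationMap:
    """Annotate genes with background GO terms plus planted enrichment.

    Background terms annotate every gene independently at
    ``go_base_frequency``.  A planted (term, family_set, f_in, f_out)
    annotates genes of the target families at ``f_in`` and all other genes
    at ``f_out``, overriding the background for that term.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = sorted(truth.gene_to_family)
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    planted_by_term = {term: (set(fams), f_in, f_out)
                       for term, fams, f_in, f_out in config.planted_go}

    gene_to_terms: dict[str, set[str]] = {g: set() for g in genes}
    fam_of = truth.gene_to_family
    for term in terms:
        if term in planted_by_term:
            fams, f_in, f_out = planted_by_term[term]
            probs = np.array([f_in if fam_of[g] in fams else f_out
                              for g in genes])
        else:
            probs = np.full(len(genes), config.go_base_frequency)
        hits = rng.random(len(genes)) < probs
        for g, h in zip(genes, hits):
            if h:
                gene_to_terms[g].add(term)
    for term in planted_by_term:
        if term not in terms:
            fams, f_in, f_out = planted_by_term[term]
            probs = np.array([f_in if fam_of[g] in fams else f_out
                              for g in genes])
            hits = rng.random(len(genes)) < probs
            for g, h in zip(genes, hits):
                if h:
                    gene_to_terms[g].add(term)
    return GOAnnotationMap(gene_to_terms=gene_to_terms)


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[dict[str, list[ProteinRecord]],
                                SyntheticTruth, GOAnnotationMap]:
    """Counts -> sequences -> annotations, all from ``config.seed``."""
    sim = simulate_family_counts(config)
    proteomes, truth = simulate_sequences(sim, config)
    annotations = assign_go_annotations(truth, config)
    return proteomes, truth, annotations


def write_dataset(outdir: str | Path, config: SimulationConfig) -> SyntheticTruth:
    """Emit FASTAs, truth tables, id2go and a JSON echo of the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteomes, truth, annotations = simulate_dataset(config)
    for taxon, records in proteomes.items():
        write_fasta(records, outdir / f"{taxon}.faa")
    with open(outdir / "gene_to_family.tsv", "w", newline="\n") as fh:
        fh.write("gene_id\tfamily_id\n")
        for gene in sorted(truth.gene_to_family):
            fh.write(f"{gene}\t{truth.gene_to_family[gene]}\n")
    truth.family_counts.to_csv(outdir / "family_counts.tsv", sep="\t")
    with open(outdir / "planted_expansions.tsv", "w", newline="\n") as fh:
        fh.write("family_id\ttarget\tfold\tbaseline\n")
        for fam, target, fold in truth.planted_expansions:
            base = truth.expansion_baselines.get((fam, target), "")
            fh.write(f"{fam}\t{target}\t{fold}\t{base}\n")
    write_id2go(annotations, outdir / "id2go.tsv")
    (outdir / "config.json").write_text(config.to_json() + "\n")
    return truth
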