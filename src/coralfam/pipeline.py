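"""End-to-end orchestration of the comparative gene-family analysis.

simulate (optional) -> similarity graph -> MCL -> count matrix ->
expansion tests -> gene-set classification -> Venn / bins / dendrogram ->
FFP phylogeny -> GO enrichment, with every stage writing its documented
TSV/newick and a final machine-readable JSON report.  All randomness
derives from one root seed through named per-stage substreams, and the
report contains no timestamps, so a rerun with the same config and seed
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (expansion_stats, family_analysis, ffp_phylogeny,
               go_enrichment, mcl_clustering, similarity_graph,
               synthetic_data)
from .family_analysis import TaxonGrouping
from .io_formats import (GOAnnotationMap, read_blast_tab, read_fasta,
                         read_id2go, read_obo_lite, write_newick)

__all__ = ["PipelineConfig", "run_all", "load_config"]

log = logging.getLogger("coralfam")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Input is either a synthetic-data block (``simulate``) or per-taxon
    FASTA paths; the similarity source is the internal k-mer scorer unless
    a tabular hits file is given.  Constants mirror the analysis defaults:
    E-value cutoff 1e-5 for ingested hits, FDR threshold q = 0.01, FFP
    feature length 8, 100 bootstrap pseudoreplicates.
    """

    outdir: str = "coralfam_out"
    seed: int = 0
    # input
    simulate: synthetic_data.SimulationConfig | None = None
    fasta: dict[str, str] = field(default_factory=dict)  # taxon -> path
    grouping: TaxonGrouping | None = None
    # similarity
    hits_file: str | None = None
    evalue_cutoff: float = 1e-5
    kmer_k: int = 4
    min_score: float = 0.2
    # clustering
    inflation: float = 2.0
    prune_below: float = 1e-5
    max_iter: int = 100
    # expansion tests
    q_threshold: float = 0.01
    clade_method: str = "binomial"
    pairwise_rule: str = "all"
    # ffp
    ffp_length: int = 8
    bootstrap: int = 100
    # enrichment
    id2go: str | None = None
    obo: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0,1)")
        if self.ffp_length < 1 or self.bootstrap < 1:
            raise ValueError("ffp_length and bootstrap must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim.setdefault("seed", raw.get("seed", 0))
        if "planted_expansions" in sim:
            sim["planted_expansions"] = [tuple(x) for x in
                                         sim["planted_expansions"]]
        if "planted_go" in sim:
            sim["planted_go"] = [
                (t, tuple(fams), fi, fo)
                for t, fams, fi, fo in (tuple(x) for x in sim["planted_go"])
            ]
        sim = synthetic_data.SimulationConfig(**sim)
    grp = raw.pop("grouping", None)
    if grp is not None:
        grp = TaxonGrouping(
            focal_clade=set(grp["focal_clade"]),
            comparison_clade=set(grp.get("comparison_clade", ())),
            outgroups=set(grp.get("outgroups", ())),
            focal_species=grp["focal_species"],
        )
    return PipelineConfig(simulate=sim, grouping=grp, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; write stage outputs, MANIFEST and report.json."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    stage = "setup"
    log.info("resolved config: %r", config)

    def emit(name: str) -> Path:
        manifest.append(name)
        return out / name

    try:
        # ---- input proteomes -------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        annotations: GOAnnotationMap | None = None
        truth = None
        if config.simulate is not None:
            proteomes, truth, annotations = synthetic_data.simulate_dataset(
                config.simulate)
            synthetic_data.write_dataset(out / "synthetic", config.simulate)
            manifest.append("synthetic/")
        else:
            proteomes = {taxon: read_fasta(path, taxon_id=taxon)
                         for taxon, path in sorted(config.fasta.items())}
            for taxon, path in sorted(config.fasta.items()):
                log.info("input %s sha256=%s", path, _sha256(Path(path)))
        gene_taxon = {r.gene_id: taxon
                      for taxon, recs in proteomes.items() for r in recs}
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---- similarity graph ------------------------------------------
        stage = "graph"
        t0 = time.perf_counter()
        if config.hits_file:
            hits = read_blast_tab(config.hits_file)
            sg = similarity_graph.build_graph_from_hits(
                hits, evalue_cutoff=config.evalue_cutoff,
                gene_taxon=gene_taxon, all_genes=gene_taxon)
        else:
            sg = similarity_graph.build_graph_internal(
                proteomes, k=config.kmer_k, min_score=config.min_score)
        similarity_graph.write_abc(sg, emit("graph.abc.tsv"))
        log.info("stage %s done in %.2fs (%d nodes, %d edges)", stage,
                 time.perf_counter() - t0, sg.graph.number_of_nodes(),
                 sg.graph.number_of_edges())

        # ---- MCL clustering --------------------------------------------
        stage = "cluster"
        t0 = time.perf_counter()
        groups = mcl_clustering.mcl(
            sg, inflation=config.inflation, max_iter=config.max_iter,
            prune_below=config.prune_below)
        mcl_clustering.write_families_tsv(groups, gene_taxon,
                                          emit("families.tsv"))
        log.info("stage %s done in %.2fs (%d families)", stage,
                 time.perf_counter() - t0, len(groups.families))

        # ---- count matrix & expansion tests ----------------------------
        stage = "expand"
        t0 = time.perf_counter()
        totals = {taxon: len(recs) for taxon, recs in proteomes.items()}
        matrix = family_analysis.build_count_matrix(groups, gene_taxon,
                                                    taxon_totals=totals)
        matrix.counts.to_csv(emit("family_counts.tsv"), sep="\t")
        grouping = config.grouping
        if grouping is None:
            raise ValueError("no taxon grouping configured")
        div_results = expansion_stats.test_clade_diversified(
            matrix, grouping, q_threshold=config.q_threshold,
            method=config.clade_method)
        pair_results, expanded = expansion_stats.test_species_expansion(
            matrix, grouping, q_threshold=config.q_threshold,
            rule=config.pairwise_rule)
        expansion_stats.write_results_tsv(div_results,
                                          emit("clade_diversified.tsv"))
        expansion_stats.write_results_tsv(pair_results,
                                          emit("species_expansion.tsv"))
        diversified = expansion_stats.significant_families(div_results)
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---- gene sets, venn, bins, dendrogram -------------------------
        stage = "classify"
        t0 = time.perf_counter()
        partition = family_analysis.classify_gene_sets(
            matrix, grouping, diversified=diversified, expanded=expanded,
            groups=groups, gene_taxon=gene_taxon)
        with open(emit("gene_sets.tsv"), "w", newline="\n") as fh:
            fh.write("set\tid\n")
            for name, ids in (("core", partition.core),
                              ("clade_specific", partition.clade_specific),
                              ("clade_diversified",
                               partition.clade_diversified),
                              ("focal_specific_gene",
                               partition.focal_specific)):
                for x in sorted(ids):
                    fh.write(f"{name}\t{x}\n")
            for taxon in sorted(partition.species_expanded):
                for fam in sorted(partition.species_expanded[taxon]):
                    fh.write(f"expanded:{taxon}\t{fam}\n")
        core_frac = family_analysis.core_gene_fraction(
            matrix, partition, grouping.focal_species)
        venn = family_analysis.venn_counts(matrix,
                                           sorted(grouping.focal_clade)[:4])
        with open(emit("venn.tsv"), "w", newline="\n") as fh:
            fh.write("region\tfamilies\n")
            for region in sorted(venn, key=lambda r: (len(r), sorted(r))):
                fh.write(f"{'&'.join(sorted(region))}\t{venn[region]}\n")
        with open(emit("size_bins.tsv"), "w", newline="\n") as fh:
            fh.write("taxon\tinterval\tfamilies\n")
            for taxon in sorted(grouping.focal_clade):
                sizes = [int(c) for c in matrix.counts[taxon] if c >= 1]
                for (lo, hi), cnt in family_analysis.exponential_bins(sizes):
                    fh.write(f"{taxon}\t({lo},{hi}]\t{cnt}\n")
        dendro = family_analysis.gene_content_dendrogram(matrix)
        (out / "gene_content_dendrogram.nwk").write_text(
            write_newick(dendro))
        manifest.append("gene_content_dendrogram.nwk")
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---- FFP phylogeny ---------------------------------------------
        stage = "phylo"
        t0 = time.perf_counter()
        profiles = [ffp_phylogeny.ffp_profile(proteomes[t],
                                              l=config.ffp_length)
                    for t in sorted(proteomes)]
        dm = ffp_phylogeny.distance_matrix(profiles)
        dm.to_tsv(emit("ffp_distances.tsv"))
        tree = ffp_phylogeny.bootstrap_tree(profiles, B=config.bootstrap,
                                            seed=config.seed + 17)
        tree_newick = write_newick(tree)
        (out / "ffp_tree.nwk").write_text(tree_newick)
        manifest.append("ffp_tree.nwk")
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---- GO enrichment ---------------------------------------------
        stage = "enrich"
        t0 = time.perf_counter()
        enrichment_summary = {}
        if annotations is None and config.id2go:
            parents = read_obo_lite(config.obo) if config.obo else None
            annotations = read_id2go(config.id2go, term_parents=parents)
        if annotations is not None:
            annotations = go_enrichment.propagate_annotations(annotations)
            focal_sp = grouping.focal_species
            universe = {g for g, t in gene_taxon.items() if t == focal_sp}
            fam_of = groups.family_of()
            sets = {
                "core": {g for g in universe
                         if fam_of[g] in partition.core},
                "clade_specific": {g for g in universe
                                   if fam_of[g] in partition.clade_specific},
                "clade_diversified": {
                    g for g in universe
                    if fam_of[g] in partition.clade_diversified},
                "focal_specific": partition.focal_specific,
            }
            for name, genes in sets.items():
                if not genes:
                    continue
                rows = go_enrichment.enrich(genes, universe, annotations)
                go_enrichment.write_enrichment_tsv(
                    rows, emit(f"enrichment_{name}.tsv"))
                enrichment_summary[name] = [
                    {"term": r.term, "observed": r.observed,
                     "expected": round(r.expected, 4),
                     "p": float(f"{r.p_value:.6g}")}
                    for r in rows[:5]
                ]
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---- report -----------------------------------------------------
        stage = "report"
        report = {
            "seed": config.seed,
            "n_genes": {t: len(r) for t, r in sorted(proteomes.items())},
            "n_families": len(groups.families),
            "set_sizes": {
                "core": len(partition.core),
                "clade_specific": len(partition.clade_specific),
                "clade_diversified": len(partition.clade_diversified),
                "focal_specific_genes": len(partition.focal_specific),
            },
            "core_gene_fraction": round(core_frac, 6),
            "expanded_families": {t: sorted(v)
                                  for t, v in sorted(expanded.items())},
            "ffp_tree": tree_newick.strip(),
            "enrichment_top": enrichment_summary,
        }
        if truth is not None:
            report["clustering_ari"] = round(
                mcl_clustering.cluster_quality(groups, truth), 6)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest.append("report.json")
        (out / "MANIFEST").write_text(
            "\n".join(["# complete"] + sorted(manifest)) + "\n")
        return report
    except Exception as exc:
        (out / "MANIFEST").write_text(
            "\n".join([f"# INCOMPLETE: stage {stage} failed: {exc}"]
                      + sorted(manifest)) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
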