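"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in dependency order: simulate -> ighv / variant filtering ->
tree reconstruction -> lineage quantification -> phenotype analyses.  Every
run writes a JSON manifest recording the configuration, seed, and a SHA-256
checksum per output file, so identical configurations yield identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clonesim import (SimConfig, simulate_bulk_vafs, simulate_ig_colonies,
                       simulate_omics, simulate_single_cell_clones,
                       random_germline)
from .clonetree import build_clonal_tree, check_heterozygosity
from .ighv import build_profiles, call_subclones, mutation_level
from .phenoclust import cluster_concordance, methylation_expression_flag
from .presets import hg3_config, hg3_tree, HG3_LINEAGE_PROPS
from .quantify import estimate_lineage_fractions

__all__ = ["PipelineConfig", "run_pipeline", "run_demo",
           "EXIT_OK", "EXIT_CONFIG", "EXIT_DATA", "EXIT_INFEASIBLE"]

log = logging.getLogger("clonelines")

EXIT_OK, EXIT_CONFIG, EXIT_DATA, EXIT_INFEASIBLE = 0, 2, 3, 4


@dataclass(frozen=True)
class PipelineConfig:
    """Stage toggles and parameters for a simulated end-to-end run."""

    outdir: str = "clonelines_run"
    seed: int = 0
    simulate: bool = True
    ighv: bool = True
    tree: bool = True
    quantify: bool = True
    phenotype: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    n_colonies: int = 10
    germline_length: int = 350
    ig_shared_mut: int = 7
    ig_specific_mut: int = 2
    bulk_depth: int = 2000


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig,
                 tree=None) -> dict:
    """Run the enabled stages on simulated data and return the manifest.

    ``tree`` overrides the simulated clonal tree (e.g. the HG3 preset).
    """
    from .clonesim import simulate_clonal_tree

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}
    outputs: list[Path] = []

    def emit(name: str, path: Path) -> None:
        outputs.append(path)
        manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)

    if not config.simulate:
        manifest["stages"] = {}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    sim = SimConfig(**{**asdict(config.sim), "seed": config.seed})
    if tree is None:
        tree = simulate_clonal_tree(sim)
    log.info("simulate: tree with %d lineages, %d mutations",
             tree.n_lineages, len(tree.mutations))
    matrix, labels = simulate_single_cell_clones(tree, sim)
    gpath, wpath = outdir / "genotypes.tsv", outdir / "genotypes_wt.tsv"
    matrix.to_tsv(gpath, wpath)
    labels.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    emit("genotypes", gpath)
    emit("genotypes_wt", wpath)
    emit("labels", outdir / "truth_labels.tsv")
    manifest["stages"]["simulate"] = {"n_clones": matrix.n_clones,
                                      "n_mutations": matrix.n_mutations}

    if config.ighv:
        germline = random_germline(config.germline_length, seed=sim.seed)
        colonies, _ = simulate_ig_colonies(
            tree, germline, config.n_colonies, config.ig_shared_mut,
            config.ig_specific_mut, sim)
        cpath, gl = outdir / "ig_colonies.fasta", outdir / "ig_germline.fasta"
        colonies.to_fasta(cpath, gl)
        emit("ig_colonies", cpath)
        emit("ig_germline", gl)
        profiles = build_profiles(colonies)
        _, set_level, hyper = mutation_level(profiles)
        call = call_subclones(profiles)
        manifest["stages"]["ighv"] = {
            "set_mutation_level": round(set_level, 4),
            "hypermutated": hyper,
            "n_clones_called": call.n_clones_called}
        log.info("ighv: level %.2f%%, %d clone(s) called", set_level,
                 call.n_clones_called)

    rec = None
    if config.tree:
        rec = build_clonal_tree(matrix)
        rec.save(outdir / "tree.json", outdir / "tree.nwk")
        emit("tree_json", outdir / "tree.json")
        emit("tree_newick", outdir / "tree.nwk")
        het = check_heterozygosity(matrix)
        manifest["stages"]["tree"] = {
            "n_lineages": rec.n_lineages,
            "n_assigned": len(rec.clone_assignments),
            "n_unassigned": len(rec.unassigned),
            "heterozygosity_consistent": het.consistent}
        log.info("tree: %d lineages, %d/%d clones assigned",
                 rec.n_lineages, len(rec.clone_assignments), matrix.n_clones)

    if config.quantify and rec is not None:
        vafs = simulate_bulk_vafs(tree, sim.props, config.bulk_depth,
                                  seed=sim.seed)
        vafs.to_csv(outdir / "bulk_vafs.tsv", sep="\t", index=False)
        emit("bulk_vafs", outdir / "bulk_vafs.tsv")
        fr = estimate_lineage_fractions(vafs, rec)
        fr.to_frame().to_csv(outdir / "lineage_fractions.tsv", sep="\t",
                             index=False)
        emit("lineage_fractions", outdir / "lineage_fractions.tsv")
        manifest["stages"]["quantify"] = {
            "fractions": {l: round(v, 4) for l, v in fr.fractions.items()},
            "trunk_vaf": round(fr.trunk_vaf, 4)}

    if config.phenotype and rec is not None and len(labels):
        expr, beta, truth = simulate_omics(tree, labels, seed=sim.seed)
        expr.to_csv(outdir / "expression.tsv", sep="\t")
        beta.to_csv(outdir / "methylation_beta.tsv", sep="\t")
        emit("expression", outdir / "expression.tsv")
        emit("methylation", outdir / "methylation_beta.tsv")
        lab = labels.set_index("clone_id")["lineage_id"]
        conc = cluster_concordance(expr, lab)
        epiflags = {}
        for gene in truth["epigenes"]:
            epiflags[gene] = methylation_expression_flag(
                beta[gene].to_numpy(), expr[gene].to_numpy())["flag"]
        manifest["stages"]["phenotype"] = {
            "expression_ari": round(conc.ari, 4),
            "epigene_flags": epiflags}
        log.info("phenotype: expression ARI %.3f", conc.ari)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def run_demo(outdir: str, seed: int = 0) -> dict:
    """One-command end-to-end demo on the HG3 preset."""
    cfg = PipelineConfig(outdir=outdir, seed=seed,
                         sim=hg3_config(seed=seed))
    return run_pipeline(cfg, tree=hg3_tree())
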