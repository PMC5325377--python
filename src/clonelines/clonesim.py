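"""Seeded generator of synthetic cell-line clonal histories.

Emulates the data a subclone study of a nominally monoclonal B-lymphoma cell
line produces: a founder ("mother") clone carrying trunk mutations, 2-4
diverging lineages that accumulate lineage- and stage-specific mutations
under the infinite-sites assumption, single-cell clones genotyped ARMS-style
(heterozygous presence/absence calls with dropout), cloned IG PCR-product
sequences with PCR errors, bulk variant allele fractions from binomial read
sampling, bimodal surface-marker intensities under either a heritable
subclone model or a transient-activation (state-switching) model, and
clones x genes expression / methylation matrices with lineage signatures and
inverse methylation-expression coupling.

All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .clonal_tree import ClonalTree, ROOT
from .genotypes import GenotypeMatrix, PRESENT, ABSENT, MISSING
from .ighv import IGColonySet

__all__ = [
    "SimConfig",
    "simulate_clonal_tree",
    "simulate_single_cell_clones",
    "simulate_ig_colonies",
    "simulate_bulk_vafs",
    "simulate_marker_intensities",
    "sort_and_regrow",
    "simulate_omics",
    "random_germline",
    "node_proportions",
    "true_vafs",
]

_BASES = np.array(list("ACGT"))


def _as_tuple(value: int | Sequence[int], n: int, name: str) -> tuple[int, ...]:
    if isinstance(value, int):
        return (value,) * n
    out = tuple(int(v) for v in value)
    if len(out) != n:
        raise ValueError(f"{name} must have length n_lineages={n}")
    return out


@dataclass(frozen=True)
class SimConfig:
    """Scenario of a simulated multiclonal cell line.

    Defaults encode a three-lineage line: a dominant lineage at 50% of cells
    with the other two splitting the remainder, one of which carries a later
    ("late") stage — the structure reported for the CLL line HG3.

    Parameters
    ----------
    n_lineages:
        Number of lineages diverging from the founder clone.
    n_trunk_mut:
        Mutations on the trunk edge (carried by every cell).
    muts_per_lineage:
        Lineage-defining mutations per lineage (int, or one count per
        lineage).
    stages_per_lineage:
        Number of chained later stages per lineage (int or per-lineage).
    muts_per_stage:
        Mutations acquired at each later stage.
    n_clones:
        Single-cell clones to sample for the genotype matrix.
    lineage_props:
        Sampling proportions of the lineages (simplex); uniform if None.
    dropout_rate:
        Per-call probability an ARMS genotype is missing.
    pcr_error_rate:
        Per-base error probability for colony (Sanger) sequencing.
    seed:
        Seed for every random draw.
    """

    n_lineages: int = 3
    n_trunk_mut: int = 2
    muts_per_lineage: int | tuple[int, ...] = 3
    stages_per_lineage: int | tuple[int, ...] = (0, 1, 0)
    muts_per_stage: int = 2
    n_clones: int = 60
    lineage_props: tuple[float, ...] | None = (0.50, 0.25, 0.25)
    dropout_rate: float = 0.0
    pcr_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        for name in ("n_trunk_mut", "muts_per_stage", "n_clones"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_rate", "pcr_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        _as_tuple(self.muts_per_lineage, self.n_lineages, "muts_per_lineage")
        _as_tuple(self.stages_per_lineage, self.n_lineages,
                  "stages_per_lineage")
        if self.lineage_props is not None:
            props = tuple(float(p) for p in self.lineage_props)
            if len(props) != self.n_lineages:
                raise ValueError("lineage_props length != n_lineages")
            if any(p < 0 for p in props):
                raise ValueError("lineage_props must be non-negative")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError("lineage_props must sum to 1 (within 1e-9)")
            object.__setattr__(self, "lineage_props", props)

    @property
    def props(self) -> tuple[float, ...]:
        if self.lineage_props is not None:
            return self.lineage_props
        return (1.0 / self.n_lineages,) * self.n_lineages

    # -- config file round trip -------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("muts_per_lineage", "stages_per_lineage", "lineage_props"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# clonal tree


def simulate_clonal_tree(config: SimConfig) -> ClonalTree:
    """Build the clonal lineage tree a SimConfig describes.

    Deterministic: the tree is fully specified by the configuration (node and
    mutation identifiers are systematic).  Structure: root (wild-type) ->
    mother (trunk edge with ``n_trunk_mut`` mutations) -> one branch per
    lineage, each extended by a chain of later stages.
    """
    edges: list[tuple[str, str, list[str]]] = []
    trunk = [f"trunk_m{i}" for i in range(config.n_trunk_mut)]
    edges.append((ROOT, "mother", trunk))
    mpl = _as_tuple(config.muts_per_lineage, config.n_lineages,
                    "muts_per_lineage")
    spl = _as_tuple(config.stages_per_lineage, config.n_lineages,
                    "stages_per_lineage")
    for li in range(config.n_lineages):
        lid = f"L{li + 1}"
        edges.append(("mother", lid,
                      [f"{lid}_m{j}" for j in range(mpl[li])]))
        parent = lid
        for st in range(1, spl[li] + 1):
            node = f"{lid}.s{st}"
            edges.append((parent, node,
                          [f"{node}_m{j}" for j in range(config.muts_per_stage)]))
            parent = node
    return ClonalTree.from_edges(edges)


def _stage_nodes(tree: ClonalTree, lineage: str) -> list[str]:
    """Lineage branch node followed by its chained stage nodes, in order of
    increasing depth."""
    nodes = [lineage]
    while True:
        kids = tree.children(nodes[-1])
        if not kids:
            return nodes
        nodes.append(kids[0])  # simulated lineages are chains


def node_proportions(tree: ClonalTree,
                     lineage_props: Sequence[float]) -> dict[str, float]:
    """Cell-population proportion of every sampled node: lineage proportions
    split uniformly over each lineage's stage chain."""
    props = dict(zip(tree.lineage_roots, lineage_props))
    out: dict[str, float] = {}
    for lineage, p in props.items():
        chain = _stage_nodes(tree, lineage)
        for node in chain:
            out[node] = p / len(chain)
    return out


# ---------------------------------------------------------------------------
# single-cell clones (ARMS-style genotypes)


def simulate_single_cell_clones(
    tree: ClonalTree, config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sample single-cell clones and genotype them ARMS-style.

    Each clone is drawn from a lineage according to ``lineage_props`` and
    placed uniformly on that lineage's stage chain; its genotype is the
    union of mutations on its root path, heterozygous (the wild-type allele
    is detected wherever the call is not missing).  Dropout masks calls
    independently at ``dropout_rate``.

    Returns the genotype matrix and a truth-label table with columns
    ``clone_id``, ``lineage_id``, ``stage_index``, ``node``.
    """
    rng = np.random.default_rng(config.seed)
    mutation_ids = tuple(sorted(tree.mutations))
    lineages = list(tree.lineage_roots)
    chains = {l: _stage_nodes(tree, l) for l in lineages}

    clone_ids, rows, labels = [], [], []
    n = config.n_clones
    lin_idx = rng.choice(len(lineages), size=n, p=list(config.props)) if n else []
    for i in range(n):
        lineage = lineages[int(lin_idx[i])]
        chain = chains[lineage]
        stage = int(rng.integers(len(chain)))
        node = chain[stage]
        path = tree.path_mutations(node)
        row = np.array([PRESENT if m in path else ABSENT
                        for m in mutation_ids], dtype=np.int8)
        cid = f"clone{i + 1:03d}"
        clone_ids.append(cid)
        rows.append(row)
        labels.append({"clone_id": cid, "lineage_id": lineage,
                       "stage_index": stage, "node": node})

    calls = (np.vstack(rows) if rows
             else np.empty((0, len(mutation_ids)), dtype=np.int8))
    wt = np.ones_like(calls)  # universal heterozygosity
    if config.dropout_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < config.dropout_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)
        wt = np.where(mask, MISSING, wt).astype(np.int8)
    matrix = GenotypeMatrix(clone_ids=tuple(clone_ids),
                            mutation_ids=mutation_ids,
                            calls=calls, wt_detected=wt)
    label_df = pd.DataFrame(labels, columns=["clone_id", "lineage_id",
                                             "stage_index", "node"])
    return matrix, label_df


# ---------------------------------------------------------------------------
# IG colony sequences


def random_germline(length: int = 350, seed: int = 0) -> str:
    """Random nucleotide sequence standing in for a rearranged VH-JH
    germline reference."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=length))


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def simulate_ig_colonies(
    tree: ClonalTree,
    germline: str,
    n_colonies: int,
    shared_mut: int,
    specific_mut_per_lineage: int,
    config: SimConfig,
) -> tuple[IGColonySet, pd.DataFrame]:
    """Simulate cloned IG PCR-product (bacterial colony) sequences.

    Every colony carries ``shared_mut`` substitutions common to the whole
    culture plus its lineage's ``specific_mut_per_lineage`` substitutions;
    Poisson(pcr_error_rate x length) additional singleton errors are private
    to each colony.  All substitution positions are unique (infinite sites).

    Returns the colony set and a truth table (colony_id, lineage_id).
    """
    if len(germline) < 100:
        raise ValueError("germline must be >= 100 nt")
    rng = np.random.default_rng(config.seed)
    n_lin = tree.n_lineages
    n_planned = shared_mut + n_lin * specific_mut_per_lineage
    if n_planned > len(germline):
        raise ValueError("requested mutations exceed sequence length")

    positions = rng.permutation(len(germline))
    planned = positions[:n_planned]
    spare = list(positions[n_planned:])
    shared_pos = planned[:shared_mut]
    lineage_pos = {
        lid: planned[shared_mut + i * specific_mut_per_lineage:
                     shared_mut + (i + 1) * specific_mut_per_lineage]
        for i, lid in enumerate(tree.lineage_roots)
    }
    shared_subs = {int(p): _mutate(germline[p], rng) for p in shared_pos}
    lineage_subs = {lid: {int(p): _mutate(germline[p], rng) for p in pos}
                    for lid, pos in lineage_pos.items()}

    lineages = list(tree.lineage_roots)
    lin_idx = rng.choice(n_lin, size=n_colonies, p=list(config.props))
    colonies, truth = [], []
    for i in range(n_colonies):
        lid = lineages[int(lin_idx[i])]
        seq = list(germline)
        for p, b in shared_subs.items():
            seq[p] = b
        for p, b in lineage_subs[lid].items():
            seq[p] = b
        n_err = int(rng.poisson(config.pcr_error_rate * len(germline)))
        for _ in range(min(n_err, len(spare))):
            p = spare.pop(int(rng.integers(len(spare))))
            seq[p] = _mutate(germline[p], rng)
        cid = f"colony{i + 1:02d}"
        colonies.append((cid, "".join(seq)))
        truth.append({"colony_id": cid, "lineage_id": lid})
    colony_set = IGColonySet(germline=germline, colonies=tuple(colonies))
    return colony_set, pd.DataFrame(truth, columns=["colony_id", "lineage_id"])


# ---------------------------------------------------------------------------
# bulk VAFs


def true_vafs(tree: ClonalTree,
              lineage_props: Sequence[float]) -> dict[str, float]:
    """Expected variant allele fraction of every mutation in an unsorted
    bulk: half the summed proportion of carrying cells (heterozygous,
    diploid).  Trunk mutations have VAF 0.5 exactly."""
    props = node_proportions(tree, lineage_props)
    out: dict[str, float] = {}
    for m in sorted(tree.mutations):
        edge = tree.edge_of_mutation[m]
        carriers = sum(props.get(n, 0.0)
                       for n in tree.subtree_nodes(edge))
        if edge == tree.mother:  # trunk: carried by every sampled cell
            carriers = 1.0
        out[m] = carriers / 2.0
    return out


def simulate_bulk_vafs(tree: ClonalTree,
                       lineage_props: Sequence[float],
                       depth: int,
                       seed: int = 0) -> pd.DataFrame:
    """Binomial read counts per mutation at the stated sequencing depth.

    Columns: mutation_id, ref_count, alt_count, depth, true_vaf.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for m, vaf in true_vafs(tree, lineage_props).items():
        alt = int(rng.binomial(depth, vaf))
        rows.append({"mutation_id": m, "ref_count": depth - alt,
                     "alt_count": alt, "depth": depth, "true_vaf": vaf})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker intensities (bimodality / sort-and-regrow)


def simulate_marker_intensities(
    model: Literal["subclone", "activation"],
    n_cells: int,
    mode_means: tuple[float, float] = (1.0, 3.0),
    mode_sd: float = 0.4,
    switch_prob: float = 0.2,
    positive_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell log marker intensities from a two-mode Gaussian mixture.

    The latent state (0 = negative mode, 1 = positive mode, positive = the
    higher mean) is heritable under the ``subclone`` model and re-drawn with
    probability ``switch_prob`` per generation step under the ``activation``
    model (the distinction only matters when the sample is regrown; the
    initial cross-section is identical).

    Columns: cell_id, state, log_intensity.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if model not in ("subclone", "activation"):
        raise ValueError(f"unknown model {model!r}")
    lo, hi = sorted(mode_means)
    if lo == hi:
        raise ValueError("mode_means must be distinct")
    rng = np.random.default_rng(seed)
    states = (rng.random(n_cells) < positive_fraction).astype(int)
    means = np.where(states == 1, hi, lo)
    vals = rng.normal(means, mode_sd)
    return pd.DataFrame({"cell_id": [f"cell{i}" for i in range(n_cells)],
                         "state": states, "log_intensity": vals})


def sort_and_regrow(
    model: Literal["subclone", "activation"],
    n_cells: int = 2000,
    steps: int = 14,
    sort_state: int = 1,
    mode_means: tuple[float, float] = (1.0, 3.0),
    mode_sd: float = 0.4,
    switch_prob: float = 0.2,
    positive_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """In-silico flow sort followed by regrowth in discrete generation steps.

    The culture is sorted to cells of ``sort_state`` (default: positive
    mode), then advanced ``steps`` generations (convention: 1 step = 1 day,
    so the 1-2 week regrowth window of a sorting experiment is 7-14 steps).
    Under ``subclone`` the latent state is heritable and never changes; under
    ``activation`` each cell re-draws its state from
    Bernoulli(``positive_fraction``) with probability ``switch_prob`` per
    step, so the sorted fraction relaxes geometrically toward the stationary
    mixture.

    Returns one row per (step, cell): step, cell_id, state, log_intensity.
    Step 0 is the freshly sorted population.
    """
    rng = np.random.default_rng(seed)
    states = np.full(n_cells, sort_state, dtype=int)  # post-sort purity
    lo, hi = sorted(mode_means)
    frames = []
    for step in range(steps + 1):
        if step > 0 and model == "activation" and switch_prob > 0:
            redraw = rng.random(n_cells) < switch_prob
            states = np.where(redraw,
                              (rng.random(n_cells) < positive_fraction),
                              states).astype(int)
        vals = rng.normal(np.where(states == 1, hi, lo), mode_sd)
        frames.append(pd.DataFrame({
            "step": step,
            "cell_id": [f"cell{i}" for i in range(n_cells)],
            "state": states.copy(), "log_intensity": vals}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# omics (expression + methylation)


def simulate_omics(
    tree: ClonalTree,
    labels: pd.DataFrame,
    n_genes: int = 200,
    n_signature_genes_per_lineage: int = 10,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    n_epigenes: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Clones x genes expression and clones x CpG methylation matrices.

    Each lineage gets ``n_signature_genes_per_lineage`` signature genes
    shifted by +/- ``effect_size`` in its clones on top of N(0, noise_sd)
    noise.  For each of ``n_epigenes`` (drawn from signature genes when
    available) a methylation beta in [0, 1] is generated as a monotone
    decreasing function of that gene's expression plus noise — the inverse
    methylation-expression pattern of an epigenetically regulated gene.

    Returns (expression, methylation_beta, truth) where truth records the
    signature-gene and epigene assignments.
    """
    n_lin = tree.n_lineages
    if n_signature_genes_per_lineage * n_lin > n_genes:
        raise ValueError("more signature genes than genes")
    rng = np.random.default_rng(seed)
    clones = list(labels["clone_id"])
    genes = [f"gene{g + 1:04d}" for g in range(n_genes)]
    expr = rng.normal(0.0, noise_sd, size=(len(clones), n_genes))

    signatures: dict[str, list[str]] = {}
    g = 0
    for lid in tree.lineage_roots:
        sig = genes[g:g + n_signature_genes_per_lineage]
        signatures[lid] = sig
        in_lineage = (labels["lineage_id"] == lid).to_numpy()
        signs = rng.choice([-1.0, 1.0], size=len(sig))
        for j, gene in enumerate(sig):
            expr[in_lineage, genes.index(gene)] += signs[j] * effect_size
        g += n_signature_genes_per_lineage

    expr_df = pd.DataFrame(expr, index=clones, columns=genes)

    sig_pool = [gn for sig in signatures.values() for gn in sig]
    pool = sig_pool if len(sig_pool) >= n_epigenes else genes
    epigenes = list(pool[:n_epigenes])
    betas = {}
    for gene in epigenes:
        z = expr_df[gene].to_numpy()
        z = (z - z.mean()) / (z.std() + 1e-12)
        beta = 1.0 / (1.0 + np.exp(2.0 * z))  # monotone decreasing in expr
        beta = beta + rng.normal(0.0, 0.03, size=len(z))
        betas[gene] = np.clip(beta, 0.001, 0.999)
    beta_df = pd.DataFrame(betas, index=clones)

    truth = {"signature_genes": signatures, "epigenes": epigenes}
    return expr_df, beta_df, truth
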