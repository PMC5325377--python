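"""Perfect-phylogeny reconstruction from clones x mutations genotypes.

Under the infinite-sites assumption every mutation arises once and is never
lost, so the clone sets carrying each mutation form a laminar family and the
clonal history is a rooted tree.  Compatibility of a pair of mutations is the
classic four-gamete test: the pair conflicts iff carrier patterns (1,0),
(0,1) and (1,1) all occur among clones with both calls observed.  The tree is
built by ordering mutations by carrier-set inclusion: mutations with
identical carrier sets share an edge, containment defines ancestry, and
mutations carried by every clone form the trunk of the founder ("mother")
clone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .clonal_tree import ClonalTree, ROOT
from .genotypes import GenotypeMatrix, PRESENT, ABSENT, MISSING

__all__ = [
    "ConflictReport",
    "PhylogenyConflictError",
    "ReconstructedTree",
    "HeterozygosityReport",
    "four_gamete_conflicts",
    "build_clonal_tree",
    "classify_mutations",
    "assign_stages",
    "check_heterozygosity",
]

MissingPolicy = Literal["strict", "impute-absent"]


@dataclass(frozen=True)
class ConflictReport:
    """Mutation pairs violating infinite-sites compatibility."""

    pairs: tuple[tuple[str, str], ...]
    gametes_observed: dict[tuple[str, str], frozenset[str]]

    @property
    def n_conflicts(self) -> int:
        return len(self.pairs)


class PhylogenyConflictError(ValueError):
    """Raised when a genotype matrix admits no perfect phylogeny."""

    def __init__(self, report: ConflictReport):
        self.report = report
        super().__init__(
            f"{report.n_conflicts} mutation pair(s) fail the four-gamete "
            f"test: {list(report.pairs)[:5]}")


@dataclass(frozen=True)
class ReconstructedTree:
    """A reconstructed clonal tree plus mutation and clone annotations.

    ``mutation_classes`` maps every placed mutation to one of
    ``trunk`` / ``lineage-defining`` / ``stage-specific`` / ``private``;
    ``clone_assignments`` maps each assigned clone to its node;
    ``unassigned`` lists clones whose genotype matches no node;
    ``unplaced_mutations`` lists mutations observed in no clone.
    """

    tree: ClonalTree
    mutation_classes: dict[str, str]
    clone_assignments: dict[str, str]
    unassigned: tuple[str, ...]
    unplaced_mutations: tuple[str, ...] = ()

    @property
    def n_lineages(self) -> int:
        return self.tree.n_lineages

    def to_json_dict(self) -> dict:
        return {
            "newick": self.tree.to_newick(),
            "n_lineages": self.n_lineages,
            "mutation_classes": dict(sorted(self.mutation_classes.items())),
            "clone_assignments": dict(sorted(self.clone_assignments.items())),
            "unassigned": list(self.unassigned),
            "unplaced_mutations": list(self.unplaced_mutations),
        }

    def save(self, json_path: str | Path,
             newick_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_json_dict(), indent=2))
        if newick_path is not None:
            Path(newick_path).write_text(self.tree.to_newick() + "\n")


@dataclass(frozen=True)
class HeterozygosityReport:
    evaluable: bool
    findings: tuple[tuple[str, str], ...]  # (clone_id, mutation_id)

    @property
    def consistent(self) -> bool:
        return self.evaluable and not self.findings


# ---------------------------------------------------------------------------


def _resolve_missing(matrix: GenotypeMatrix,
                     policy: MissingPolicy) -> np.ndarray:
    calls = matrix.calls
    if policy == "impute-absent":
        return np.where(calls == MISSING, ABSENT, calls).astype(np.int8)
    if policy == "strict":
        return calls
    raise ValueError(f"unknown missing policy {policy!r}")


def four_gamete_conflicts(matrix: GenotypeMatrix) -> ConflictReport:
    """Four-gamete test over all mutation pairs on complete cases.

    A pair conflicts iff patterns (1,0), (0,1) and (1,1) all occur among
    clones where both calls are non-missing; (0,0) is uninformative.
    """
    if matrix.n_mutations < 2:
        return ConflictReport(pairs=(), gametes_observed={})
    calls = matrix.calls
    muts = matrix.mutation_ids
    pairs: list[tuple[str, str]] = []
    gametes: dict[tuple[str, str], frozenset[str]] = {}
    for i in range(len(muts)):
        for j in range(i + 1, len(muts)):
            a, b = calls[:, i], calls[:, j]
            ok = (a != MISSING) & (b != MISSING)
            seen = set()
            if np.any(ok & (a == PRESENT) & (b == ABSENT)):
                seen.add("10")
            if np.any(ok & (a == ABSENT) & (b == PRESENT)):
                seen.add("01")
            if np.any(ok & (a == PRESENT) & (b == PRESENT)):
                seen.add("11")
            key = (muts[i], muts[j])
            gametes[key] = frozenset(seen)
            if seen == {"10", "01", "11"}:
                pairs.append(key)
    return ConflictReport(pairs=tuple(pairs), gametes_observed=gametes)


def _pair_relation(a: np.ndarray, b: np.ndarray) -> str:
    """Relation between two mutation columns from complete cases:
    'equal', 'a_super', 'b_super', 'disjoint' (or 'conflict')."""
    ok = (a != MISSING) & (b != MISSING)
    g10 = bool(np.any(ok & (a == PRESENT) & (b == ABSENT)))
    g01 = bool(np.any(ok & (a == ABSENT) & (b == PRESENT)))
    g11 = bool(np.any(ok & (a == PRESENT) & (b == PRESENT)))
    if g10 and g01 and g11:
        return "conflict"
    if not g11:
        return "disjoint"
    if not g10 and not g01:
        return "equal"
    return "a_super" if g10 else "b_super"


def build_clonal_tree(matrix: GenotypeMatrix,
                      missing_policy: MissingPolicy = "strict"
                      ) -> ReconstructedTree:
    """Reconstruct the clonal lineage tree of a genotype matrix.

    Mutations with identical carrier sets merge onto one edge; carrier-set
    containment defines ancestry; mutations present in every clone (no
    observed absent call) form the trunk edge below the wild-type root, and
    their node is the founder ("mother") clone.  Each clone is assigned to
    the unique node whose root-path mutation set matches its non-missing
    genotype; clones matching no node are reported unassigned.

    Under ``strict`` (default) missing calls are excluded from carrier sets
    and pair relations use complete cases; under ``impute-absent`` missing
    is treated as absent (ARMS dropout read as signal failure).

    Raises :class:`PhylogenyConflictError` when any mutation pair fails the
    four-gamete test under the chosen policy.
    """
    calls = _resolve_missing(matrix, missing_policy)
    work = GenotypeMatrix(clone_ids=matrix.clone_ids,
                          mutation_ids=matrix.mutation_ids,
                          calls=calls, wt_detected=matrix.wt_detected)
    report = four_gamete_conflicts(work)
    if report.pairs:
        raise PhylogenyConflictError(report)

    muts = list(work.mutation_ids)
    carrier_count = {m: int(np.sum(work.column(m) == PRESENT)) for m in muts}
    unplaced = tuple(sorted(m for m in muts if carrier_count[m] == 0))
    placed = [m for m in muts if carrier_count[m] > 0]
    # deterministic ordering: carrier count desc, mutation id asc
    placed.sort(key=lambda m: (-carrier_count[m], m))

    # group mutations sharing an edge (identical carrier sets) — union-find
    parent_uf = {m: m for m in placed}

    def find(m: str) -> str:
        while parent_uf[m] != m:
            parent_uf[m] = parent_uf[parent_uf[m]]
            m = parent_uf[m]
        return m

    relations: dict[tuple[str, str], str] = {}
    for i, a in enumerate(placed):
        for b in placed[i + 1:]:
            rel = _pair_relation(work.column(a), work.column(b))
            relations[(a, b)] = rel
            if rel == "equal":
                ra, rb = find(a), find(b)
                if ra != rb:
                    # keep the earlier mutation (in deterministic order) as rep
                    keep, drop = sorted((ra, rb),
                                        key=lambda m: (-carrier_count[m], m))
                    parent_uf[drop] = keep

    groups: dict[str, list[str]] = {}
    for m in placed:
        groups.setdefault(find(m), []).append(m)

    def rel(a: str, b: str) -> str:
        """'a_super' if a's carriers strictly contain b's, etc."""
        if (a, b) in relations:
            return relations[(a, b)]
        r = relations[(b, a)]
        return {"a_super": "b_super", "b_super": "a_super"}.get(r, r)

    reps = sorted(groups, key=lambda m: (-carrier_count[m], m))
    # parent of each group: among its strict supersets, the smallest one
    group_parent: dict[str, str | None] = {}
    for g in reps:
        supers = [h for h in reps if h != g and rel(h, g) == "a_super"]
        if not supers:
            group_parent[g] = None
        else:
            group_parent[g] = min(supers,
                                  key=lambda h: (carrier_count[h], h))

    n_clones_called = {
        m: int(np.sum(work.column(m) != MISSING)) for m in placed}
    is_trunk_rep = {g: carrier_count[g] == n_clones_called[g]
                    and carrier_count[g] > 0 and group_parent[g] is None
                    for g in reps}
    trunk_reps = [g for g in reps if is_trunk_rep[g]]

    # node naming: trunk node is "mother"; others named after their
    # representative mutation
    node_of: dict[str, str] = {}
    for g in trunk_reps:
        node_of[g] = "mother"
    for g in reps:
        if g not in node_of:
            node_of[g] = f"n_{g}"

    edges: list[tuple[str, str, list[str]]] = []
    trunk_muts = sorted(m for g in trunk_reps for m in groups[g])
    edges.append((ROOT, "mother", trunk_muts))
    for g in reps:
        if g in trunk_reps:
            continue
        par = group_parent[g]
        par_node = "mother" if par is None else node_of[par]
        edges.append((par_node, node_of[g], sorted(groups[g])))
    tree = ClonalTree.from_edges(edges)

    # clone assignment: node whose path-set matches the observed genotype
    path_sets = {n: tree.path_mutations(n) for n in tree.nodes}
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for ci, cid in enumerate(work.clone_ids):
        row = work.calls[ci]
        present = {m for m, v in zip(work.mutation_ids, row) if v == PRESENT}
        absent = {m for m, v in zip(work.mutation_ids, row) if v == ABSENT}
        candidates = [n for n, ps in path_sets.items()
                      if present <= ps and not (ps & absent)]
        if not candidates:
            unassigned.append(cid)
            continue
        best = min(len(path_sets[n]) for n in candidates)
        top = sorted({path_sets[n] for n in candidates
                      if len(path_sets[n]) == best},
                     key=sorted)
        if len(top) > 1:
            unassigned.append(cid)
            continue
        node = min(n for n in candidates if path_sets[n] == top[0])
        assignments[cid] = node

    rec = ReconstructedTree(tree=tree, mutation_classes={},
                            clone_assignments=assignments,
                            unassigned=tuple(unassigned),
                            unplaced_mutations=unplaced)
    classes = classify_mutations(rec, carrier_count)
    return ReconstructedTree(tree=tree, mutation_classes=classes,
                             clone_assignments=assignments,
                             unassigned=tuple(unassigned),
                             unplaced_mutations=unplaced)


def classify_mutations(rec: ReconstructedTree,
                       carrier_count: dict[str, int] | None = None
                       ) -> dict[str, str]:
    """Class per placed mutation: ``trunk`` (root edge of the mother clone),
    ``lineage-defining`` (edge below the mother), ``stage-specific``
    (deeper edge), or ``private`` (carried by exactly one clone)."""
    tree = rec.tree
    if carrier_count is None:
        counts: dict[str, int] = {m: 0 for m in tree.mutations}
        for node in rec.clone_assignments.values():
            for m in tree.path_mutations(node):
                counts[m] += 1
        carrier_count = counts
    classes: dict[str, str] = {}
    for m in tree.mutations:
        edge = tree.edge_of_mutation[m]
        if carrier_count.get(m, 0) == 1:
            classes[m] = "private"
        elif edge == tree.mother:
            classes[m] = "trunk"
        elif tree.parent[edge] == tree.mother:
            classes[m] = "lineage-defining"
        else:
            classes[m] = "stage-specific"
    return classes


def assign_stages(rec: ReconstructedTree) -> dict[str, tuple[str | None, int]]:
    """Per-assigned-clone (lineage, stage_index).

    Within a lineage, stages are ordered by strictly increasing root-path
    mutation count (early = fewer mutations); sibling branches with equal
    counts share a stage index.  Clones at the mother or root map to
    (None, 0).
    """
    tree = rec.tree
    stage_of_node: dict[str, tuple[str | None, int]] = {}
    for lineage in tree.lineage_roots:
        nodes = tree.subtree_nodes(lineage)
        counts = sorted({len(tree.path_mutations(n)) for n in nodes})
        for n in nodes:
            stage_of_node[n] = (lineage,
                                counts.index(len(tree.path_mutations(n))))
    out: dict[str, tuple[str | None, int]] = {}
    for cid, node in rec.clone_assignments.items():
        out[cid] = stage_of_node.get(node, (None, 0))
    return out


def check_heterozygosity(matrix: GenotypeMatrix) -> HeterozygosityReport:
    """Sites where the mutant allele was detected without the wild-type
    allele — inconsistent with universal heterozygosity.

    An empty finding list means the matrix is consistent with every clone
    retaining the wild-type allele at every mutant site."""
    if matrix.wt_detected is None:
        return HeterozygosityReport(evaluable=False, findings=())
    findings = []
    for ci, cid in enumerate(matrix.clone_ids):
        for mi, mid in enumerate(matrix.mutation_ids):
            if (matrix.calls[ci, mi] == PRESENT
                    and matrix.wt_detected[ci, mi] == 0):
                findings.append((cid, mid))
    return HeterozygosityReport(evaluable=True, findings=tuple(findings))
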