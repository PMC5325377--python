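"""Rooted clonal lineage trees under the infinite-sites assumption.

A :class:`ClonalTree` describes the clonal history of a cell line: the root is
the wild-type (pre-neoplastic) cell, the single edge below it carries the
trunk mutations of the founder ("mother") clone, the mother's children are the
diverging clonal lineages, and deeper chained nodes are later stages of a
lineage.  Every mutation is placed on exactly one edge and is never lost, so
the carrier sets of any two mutations are either nested or disjoint (a laminar
family) — the structure a perfect phylogeny encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

__all__ = ["ClonalTree", "ROOT"]

ROOT = "root"


@dataclass(frozen=True)
class ClonalTree:
    """Rooted tree with mutation sets attached to edges.

    Parameters
    ----------
    parent:
        Mapping node -> parent node; the root maps to ``None``.
    edge_mutations:
        Mapping child node -> mutations on the edge (parent -> child).
        Every non-root node must have an entry (possibly empty).
    root:
        Identifier of the root (wild-type) node.
    """

    parent: Mapping[str, str | None]
    edge_mutations: Mapping[str, frozenset[str]]
    root: str = ROOT

    def __post_init__(self) -> None:
        if self.root not in self.parent or self.parent[self.root] is not None:
            raise ValueError("root must be a node with parent None")
        seen: set[str] = set()
        for node, par in self.parent.items():
            if node == self.root:
                continue
            if par not in self.parent:
                raise ValueError(f"parent of {node!r} is not a node")
            muts = self.edge_mutations.get(node, frozenset())
            if seen & set(muts):
                raise ValueError("mutation assigned to more than one edge")
            seen |= set(muts)
            # walk to root to guarantee connectivity / acyclicity
            hops, cur = 0, node
            while cur != self.root:
                cur = self.parent[cur]  # type: ignore[assignment]
                hops += 1
                if hops > len(self.parent):
                    raise ValueError(f"cycle detected at node {node!r}")

    # -- structure ---------------------------------------------------------

    @cached_property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.parent))

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parent.items() if p == node)

    @cached_property
    def mother(self) -> str:
        """The founder-clone node: the unique child of the wild-type root."""
        kids = self.children(self.root)
        if len(kids) != 1:
            raise ValueError("tree has no unique founder node below the root")
        return kids[0]

    @property
    def trunk_mutations(self) -> frozenset[str]:
        return self.edge_mutations.get(self.mother, frozenset())

    @cached_property
    def lineage_roots(self) -> tuple[str, ...]:
        """Children of the founder node — one per diverging clonal lineage."""
        return tuple(self.children(self.mother))

    @property
    def n_lineages(self) -> int:
        return len(self.lineage_roots)

    def path_nodes(self, node: str) -> list[str]:
        """Nodes from the root down to ``node`` inclusive."""
        path = [node]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])  # type: ignore[arg-type]
        return path[::-1]

    def path_mutations(self, node: str) -> frozenset[str]:
        """All mutations carried by a cell sitting at ``node``."""
        out: set[str] = set()
        for n in self.path_nodes(node):
            out |= self.edge_mutations.get(n, frozenset())
        return frozenset(out)

    @cached_property
    def mutations(self) -> frozenset[str]:
        out: set[str] = set()
        for muts in self.edge_mutations.values():
            out |= muts
        return frozenset(out)

    @cached_property
    def edge_of_mutation(self) -> dict[str, str]:
        """Mutation id -> child node of the edge carrying it."""
        out: dict[str, str] = {}
        for node, muts in self.edge_mutations.items():
            for m in muts:
                out[m] = node
        return out

    def lineage_of_node(self, node: str) -> str | None:
        """The lineage-root ancestor of ``node`` (None for root/mother)."""
        path = self.path_nodes(node)
        for n in path:
            if n in self.lineage_roots:
                return n
        return None

    def subtree_nodes(self, node: str) -> list[str]:
        out = [node]
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return sorted(out)

    # -- export ------------------------------------------------------------

    def to_newick(self, annotate: bool = True) -> str:
        """Newick string; branch length = #mutations on the edge, mutation
        ids listed in a bracketed comment when ``annotate`` is true."""

        def fmt(node: str) -> str:
            kids = self.children(node)
            inner = f"({','.join(fmt(k) for k in kids)})" if kids else ""
            muts = sorted(self.edge_mutations.get(node, frozenset()))
            label = f"{inner}{node}:{len(muts)}"
            if annotate and muts:
                label += f"[&mutations={'|'.join(muts)}]"
            return label

        kids = self.children(self.root)
        return f"({','.join(fmt(k) for k in kids)}){self.root};"

    @staticmethod
    def from_edges(edges: Iterable[tuple[str, str, Iterable[str]]],
                   root: str = ROOT) -> "ClonalTree":
        """Build from (parent, child, mutations) triples."""
        parent: dict[str, str | None] = {root: None}
        edge_mutations: dict[str, frozenset[str]] = {}
        for par, child, muts in edges:
            parent[child] = par
            edge_mutations[child] = frozenset(muts)
        return ClonalTree(parent=parent, edge_mutations=edge_mutations, root=root)
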