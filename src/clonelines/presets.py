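"""Packaged scenario presets.

The HG3 preset is a synthetic reconstruction of the published clonal
structure of the CLL cell line HG3 — trunk mutation CAV1 T46I in all 60
single-cell clones, three lineages conventionally coloured blue / green /
yellow with one ARMS marker each (SRSF12 R49C, ZNF330 G246A, CYP4X1 H183P),
a later "late" stage in the green lineage, and a bulk composition of roughly
50% blue with green and yellow splitting the remainder.  It is generated
data with that structure, not the original assay measurements.
"""

from __future__ import annotations

from .clonal_tree import ClonalTree, ROOT
from .clonesim import SimConfig

__all__ = ["hg3_tree", "hg3_config", "HG3_LINEAGE_PROPS"]

#: blue ~50%, green and yellow split the remainder
HG3_LINEAGE_PROPS: tuple[float, float, float] = (0.50, 0.25, 0.25)


def hg3_tree() -> ClonalTree:
    """Three-lineage clonal tree of the HG3 scenario.

    Trunk: CAV1_T46I (mother clone).  Lineages: blue (SRSF12_R49C),
    green (ZNF330_G246A) with a deeper late stage (two additional
    mutations), yellow (CYP4X1_H183P).
    """
    return ClonalTree.from_edges([
        (ROOT, "mother", ["CAV1_T46I"]),
        ("mother", "blue", ["SRSF12_R49C"]),
        ("mother", "green", ["ZNF330_G246A"]),
        ("mother", "yellow", ["CYP4X1_H183P"]),
        ("green", "green.s1", ["green_late_m1", "green_late_m2"]),
    ])


def hg3_config(n_clones: int = 60, dropout_rate: float = 0.0,
               seed: int = 0) -> SimConfig:
    """SimConfig matching :func:`hg3_tree` (lineage order blue, green,
    yellow)."""
    return SimConfig(
        n_lineages=3,
        n_trunk_mut=1,
        muts_per_lineage=1,
        stages_per_lineage=(0, 1, 0),
        muts_per_stage=2,
        n_clones=n_clones,
        lineage_props=HG3_LINEAGE_PROPS,
        dropout_rate=dropout_rate,
        seed=seed,
    )
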