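"""VAF-based subclone quantification and qPCR relative expression.

For a heterozygous diploid mutation private to a subpopulation, the cell
fraction carrying it is twice its variant allele fraction (VAF).  Lineage
proportions of a bulk culture are estimated from the VAFs of each lineage's
defining mutations (inverse-variance-weighted), normalized to sum to one;
the pooled VAF of trunk mutations is reported as a diagnostic (expected 0.5
in a pure diploid culture).  Stage-specific mutations deeper in a lineage
mark only part of it, so they contribute a lower bound on the lineage
fraction, not the point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .clonetree import ReconstructedTree

__all__ = ["LineageFractions", "estimate_lineage_fractions",
           "ddct_fold_change"]


@dataclass(frozen=True)
class LineageFractions:
    """Estimated bulk composition by clonal lineage.

    ``fractions`` are normalized point estimates in [0, 1] (NaN when a
    lineage had no usable mutation); ``ci`` holds 95% Wilson intervals on
    the *unnormalized* cell-fraction scale; ``raw`` the unnormalized
    estimates; ``lower_bounds`` per-lineage lower bounds from stage-specific
    mutations; ``trunk_vaf`` the pooled trunk VAF diagnostic (NaN when no
    trunk mutation has reads).
    """

    fractions: dict[str, float]
    ci: dict[str, tuple[float, float]]
    raw: dict[str, float]
    lower_bounds: dict[str, float]
    normalization: float
    trunk_vaf: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lid in self.fractions:
            lo, hi = self.ci.get(lid, (np.nan, np.nan))
            rows.append({"lineage": lid, "fraction": self.fractions[lid],
                         "raw": self.raw[lid], "ci_low": lo, "ci_high": hi,
                         "stage_lower_bound": self.lower_bounds.get(lid,
                                                                    np.nan)})
        return pd.DataFrame(rows)


def _pooled_fraction(sub: pd.DataFrame) -> tuple[float, float, tuple[float, float]]:
    """Inverse-variance-weighted cell fraction (2 x VAF) over mutations.

    Returns (estimate, weight_sum, wilson 95% CI on the cell-fraction
    scale, pooled over reads)."""
    vafs = sub["alt_count"] / sub["depth"]
    fracs = 2.0 * vafs
    var = 4.0 * vafs * (1.0 - vafs) / sub["depth"]
    var = var.clip(lower=1e-12)
    w = 1.0 / var
    est = float(np.average(fracs, weights=w))
    lo, hi = proportion_confint(int(sub["alt_count"].sum()),
                                int(sub["depth"].sum()), alpha=0.05,
                                method="wilson")
    return est, float(w.sum()), (2.0 * float(lo), 2.0 * float(hi))


def estimate_lineage_fractions(vafs: pd.DataFrame,
                               tree: ReconstructedTree,
                               normalize: bool = True) -> LineageFractions:
    """Estimate lineage proportions of a bulk culture from mutation VAFs.

    ``vafs`` needs columns mutation_id, alt_count, depth (ref_count is
    accepted and ignored).  Mutations are mapped to tree edges; each
    lineage's point estimate pools its lineage-defining-edge mutations by
    inverse-variance weighting; stage-specific mutations yield per-lineage
    lower bounds.  When ``normalize`` (default) the determined estimates are
    rescaled to sum to 1 over determined lineages; lineages with no usable
    mutation stay NaN ("undetermined").
    """
    t = tree.tree
    df = vafs[vafs["depth"] > 0].copy()
    df = df[df["mutation_id"].isin(t.mutations)]

    def lineage_of(m: str) -> str | None:
        return t.lineage_of_node(t.edge_of_mutation[m])

    df["lineage"] = df["mutation_id"].map(lineage_of)
    df["edge"] = df["mutation_id"].map(t.edge_of_mutation)

    trunk = df[df["edge"] == t.mother]
    trunk_vaf = (float(trunk["alt_count"].sum() / trunk["depth"].sum())
                 if len(trunk) else float("nan"))

    raw: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    lower: dict[str, float] = {}
    for lid in t.lineage_roots:
        defining = df[(df["lineage"] == lid) & (df["edge"] == lid)]
        deeper = df[(df["lineage"] == lid) & (df["edge"] != lid)]
        if len(defining):
            est, _, interval = _pooled_fraction(defining)
            raw[lid] = est
            ci[lid] = interval
        elif len(deeper):
            # only stage-level evidence: the lower bound doubles as the
            # (conservative) point estimate
            est, _, interval = _pooled_fraction(deeper)
            raw[lid] = est
            ci[lid] = interval
        else:
            raw[lid] = float("nan")
        if len(deeper):
            lower[lid] = _pooled_fraction(deeper)[0]

    determined = {l: v for l, v in raw.items() if np.isfinite(v)}
    total = sum(determined.values())
    if normalize and determined and total > 0:
        fractions = {l: (determined[l] / total if l in determined
                         else float("nan")) for l in raw}
        norm = total
    else:
        fractions = dict(raw)
        norm = 1.0
    return LineageFractions(fractions=fractions, ci=ci, raw=raw,
                            lower_bounds=lower, normalization=float(norm),
                            trunk_vaf=trunk_vaf)


def ddct_fold_change(ct_target_sample: float, ct_control_sample: float,
                     ct_target_calibrator: float,
                     ct_control_calibrator: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_control)_sample - (Ct_target - Ct_control)_calibrator;
    the fold change is 2**(-ddCt).
    """
    for v in (ct_target_sample, ct_control_sample,
              ct_target_calibrator, ct_control_calibrator):
        if not np.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = ((ct_target_sample - ct_control_sample)
            - (ct_target_calibrator - ct_control_calibrator))
    return float(2.0 ** (-ddct))
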