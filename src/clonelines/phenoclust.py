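"""Phenotype and omics concordance with clonal structure.

Four analyses: (i) bimodality detection in surface-marker log intensities by
1- vs 2-component Gaussian mixture comparison (BIC plus Ashman's D
separation and a component-weight floor); (ii) classification of a
sorted-and-regrown population as a stable subclone vs transient activation,
from the minority-mode fraction at the end of the regrowth window;
(iii) concordance of unsupervised clone clustering (expression or
methylation) with mutational lineage labels via the adjusted Rand index;
(iv) flagging of epigenetically regulated genes by inverse
methylation-expression correlation across clones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "BimodalityResult",
    "StabilityVerdict",
    "ConcordanceReport",
    "detect_bimodality",
    "classify_stability",
    "minority_fraction_trajectory",
    "cluster_concordance",
    "methylation_expression_flag",
    "ashman_d",
]


def ashman_d(mu1: float, mu2: float, sd1: float, sd2: float) -> float:
    """Ashman's D separation of two Gaussian modes:
    sqrt(2)|mu1-mu2| / sqrt(sd1^2 + sd2^2).  D >= 2 marks clear
    bimodality."""
    return math.sqrt(2.0) * abs(mu1 - mu2) / math.sqrt(sd1**2 + sd2**2)


@dataclass(frozen=True)
class BimodalityResult:
    verdict: str                      # "unimodal" | "bimodal"
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    separation: float                 # Ashman's D (0 for 1 component)
    delta_bic: float                  # BIC(1 comp) - BIC(2 comp)

    @property
    def bimodal(self) -> bool:
        return self.verdict == "bimodal"


def detect_bimodality(
    intensities: Sequence[float] | np.ndarray,
    min_weight: float = 0.05,
    min_ashman_d: float = 2.0,
    min_delta_bic: float = 10.0,
    log_transform: bool = False,
    pseudo_offset: float = 1.0,
    seed: int = 0,
) -> BimodalityResult:
    """Call a marker-intensity sample unimodal or bimodal.

    Fits 1- and 2-component Gaussian mixtures (multi-start EM, fixed seed)
    and calls bimodal iff the 2-component BIC improves by at least
    ``min_delta_bic`` AND Ashman's D of the two modes is at least
    ``min_ashman_d`` AND both weights are at least ``min_weight``.

    Pass ``log_transform=True`` for raw (linear) cytometry intensities;
    non-positive values are shifted by ``pseudo_offset`` before the log.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 1 or len(x) < 50:
        raise ValueError("need >= 50 cells for mixture fitting")
    if log_transform:
        shift = pseudo_offset - min(0.0, float(x.min()))
        x = np.log(x + shift)
    if np.ptp(x) == 0 or np.std(x) < 1e-12:
        warnings.warn("degenerate (zero-variance) sample; unimodal",
                      stacklevel=2)
        return BimodalityResult("unimodal", (float(x[0]),), (0.0,), (1.0,),
                                0.0, 0.0)
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, n_init=5, random_state=seed).fit(X)
    delta_bic = float(gm1.bic(X) - gm2.bic(X))
    order = np.argsort(gm2.means_.ravel())
    means = tuple(float(m) for m in gm2.means_.ravel()[order])
    sds = tuple(float(np.sqrt(v)) for v in gm2.covariances_.ravel()[order])
    weights = tuple(float(w) for w in gm2.weights_[order])
    d = ashman_d(means[0], means[1], sds[0], sds[1])
    bimodal = (delta_bic >= min_delta_bic and d >= min_ashman_d
               and min(weights) >= min_weight)
    if not bimodal:
        return BimodalityResult("unimodal",
                                (float(gm1.means_[0, 0]),),
                                (float(np.sqrt(gm1.covariances_[0, 0, 0])),),
                                (1.0,), d, delta_bic)
    return BimodalityResult("bimodal", means, sds, weights, d, delta_bic)


@dataclass(frozen=True)
class StabilityVerdict:
    verdict: str                     # "subclone" | "activation"
    minority_fractions: tuple[float, ...]   # per regrow step, step 0 first
    final_minority_fraction: float
    provisional: bool = False        # trajectory shorter than requested


def minority_fraction_trajectory(regrow: pd.DataFrame,
                                 threshold: float) -> list[float]:
    """Per-step fraction of cells on the other side of ``threshold`` than
    the sorted (majority) mode, from a sort-and-regrow intensity table with
    columns step and log_intensity."""
    out = []
    steps = sorted(regrow["step"].unique())
    side0 = None
    for s in steps:
        x = regrow.loc[regrow["step"] == s, "log_intensity"].to_numpy()
        above = float(np.mean(x > threshold))
        if side0 is None:
            side0 = above >= 0.5  # sorted mode side
        out.append(1.0 - above if side0 else above)
    return out


def classify_stability(
    minority_fractions: Sequence[float],
    regrow_steps: int = 14,
    relapse_threshold: float = 0.15,
) -> StabilityVerdict:
    """Stable subclone vs transient activation after an in-silico sort.

    ``minority_fractions`` is the fraction of cells that have returned to
    the sorted-away mode, per regrowth step (step 0 = freshly sorted, which
    must be >= 95% pure).  Verdict is ``activation`` iff the minority
    fraction at the final step exceeds ``relapse_threshold`` (the population
    "regained" its second mode); ``subclone`` otherwise.  A trajectory
    shorter than ``regrow_steps`` is evaluated on its final available step
    and flagged provisional.
    """
    traj = [float(f) for f in minority_fractions]
    if not traj:
        raise ValueError("empty trajectory")
    if traj[0] > 0.05:
        raise ValueError("sorted population must start >= 95% single-mode")
    provisional = len(traj) - 1 < regrow_steps
    final = traj[-1]
    verdict = "activation" if final > relapse_threshold else "subclone"
    return StabilityVerdict(verdict=verdict,
                            minority_fractions=tuple(traj),
                            final_minority_fraction=final,
                            provisional=provisional)


@dataclass(frozen=True)
class ConcordanceReport:
    clusters: dict[str, int]          # clone -> cluster label
    lineage_labels: dict[str, str]
    ari: float
    gene_specificity: pd.DataFrame    # per-gene lineage-specificity scores
    low_power: bool = False


def _gene_specificity(matrix: pd.DataFrame,
                      labels: pd.Series) -> pd.DataFrame:
    """Per-gene standardized between-lineage mean difference: max pairwise
    |mean difference| / pooled within-lineage sd."""
    groups = {l: matrix.loc[labels[labels == l].index]
              for l in labels.unique()}
    means = pd.DataFrame({l: g.mean() for l, g in groups.items()})
    pooled_sd = np.sqrt(pd.DataFrame(
        {l: g.var(ddof=1) for l, g in groups.items()}).mean(axis=1))
    spread = means.max(axis=1) - means.min(axis=1)
    score = spread / pooled_sd.replace(0.0, np.nan)
    return pd.DataFrame({"specificity": score}).sort_values(
        "specificity", ascending=False)


def cluster_concordance(
    matrix: pd.DataFrame,
    lineage_labels: pd.Series | dict[str, str] | None = None,
    linkage_method: str = "average",
    distance: str = "correlation",
    k: int | None = None,
) -> ConcordanceReport:
    """Agreement of unsupervised clone clustering with lineage labels.

    ``matrix`` is clones x features (expression or methylation).  Clones are
    clustered hierarchically (average linkage, correlation distance by
    default) and the dendrogram cut at the number of distinct lineages (or
    at ``k``; without labels, k is chosen by silhouette over 2..6).  The
    adjusted Rand index against the labels and per-gene lineage-specificity
    scores are reported.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 clones")
    labels = (pd.Series(lineage_labels).reindex(matrix.index)
              if lineage_labels is not None else None)
    if labels is not None and labels.nunique() < 2:
        raise ValueError("need >= 2 lineages represented")
    dist = pdist(matrix.to_numpy(), metric=distance)
    Z = linkage(dist, method=linkage_method)
    if k is None:
        if labels is not None:
            k = int(labels.nunique())
        else:
            from scipy.spatial.distance import squareform
            sq = squareform(dist)
            best = (-np.inf, 2)
            for kk in range(2, min(6, len(matrix) - 1) + 1):
                cand = fcluster(Z, kk, criterion="maxclust")
                if len(set(cand)) < 2:
                    continue
                s = silhouette_score(sq, cand, metric="precomputed")
                if s > best[0]:
                    best = (s, kk)
            k = best[1]
    clusters = fcluster(Z, k, criterion="maxclust")
    cluster_map = dict(zip(matrix.index, (int(c) for c in clusters)))
    if labels is not None:
        ari = float(adjusted_rand_score(labels.to_numpy(), clusters))
        counts = labels.value_counts()
        low_power = bool((counts == 1).all())
        spec = _gene_specificity(matrix, labels)
        label_map = labels.to_dict()
    else:
        ari, low_power, label_map = float("nan"), False, {}
        spec = pd.DataFrame(columns=["specificity"])
    return ConcordanceReport(clusters=cluster_map, lineage_labels=label_map,
                             ari=ari, gene_specificity=spec,
                             low_power=low_power)


def methylation_expression_flag(
    beta: Sequence[float],
    expression: Sequence[float],
    r_threshold: float = -0.7,
    min_dynamic_range: float = 1.0,
) -> dict:
    """Flag a gene as epigenetically regulated from paired per-clone
    methylation betas and expression values.

    Flagged iff Pearson r <= ``r_threshold`` (strong inverse correlation)
    and the expression dynamic range (max - min) exceeds
    ``min_dynamic_range``.  Constant vectors are not evaluable.
    """
    b = np.asarray(beta, dtype=float)
    e = np.asarray(expression, dtype=float)
    if b.shape != e.shape or b.ndim != 1:
        raise ValueError("beta and expression must be equal-length vectors")
    if len(b) < 4:
        raise ValueError("need >= 4 clones with paired values")
    if np.ptp(b) == 0 or np.ptp(e) == 0:
        return {"flag": "not evaluable", "pearson_r": float("nan"),
                "spearman_r": float("nan"),
                "dynamic_range": float(np.ptp(e))}
    pr = float(pearsonr(b, e).statistic)
    sr = float(spearmanr(b, e).statistic)
    flagged = pr <= r_threshold and float(np.ptp(e)) > min_dynamic_range
    return {"flag": "epigenetically regulated" if flagged else "not flagged",
            "pearson_r": pr, "spearman_r": sr,
            "dynamic_range": float(np.ptp(e))}
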