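"""Clones x mutation-sites genotype matrices (ARMS-style evidence).

An ARMS (amplification-refractory mutation system) assay reports, per
single-cell clone and per mutation site, whether the mutant allele was
detected and — via a paired wild-type reaction — whether the wild-type allele
was detected.  Calls are ternary: present / absent / missing (assay dropout).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PRESENT", "ABSENT", "MISSING"]

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1


@dataclass(frozen=True)
class GenotypeMatrix:
    """Ternary clones x mutations call matrix plus wild-type detection flags.

    ``calls`` and ``wt_detected`` are int8 arrays with values 1 (yes),
    0 (no) and -1 (missing), shaped (n_clones, n_mutations).
    """

    clone_ids: tuple[str, ...]
    mutation_ids: tuple[str, ...]
    calls: np.ndarray
    wt_detected: np.ndarray | None = None

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        if calls.shape != (len(self.clone_ids), len(self.mutation_ids)):
            raise ValueError("calls shape does not match clone/mutation ids")
        if not np.isin(calls, [PRESENT, ABSENT, MISSING]).all():
            raise ValueError("calls must be in {1, 0, -1}")
        if self.wt_detected is not None:
            wt = np.asarray(self.wt_detected, dtype=np.int8)
            object.__setattr__(self, "wt_detected", wt)
            if wt.shape != calls.shape:
                raise ValueError("wt_detected shape mismatch")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    def column(self, mutation_id: str) -> np.ndarray:
        return self.calls[:, self.mutation_ids.index(mutation_id)]

    def genotype_of(self, clone_id: str) -> frozenset[str]:
        """Mutations called present in a clone (missing excluded)."""
        row = self.calls[self.clone_ids.index(clone_id)]
        return frozenset(m for m, v in zip(self.mutation_ids, row) if v == PRESENT)

    # -- pandas / TSV interop ---------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls.astype(float),
                          index=list(self.clone_ids),
                          columns=list(self.mutation_ids))
        return df.where(df != MISSING, other=np.nan)

    def to_tsv(self, path: str | Path, wt_path: str | Path | None = None) -> None:
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index_label="clone_id", na_rep="NA",
                  float_format="%.0f")
        if wt_path is not None and self.wt_detected is not None:
            wt = pd.DataFrame(self.wt_detected.astype(float),
                              index=list(self.clone_ids),
                              columns=list(self.mutation_ids))
            wt = wt.where(wt != MISSING, other=np.nan)
            wt.to_csv(wt_path, sep="\t", index_label="clone_id", na_rep="NA",
                      float_format="%.0f")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 wt_path: str | Path | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="clone_id",
                         na_values=["NA"])
        calls = df.fillna(MISSING).to_numpy(dtype=np.int8)
        wt = None
        if wt_path is not None:
            wdf = pd.read_csv(wt_path, sep="\t", index_col="clone_id",
                              na_values=["NA"])
            wt = wdf.reindex(index=df.index, columns=df.columns) \
                    .fillna(MISSING).to_numpy(dtype=np.int8)
        return cls(clone_ids=tuple(str(i) for i in df.index),
                   mutation_ids=tuple(str(c) for c in df.columns),
                   calls=calls, wt_detected=wt)
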