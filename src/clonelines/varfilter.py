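"""Consensus filtering of two variant callers' outputs.

Whole-exome variants called independently by two callers (e.g. GATK and
VarScan) are reduced to the records both agree on, then filtered to the
clone-discriminating set: depth strictly above 20x, alt-read fraction
strictly above 0.25, missense consequence, and strand-bias statistic
strictly below 0.05.  All thresholds are configurable.

The printed "> 0.25% allele frequency" of the source protocol is read here
as an alt-read *fraction* of 0.25 (25%) — consistent with selecting clonal
heterozygous mutations, whose expected fraction in a pure single-cell clone
is ~0.5.  The literal per-cent reading (0.0025) is available via
``FilterConfig(min_alt_fraction=0.0025)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "intersect_callers",
    "apply_filters",
    "read_vcf",
    "write_vcf",
]

log = logging.getLogger(__name__)

#: variant identity used for caller intersection
VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with the annotations the filters consume."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int | None = None
    alt_fraction: float | None = None
    consequence: str | None = None
    strand_bias_p: float | None = None
    caller: str = ""

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.alt_fraction is not None and not 0 <= self.alt_fraction <= 1:
            raise ValueError("alt_fraction must be in [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for clone-discriminating variants (all strict
    inequalities)."""

    min_depth: int = 20
    min_alt_fraction: float = 0.25
    required_consequence: str = "missense"
    max_strand_bias: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 <= self.min_alt_fraction <= 1:
            raise ValueError("min_alt_fraction must be in [0, 1]")
        if not 0 <= self.max_strand_bias <= 1:
            raise ValueError("max_strand_bias must be in [0, 1]")


def _keyed(records: list[VariantRecord], label: str
           ) -> dict[VariantKey, VariantRecord]:
    out: dict[VariantKey, VariantRecord] = {}
    for r in records:
        if r.key in out:
            raise ValueError(f"duplicate variant key {r.key} in set {label}")
        out[r.key] = r
    return out


def intersect_callers(
    set_a: list[VariantRecord], set_b: list[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, list[VariantKey]]]:
    """Variants called by both callers.

    Records are matched on (chrom, pos, ref, alt); numeric fields of the
    consensus come from caller A (caller B's record is discarded after the
    match).  The second return value logs the symmetric difference:
    ``{"only_a": [...], "only_b": [...]}``.
    """
    a = _keyed(set_a, "A")
    b = _keyed(set_b, "B")
    shared = sorted(set(a) & set(b))
    diff = {"only_a": sorted(set(a) - set(b)),
            "only_b": sorted(set(b) - set(a))}
    log.info("caller intersection: %d shared, %d only in A, %d only in B",
             len(shared), len(diff["only_a"]), len(diff["only_b"]))
    return [a[k] for k in shared], diff


_CRITERIA = ("depth", "alt_fraction", "consequence", "strand_bias")


def _passes(r: VariantRecord, crit: str, cfg: FilterConfig) -> bool | None:
    """True/False, or None when the needed annotation is missing."""
    if crit == "depth":
        return None if r.depth is None else r.depth > cfg.min_depth
    if crit == "alt_fraction":
        return (None if r.alt_fraction is None
                else r.alt_fraction > cfg.min_alt_fraction)
    if crit == "consequence":
        return (None if r.consequence is None
                else cfg.required_consequence in r.consequence)
    if crit == "strand_bias":
        return (None if r.strand_bias_p is None
                else r.strand_bias_p < cfg.max_strand_bias)
    raise ValueError(crit)


def apply_filters(
    records: list[VariantRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply the four clone-discrimination filters.

    Keeps records with depth > min_depth AND alt_fraction > min_alt_fraction
    AND consequence containing the required term AND strand bias <
    max_strand_bias.  Records missing any needed annotation are dropped and
    counted as ``unannotated`` (with a warning).

    Returns (kept records, attrition counts): ``fail_<criterion>`` counts
    failures of each criterion independently over annotated records;
    ``cum_after_<criterion>`` counts survivors after applying the criteria
    cumulatively in the stated order; plus ``input``, ``unannotated`` and
    ``kept``.
    """
    attrition: dict[str, int] = {"input": len(records), "unannotated": 0}
    annotated: list[VariantRecord] = []
    for r in records:
        verdicts = {c: _passes(r, c, config) for c in _CRITERIA}
        if any(v is None for v in verdicts.values()):
            attrition["unannotated"] += 1
            warnings.warn(f"variant {r.key} missing annotation; dropped",
                          stacklevel=2)
            continue
        annotated.append(r)
    for crit in _CRITERIA:
        attrition[f"fail_{crit}"] = sum(
            1 for r in annotated if not _passes(r, crit, config))
    surviving = annotated
    for crit in _CRITERIA:
        surviving = [r for r in surviving if _passes(r, crit, config)]
        attrition[f"cum_after_{crit}"] = len(surviving)
    attrition["kept"] = len(surviving)
    return surviving, attrition


# ---------------------------------------------------------------------------
# VCF interop


def read_vcf(
    path: str | Path,
    caller: str = "",
    depth_field: str = "DP",
    consequence_field: str = "CSQ",
    strand_bias_field: str = "SBP",
    alt_fraction_field: str = "AF",
) -> list[VariantRecord]:
    """Read variant records from a VCF 4.x file (one record per ALT allele).

    Depth comes from FORMAT/INFO ``depth_field``; alt fraction from
    ``alt_fraction_field`` or, failing that, from FORMAT AD of the first
    sample; consequence from ``consequence_field`` (first annotation);
    strand-bias p from ``strand_bias_field``.  Absent fields yield None and
    are handled by :func:`apply_filters` as unannotated.
    """
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        depth = v.INFO.get(depth_field)
        if depth is None and v.format(depth_field) is not None:
            depth = int(v.format(depth_field)[0][0])
        af = v.INFO.get(alt_fraction_field)
        if af is None and v.format("AD") is not None:
            ad = v.format("AD")[0]
            tot = float(sum(ad))
            af = float(ad[1]) / tot if tot > 0 and len(ad) > 1 else None
        csq = v.INFO.get(consequence_field)
        if isinstance(csq, str):
            csq = csq.split(",")[0]
        sbp = v.INFO.get(strand_bias_field)
        for alt in v.ALT:
            out.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                depth=int(depth) if depth is not None else None,
                alt_fraction=float(af) if af is not None else None,
                consequence=csq,
                strand_bias_p=float(sbp) if sbp is not None else None,
                caller=caller))
    vcf.close()
    return out


def write_vcf(records: list[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal VCF 4.2 file with DP/AF/CSQ/SBP INFO
    fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt read fraction">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence">',
        '##INFO=<ID=SBP,Number=1,Type=Float,Description="Strand bias p">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in sorted(records, key=lambda r: r.key):
        info = []
        if r.depth is not None:
            info.append(f"DP={r.depth}")
        if r.alt_fraction is not None:
            info.append(f"AF={r.alt_fraction:.6g}")
        if r.consequence is not None:
            info.append(f"CSQ={r.consequence}")
        if r.strand_bias_p is not None:
            info.append(f"SBP={r.strand_bias_p:.6g}")
        lines.append("\t".join([r.chrom, str(r.pos), ".", r.ref, r.alt,
                                ".", "PASS", ";".join(info) or "."]))
    Path(path).write_text("\n".join(lines) + "\n")
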