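"""IGHV somatic-hypermutation analysis of cloned IG PCR products.

Rearranged immunoglobulin heavy-chain PCR products are cloned into bacteria
and individually Sanger-sequenced; each bacterial colony samples one IG
molecule from the culture.  Comparing each colony to the germline reference
yields its somatic substitutions and a mutation level (% divergence).  A
culture is hypermutated when its mutation level exceeds 2%.  Substitutions
shared by a subset of colonies — but not all, and not just one (putative PCR
error) — are subclone-specific: when strictly more than ``min_support``
colonies per ``n_reference`` sequenced carry such a signature, the culture is
called multiclonal.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IGColonySet",
    "MutationProfile",
    "SubcloneCall",
    "Substitution",
    "align_to_germline",
    "build_profiles",
    "mutation_level",
    "partition_shared_specific",
    "call_subclones",
    "HYPERMUTATION_THRESHOLD",
]

# mutation level strictly above this percent counts as IG hypermutated
HYPERMUTATION_THRESHOLD = 2.0

#: (0-based germline position, germline base, observed base)
Substitution = tuple[int, str, str]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class IGColonySet:
    """Germline reference plus cloned-colony sequences for one cell line."""

    germline: str
    colonies: tuple[tuple[str, str], ...]  # (colony_id, sequence)

    def __post_init__(self) -> None:
        if not self.colonies:
            raise ValueError("at least one colony is required")
        for cid, seq in (("germline", self.germline), *self.colonies):
            if not seq:
                raise ValueError(f"empty sequence for {cid!r}")
            if set(seq.upper()) - _VALID:
                raise ValueError(f"non-ACGTN characters in {cid!r}")

    def to_fasta(self, colonies_path: str | Path,
                 germline_path: str | Path) -> None:
        SeqIO.write([SeqRecord(Seq(self.germline), id="germline",
                               description="")],
                    str(germline_path), "fasta")
        SeqIO.write([SeqRecord(Seq(seq), id=cid, description="")
                     for cid, seq in self.colonies],
                    str(colonies_path), "fasta")

    @classmethod
    def from_fasta(cls, colonies_path: str | Path,
                   germline_path: str | Path,
                   germline_id: str | None = None) -> "IGColonySet":
        germ_records = list(SeqIO.parse(str(germline_path), "fasta"))
        if germline_id is not None:
            germ_records = [r for r in germ_records if r.id == germline_id]
        if len(germ_records) != 1:
            raise ValueError("germline FASTA must contain exactly one record "
                             "(or use germline_id to select one)")
        colonies = tuple((r.id, str(r.seq).upper())
                         for r in SeqIO.parse(str(colonies_path), "fasta"))
        return cls(germline=str(germ_records[0].seq).upper(),
                   colonies=colonies)


@dataclass(frozen=True)
class MutationProfile:
    """Somatic substitutions of one colony relative to germline.

    ``aligned_length`` counts alignment columns where both sequences have a
    non-N base (gap and N columns are excluded from numerator and
    denominator of the mutation level).
    """

    colony_id: str
    substitutions: frozenset[Substitution]
    aligned_length: int

    @property
    def mutation_level(self) -> float:
        """Percent divergence from germline over evaluable columns."""
        if self.aligned_length == 0:
            return 0.0
        return 100.0 * len(self.substitutions) / self.aligned_length


@dataclass(frozen=True)
class SubcloneCall:
    """Multiclonality verdict from shared subclone-specific substitutions."""

    n_colonies: int
    groups: tuple[tuple[str, ...], ...]   # partition of colony ids
    n_clones_called: int
    hypermutated: bool
    set_mutation_level: float

    def __post_init__(self) -> None:
        members = [c for g in self.groups for c in g]
        if len(members) != len(set(members)) or len(members) != self.n_colonies:
            raise ValueError("groups must partition all colonies")


def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1.0
    aln.mismatch_score = -1.0
    aln.open_gap_score = -4.0
    aln.extend_gap_score = -0.5
    # free end gaps: colonies may be truncated amplicons
    try:
        aln.end_insertion_score = 0.0
        aln.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aln.target_end_gap_score = 0.0
        aln.query_end_gap_score = 0.0
    return aln


def align_to_germline(colony_seq: str, germline: str,
                      primer_margin: int = 0) -> tuple[frozenset[Substitution], int] | None:
    """Globally align a colony to germline and extract substitutions.

    Returns (substitutions in germline coordinates, evaluable length), or
    ``None`` when fewer than 50% of germline positions align (unalignable
    colony, e.g. a contaminating insert).

    ``primer_margin`` germline positions at each end are excluded from both
    the substitution set and the evaluable length (primer-encoded sequence).
    """
    colony_seq, germline = colony_seq.upper(), germline.upper()
    if not colony_seq or not germline:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(germline, colony_seq)[0]
    subs: set[Substitution] = set()
    length = 0
    covered = 0
    lo, hi = primer_margin, len(germline) - primer_margin
    for (g0, g1), (c0, c1) in zip(*aln.aligned):
        covered += g1 - g0
        for off in range(g1 - g0):
            gpos = g0 + off
            gb, cb = germline[gpos], colony_seq[c0 + off]
            if gb == "N" or cb == "N" or not (lo <= gpos < hi):
                continue
            length += 1
            if gb != cb:
                subs.add((gpos, gb, cb))
    if covered < 0.5 * len(germline):
        return None
    return frozenset(subs), length


def build_profiles(colony_set: IGColonySet,
                   primer_margin: int = 0) -> list[MutationProfile]:
    """Profile every alignable colony; unalignable colonies are dropped
    with a warning."""
    profiles: list[MutationProfile] = []
    for cid, seq in colony_set.colonies:
        res = align_to_germline(seq, colony_set.germline, primer_margin)
        if res is None:
            warnings.warn(f"colony {cid!r} unalignable (<50% germline "
                          "coverage); excluded", stacklevel=2)
            continue
        subs, length = res
        profiles.append(MutationProfile(colony_id=cid, substitutions=subs,
                                        aligned_length=length))
    return profiles


def mutation_level(profiles: list[MutationProfile]
                   ) -> tuple[dict[str, float], float, bool]:
    """Per-colony levels, set-level summary (median) and hypermutation flag.

    The set is hypermutated iff the median level is strictly above 2.0%.
    """
    if not profiles:
        raise ValueError("no evaluable colonies")
    per_colony = {p.colony_id: p.mutation_level for p in profiles}
    set_level = float(statistics.median(per_colony.values()))
    return per_colony, set_level, set_level > HYPERMUTATION_THRESHOLD


def partition_shared_specific(profiles: list[MutationProfile]
                              ) -> dict[Substitution, str]:
    """Classify each substitution as universal (all colonies),
    shared-subset (>=2 but not all) or singleton (one colony; putative PCR
    error)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 colonies to partition")
    counts: dict[Substitution, int] = {}
    for p in profiles:
        for s in p.substitutions:
            counts[s] = counts.get(s, 0) + 1
    n = len(profiles)
    out: dict[Substitution, str] = {}
    for s, c in counts.items():
        out[s] = ("universal" if c == n
                  else "singleton" if c == 1
                  else "shared-subset")
    return out


def call_subclones(profiles: list[MutationProfile],
                   min_support: int = 3,
                   n_reference: int = 10) -> SubcloneCall:
    """Call the number of IG-defined subclones in a culture.

    Colonies are grouped by their signature: the set of shared-subset
    substitutions they carry (singletons ignored as PCR noise).  A signature
    that is a strict subset of exactly one other signature is merged into it
    (earlier-stage molecules of the same lineage).  A group supports a
    subclone when its size is strictly greater than
    ``min_support * n_colonies / n_reference`` — i.e. more than 3 colonies
    when 10 are sequenced, scaled proportionally otherwise.  Colonies with an
    empty signature form the baseline group.  The call is at least 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 colonies to call subclones")
    classes = partition_shared_specific(profiles)
    shared = {s for s, c in classes.items() if c == "shared-subset"}

    sig_of = {p.colony_id: frozenset(p.substitutions & shared)
              for p in profiles}
    sigs = sorted({s for s in sig_of.values() if s},
                  key=lambda s: (len(s), sorted(s)))
    # merge a nested signature into its unique strict superset
    merged_into: dict[frozenset, frozenset] = {}
    for sig in sigs:
        supers = [t for t in sigs if sig < t]
        if len(supers) == 1:
            merged_into[sig] = supers[0]
    def resolve(sig: frozenset) -> frozenset:
        while sig in merged_into:
            sig = merged_into[sig]
        return sig

    groups: dict[frozenset, list[str]] = {}
    for p in profiles:
        key = resolve(sig_of[p.colony_id])
        groups.setdefault(key, []).append(p.colony_id)

    n = len(profiles)
    threshold = min_support * n / n_reference
    supported = sum(1 for members in groups.values() if len(members) > threshold)
    _, set_level, hyper = mutation_level(profiles)
    ordered = tuple(tuple(sorted(members))
                    for _, members in sorted(groups.items(),
                                             key=lambda kv: sorted(kv[1])))
    return SubcloneCall(n_colonies=n, groups=ordered,
                        n_clones_called=max(1, supported),
                        hypermutated=hyper, set_mutation_level=set_level)
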