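"""Core domain types: structural-variant records, callsets, and summaries.

Coordinates are 1-based inclusive throughout (VCF convention). A record's
``end`` equals its ``pos`` for insertions; for span types (DEL, INV, DUP)
``end >= pos``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple


class SVType(str, enum.Enum):
    """Structural-variant class. Only DEL, INS, INV and DUP are analysed
    downstream; anything else (BND, TRA, CNV, ...) is carried as OTHER and
    removed by the record filter."""

    DEL = "DEL"
    INS = "INS"
    INV = "INV"
    DUP = "DUP"
    OTHER = "OTHER"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"
    OTHER = "other"


#: Genotype strings as they appear in VCF sample columns.
_GT_FROM_VCF = {
    (0, 0): Genotype.HOM_REF,
    (None, None): Genotype.MISSING,
    (None,): Genotype.MISSING,
}


def genotype_from_alleles(alleles: Tuple[Optional[int], ...]) -> Genotype:
    """Map a tuple of allele indices (pysam style) onto the genotype enum."""
    if alleles is None or len(alleles) == 0:
        return Genotype.MISSING
    if all(a is None for a in alleles):
        return Genotype.MISSING
    if any(a is None for a in alleles):
        return Genotype.OTHER
    if all(a == 0 for a in alleles):
        return Genotype.HOM_REF
    nonref = {a for a in alleles if a != 0}
    if len(nonref) > 1:
        return Genotype.OTHER
    if 0 in alleles:
        return Genotype.HET
    return Genotype.HOM_ALT


_GT_TO_VCF = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
    Genotype.OTHER: "1/2",
}


@dataclass(frozen=True)
class SVRecord:
    """One normalised SV call.

    ``svlen`` is stored as given by the caller (negative for deletions is
    common); ``abs_len`` is the derived non-negative length used by every
    size rule. ``support`` is the caller's read support; ``None`` means the
    caller did not report it.
    """

    sample_id: str
    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: Optional[int] = None
    qual: float = 0.0
    support: Optional[int] = None
    precise: bool = True
    gt: Genotype = Genotype.HET
    strands: Optional[str] = None  # e.g. "+-"; None = unknown
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.svtype is SVType.INS:
            if self.end != self.pos:
                object.__setattr__(self, "end", self.pos)
        elif self.svtype is not SVType.OTHER and self.end < self.pos:
            raise ValueError(
                f"end ({self.end}) < pos ({self.pos}) for {self.svtype.value}"
            )

    @property
    def abs_len(self) -> int:
        if self.svlen is not None:
            return abs(self.svlen)
        if self.svtype in (SVType.DEL, SVType.INV, SVType.DUP):
            return self.end - self.pos + 1
        return 0

    @property
    def span(self) -> int:
        """Reference footprint in bp (1 for insertions)."""
        return self.end - self.pos + 1

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.end, self.svtype.value, self.sample_id)

    def with_sample(self, sample_id: str) -> "SVRecord":
        return replace(self, sample_id=sample_id)

    def gt_string(self) -> str:
        return _GT_TO_VCF[self.gt]


@dataclass
class SVCallset:
    """An ordered collection of SV records belonging to one sample."""

    sample_id: str
    records: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=SVRecord.sort_key)
        for r in self.records:
            if r.sample_id != self.sample_id:
                raise ValueError(
                    f"record sample_id {r.sample_id!r} != callset {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def relabelled(self, sample_id: str) -> "SVCallset":
        recs = [r.with_sample(sample_id) for r in self.records]
        return SVCallset(sample_id, recs, provenance=self.provenance)


@dataclass
class CallsetSummary:
    """Per-type counts and total lengths for one callset (Table-1 style)."""

    sample_id: str
    counts: dict
    total: int
    lengths: dict
    total_length: int

    def as_row(self) -> dict:
        row = {"sample_id": self.sample_id}
        for t in (SVType.DEL, SVType.INS, SVType.INV, SVType.DUP):
            row[t.value] = self.counts.get(t, 0)
        row["OTHER"] = self.counts.get(SVType.OTHER, 0)
        row["total"] = self.total
        for t in (SVType.DEL, SVType.INS, SVType.INV, SVType.DUP):
            row[f"{t.value}_bp"] = self.lengths.get(t, 0)
        row["total_bp"] = self.total_length
        return row


def summarize_callset(callset: SVCallset) -> CallsetSummary:
    """Tally records and cumulative lengths per SV type.

    The grand total always equals the record count, so published per-type
    counts can be checked against their printed row totals.
    """
    counts: dict = {}
    lengths: dict = {}
    for rec in callset:
        counts[rec.svtype] = counts.get(rec.svtype, 0) + 1
        lengths[rec.svtype] = lengths.get(rec.svtype, 0) + rec.abs_len
    return CallsetSummary(
        sample_id=callset.sample_id,
        counts=counts,
        total=sum(counts.values()),
        lengths=lengths,
        total_length=sum(lengths.values()),
    )


def summarize_counts(counts: dict) -> int:
    """Total over a per-type count mapping (e.g. a published table row)."""
    return int(sum(counts.values()))


def aggregate_callsets(callsets: Sequence[SVCallset], sample_id: str) -> SVCallset:
    """Concatenate callsets into one composite set under a new sample id.

    No deduplication is performed: the composite maternal set is only ever
    used as a subtraction reference, where duplicates are harmless, and
    plain concatenation keeps per-caller count arithmetic intact.
    """
    records = []
    prov = []
    for cs in callsets:
        records.extend(r.with_sample(sample_id) for r in cs.records)
        prov.append(cs.provenance or cs.sample_id)
    return SVCallset(sample_id, records, provenance="aggregate(" + "+".join(prov) + ")")
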