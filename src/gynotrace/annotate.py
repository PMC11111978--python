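"""Gene-region annotation of SVs.

Each record is classified against a gene model into one of the standard
gene-centric categories (exonic, splicing, UTR5, UTR3, intronic, the
ncRNA_* counterparts for non-coding transcripts, upstream, downstream,
upstream_downstream, intergenic), using the conventional severity
precedence: any gene-body hit beats a flank hit, coding consequences beat
non-coding, and the most severe category across all overlapping
transcripts wins. Exonic insertions/deletions are typed frameshift or
non-frameshift by whether the net coding-length change is divisible by 3.

The model loads from GFF3 via :mod:`gffutils`; coordinates are 1-based
inclusive throughout (GFF3 and VCF agree on this).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from .models import SVRecord, SVType


class Biotype(str, enum.Enum):
    PROTEIN_CODING = "protein_coding"
    LNCRNA = "lncRNA"
    OTHER_NCRNA = "other_ncRNA"
    PSEUDOGENE = "pseudogene"
    OTHER = "other"


_BIOTYPE_ALIASES = {
    "protein_coding": Biotype.PROTEIN_CODING,
    "lncrna": Biotype.LNCRNA,
    "lnc_rna": Biotype.LNCRNA,
    "lincrna": Biotype.LNCRNA,
    "pseudogene": Biotype.PSEUDOGENE,
    "processed_pseudogene": Biotype.PSEUDOGENE,
    "mirna": Biotype.OTHER_NCRNA,
    "snorna": Biotype.OTHER_NCRNA,
    "snrna": Biotype.OTHER_NCRNA,
    "rrna": Biotype.OTHER_NCRNA,
    "trna": Biotype.OTHER_NCRNA,
    "ncrna": Biotype.OTHER_NCRNA,
}


class Category(str, enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "intronic"
    NCRNA_EXONIC = "ncRNA_exonic"
    NCRNA_SPLICING = "ncRNA_splicing"
    NCRNA_INTRONIC = "ncRNA_intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UPSTREAM_DOWNSTREAM = "upstream_downstream"
    INTERGENIC = "intergenic"


#: Severity order; lower rank = more severe, wins across transcripts.
_SEVERITY = {
    Category.EXONIC: 0,
    Category.SPLICING: 1,
    Category.UTR5: 2,
    Category.UTR3: 3,
    Category.INTRONIC: 4,
    Category.NCRNA_EXONIC: 5,
    Category.NCRNA_SPLICING: 6,
    Category.NCRNA_INTRONIC: 7,
}

GENE_ASSOCIATED = frozenset(Category) - {Category.INTERGENIC}


class Consequence(str, enum.Enum):
    FRAMESHIFT = "frameshift_substitution"
    NONFRAMESHIFT = "nonframeshift_substitution"
    OTHER = "other"


Interval = Tuple[int, int]  # 1-based inclusive


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)

    @property
    def coding(self) -> bool:
        return bool(self.cds)


@dataclass
class Gene:
    gene_id: str
    symbol: str
    biotype: Biotype
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: List[Transcript] = field(default_factory=list)


@dataclass
class GeneModel:
    """Genes plus an interval index for overlap queries."""

    genes: Dict[str, Gene] = field(default_factory=dict)
    _tree: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._tree = {}
        for gene in self.genes.values():
            self._tree.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end + 1, gene.gene_id
            )

    def overlapping(self, chrom: str, start: int, end: int) -> List[Gene]:
        tree = self._tree.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start, end + 1)
        return sorted((self.genes[h.data] for h in hits), key=lambda g: g.gene_id)


@dataclass(frozen=True)
class AnnotateParams:
    flank: int = 2000  # bp beyond which a variant counts as intergenic
    splice_window: int = 2

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class RegionCall:
    record: SVRecord
    category: Category
    genes_hit: List[str]
    consequence: Optional[Consequence] = None


def _parse_biotype(raw: Optional[str]) -> Biotype:
    if not raw:
        return Biotype.OTHER
    return _BIOTYPE_ALIASES.get(raw.lower(), Biotype.OTHER)


_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "lnc_RNA", "ncRNA", "miRNA", "snoRNA",
    "snRNA", "rRNA", "tRNA", "pseudogenic_transcript",
}


def load_gene_model(gff3_path: Union[str, Path]) -> GeneModel:
    """Parse a GFF3 gene model (genes, transcripts, exons, CDS, UTRs)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: Dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        biotype_raw = (
            g.attributes.get("biotype", [None])[0]
            or g.attributes.get("gene_biotype", [None])[0]
        )
        gene = Gene(
            gene_id=g.id,
            symbol=g.attributes.get("Name", [g.id])[0],
            biotype=_parse_biotype(biotype_raw),
            chrom=g.seqid,
            strand=g.strand,
            start=g.start,
            end=g.end,
        )
        for t in db.children(g, level=1):
            if t.featuretype not in _TRANSCRIPT_TYPES:
                continue
            tx = Transcript(
                transcript_id=t.id,
                gene_id=g.id,
                chrom=t.seqid,
                strand=t.strand,
                start=t.start,
                end=t.end,
            )
            for child in db.children(t, level=1):
                iv = (child.start, child.end)
                if child.featuretype == "exon":
                    tx.exons.append(iv)
                elif child.featuretype == "CDS":
                    tx.cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    tx.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    tx.utr3.append(iv)
            tx.__post_init__()
            gene.transcripts.append(tx)
        genes[g.id] = gene
    return GeneModel(genes)


def _overlaps_any(start: int, end: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= end and start <= e for s, e in intervals)


def _classify_transcript(
    start: int, end: int, tx: Transcript, splice_window: int
) -> Optional[Category]:
    """Category of [start, end] within one transcript, or None if outside."""
    if end < tx.start or start > tx.end:
        return None
    in_exon = _overlaps_any(start, end, tx.exons)
    if tx.coding:
        if _overlaps_any(start, end, tx.cds):
            return Category.EXONIC
        if not in_exon and _near_splice(start, end, tx, splice_window):
            return Category.SPLICING
        if _overlaps_any(start, end, tx.utr5):
            return Category.UTR5
        if _overlaps_any(start, end, tx.utr3):
            return Category.UTR3
        if in_exon:  # exon portion without CDS/UTR annotation
            return Category.EXONIC
        return Category.INTRONIC
    if in_exon:
        return Category.NCRNA_EXONIC
    if _near_splice(start, end, tx, splice_window):
        return Category.NCRNA_SPLICING
    return Category.NCRNA_INTRONIC


def _near_splice(start: int, end: int, tx: Transcript, window: int) -> bool:
    if window <= 0 or len(tx.exons) < 2:
        return False
    for i, (ex_s, ex_e) in enumerate(tx.exons):
        if i > 0:  # acceptor side of the upstream intron
            if start <= ex_s - 1 and end >= ex_s - window:
                return True
        if i < len(tx.exons) - 1:  # donor side
            if start <= ex_e + window and end >= ex_e + 1:
                return True
    return False


def classify_region(
    record: SVRecord,
    model: GeneModel,
    params: AnnotateParams = AnnotateParams(),
) -> RegionCall:
    """Assign one region category (and exonic consequence) to a record."""
    start = record.pos
    end = record.pos if record.svtype is SVType.INS else record.end
    body_hits: List[Tuple[Category, str]] = []
    for gene in model.overlapping(record.chrom, start, end):
        for tx in gene.transcripts:
            cat = _classify_transcript(start, end, tx, params.splice_window)
            if cat is not None:
                body_hits.append((cat, gene.gene_id))
        if not gene.transcripts:
            # bare gene span: treat by biotype
            cat = (
                Category.INTRONIC
                if gene.biotype is Biotype.PROTEIN_CODING
                else Category.NCRNA_INTRONIC
            )
            body_hits.append((cat, gene.gene_id))
    if body_hits:
        best = min(_SEVERITY[c] for c, _ in body_hits)
        category = next(c for c, _ in body_hits if _SEVERITY[c] == best)
        genes = sorted({g for c, g in body_hits if _SEVERITY[c] == best})
        consequence = (
            exonic_consequence(record) if category is Category.EXONIC else None
        )
        return RegionCall(record, category, genes, consequence)
    # flank search: within `flank` bp of a gene on its 5' or 3' side
    up_genes: List[str] = []
    down_genes: List[str] = []
    for gene in model.overlapping(
        record.chrom, max(1, start - params.flank), end + params.flank
    ):
        if end < gene.start:
            side_5prime = gene.strand != "-"
        elif start > gene.end:
            side_5prime = gene.strand == "-"
        else:  # pragma: no cover - body hits handled above
            continue
        (up_genes if side_5prime else down_genes).append(gene.gene_id)
    if up_genes and down_genes:
        return RegionCall(
            record, Category.UPSTREAM_DOWNSTREAM, sorted(set(up_genes + down_genes))
        )
    if up_genes:
        return RegionCall(record, Category.UPSTREAM, sorted(set(up_genes)))
    if down_genes:
        return RegionCall(record, Category.DOWNSTREAM, sorted(set(down_genes)))
    return RegionCall(record, Category.INTERGENIC, [])


def exonic_consequence(record: SVRecord) -> Consequence:
    """Frameshift typing by net coding-length change (sequence-free)."""
    if record.svtype not in (SVType.INS, SVType.DEL):
        warnings.warn(
            f"exonic {record.svtype.value} at {record.chrom}:{record.pos} "
            "not typed (only INS/DEL are)"
        )
        return Consequence.OTHER
    return (
        Consequence.FRAMESHIFT
        if record.abs_len % 3 != 0
        else Consequence.NONFRAMESHIFT
    )


@dataclass
class AnnotationTallies:
    per_category: Dict[Category, int]
    total: int
    n_intergenic: int
    n_gene_associated: int
    intergenic_fraction: float
    gene_associated_fraction: float
    genes_per_biotype: Dict[Biotype, int]


def tally_annotations(
    calls: Sequence[RegionCall], model: GeneModel
) -> AnnotationTallies:
    """Per-category counts, intergenic/gene-associated split, biotype tally.

    The biotype tally counts distinct genes hit by at least one
    non-intergenic call, grouped by gene biotype.
    """
    per_cat: Dict[Category, int] = {c: 0 for c in Category}
    genes_hit = set()
    for call in calls:
        per_cat[call.category] += 1
        if call.category is not Category.INTERGENIC:
            genes_hit.update(call.genes_hit)
    total = len(calls)
    n_inter = per_cat[Category.INTERGENIC]
    n_assoc = total - n_inter
    biotype: Dict[Biotype, int] = {}
    for gid in genes_hit:
        bt = model.genes[gid].biotype if gid in model.genes else Biotype.OTHER
        biotype[bt] = biotype.get(bt, 0) + 1
    return AnnotationTallies(
        per_category=per_cat,
        total=total,
        n_intergenic=n_inter,
        n_gene_associated=n_assoc,
        intergenic_fraction=(n_inter / total) if total else 0.0,
        gene_associated_fraction=(n_assoc / total) if total else 0.0,
        genes_per_biotype=biotype,
    )


def write_annotation_tsv(calls: Sequence[RegionCall], model: GeneModel, path) -> None:
    import pandas as pd

    rows = []
    for call in calls:
        r = call.record
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "end": r.end,
                "svtype": r.svtype.value,
                "abs_len": r.abs_len,
                "category": call.category.value,
                "genes_hit": ",".join(call.genes_hit),
                "biotypes": ",".join(
                    sorted(
                        {
                            model.genes[g].biotype.value
                            for g in call.genes_hit
                            if g in model.genes
                        }
                    )
                ),
                "consequence": call.consequence.value if call.consequence else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
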