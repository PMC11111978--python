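"""Synthetic gynogenetic-cohort generator.

Emulates, at callset level, a study design with one maternal sample (PF),
a same-species ("homologous") male PM, a strongly diverged
("heterologous") male CM, and nine gynogenetic offspring per male (PP1-9
stimulated by PM sperm, PC1-9 by CM sperm):

* the maternal callset is a set of SV loci drawn over a small genome;
* each male carries the maternal loci plus a private male-specific set,
  the heterologous male's private set scaled up by a divergence
  multiplier;
* each offspring inherits the maternal loci (with per-record breakpoint
  jitter and dropout), receives each of its male's private loci
  independently with probability ``leakage_rate`` (paternal leakage — the
  parameter the MSSV pipeline is built to recover), and adds Poisson
  numbers of private de-novo SVs and false-positive calls;
* maternal coverage is a constant-depth track (9x by default) with
  optional zero-depth holes.

Every emitted record is logged in a sidecar truth table mapping it to its
origin, so detection results can be scored against ground truth. The
truth never enters the VCFs: the pipeline runs blind.

Distinct SV loci are placed with a minimum start-to-start spacing (2100 bp
by default, comfortably beyond the 1000 bp match window), so records of
different origin can never be chained into one merge cluster; copies of
the same locus across samples still cluster. This is what makes exact
zero-noise parameter recovery well-defined.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import Biotype, Gene, GeneModel, Transcript
from .coverage import CoverageTrack, constant_track, write_coverage_bed
from .io import write_sv_vcf
from .models import Genotype, SVCallset, SVRecord, SVType

DEFAULT_GENOME = {"A1": 5_000_000, "A2": 5_000_000, "B1": 5_000_000, "B2": 5_000_000}

#: Length models per SV type: (mean of log-length, sd of log-length).
DEFAULT_LENGTH_MODEL = {
    SVType.DEL: (5.7, 1.0),
    SVType.INS: (5.7, 1.0),
    SVType.INV: (6.9, 0.8),
    SVType.DUP: (6.9, 0.8),
}


class Origin(str, enum.Enum):
    MATERNAL = "maternal"
    MALE_SPECIFIC = "male_specific"
    PATERNAL_TRANSMITTED = "paternal_transmitted"
    DENOVO = "denovo"
    FALSE_POSITIVE = "false_positive"


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults define the standard ("paper-like") study conditions: DEL/INS
    dominated callsets, nine offspring per male, ~9x maternal depth, a
    50-fold larger private SV set for the heterologous male, and leakage
    rates putting the homologous MSSV/DSV fraction near 0.2 and the
    heterologous one near 0.05. ``leakage_rate_het=None`` means the
    homologous rate applies to both cohorts.
    """

    seed: int = 0
    genome: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_maternal_sv: int = 1000
    type_mix: Dict[SVType, float] = field(
        default_factory=lambda: {
            SVType.DEL: 0.48,
            SVType.INS: 0.48,
            SVType.INV: 0.02,
            SVType.DUP: 0.02,
        }
    )
    length_model: Dict[SVType, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MODEL)
    )
    min_sv_len: int = 50
    max_sv_len: int = 8000
    n_male_specific: int = 100
    heterologous_multiplier: float = 50.0
    n_offspring: int = 9
    leakage_rate: float = 0.2
    leakage_rate_het: Optional[float] = 0.001
    denovo_rate: float = 80.0
    jitter_sd: float = 20.0
    dropout_rate: float = 0.02
    fp_rate: float = 5.0
    depth_mean: float = 9.0
    n_coverage_holes: int = 0
    coverage_hole_len: int = 5000
    qual_offset: float = 20.0
    qual_scale: float = 15.0
    support_offset: int = 4
    min_locus_spacing: int = 2100
    genes_per_mb: float = 40.0

    def __post_init__(self) -> None:
        for name in ("leakage_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.leakage_rate_het is not None and not 0 <= self.leakage_rate_het <= 1:
            raise ValueError("leakage_rate_het must be in [0, 1]")
        if self.jitter_sd < 0 or self.fp_rate < 0 or self.denovo_rate < 0:
            raise ValueError("rates must be non-negative")
        if min(self.n_maternal_sv, self.n_male_specific, self.n_offspring) < 0:
            raise ValueError("counts must be >= 0")

    def zero_noise(self, **overrides) -> "SimConfig":
        """Copy of this config with all caller-noise channels switched off."""
        base = asdict(self)
        base.update(jitter_sd=0.0, dropout_rate=0.0, fp_rate=0.0)
        base.update(overrides)
        return SimConfig(**base)


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    pos: int
    svtype: SVType
    length: int

    @property
    def end(self) -> int:
        if self.svtype is SVType.INS:
            return self.pos
        return self.pos + self.length - 1


@dataclass(frozen=True)
class TruthRow:
    sample_id: str
    record_id: str
    origin: Origin
    source: str  # locus id, or "" for false positives


@dataclass
class CohortTruth:
    """Sidecar mapping of every emitted record to its origin."""

    rows: List[TruthRow] = field(default_factory=list)

    def record_ids(self, sample_id: str, origins: Sequence[Origin]) -> set:
        wanted = set(origins)
        return {
            r.record_id
            for r in self.rows
            if r.sample_id == sample_id and r.origin in wanted
        }

    def count(self, sample_id: str, origin: Origin) -> int:
        return sum(
            1 for r in self.rows if r.sample_id == sample_id and r.origin is origin
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.record_id, r.origin.value, r.source)
                for r in self.rows
            ],
            columns=["sample_id", "record_id", "origin", "source"],
        )


@dataclass
class SimulatedCohort:
    config: SimConfig
    callsets: Dict[str, SVCallset]
    maternal_coverage: CoverageTrack
    gene_model: GeneModel
    truth: CohortTruth

    @property
    def maternal(self) -> SVCallset:
        return self.callsets["PF"]

    def offspring_ids(self, cohort: str) -> List[str]:
        prefix = {"hom": "PP", "het": "PC"}[cohort]
        return [s for s in self.callsets if s.startswith(prefix)]


def _place_loci(cfg: SimConfig, n_total: int, rng: np.random.Generator) -> List[Tuple[str, int]]:
    """Place n_total locus start positions with the minimum spacing."""
    chroms = sorted(cfg.genome)
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=float)
    quotas = np.floor(n_total * lengths / lengths.sum()).astype(int)
    # distribute the remainder to the largest chromosomes first
    for i in np.argsort(-lengths):
        if quotas.sum() >= n_total:
            break
        quotas[i] += n_total - quotas.sum()
    placed: List[Tuple[str, int]] = []
    for chrom, L, k in zip(chroms, lengths.astype(int), quotas):
        if k == 0:
            continue
        slack = L - cfg.max_sv_len - (k - 1) * cfg.min_locus_spacing - 1
        if slack < k:
            raise ValueError(
                f"infeasible placement: {k} loci at spacing "
                f"{cfg.min_locus_spacing} bp do not fit on {chrom} ({L} bp)"
            )
        base = np.sort(rng.integers(1, slack + 1, size=k))
        starts = base + np.arange(k) * cfg.min_locus_spacing
        placed.extend((chrom, int(s)) for s in starts)
    return placed


def _draw_loci(cfg: SimConfig, n_total: int, rng: np.random.Generator) -> List[Locus]:
    sites = _place_loci(cfg, n_total, rng)
    rng.shuffle(sites)
    types = list(cfg.type_mix)
    probs = np.array([cfg.type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    chosen = rng.choice(len(types), size=n_total, p=probs)
    loci = []
    for i, ((chrom, pos), ti) in enumerate(zip(sites, chosen)):
        svtype = types[ti]
        mu, sigma = cfg.length_model[svtype]
        length = int(np.clip(round(rng.lognormal(mu, sigma)), cfg.min_sv_len, cfg.max_sv_len))
        loci.append(Locus(f"L{i:06d}", chrom, pos, svtype, length))
    return loci


def _realize(
    locus: Locus,
    sample_id: str,
    record_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    jitter: bool = True,
) -> SVRecord:
    """One sample's call of a locus: jittered breakpoints, sampled QC fields."""
    chrom_len = cfg.genome[locus.chrom]
    pos, end = locus.pos, locus.end
    if jitter and cfg.jitter_sd > 0:
        pos = int(round(pos + rng.normal(0.0, cfg.jitter_sd)))
        pos = min(max(pos, 1), chrom_len)
        if locus.svtype is SVType.INS:
            end = pos
        else:
            end = int(round(locus.end + rng.normal(0.0, cfg.jitter_sd)))
            end = min(max(end, pos), chrom_len)
    svlen = -locus.length if locus.svtype is SVType.DEL else locus.length
    qual = round(cfg.qual_offset + rng.exponential(cfg.qual_scale), 1)
    lam = max(cfg.depth_mean - cfg.support_offset, 0.0)
    support = int(cfg.support_offset + rng.poisson(lam))
    return SVRecord(
        sample_id=sample_id,
        chrom=locus.chrom,
        pos=pos,
        end=end,
        svtype=locus.svtype,
        svlen=svlen,
        qual=qual,
        support=support,
        precise=True,
        gt=Genotype.HET,
        record_id=record_id,
    )


def _toy_gene_model(cfg: SimConfig, rng: np.random.Generator) -> GeneModel:
    """Small gene model tiled over the genome: mostly protein-coding genes
    with 3-5 exons, CDS and UTRs, plus a minority of lncRNA genes."""
    genes: Dict[str, Gene] = {}
    gi = 0
    for chrom in sorted(cfg.genome):
        L = cfg.genome[chrom]
        n_genes = int(cfg.genes_per_mb * L / 1e6)
        if n_genes == 0:
            continue
        pitch = L // n_genes
        for k in range(n_genes):
            gi += 1
            gene_id = f"G{gi:05d}"
            start = k * pitch + int(rng.integers(5_000, max(pitch // 3, 5_001)))
            span = int(rng.integers(5_000, 20_001))
            end = min(start + span - 1, L)
            strand = "+" if rng.random() < 0.5 else "-"
            u = rng.random()
            biotype = (
                Biotype.PROTEIN_CODING
                if u < 0.8
                else (Biotype.LNCRNA if u < 0.95 else Biotype.OTHER_NCRNA)
            )
            n_exons = int(rng.integers(3, 6))
            exons = _tile_exons(start, end, n_exons, rng)
            tx = Transcript(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=exons,
            )
            if biotype is Biotype.PROTEIN_CODING:
                _assign_cds(tx)
            genes[gene_id] = Gene(
                gene_id=gene_id,
                symbol=f"gene{gi}",
                biotype=biotype,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                transcripts=[tx],
            )
    return GeneModel(genes)


def _tile_exons(start: int, end: int, n: int, rng: np.random.Generator) -> List[Tuple[int, int]]:
    span = end - start + 1
    block = span // n
    exons = []
    for i in range(n):
        ex_start = start + i * block
        ex_len = max(int(block * 0.4), 100)
        ex_len = min(ex_len, block - 50) if i < n - 1 else min(ex_len, end - ex_start + 1)
        exons.append((ex_start, ex_start + max(ex_len, 50) - 1))
    exons[0] = (start, exons[0][1])
    last_s, last_e = exons[-1]
    exons[-1] = (last_s, min(last_e, end))
    return exons


def _assign_cds(tx: Transcript) -> None:
    """Split a coding transcript's exons into UTR5 / CDS / UTR3 (in genomic
    order for a + gene; mirrored for -): first exon's first half is UTR,
    last exon's second half is UTR, everything between is CDS."""
    exons = tx.exons
    first_s, first_e = exons[0]
    last_s, last_e = exons[-1]
    cut1 = first_s + max((first_e - first_s) // 2, 1)
    cut2 = last_s + max((last_e - last_s) // 2, 1)
    if len(exons) == 1:
        cut2 = max(cut2, cut1 + 1)
    left_utr = (first_s, cut1 - 1)
    right_utr = (cut2 + 1, last_e)
    cds = []
    for i, (s, e) in enumerate(exons):
        lo, hi = s, e
        if i == 0:
            lo = cut1
        if i == len(exons) - 1:
            hi = cut2
        if hi >= lo:
            cds.append((lo, hi))
    tx.cds = cds
    if tx.strand == "+":
        tx.utr5, tx.utr3 = [left_utr], [right_utr]
    else:
        tx.utr5, tx.utr3 = [right_utr], [left_utr]
    tx.__post_init__()


def simulate_cohort(config: SimConfig = SimConfig()) -> SimulatedCohort:
    """Generate the full cohort: callsets, coverage, gene model, truth.

    Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_ms_hom = cfg.n_male_specific
    n_ms_het = int(round(cfg.n_male_specific * cfg.heterologous_multiplier))
    hom_ids = [f"PP{i}" for i in range(1, cfg.n_offspring + 1)]
    het_ids = [f"PC{i}" for i in range(1, cfg.n_offspring + 1)]
    n_denovo = {s: int(rng.poisson(cfg.denovo_rate)) for s in hom_ids + het_ids}
    n_fp = {s: int(rng.poisson(cfg.fp_rate)) for s in hom_ids + het_ids}
    n_total = (
        cfg.n_maternal_sv
        + n_ms_hom
        + n_ms_het
        + sum(n_denovo.values())
        + sum(n_fp.values())
    )
    loci = _draw_loci(cfg, n_total, rng)
    cursor = 0

    def take(n: int) -> List[Locus]:
        nonlocal cursor
        out = loci[cursor : cursor + n]
        cursor += n
        return out

    maternal_loci = take(cfg.n_maternal_sv)
    ms_loci = {"PM": take(n_ms_hom), "CM": take(n_ms_het)}
    denovo_loci = {s: take(n_denovo[s]) for s in hom_ids + het_ids}
    fp_loci = {s: take(n_fp[s]) for s in hom_ids + het_ids}

    truth = CohortTruth()
    callsets: Dict[str, SVCallset] = {}

    def emit(sample: str, locus: Locus, origin: Origin, idx: int,
             records: list, jitter: bool = True) -> None:
        rid = f"{sample}.{idx:06d}"
        records.append(_realize(locus, sample, rid, cfg, rng, jitter=jitter))
        source = "" if origin is Origin.FALSE_POSITIVE else locus.locus_id
        truth.rows.append(TruthRow(sample, rid, origin, source))

    # maternal composite callset: its records define the loci, no jitter
    pf_records: list = []
    for i, locus in enumerate(maternal_loci):
        emit("PF", locus, Origin.MATERNAL, i, pf_records, jitter=False)
    callsets["PF"] = SVCallset("PF", pf_records, provenance="simulated maternal composite")

    for male in ("PM", "CM"):
        recs: list = []
        i = 0
        for locus in maternal_loci:
            emit(male, locus, Origin.MATERNAL, i, recs)
            i += 1
        for locus in ms_loci[male]:
            emit(male, locus, Origin.MALE_SPECIFIC, i, recs)
            i += 1
        callsets[male] = SVCallset(male, recs, provenance=f"simulated male {male}")

    leak = {
        "PM": cfg.leakage_rate,
        "CM": cfg.leakage_rate if cfg.leakage_rate_het is None else cfg.leakage_rate_het,
    }
    for male, kids in (("PM", hom_ids), ("CM", het_ids)):
        for kid in kids:
            recs = []
            i = 0
            for locus in maternal_loci:
                if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
                    continue
                emit(kid, locus, Origin.MATERNAL, i, recs)
                i += 1
            for locus in ms_loci[male]:
                if rng.random() < leak[male]:
                    emit(kid, locus, Origin.PATERNAL_TRANSMITTED, i, recs)
                    i += 1
            for locus in denovo_loci[kid]:
                emit(kid, locus, Origin.DENOVO, i, recs)
                i += 1
            for locus in fp_loci[kid]:
                emit(kid, locus, Origin.FALSE_POSITIVE, i, recs)
                i += 1
            callsets[kid] = SVCallset(kid, recs, provenance=f"simulated offspring of {male}")

    holes: Dict[str, List[Tuple[int, int]]] = {}
    for _ in range(cfg.n_coverage_holes):
        chrom = sorted(cfg.genome)[int(rng.integers(0, len(cfg.genome)))]
        start = int(rng.integers(1, cfg.genome[chrom] - cfg.coverage_hole_len))
        holes.setdefault(chrom, []).append((start, start + cfg.coverage_hole_len - 1))
    coverage = constant_track("PF", cfg.genome, cfg.depth_mean, holes=holes)

    gene_model = _toy_gene_model(cfg, np.random.default_rng(cfg.seed + 7))

    return SimulatedCohort(cfg, callsets, coverage, gene_model, truth)


def write_gff3(model: GeneModel, path: Union[str, Path]) -> None:
    """Write the gene model as GFF3 (genes, transcripts, exons, CDS, UTRs)."""
    lines = ["##gff-version 3"]
    for gene_id in sorted(model.genes):
        g = model.genes[gene_id]
        attrs = f"ID={g.gene_id};Name={g.symbol};biotype={g.biotype.value}"
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for tx in g.transcripts:
            feat = "mRNA" if tx.coding else "lnc_RNA"
            lines.append(
                f"{tx.chrom}\tsim\t{feat}\t{tx.start}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={g.gene_id}"
            )
            for kind, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_UTR", tx.utr5),
                ("three_prime_UTR", tx.utr3),
            ):
                for j, (s, e) in enumerate(ivs):
                    frame = "0" if kind == "CDS" else "."
                    lines.append(
                        f"{tx.chrom}\tsim\t{kind}\t{s}\t{e}\t.\t{tx.strand}\t{frame}\t"
                        f"ID={tx.transcript_id}.{kind}.{j};Parent={tx.transcript_id}"
                    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: SimulatedCohort, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Write VCFs, coverage BED, GFF3 gene model and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    contigs = dict(cohort.config.genome)
    for sample in sorted(cohort.callsets):
        p = outdir / f"{sample}.vcf"
        write_sv_vcf(cohort.callsets[sample], p, contigs=contigs)
        paths[f"vcf:{sample}"] = p
    cov = outdir / "PF.depth.bed"
    write_coverage_bed(cohort.maternal_coverage, cov)
    paths["coverage"] = cov
    gff = outdir / "genes.gff3"
    write_gff3(cohort.gene_model, gff)
    paths["gene_model"] = gff
    tru = outdir / "truth.tsv"
    cohort.truth.to_frame().to_csv(tru, sep="\t", index=False)
    paths["truth"] = tru
    cfg = outdir / "sim_config.json"
    cfg_dict = asdict(cohort.config)
    cfg_dict["type_mix"] = {k.value: v for k, v in cfg_dict["type_mix"].items()}
    cfg_dict["length_model"] = {
        k.value: list(v) for k, v in cfg_dict["length_model"].items()
    }
    cfg.write_text(json.dumps(cfg_dict, indent=2) + "\n")
    paths["config"] = cfg
    return paths
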