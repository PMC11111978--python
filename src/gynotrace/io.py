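"""VCF and TSV input/output for SV callsets.

Reads caller VCFs (Sniffles2 / cuteSV / SVIM dialects) into :class:`SVCallset`
and writes the same dialect back, losslessly for every field the pipeline
uses. Reading goes through :mod:`cyvcf2`, which exposes the raw END INFO
value needed for the END-wins reconciliation rule.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

from cyvcf2 import VCF

from .models import (
    Genotype,
    SVCallset,
    SVRecord,
    SVType,
    genotype_from_alleles,
    summarize_callset,
)

log = logging.getLogger(__name__)

_SYMBOLIC_TYPES = {"DEL", "INS", "INV", "DUP", "DUP:TANDEM", "DUP:INT"}
#: INFO keys different callers use for read support.
_SUPPORT_KEYS = ("SUPPORT", "RE", "SUPP_READS")


class VCFParseError(ValueError):
    pass


def _svtype_of(rec) -> SVType:
    raw = rec.INFO.get("SVTYPE")
    if raw is None and rec.ALT:
        alt = rec.ALT[0]
        if alt.startswith("<") and alt.endswith(">"):
            raw = alt[1:-1]
    if raw is None:
        return SVType.OTHER
    raw = str(raw).split(":")[0].upper()
    try:
        return SVType(raw)
    except ValueError:
        return SVType.OTHER


def _scalar(value) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
        if value is None:
            return None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def read_sv_vcf(path: Union[str, Path], sample_id: str) -> SVCallset:
    """Read one per-sample SV VCF into a normalised callset.

    END and SVLEN are reconciled per record: for span types an explicit END
    wins when the two disagree (END is positional ground truth in caller
    output) and a warning is logged. Records whose coordinates cannot be
    resolved are kept but demoted to type OTHER, which the standard record
    filter removes.
    """
    path = str(path)
    records = []
    try:
        vf = VCF(path)
    except Exception as exc:
        raise VCFParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    has_samples = bool(vf.samples)
    n_inconsistent = 0
    for rec in vf:
        try:
            record, inconsistent = _convert_record(rec, sample_id, has_samples)
            records.append(record)
            n_inconsistent += inconsistent
        except Exception as exc:  # malformed record: keep, mark OTHER
            warnings.warn(
                f"{path}:{rec.CHROM}:{rec.POS}: unresolvable record "
                f"({exc}); marked OTHER"
            )
            records.append(
                SVRecord(
                    sample_id=sample_id,
                    chrom=rec.CHROM,
                    pos=max(rec.POS, 1),
                    end=max(rec.POS, 1),
                    svtype=SVType.OTHER,
                    qual=rec.QUAL or 0.0,
                )
            )
    vf.close()
    if n_inconsistent:
        log.warning(
            "%s: %d record(s) with SVLEN inconsistent with END; END used",
            path, n_inconsistent,
        )
    return SVCallset(sample_id, records, provenance=f"read_sv_vcf({path})")


def _convert_record(rec, sample_id: str, has_samples: bool):
    svtype = _svtype_of(rec)
    pos = rec.POS  # 1-based
    svlen = _scalar(rec.INFO.get("SVLEN"))
    end_info = _scalar(rec.INFO.get("END"))
    inconsistent = 0
    if svtype in (SVType.DEL, SVType.INV, SVType.DUP):
        if end_info is not None:
            end = end_info  # END wins over SVLEN when both are present
            if svlen is not None and abs(svlen) != end - pos + 1:
                inconsistent = 1
        elif svlen is not None:
            end = pos + abs(svlen) - 1
        else:
            end = rec.end  # from the reference allele span
        if end < pos:
            raise ValueError(f"END {end} < POS {pos}")
    else:
        end = pos
    precise = not bool(rec.INFO.get("IMPRECISE"))
    support = None
    for key in _SUPPORT_KEYS:
        val = _scalar(rec.INFO.get(key))
        if val is not None:
            support = val
            break
    strands = rec.INFO.get("STRANDS") or rec.INFO.get("STRAND")
    gt = Genotype.MISSING
    if has_samples:
        alleles = tuple(
            None if a < 0 else int(a) for a in rec.genotypes[0][:-1]
        )
        gt = genotype_from_alleles(alleles)
    record = SVRecord(
        sample_id=sample_id,
        chrom=rec.CHROM,
        pos=pos,
        end=end,
        svtype=svtype,
        svlen=svlen,
        qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
        support=support,
        precise=precise,
        gt=gt,
        strands=str(strands) if strands else None,
        record_id=rec.ID,
    )
    return record, inconsistent


_INFO_HEADER = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting reads">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">
##INFO=<ID=STRANDS,Number=1,Type=String,Description="Breakpoint strands">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">"""


def _fmt_qual(q: float) -> str:
    return f"{q:g}"


def write_sv_vcf(
    callset: SVCallset,
    path: Union[str, Path],
    contigs: Optional[dict] = None,
) -> None:
    """Write a callset as VCF 4.2 (symbolic ALT alleles).

    ``contigs`` maps chromosome name to length; chromosomes seen in the
    records but absent from the mapping are declared without a length.
    The text is emitted directly: htslib-based writers re-derive END from
    SVLEN under the newer VCF convention, which would silently override an
    explicit caller END — the one field the reconciliation rule must keep.
    """
    contigs = dict(contigs or {})
    for rec in callset:
        contigs.setdefault(rec.chrom, None)
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(
            f"##contig=<ID={chrom},length={length}>" if length else f"##contig=<ID={chrom}>"
        )
    lines.append(_INFO_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + callset.sample_id
    )
    for i, rec in enumerate(callset):
        info = ["PRECISE" if rec.precise else "IMPRECISE", f"SVTYPE={rec.svtype.value}"]
        if rec.svlen is not None:
            info.append(f"SVLEN={rec.svlen}")
        if rec.svtype is not SVType.INS:
            info.append(f"END={rec.end}")
        if rec.support is not None:
            info.append(f"SUPPORT={rec.support}")
        if rec.strands:
            info.append(f"STRANDS={rec.strands}")
        rid = rec.record_id or f"{callset.sample_id}.{i}"
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rid}\tN\t<{rec.svtype.value}>\t"
            f"{_fmt_qual(rec.qual)}\tPASS\t{';'.join(info)}\tGT\t{rec.gt_string()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_tsv(summaries, path: Union[str, Path]) -> None:
    """Write Table-1 style per-type count/length rows for one or more callsets."""
    import pandas as pd

    rows = [s.as_row() for s in summaries]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def summarize_vcf(path: Union[str, Path], sample_id: str):
    return summarize_callset(read_sv_vcf(path, sample_id))
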