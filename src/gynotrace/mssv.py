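"""Male-specific SV (MSSV) detection.

An MSSV is an offspring DSV, no larger than 10 kb, that matches a DSV of
the stimulating male under a tight 100 bp breakpoint window — the
operational signature of paternal genetic transmission in a gynogenetic
cohort. Common MSSVs are match clusters supported by every offspring of a
cohort (distinct-sample support = cohort size, 9 in the study design).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence

from .match import MergeCluster, MergeParams, build_clusters, intersect
from .models import SVCallset

MSSV_MERGE_DEFAULT = MergeParams(100, 2, True, True, False, 50)
COMMON_MERGE_DEFAULT = MergeParams(100, 9, True, True, False, 50)


@dataclass(frozen=True)
class MSSVParams:
    max_sv_span: int = 10_000
    merge: MergeParams = MSSV_MERGE_DEFAULT
    common_min_samples: int = 9

    def __post_init__(self) -> None:
        if self.max_sv_span <= 0:
            raise ValueError("max_sv_span must be > 0")
        if self.common_min_samples < 2:
            raise ValueError("common_min_samples must be >= 2")

    @property
    def common_merge(self) -> MergeParams:
        return MergeParams(
            self.merge.max_dist,
            self.common_min_samples,
            self.merge.type_agreement,
            self.merge.strand_agreement,
            self.merge.size_estimate,
            self.merge.min_size,
        )


@dataclass
class MSSVResult:
    sample_id: str
    mssv: SVCallset
    n_mssv: int
    fraction_of_dsv: float
    fraction_of_filtered: float


def size_prefilter(dsvs: SVCallset, max_sv_span: int = 10_000) -> SVCallset:
    """Drop DSVs larger than ``max_sv_span`` (strictly larger is excluded).

    Size is max(abs_len, reference span), which treats insertions (span 1
    on the reference but potentially long) and imprecise deletions
    symmetrically.
    """
    kept = [r for r in dsvs if max(r.abs_len, r.span) <= max_sv_span]
    return SVCallset(
        dsvs.sample_id,
        kept,
        provenance=f"{dsvs.provenance}; size_prefilter(<= {max_sv_span})",
    )


def detect_mssv(
    offspring_dsv: SVCallset,
    male_dsv: SVCallset,
    params: MSSVParams = MSSVParams(),
    n_filtered: int = 0,
) -> MSSVResult:
    """Intersect an offspring's DSVs with its male's DSVs (both <= 10 kb).

    ``n_filtered`` is the offspring's filtered-SV count, used only for the
    reported fraction; pass 0 when unknown.
    """
    if offspring_dsv.sample_id == male_dsv.sample_id:
        raise ValueError("offspring and male share a sample_id")
    off = size_prefilter(offspring_dsv, params.max_sv_span)
    male = size_prefilter(male_dsv, params.max_sv_span)
    mssv = intersect(off, male, params.merge, mode="cluster")
    n_dsv = len(offspring_dsv)
    return MSSVResult(
        sample_id=offspring_dsv.sample_id,
        mssv=mssv,
        n_mssv=len(mssv),
        fraction_of_dsv=(len(mssv) / n_dsv) if n_dsv else 0.0,
        fraction_of_filtered=(len(mssv) / n_filtered) if n_filtered else 0.0,
    )


def common_mssv(
    cohort_mssv: Sequence[MSSVResult],
    params: MSSVParams = MSSVParams(),
) -> List[MergeCluster]:
    """Clusters of MSSVs shared by at least ``common_min_samples`` offspring."""
    if len(cohort_mssv) < params.common_min_samples:
        raise ValueError(
            f"cohort of {len(cohort_mssv)} smaller than "
            f"common_min_samples={params.common_min_samples}"
        )
    callsets = [r.mssv for r in cohort_mssv]
    clusters = build_clusters(callsets, params.common_merge)
    return [c for c in clusters if c.n_samples >= params.common_min_samples]


def per_chromosome_tally(clusters: Sequence[MergeCluster]) -> Dict[str, int]:
    """Count qualifying clusters per chromosome (by representative)."""
    return dict(Counter(c.representative.chrom for c in clusters))
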