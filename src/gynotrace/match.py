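"""Tolerance-window SV matching, clustering, subtraction and intersection.

Two SV records match when they sit on the same chromosome, agree in type
(and, when required, strand), and both breakpoints lie within ``max_dist``
of each other. Multi-sample merging then takes connected components of the
match graph — the clustering semantics of the standard SV merge tools,
whose six positional parameters

    max_dist  min_support  type_agreement  strand_agreement  size_estimate  min_size

are mirrored here (``size_estimate`` is off in every analysis stage, so SV
length similarity never enters the predicate).

Subtraction and intersection of a target callset against a reference come
in two modes: ``cluster`` (a target record is matched if its connected
component contains any reference record — the default, mirroring
cluster-based merge tools) and ``pairwise`` (a direct O(n^2) match against
any single reference record — the independent oracle). On sparse data the
two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Set, Tuple

from .models import SVCallset, SVRecord, SVType

Mode = Literal["cluster", "pairwise"]


@dataclass(frozen=True)
class MergeParams:
    """Merge parameterisation in the positional order of the merge tools."""

    max_dist: int = 1000
    min_support: int = 2
    type_agreement: bool = True
    strand_agreement: bool = True
    size_estimate: bool = False
    min_size: int = 50

    def __post_init__(self) -> None:
        if self.max_dist < 0:
            raise ValueError("max_dist must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")

    @classmethod
    def from_string(cls, text: str) -> "MergeParams":
        """Parse '1000,2,1,1,0,50' or '1000 2 1 1 0 50' (commas in numbers ok)."""
        parts = text.split()
        if len(parts) == 6:  # space-separated; tolerate thousands separators
            vals = [int(p.replace(",", "")) for p in parts]
        else:
            vals = [int(p) for p in text.split(",")]
            if len(vals) != 6:
                raise ValueError(f"expected 6 merge parameters, got {text!r}")
        d, s, t, st, sz, m = vals
        return cls(d, s, bool(t), bool(st), bool(sz), m)

    def as_string(self) -> str:
        return (
            f"{self.max_dist} {self.min_support} {int(self.type_agreement)} "
            f"{int(self.strand_agreement)} {int(self.size_estimate)} {self.min_size}"
        )


def records_match(a: SVRecord, b: SVRecord, params: MergeParams) -> bool:
    """Symmetric tolerance-window match predicate.

    Records below ``min_size`` never match (the merge tools exclude them
    from merging altogether). Unknown strands are compatible with anything:
    most DEL/INS caller records carry no strand, and requiring one would
    void all matches.
    """
    if a.abs_len < params.min_size or b.abs_len < params.min_size:
        return False
    if a.chrom != b.chrom:
        return False
    if params.type_agreement and a.svtype is not b.svtype:
        return False
    if (
        params.strand_agreement
        and a.strands is not None
        and b.strands is not None
        and a.strands != b.strands
    ):
        return False
    return abs(a.pos - b.pos) <= params.max_dist and abs(a.end - b.end) <= params.max_dist


@dataclass
class MergeCluster:
    """One connected component of the match graph."""

    members: List[SVRecord]
    representative: SVRecord
    samples: Set[str]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def below_threshold(self, params: MergeParams) -> bool:
        return self.n_samples < params.min_support


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster_records(
    records: Sequence[SVRecord], params: MergeParams
) -> List[List[int]]:
    """Connected components over the match graph; indices into ``records``.

    ``records`` must be sorted by (chrom, pos, ...); a sweep over the
    position-sorted list bounds candidate pairs by ``|pos_i - pos_j| <=
    max_dist``, which is necessary for a match.
    """
    uf = _UnionFind(len(records))
    n = len(records)
    for i in range(n):
        a = records[i]
        for j in range(i + 1, n):
            b = records[j]
            if b.chrom != a.chrom or b.pos - a.pos > params.max_dist:
                break
            if records_match(a, b, params):
                uf.union(i, j)
    comps: Dict[int, List[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    # deterministic order: by root index == first member in global sort order
    return [comps[root] for root in sorted(comps)]


def build_clusters(
    callsets: Sequence[SVCallset], params: MergeParams
) -> List[MergeCluster]:
    """Cluster the union of records from several callsets.

    Deterministic: records are globally sorted by (chrom, pos, end, type,
    sample) before component construction and the representative is the
    first member in that order. Clusters below the ``min_support`` distinct-
    sample count are still returned; callers decide what to keep (see
    :meth:`MergeCluster.below_threshold`).
    """
    pool = sorted(
        (r for cs in callsets for r in cs.records), key=SVRecord.sort_key
    )
    clusters = []
    for idxs in _cluster_records(pool, params):
        members = [pool[i] for i in idxs]
        clusters.append(
            MergeCluster(
                members=members,
                representative=members[0],
                samples={m.sample_id for m in members},
            )
        )
    return clusters


def _matched_keys_cluster(
    target: SVCallset, reference: SVCallset, params: MergeParams
) -> Set[int]:
    """ids of target records sharing a cluster with >=1 reference record."""
    pool = sorted(
        list(target.records) + list(reference.records), key=SVRecord.sort_key
    )
    ref_ids = {id(r) for r in reference.records}
    matched: Set[int] = set()
    for idxs in _cluster_records(pool, params):
        members = [pool[i] for i in idxs]
        if any(id(m) in ref_ids for m in members):
            matched.update(id(m) for m in members if id(m) not in ref_ids)
    return matched


def _matched_keys_pairwise(
    target: SVCallset, reference: SVCallset, params: MergeParams
) -> Set[int]:
    """ids of target records directly matching >=1 reference record (oracle)."""
    by_chrom: Dict[str, List[SVRecord]] = {}
    for r in reference.records:
        by_chrom.setdefault(r.chrom, []).append(r)
    matched: Set[int] = set()
    for t in target.records:
        for r in by_chrom.get(t.chrom, ()):
            if records_match(t, r, params):
                matched.add(id(t))
                break
    return matched


def _split(
    target: SVCallset, reference: SVCallset, params: MergeParams, mode: Mode
) -> Tuple[List[SVRecord], List[SVRecord]]:
    if target.sample_id == reference.sample_id:
        raise ValueError(
            f"target and reference share sample_id {target.sample_id!r}"
        )
    if mode == "cluster":
        matched = _matched_keys_cluster(target, reference, params)
    elif mode == "pairwise":
        matched = _matched_keys_pairwise(target, reference, params)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hit = [r for r in target.records if id(r) in matched]
    miss = [r for r in target.records if id(r) not in matched]
    return hit, miss


def subtract(
    target: SVCallset,
    reference: SVCallset,
    params: MergeParams,
    mode: Mode = "cluster",
) -> SVCallset:
    """Target records NOT attributable to the reference set."""
    _, miss = _split(target, reference, params, mode)
    return SVCallset(
        target.sample_id,
        miss,
        provenance=f"{target.provenance}; subtract({reference.sample_id}, "
        f"[{params.as_string()}], {mode})",
    )


def intersect(
    target: SVCallset,
    reference: SVCallset,
    params: MergeParams,
    mode: Mode = "cluster",
) -> SVCallset:
    """Target records attributable to the reference set (dual of subtract)."""
    hit, _ = _split(target, reference, params, mode)
    return SVCallset(
        target.sample_id,
        hit,
        provenance=f"{target.provenance}; intersect({reference.sample_id}, "
        f"[{params.as_string()}], {mode})",
    )
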