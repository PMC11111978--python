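"""Tolerance-window matching, clustering, subtraction, intersection.

The independent oracle throughout is a brute-force O(n^2) match graph with
breadth-first connected components.
"""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gynotrace import (
    MergeParams,
    SVCallset,
    SVType,
    build_clusters,
    intersect,
    records_match,
    subtract,
)

from conftest import make_callset, make_rec

P1000 = MergeParams(1000, 2, True, True, False, 50)
P100 = MergeParams(100, 2, True, True, False, 50)


def brute_components(records, params):
    """Oracle: BFS connected components of the full pairwise match graph."""
    n = len(records)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if records_match(records[i], records[j], params):
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset(records[k].record_id for k in comp))
    return set(comps)


class TestRecordsMatch:
    def test_reflexive_and_symmetric(self):
        a = make_rec(pos=1000, end=2000, svlen=-1001)
        b = make_rec(pos=1950, end=2950, svlen=-1001)
        assert records_match(a, a, P1000)
        assert records_match(a, b, P1000) == records_match(b, a, P1000)

    def test_distance_window(self):
        a = make_rec(pos=1000, end=2000, svlen=-1001)
        b = make_rec(pos=1950, end=2950, svlen=-1001)
        assert records_match(a, b, P1000)
        assert not records_match(a, b, P100)

    def test_both_breakpoints_must_agree(self):
        a = make_rec(pos=1000, end=2000, svlen=-1001)
        b = make_rec(pos=1000, end=4000, svlen=-3001)  # same start, far end
        assert not records_match(a, b, P1000)

    def test_type_agreement(self):
        a = make_rec(pos=1000, svtype=SVType.DEL, end=1099, svlen=-100)
        b = make_rec(pos=1000, svtype=SVType.INS, svlen=100)
        assert not records_match(a, b, MergeParams(1000, 2, True, True, False, 50))
        # INS end degenerates to pos: compare at same coordinates
        b2 = make_rec(pos=1000, svtype=SVType.DEL, end=1099, svlen=-100)
        assert records_match(a, b2, P1000)

    def test_offset_boundary_is_inclusive(self):
        a = make_rec(pos=1000, svtype=SVType.INS, svlen=100)
        at = make_rec(pos=1000 + 1000, svtype=SVType.INS, svlen=100)
        over = make_rec(pos=1000 + 1001, svtype=SVType.INS, svlen=100)
        assert records_match(a, at, P1000)
        assert not records_match(a, over, P1000)

    def test_different_chromosomes_never_match(self):
        a = make_rec(chrom="A1")
        b = make_rec(chrom="A2")
        assert not records_match(a, b, P1000)

    def test_below_min_size_never_matches(self):
        a = make_rec(svtype=SVType.INS, svlen=30)
        assert not records_match(a, a, P1000)

    def test_strand_agreement_with_unknowns(self):
        plus = make_rec(svtype=SVType.INV, pos=100, end=600, svlen=501, strands="++")
        minus = make_rec(svtype=SVType.INV, pos=100, end=600, svlen=501, strands="--")
        unknown = make_rec(svtype=SVType.INV, pos=100, end=600, svlen=501)
        assert not records_match(plus, minus, P1000)
        assert records_match(plus, unknown, P1000)


class TestBuildClusters:
    def test_two_identical_records_two_samples(self):
        a = make_callset([make_rec(sample="S1")], sample="S1")
        b = make_callset([make_rec(sample="S2")], sample="S2")
        (c,) = build_clusters([a, b], P1000)
        assert c.n_samples == 2 and not c.below_threshold(P1000)

    def test_transitive_chain_is_one_cluster(self):
        # A-B match and B-C match but A-C do not: one component of three
        recs = [
            make_rec(pos=1000, svtype=SVType.INS, svlen=100, record_id="A"),
            make_rec(pos=1900, svtype=SVType.INS, svlen=100, record_id="B"),
            make_rec(pos=2800, svtype=SVType.INS, svlen=100, record_id="C"),
        ]
        assert not records_match(recs[0], recs[2], P1000)
        (c,) = build_clusters([make_callset(recs)], P1000)
        assert {m.record_id for m in c.members} == {"A", "B", "C"}
        assert c.representative.record_id == "A"

    def test_distant_records_stay_singletons(self):
        recs = [
            make_rec(pos=1 + i * 10_000, svtype=SVType.INS, svlen=100, record_id=str(i))
            for i in range(5)
        ]
        clusters = build_clusters([make_callset(recs)], P1000)
        assert len(clusters) == 5

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_clusters_equal_brute_force_components(self, data):
        n = data.draw(st.integers(1, 40))
        recs = []
        for i in range(n):
            pos = data.draw(st.integers(1, 20_000))
            svtype = data.draw(st.sampled_from([SVType.DEL, SVType.INS]))
            length = data.draw(st.integers(50, 500))
            recs.append(
                make_rec(
                    sample=f"S{i % 3}",
                    pos=pos,
                    end=pos if svtype is SVType.INS else pos + length - 1,
                    svtype=svtype,
                    svlen=length if svtype is SVType.INS else -length,
                    record_id=str(i),
                )
            )
        callsets = [
            make_callset([r for r in recs if r.sample_id == s], sample=s)
            for s in {r.sample_id for r in recs}
        ]
        got = {
            frozenset(m.record_id for m in c.members)
            for c in build_clusters(callsets, P1000)
        }
        assert got == brute_components(recs, P1000)


def random_callset(rng, sample, n, lo, hi, spacing=None):
    recs = []
    positions = (
        [lo + i * spacing for i in range(n)]
        if spacing
        else [rng.randint(lo, hi) for _ in range(n)]
    )
    for i, pos in enumerate(positions):
        svtype = rng.choice([SVType.DEL, SVType.INS])
        length = rng.randint(50, 400)
        recs.append(
            make_rec(
                sample=sample,
                pos=pos,
                end=pos if svtype is SVType.INS else pos + length - 1,
                svtype=svtype,
                svlen=length if svtype is SVType.INS else -length,
                record_id=f"{sample}.{i}",
            )
        )
    return make_callset(recs, sample=sample)


class TestSubtractIntersect:
    def test_self_subtraction_empty(self):
        x = random_callset(random.Random(1), "X", 30, 1, 100_000)
        y = x.relabelled("Y")
        assert len(subtract(x, y, P1000)) == 0
        assert len(intersect(x, y, P1000)) == len(x)

    def test_subtract_empty_reference_is_identity(self):
        x = random_callset(random.Random(2), "X", 10, 1, 100_000)
        empty = SVCallset("R", [])
        assert [r.record_id for r in subtract(x, empty, P1000)] == [
            r.record_id for r in x
        ]
        assert len(intersect(x, empty, P1000)) == 0

    def test_same_sample_id_rejected(self):
        x = random_callset(random.Random(3), "X", 3, 1, 100_000)
        with pytest.raises(ValueError, match="sample_id"):
            subtract(x, x, P1000)

    def test_chain_cluster_vs_pairwise(self):
        # target A(1000), B(1900); reference R(2800): pairwise removes only B,
        # cluster removes both (A joins the mixed component through B)
        target = make_callset(
            [
                make_rec(pos=1000, svtype=SVType.INS, svlen=100, record_id="A"),
                make_rec(pos=1900, svtype=SVType.INS, svlen=100, record_id="B"),
            ]
        )
        ref = make_callset(
            [make_rec(sample="R", pos=2800, svtype=SVType.INS, svlen=100)],
            sample="R",
        )
        pw = subtract(target, ref, P1000, mode="pairwise")
        cl = subtract(target, ref, P1000, mode="cluster")
        assert [r.record_id for r in pw] == ["A"]
        assert len(cl) == 0

    def test_partition_into_subtract_and_intersect(self):
        rng = random.Random(4)
        x = random_callset(rng, "X", 50, 1, 200_000)
        r = random_callset(rng, "R", 50, 1, 200_000)
        for mode in ("cluster", "pairwise"):
            sub = {id(rec) for rec in subtract(x, r, P1000, mode)}
            inter = {id(rec) for rec in intersect(x, r, P1000, mode)}
            assert sub | inter == {id(rec) for rec in x}
            assert sub & inter == set()

    def test_growing_reference_monotonicity(self):
        rng = random.Random(5)
        x = random_callset(rng, "X", 40, 1, 200_000)
        r_small = random_callset(rng, "R", 20, 1, 200_000)
        r_big = make_callset(
            list(r_small.records)
            + list(random_callset(rng, "R", 20, 1, 200_000).records),
            sample="R",
        )
        for mode in ("cluster", "pairwise"):
            assert len(subtract(x, r_big, P1000, mode)) <= len(
                subtract(x, r_small, P1000, mode)
            )
            assert len(intersect(x, r_big, P1000, mode)) >= len(
                intersect(x, r_small, P1000, mode)
            )

    def test_cluster_subtract_removes_superset_of_pairwise(self):
        rng = random.Random(6)
        x = random_callset(rng, "X", 60, 1, 100_000)
        r = random_callset(rng, "R", 60, 1, 100_000)
        pw_removed = {r_.record_id for r_ in x} - {
            r_.record_id for r_ in subtract(x, r, P1000, "pairwise")
        }
        cl_removed = {r_.record_id for r_ in x} - {
            r_.record_id for r_ in subtract(x, r, P1000, "cluster")
        }
        assert pw_removed <= cl_removed

    def test_modes_coincide_on_sparse_callsets(self):
        # intra-callset spacing > 2*max_dist makes chaining impossible
        rng = random.Random(7)
        x = random_callset(rng, "X", 30, 1, None, spacing=2 * 1000 + 50)
        jittered = []
        for i, rec in enumerate(x):
            if rng.random() >= 0.6:
                continue
            pos = rec.pos + rng.randint(-400, 400)
            end = pos if rec.svtype is SVType.INS else max(
                pos, rec.end + rng.randint(-400, 400)
            )
            jittered.append(
                make_rec(sample="R", pos=pos, end=end, svtype=rec.svtype,
                         svlen=rec.svlen, record_id=f"R.{i}")
            )
        ref = make_callset(jittered, sample="R") if jittered else SVCallset("R", [])
        for op in (subtract, intersect):
            a = [r.record_id for r in op(x, ref, P1000, "cluster")]
            b = [r.record_id for r in op(x, ref, P1000, "pairwise")]
            assert a == b


class TestMergeParams:
    def test_positional_string_parsing(self):
        p = MergeParams.from_string("1,000 2 1 1 0 50")
        assert p == MergeParams(1000, 2, True, True, False, 50)
        assert MergeParams.from_string("100,9,1,1,0,50") == MergeParams(
            100, 9, True, True, False, 50
        )

    def test_round_trip_string(self):
        p = MergeParams(100, 9, True, True, False, 50)
        assert MergeParams.from_string(p.as_string()) == p
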