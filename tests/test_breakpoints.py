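"""Junction extraction/clustering/typing and architecture enumeration."""

import itertools
import random

import pytest

from asval.breakpoints import (
    ArchitectureSolution,
    GraphSegment,
    Junction,
    RawJunctionObservation,
    SegmentGraph,
    ambiguous_repeat_graph,
    classify_junction,
    cluster_junctions,
    enumerate_architectures,
    extract_raw_junctions,
    verify_breakpoint,
)
from asval.types import (
    AlignmentSegment,
    CNSegment,
    JunctionSide,
    JunctionType,
    Orientation,
    SegmentStatus,
    Verdict,
)

H, T = Orientation.HEAD, Orientation.TAIL


def seg(read_id, idx, contig, start, end, strand="+"):
    return AlignmentSegment(read_id, idx, contig, start, end, strand)


def side(contig, pos, ori):
    return JunctionSide(contig, pos, ori)


def junction(a, b, support=5):
    j = Junction(side_a=a, side_b=b, support=support) if a.key() <= b.key() else Junction(
        side_a=b, side_b=a, support=support
    )
    j.type = classify_junction(j)
    return j


class TestExtractRawJunctions:
    def test_clean_deletion_split(self):
        (obs,) = extract_raw_junctions(
            [seg("r", 0, "chr1", 50_000, 100_000), seg("r", 1, "chr1", 200_000, 250_000)]
        )
        assert obs.side_a == side("chr1", 100_000, T)
        assert obs.side_b == side("chr1", 200_000, H)

    def test_inter_contig_split_is_tra_compatible(self):
        (obs,) = extract_raw_junctions(
            [seg("r", 0, "chr6", 0, 10_000), seg("r", 1, "chr22", 5_000, 15_000)]
        )
        assert {obs.side_a.contig, obs.side_b.contig} == {"chr6", "chr22"}

    def test_three_segment_read_two_observations(self):
        obs = extract_raw_junctions(
            [
                seg("r", 0, "chr1", 0, 1000),
                seg("r", 1, "chr1", 5000, 6000),
                seg("r", 2, "chr1", 9000, 10_000),
            ]
        )
        assert len(obs) == 2

    def test_single_segment_reads_contribute_nothing(self):
        assert extract_raw_junctions([seg("r", 0, "chr1", 0, 1000)]) == []

    def test_reverse_read_same_canonical_observation(self):
        fwd = extract_raw_junctions(
            [seg("r", 0, "chr1", 0, 1000, "+"), seg("r", 1, "chr1", 5000, 6000, "+")]
        )
        rev = extract_raw_junctions(
            [seg("r", 0, "chr1", 5000, 6000, "-"), seg("r", 1, "chr1", 0, 1000, "-")]
        )
        assert (fwd[0].side_a, fwd[0].side_b) == (rev[0].side_a, rev[0].side_b)


class TestClassifyJunction:
    def test_translocation(self):
        j = junction(side("chr6", 96_500_931, T), side("chr22", 3_117_669, H))
        assert j.type == JunctionType.TRA

    def test_deletion_like(self):
        j = junction(side("chr1", 100_000, T), side("chr1", 200_000, H))
        assert j.type == JunctionType.DEL_LIKE

    def test_tandem_duplication_like(self):
        # a tandem copy joins the block's end (tail @ high) back to its
        # start (head @ low)
        j = junction(side("chr1", 200_000, T), side("chr1", 100_000, H))
        assert j.type == JunctionType.DUP_LIKE

    def test_inversion_like(self):
        j = junction(side("chr1", 100_000, T), side("chr1", 200_000, T))
        assert j.type == JunctionType.INV_LIKE

    def test_same_position_self_junction_ambiguous(self):
        j = junction(side("chr1", 100_000, T), side("chr1", 100_000, H))
        assert j.type == JunctionType.AMBIGUOUS


def jittered_observations(rng, pos_a, pos_b, n, jitter, read_prefix="r"):
    out = []
    for i in range(n):
        da, db = rng.randint(-jitter, jitter), rng.randint(-jitter, jitter)
        out.append(
            RawJunctionObservation(
                side("chr1", pos_a + da, T), side("chr1", pos_b + db, H), f"{read_prefix}{i}"
            )
        )
    return out


class TestClusterJunctions:
    def test_jittered_observations_form_one_cluster(self):
        rng = random.Random(1)
        obs = jittered_observations(rng, 100_000, 200_000, n=5, jitter=10)
        (j,) = cluster_junctions(obs)
        assert j.support == 5
        positions = sorted(o.side_a.position for o in obs)
        assert j.side_a.position == positions[2]  # median of five

    def test_below_min_support_dropped(self):
        rng = random.Random(2)
        obs = jittered_observations(rng, 100_000, 200_000, n=2, jitter=5)
        assert cluster_junctions(obs, min_support=3) == []

    def test_distant_junctions_never_merge(self):
        rng = random.Random(3)
        obs = jittered_observations(rng, 100_000, 200_000, n=4, jitter=10)
        obs += jittered_observations(rng, 110_000, 210_000, n=4, jitter=10, read_prefix="s")
        juncs = cluster_junctions(obs, tol=50)
        assert len(juncs) == 2

    def test_permutation_invariance(self):
        rng = random.Random(4)
        obs = jittered_observations(rng, 100_000, 200_000, n=6, jitter=15)
        obs += jittered_observations(rng, 400_000, 500_000, n=4, jitter=15, read_prefix="s")
        base = cluster_junctions(obs)
        for seed in range(5):
            shuffled = obs[:]
            random.Random(seed).shuffle(shuffled)
            assert cluster_junctions(shuffled) == base

    def test_support_conservation(self):
        rng = random.Random(5)
        obs = jittered_observations(rng, 100_000, 200_000, n=6, jitter=10)
        obs += jittered_observations(rng, 400_000, 500_000, n=5, jitter=10, read_prefix="s")
        juncs = cluster_junctions(obs, min_support=1)
        assert sum(j.support for j in juncs) == len(obs)


class TestVerifyBreakpoint:
    def test_supported_junction_confirms_at_nucleotide(self):
        j = junction(side("chr1", 150_000, T), side("chr1", 300_000, H), support=8)
        res = verify_breakpoint(("chr1", 100_000, 200_000), [j], min_support=3)
        assert res.verdict == Verdict.CONFIRMED_NUCLEOTIDE
        assert res.position == 150_000

    def test_one_sided_translocation_confirms(self):
        # partner side on an untargeted contig: one side in the interval is enough
        j = junction(side("chr6", 96_500_931, T), side("chr22", 3_117_669, H), support=6)
        res = verify_breakpoint(("chr6", 96_000_000, 97_000_000), [j])
        assert res.verdict == Verdict.CONFIRMED_NUCLEOTIDE

    def test_depth_only_support(self):
        cn = CNSegment("chr1", 120_000, 180_000, -1.0, 1, 120, SegmentStatus.LOSS)
        res = verify_breakpoint(("chr1", 100_000, 200_000), [], [cn])
        assert res.verdict == Verdict.SUPPORTED_DEPTH_ONLY

    def test_no_evidence_not_confirmed(self):
        res = verify_breakpoint(("chr1", 100_000, 200_000), [], [])
        assert res.verdict == Verdict.NOT_CONFIRMED

    def test_insufficient_support_falls_through(self):
        j = junction(side("chr1", 150_000, T), side("chr1", 300_000, H), support=2)
        res = verify_breakpoint(("chr1", 100_000, 200_000), [j], min_support=3)
        assert res.verdict == Verdict.NOT_CONFIRMED


# --------------------------------------------------------------------------
# architecture enumeration, with an independent exhaustive-walk oracle
# --------------------------------------------------------------------------


def oracle_enumerate(graph: SegmentGraph) -> set[tuple]:
    """All valid walks by filtering every permutation of the oriented multiset.

    Independent of the DFS: build the multiset of segment copies, try every
    distinct ordering with every orientation assignment, and keep those
    whose consecutive end-pairs (including the anchors) are graph edges.
    """
    edges = set()
    for a, b in graph.edges():
        edges.add((a, b))
        edges.add((b, a))
    multiset = []
    for i, s in enumerate(graph.segments):
        multiset.extend([i] * s.multiplicity)

    def ends(i, orientation):
        entry = (i, "head") if orientation == "+" else (i, "tail")
        exit_ = (i, "tail") if orientation == "+" else (i, "head")
        return entry, exit_

    solutions = set()
    for perm in set(itertools.permutations(multiset)):
        for oris in itertools.product("+-", repeat=len(perm)):
            prev_exit = ("L",)
            ok = True
            for i, o in zip(perm, oris):
                entry, exit_ = ends(i, o)
                if (prev_exit, entry) not in edges:
                    ok = False
                    break
                prev_exit = exit_
            if ok and (prev_exit, ("R",)) in edges:
                solutions.add(
                    tuple((graph.segments[i].seg_id, o) for i, o in zip(perm, oris))
                )
    return solutions


def tandem_dup_graph():
    return SegmentGraph(
        segments=[
            GraphSegment("S1", "chr1", 0, 100, 1),
            GraphSegment("S2", "chr1", 100, 200, 2),
            GraphSegment("S3", "chr1", 200, 300, 1),
        ],
        junction_edges=[((1, "tail"), (1, "head"))],
    )


def inversion_graph():
    return SegmentGraph(
        segments=[
            GraphSegment("S1", "chr1", 0, 100, 1),
            GraphSegment("S2", "chr1", 100, 200, 1),
            GraphSegment("S3", "chr1", 200, 300, 1),
        ],
        junction_edges=[
            ((0, "tail"), (1, "tail")),  # fold into the inverted block
            ((1, "head"), (2, "head")),  # and out of it
        ],
    )


class TestEnumerateArchitectures:
    def test_trivial_reference_walk(self):
        g = SegmentGraph(segments=[GraphSegment("S1", "chr1", 0, 100, 1)])
        enum = enumerate_architectures(g)
        assert [s.path for s in enum.solutions] == [(("S1", "+"),)]

    def test_tandem_duplication_unique_solution(self):
        enum = enumerate_architectures(tandem_dup_graph())
        assert [s.path for s in enum.solutions] == [
            (("S1", "+"), ("S2", "+"), ("S2", "+"), ("S3", "+"))
        ]

    def test_inversion_recovered_with_orientation(self):
        # the inverted walk is found; the reference walk also remains valid
        # because a walk is not obliged to use every observed junction
        enum = enumerate_architectures(inversion_graph())
        paths = {s.path for s in enum.solutions}
        assert (("S1", "+"), ("S2", "-"), ("S3", "+")) in paths

    def test_unanchored_repeat_is_ambiguous(self):
        enum = enumerate_architectures(ambiguous_repeat_graph())
        assert len(enum.solutions) > 1
        assert not enum.truncated

    def test_deletion_skips_lost_segment(self):
        g = SegmentGraph(
            segments=[
                GraphSegment("S1", "chr1", 0, 100, 1),
                GraphSegment("Sdel", "chr1", 100, 200, 0),
                GraphSegment("S3", "chr1", 200, 300, 1),
            ],
            junction_edges=[((0, "tail"), (2, "head"))],
        )
        enum = enumerate_architectures(g)
        assert [s.path for s in enum.solutions] == [(("S1", "+"), ("S3", "+"))]

    def test_inconsistent_evidence_gives_empty(self):
        # two copies demanded but no junction to revisit the segment
        g = SegmentGraph(
            segments=[
                GraphSegment("S1", "chr1", 0, 100, 1),
                GraphSegment("S2", "chr1", 100, 200, 2),
            ]
        )
        assert enumerate_architectures(g).solutions == []

    @pytest.mark.parametrize(
        "graph",
        [tandem_dup_graph(), inversion_graph(), ambiguous_repeat_graph()],
        ids=["tandem", "inversion", "ambiguous-repeat"],
    )
    def test_matches_exhaustive_oracle(self, graph):
        enum = enumerate_architectures(graph, max_solutions=1000)
        assert {s.path for s in enum.solutions} == oracle_enumerate(graph)

    def test_solutions_revalidate_against_graph(self):
        """Every returned walk satisfies multiplicities and edges (checker)."""
        graph = ambiguous_repeat_graph()
        edges = set()
        for a, b in graph.edges():
            edges.add((a, b))
            edges.add((b, a))
        ids = {s.seg_id: i for i, s in enumerate(graph.segments)}
        for sol in enumerate_architectures(graph).solutions:
            counts = {s.seg_id: 0 for s in graph.segments}
            prev_exit = ("L",)
            for seg_id, o in sol.path:
                counts[seg_id] += 1
                i = ids[seg_id]
                entry = (i, "head") if o == "+" else (i, "tail")
                assert (prev_exit, entry) in edges
                prev_exit = (i, "tail") if o == "+" else (i, "head")
            assert (prev_exit, ("R",)) in edges
            assert counts == {s.seg_id: s.multiplicity for s in graph.segments}

    def test_graph_from_clean_cn_calls(self):
        cn = [
            CNSegment("chr1", 0, 100, 0.0, 2, 1, SegmentStatus.NEUTRAL),
            CNSegment("chr1", 100, 200, 0.585, 3, 1, SegmentStatus.GAIN),
            CNSegment("chr1", 200, 300, 0.0, 2, 1, SegmentStatus.NEUTRAL),
        ]
        j = junction(side("chr1", 200, T), side("chr1", 100, H))
        graph = SegmentGraph.from_calls(cn, [j], tol=10)
        assert [s.multiplicity for s in graph.segments] == [1, 2, 1]
        enum = enumerate_architectures(graph)
        assert [s.path for s in enum.solutions] == [
            (("S1", "+"), ("S2", "+"), ("S2", "+"), ("S3", "+"))
        ]

    def test_truncation_flag(self):
        enum = enumerate_architectures(ambiguous_repeat_graph(), max_solutions=1)
        assert len(enum.solutions) == 1
        assert enum.truncated

    def test_multiplicity_cap(self):
        g = SegmentGraph(segments=[GraphSegment("S1", "chr1", 0, 100, 25)])
        with pytest.raises(ValueError, match="cap"):
            enumerate_architectures(g)
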