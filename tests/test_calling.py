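"""Read classification, junction typing, dedup, clustering and pairing."""

import pytest

from tislocate.align import ReadPairAlignment, SegmentAlignment, align_read
from tislocate.calling import (
    JunctionEvidence,
    ReadClass,
    TISCall,
    classify_read_pair,
    cluster_calls,
    dedupe_evidence,
    enumerate_insertion_types,
    junction_from_split,
    pair_full_tis,
    resolve_multimap,
    subtract_control,
)
from tislocate.construct import TDNA_CONTIG

from conftest import all_junction_geometries, make_junction_read


def seg(contig, ref_start, ref_end, strand="+", read_start=0, read_end=None,
        mate="R1", read_id="r", cohits=()):
    if read_end is None:
        read_end = read_start + (ref_end - ref_start)
    return SegmentAlignment(
        read_id=read_id, mate=mate, contig=contig, ref_start=ref_start,
        ref_end=ref_end, strand=strand, read_start=read_start, read_end=read_end,
        cohits=tuple(cohits),
    )


def pair(segs1, segs2, read_id="r"):
    return ReadPairAlignment(read_id=read_id, segments_r1=segs1, segments_r2=segs2)


class TestClassify:
    def test_genome_only_pair(self):
        p = pair([seg("chr2", 100, 250)], [seg("chr2", 400, 550)])
        assert classify_read_pair(p) is ReadClass.INVALID_GENOME_ONLY

    def test_tdna_only_pair(self):
        p = pair([seg(TDNA_CONTIG, 10, 160)], [seg(TDNA_CONTIG, 300, 450)])
        assert classify_read_pair(p) is ReadClass.INVALID_TDNA_ONLY

    def test_split_on_r2(self):
        p = pair(
            [seg("chr1", 900, 1050)],
            [seg(TDNA_CONTIG, 0, 70, read_start=0), seg("chr1", 1050, 1130, read_start=70)],
        )
        assert classify_read_pair(p) is ReadClass.SPLIT

    def test_discordant_pair(self):
        p = pair([seg("chr1", 900, 1050)], [seg(TDNA_CONTIG, 100, 250)])
        assert classify_read_pair(p) is ReadClass.DISCORDANT

    @pytest.mark.parametrize("non_overlap", list(range(1, 51)))
    def test_split_validity_threshold(self, non_overlap):
        """Split validity requires >= 20 bp exclusive coverage per segment."""
        p = pair(
            [
                seg("chr1", 1000, 1100, read_start=0, read_end=100),
                seg(TDNA_CONTIG, 0, non_overlap, read_start=100, read_end=100 + non_overlap),
            ],
            [seg(TDNA_CONTIG, 100, 250)],
        )
        if non_overlap >= 20:
            assert classify_read_pair(p) is ReadClass.SPLIT
        else:
            assert classify_read_pair(p) is not ReadClass.SPLIT

    def test_three_segments_give_no_split(self):
        segs = [
            seg("chr1", 1000, 1060, read_start=0, read_end=60),
            seg(TDNA_CONTIG, 0, 50, read_start=60, read_end=110),
            seg("chr2", 5000, 5040, read_start=110, read_end=150),
        ]
        p = pair(segs, [seg(TDNA_CONTIG, 100, 250)])
        assert classify_read_pair(p) is not ReadClass.SPLIT


class TestJunctionFromSplit:
    def test_canonical_left_lb_forward(self, toy_construct):
        p = pair(
            [seg("chr1", 4900, 5000, strand="+", read_start=0, read_end=100),
             seg(TDNA_CONTIG, 0, 50, strand="+", read_start=100, read_end=150)],
            [],
        )
        ev = junction_from_split(p, toy_construct)
        assert (ev.ref_side, ev.breakpoint, ev.border, ev.direction) == ("Left", 5000, "LB", "Forward")
        assert ev.label == "Left&LB&Forward"

    def test_reverse_tdna_strand_flips_direction(self, toy_construct):
        p = pair(
            [seg("chr1", 4900, 5000, strand="+", read_start=0, read_end=100),
             seg(TDNA_CONTIG, 0, 50, strand="-", read_start=100, read_end=150)],
            [],
        )
        ev = junction_from_split(p, toy_construct)
        assert ev.label == "Left&LB&Reverse"

    def test_right_rb_forward(self, toy_construct):
        L = toy_construct.length
        p = pair(
            [seg(TDNA_CONTIG, L - 70, L, strand="+", read_start=0, read_end=70),
             seg("chr1", 5000, 5080, strand="+", read_start=70, read_end=150)],
            [],
        )
        ev = junction_from_split(p, toy_construct)
        assert (ev.ref_side, ev.breakpoint) == ("Right", 5001)
        assert ev.label == "Right&RB&Forward"

    def test_geometry_sweep_is_exhaustive_and_layout_invariant(
        self, toy_genome, toy_construct, toy_index
    ):
        """Every junction geometry, realized as an actual read in both
        orientations, yields its own label; the sweep emits exactly the
        8-type vocabulary and the label ignores read orientation."""
        from tislocate.construct import revcomp

        labels = set()
        for side, border, direction in all_junction_geometries():
            read = make_junction_read(side, border, direction, toy_genome["chr1"], toy_construct)
            per_geometry = set()
            for oriented in (read, revcomp(read)):
                for mate_layout in ("R1", "R2"):
                    segs = align_read(oriented, toy_index, read_id="g", mate=mate_layout)
                    p = (pair(segs, []) if mate_layout == "R1" else pair([], segs))
                    ev = junction_from_split(p, toy_construct)
                    assert ev is not None
                    per_geometry.add(ev.label)
            assert len(per_geometry) == 1, (side, border, direction, per_geometry)
            labels.add(per_geometry.pop())
        assert labels == set(enumerate_insertion_types())


class TestEnumerate:
    def test_vocabulary(self):
        labels = enumerate_insertion_types()
        assert len(labels) == 8
        assert labels[0] == "Left&LB&Forward"
        assert len(set(labels)) == 8


def ev(bp, kind="split", sig=None, read_id="r1", chrom="chr1", side="Left",
       border="LB", direction="Forward", mism=0, cosites=()):
    return JunctionEvidence(
        read_id=read_id, chrom=chrom, breakpoint=bp, ref_side=side, border=border,
        direction=direction, tdna_pos=1, kind=kind,
        fragment_sig=sig or (chrom, bp - 100, "+"), n_mismatches=mism,
        cosites=tuple(cosites),
    )


class TestDedupe:
    def test_same_fragment_signature_collapses(self):
        a = ev(5000, sig=("chr1", 153, "+"), read_id="a")
        b = ev(5000, sig=("chr1", 153, "+"), read_id="b")
        assert dedupe_evidence([a, b]) == [a]

    def test_distinct_cut_sites_kept(self):
        a = ev(5000, sig=("chr1", 153, "+"), read_id="a")
        b = ev(5000, sig=("chr1", 187, "+"), read_id="b")
        assert len(dedupe_evidence([a, b])) == 2

    def test_fewest_mismatches_wins(self):
        a = ev(5000, sig=("chr1", 153, "+"), read_id="a", mism=2)
        b = ev(5000, sig=("chr1", 153, "+"), read_id="b", mism=0)
        assert dedupe_evidence([a, b]) == [b]

    def test_empty(self):
        assert dedupe_evidence([]) == []


class TestCluster:
    def test_five_splits_one_call(self):
        evs = [ev(5000, read_id=f"r{i}", sig=("chr1", i, "+")) for i in range(5)]
        (call,) = cluster_calls(evs, "s")
        assert (call.breakpoint, call.split_supportN, call.discort_supportN) == (5000, 5, 0)

    def test_one_split_three_discordant_kept(self):
        evs = [ev(5000, read_id="s0", sig=("chr1", 0, "+"))] + [
            ev(4900, kind="discordant", read_id=f"d{i}", sig=("chr1", 10 + i, "+"))
            for i in range(3)
        ]
        (call,) = cluster_calls(evs, "s")
        assert call.breakpoint == 5000
        assert (call.split_supportN, call.discort_supportN) == (1, 3)

    def test_single_split_filtered(self):
        assert cluster_calls([ev(5000)], "s") == []

    def test_discordant_only_cluster_is_imprecise(self):
        evs = [
            ev(4900 + i, kind="discordant", read_id=f"d{i}", sig=("chr1", i, "+"))
            for i in range(4)
        ]
        (call,) = cluster_calls(evs, "s")
        assert call.imprecise and call.split_supportN == 0

    def test_modal_breakpoint_tie_takes_smallest(self):
        evs = [ev(5000, read_id="a", sig=("chr1", 1, "+")),
               ev(5002, read_id="b", sig=("chr1", 2, "+"))]
        (call,) = cluster_calls(evs, "s")
        assert call.breakpoint == 5000

    def test_adding_reads_never_removes_calls(self):
        base = [ev(5000, read_id=f"r{i}", sig=("chr1", i, "+")) for i in range(3)]
        extra = base + [ev(9000, read_id="x", sig=("chr1", 999, "+"))]
        bps_base = {c.breakpoint for c in cluster_calls(base, "s")}
        bps_more = {c.breakpoint for c in cluster_calls(dedupe_evidence(extra), "s")}
        assert bps_base <= bps_more


def call(bp, side="Left", chrom="chr1", border="LB", direction="Forward",
         ns=3, nd=0, ambiguous=()):
    return TISCall(
        sample="s", chrom=chrom, breakpoint=bp, ref_side=side, border=border,
        direction=direction, split_supportN=ns, discort_supportN=nd,
        ambiguous_sites=tuple(ambiguous),
    )


class TestControlSubtraction:
    def test_within_radius_removed(self):
        kept = subtract_control([call(777, chrom="chr3")], [call(780, chrom="chr3")], radius=10)
        assert kept == []

    def test_no_controls_identity(self):
        calls = [call(777)]
        assert subtract_control(calls, []) == calls

    def test_disjoint_control_removes_nothing(self):
        calls = [call(777)]
        assert subtract_control(calls, [call(9999)]) == calls


class TestPairFullTis:
    def test_clean_junction_zero_deletion(self):
        full, unpaired = pair_full_tis([call(5000, "Left"), call(5001, "Right")])
        assert unpaired == []
        assert full[0].target_deletion_bp == 0

    def test_thirty_bp_deletion(self):
        full, _ = pair_full_tis([call(5000, "Left"), call(5031, "Right", border="RB")])
        assert full[0].target_deletion_bp == 30
        assert full[0].pattern == "Left&LB&Forward + Right&RB&Forward"

    def test_unpaired_left_beyond_window(self):
        full, unpaired = pair_full_tis([call(5000, "Left"), call(9000, "Right")])
        assert full == []
        assert {c.breakpoint for c in unpaired} == {5000, 9000}


class TestResolveMultimap:
    def test_ambiguous_call_keeps_all_candidates(self):
        c = call(5000, ambiguous=(("chr2", 1000), ("chr3", 2000), ("chr4", 3000)))
        (out,) = resolve_multimap([c])
        assert out.is_ambiguous and len(out.ambiguous_sites) == 3

    def test_unambiguous_unchanged(self):
        c = call(5000)
        assert resolve_multimap([c]) == [c]

    def test_cluster_unions_member_cosites(self):
        evs = [
            ev(5000, read_id="a", sig=("chr1", 1, "+"), cosites=(("chr2", 100),)),
            ev(5000, read_id="b", sig=("chr1", 2, "+"), cosites=(("chr3", 200),)),
        ]
        (c,) = cluster_calls(evs, "s")
        assert set(c.ambiguous_sites) == {("chr2", 100), ("chr3", 200)}
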