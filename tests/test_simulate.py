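"""Simulator: genomes, insertion events, truth records and libraries."""

import pytest

from tislocate.construct import GenomeInterval, TDNA_CONTIG, revcomp
from tislocate.simulate import (
    InsertionEvent,
    LibraryParams,
    SimulationError,
    event_labels,
    implant_insertions,
    make_scenario,
    simulate_genome,
    simulate_capture_library,
    write_fastq,
)


class TestSimulateGenome:
    def test_seed_determinism(self):
        a = simulate_genome(2, [5000, 5000], 0.4, seed=1)
        b = simulate_genome(2, [5000, 5000], 0.4, seed=1)
        assert a == b
        assert list(a) == ["chr1", "chr2"]

    def test_gc_extremes(self):
        pure = simulate_genome(1, [500], gc=1.0, seed=3)["chr1"]
        assert set(pure) <= {"G", "C"}

    def test_invalid_inputs(self):
        with pytest.raises(SimulationError):
            simulate_genome(0, [], seed=1)
        with pytest.raises(SimulationError):
            simulate_genome(1, [-5], seed=1)


class TestImplant:
    def test_ideal_forward_event(self, toy_genome, toy_construct):
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000))
        res = implant_insertions(toy_genome, toy_construct, [ev])
        (t,) = res.truth
        assert (t.left_label, t.right_label) == ("Left&LB&Forward", "Right&RB&Forward")
        assert t.detectable_left and t.detectable_right
        assert (t.left_breakpoint, t.right_breakpoint) == (5000, 5001)
        assert t.target_deletion_bp == 0
        mod = res.contigs["chr1"]
        assert len(mod) == 10_000 + toy_construct.length
        assert mod[5000 : 5000 + toy_construct.length] == toy_construct.tdna_seq

    def test_truncation_removes_bridge_site(self, toy_genome, toy_construct):
        cut = toy_construct.lb_bridge.pos + 1  # LB bridge falls off
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000), lb_truncation=cut)
        res = implant_insertions(toy_genome, toy_construct, [ev])
        (t,) = res.truth
        assert not t.detectable_left
        assert t.detectable_right

    def test_head_to_head_concatemer_labels(self):
        """A Forward-then-Reverse dimer exposes LB at both outer junctions."""
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000), units=("F", "R"))
        assert event_labels(ev) == ("Left&LB&Forward", "Right&LB&Reverse")

    def test_reverse_single_unit_labels(self):
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000), units=("R",))
        assert event_labels(ev) == ("Left&RB&Reverse", "Right&LB&Reverse")

    def test_deletion_and_filler_accounting(self, toy_genome, toy_construct):
        ev = InsertionEvent(
            "e1", GenomeInterval("chr1", 5000, 5030),
            filler_left="AAAA", filler_right="TTTTT",
        )
        res = implant_insertions(toy_genome, toy_construct, [ev])
        (t,) = res.truth
        assert t.target_deletion_bp == 30
        assert len(res.contigs["chr1"]) == 10_000 - 30 + toy_construct.length + 9

    def test_overlapping_events_rejected(self, toy_genome, toy_construct):
        evs = [
            InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000)),
            InsertionEvent("e2", GenomeInterval("chr1", 5500, 5500)),
        ]
        with pytest.raises(SimulationError, match="overlap"):
            implant_insertions(toy_genome, toy_construct, evs)

    def test_event_past_contig_end_rejected(self, toy_genome, toy_construct):
        ev = InsertionEvent("e1", GenomeInterval("chr1", 9990, 10_050))
        with pytest.raises(SimulationError, match="outside"):
            implant_insertions(toy_genome, toy_construct, [ev])


class TestLibrary:
    def test_wild_type_library_has_no_tdna_reads(self, toy_genome, toy_construct):
        res = implant_insertions(toy_genome, toy_construct, [])
        lib = simulate_capture_library(res, toy_construct, LibraryParams(seed=9, n_background=50))
        assert lib.n_junction == 0
        for rec in lib.reads:
            for seg in rec.segs1 + rec.segs2:
                assert seg.contig != TDNA_CONTIG

    def test_seed_determinism_byte_identical(self, tmp_path, small_scenario):
        scen = small_scenario
        paths = []
        for tag in ("a", "b"):
            lib = simulate_capture_library(scen.implant, scen.construct, scen.params)
            r1, r2 = tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq"
            write_fastq(lib, r1, r2)
            paths.append((r1.read_bytes(), r2.read_bytes()))
        assert paths[0] == paths[1]

    def test_fragment_bookkeeping(self, small_scenario, small_library):
        lib = small_library
        assert len(lib.reads) == lib.n_background + lib.n_junction

    def test_r2_starts_at_bridge_site_toward_border(self, toy_genome, toy_construct):
        """Junction-amplicon read 2 begins with construct sequence from the
        bridge site, oriented toward its border repeat."""
        c = toy_construct
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000))
        res = implant_insertions(toy_genome, c, [ev])
        lib = simulate_capture_library(res, c, LibraryParams(seed=4, n_background=0))
        lb_expect = revcomp(c.tdna_seq[: c.lb_bridge.pos + 1])[:40]
        rb_expect = c.tdna_seq[c.rb_bridge.pos :][:40]
        assert lib.reads
        for rec in lib.reads:
            tag = rec.read_id.split(":")[1]
            if tag.startswith("e1L"):
                assert rec.r2.startswith(lb_expect)
            else:
                assert rec.r2.startswith(rb_expect)

    def test_duplicates_share_fragment_coordinates(self, toy_genome, toy_construct):
        ev = InsertionEvent("e1", GenomeInterval("chr1", 5000, 5000))
        res = implant_insertions(toy_genome, toy_construct, [ev])
        lib = simulate_capture_library(
            res, toy_construct,
            LibraryParams(seed=4, n_background=0, duplicate_rate=1.0),
        )
        assert lib.n_duplicates > 0
        by_seq = {}
        for rec in lib.reads:
            by_seq.setdefault((rec.r1, rec.r2), []).append(rec.read_id)
        assert any(len(v) > 1 for v in by_seq.values())

    def test_invalid_params(self):
        with pytest.raises(SimulationError):
            LibraryParams(read_len=1000, fragment_len=(150, 900))
        with pytest.raises(SimulationError):
            LibraryParams(substitution_rate=0.5)


class TestScenario:
    def test_truth_sam_matches_truth_records(self, small_scenario, small_library):
        """Oracle alignments fed to the caller reproduce the truth exactly
        (checked end-to-end in the acceptance suite; here: labels exist)."""
        scen = small_scenario
        labels = {t.left_label for t in scen.implant.truth}
        labels |= {t.right_label for t in scen.implant.truth}
        vocab = {f"{s}&{b}&{d}" for s in ("Left", "Right") for b in ("LB", "RB")
                 for d in ("Forward", "Reverse")}
        assert labels <= vocab

    def test_scenario_reproducible(self):
        a = make_scenario(13, contig_len=30_000)
        b = make_scenario(13, contig_len=30_000)
        assert a.genome == b.genome
        assert [e for e in a.events] == [e for e in b.events]
        assert a.construct.tdna_seq == b.construct.tdna_seq
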