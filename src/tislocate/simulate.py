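"""Synthetic genomes, T-DNA integration events and tagmentation libraries.

The generator emulates the bridge-primer capture chemistry: every informative
amplicon runs from a bridge-primer site inside the construct, across the
(possibly truncated) border repeat and the integration junction, to a random
Tn5 cut site in the flanking genome.  Read 2 starts at the bridge site and
reads toward the border; read 1 starts at the Tn5 cut and reads inward.  With
the default bridge-to-border distance (150-200 bp) and PE150 reads, read 2
rarely sequences through the junction, so split evidence typically comes from
read 1 when the cut lands within a read length of the junction; all other
junction fragments yield discordant pairs.  PCR size bias toward short
amplicons is emulated by drawing a fixed quota of each junction's capturable
fragments from the short-amplicon regime, which guarantees sequence-through
coverage of every detectable junction.

Every read carries oracle alignments (the true source segments of its bases),
writable as a truth SAM, and every event a :class:`TruthRecord` with
breakpoints on the *original* genome coordinates — the same coordinates the
caller reports, since alignment is against the unmodified genome plus the
construct contig.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import SegmentAlignment, write_sam
from .construct import (
    ConstructModel,
    BridgeSite,
    GenomeInterval,
    MergedReference,
    TDNA_CONTIG,
    build_merged_reference,
    revcomp,
    write_fasta,
)

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: canonical 19 bp Tn5 mosaic-end sequence, optionally left on read 1
ME_SEQ = "AGATGTGTATAAGAGACAG"


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    n_contigs: int, lengths: Sequence[int], gc: float = 0.4, seed: int = 0
) -> dict[str, str]:
    """Simulate a random genome; contigs are named chr1..chrN.

    Deterministic for a fixed seed.  GC content sets the base composition;
    lengths of at least ~10 kb are recommended so that k-mer seeds are
    effectively unique.
    """
    if n_contigs < 1:
        raise SimulationError("n_contigs must be >= 1")
    if len(lengths) != n_contigs:
        raise SimulationError("one length per contig required")
    if any(l <= 0 for l in lengths):
        raise SimulationError("contig lengths must be positive")
    if not (0.0 <= gc <= 1.0):
        raise SimulationError("gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for i, length in enumerate(lengths, start=1):
        out[f"chr{i}"] = "".join(rng.choice(BASES, size=length, p=p))
    return out


def random_construct(
    seed: int = 0, length: int = 2400, repeat_len: int = 25, gc: float = 0.45
) -> ConstructModel:
    """A random construct with border repeats at the ends and bridge sites
    drawn 150-200 bp interior of each repeat (the recommended primer design
    distance)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(BASES, size=length, p=p))
    d_lb = int(rng.integers(150, 201))
    d_rb = int(rng.integers(150, 201))
    return ConstructModel(
        name=f"sim_construct_{seed}",
        tdna_seq=seq,
        lb_repeat=(0, repeat_len),
        rb_repeat=(length - repeat_len, length),
        lb_bridge=BridgeSite(pos=repeat_len + d_lb - 1, strand="-"),
        rb_bridge=BridgeSite(pos=length - repeat_len - d_rb, strand="+"),
    )


# ---------------------------------------------------------------------------
# Insertion events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionEvent:
    """One T-DNA integration event.

    ``units`` lists the orientation of each tandem construct unit in genomic
    left-to-right order ("F" forward, "R" reverse).  ``lb_truncation`` /
    ``rb_truncation`` remove bases from the payload end exposing the LB / RB
    border (for a single forward unit: the left / right edge); when a border
    is exposed at both outer ends the value applies to both.  ``filler_left``
    and ``filler_right`` are untemplated sequences at the two junctions.  The
    target interval is deleted from the genome and replaced by
    filler_left + payload + filler_right.
    """

    event_id: str
    target: GenomeInterval
    units: tuple[str, ...] = ("F",)
    lb_truncation: int = 0
    rb_truncation: int = 0
    filler_left: str = ""
    filler_right: str = ""

    def __post_init__(self) -> None:
        if not self.units or any(u not in ("F", "R") for u in self.units):
            raise SimulationError(f"{self.event_id}: units must be a list of F/R")
        if self.lb_truncation < 0 or self.rb_truncation < 0:
            raise SimulationError(f"{self.event_id}: truncations must be >= 0")

    @property
    def orientation(self) -> str:
        return "Forward" if self.units[0] == "F" else "Reverse"

    def outer_borders(self) -> tuple[str, str]:
        """Borders exposed at the (left, right) outer ends of the payload."""
        left = "LB" if self.units[0] == "F" else "RB"
        right = "RB" if self.units[-1] == "F" else "LB"
        return left, right

    def outer_truncations(self) -> tuple[int, int]:
        left_b, right_b = self.outer_borders()
        left = self.lb_truncation if left_b == "LB" else self.rb_truncation
        right = self.rb_truncation if right_b == "RB" else self.lb_truncation
        return left, right


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one event, on original genome coordinates (1-based)."""

    event_id: str
    chrom: str
    left_breakpoint: int
    right_breakpoint: int
    left_label: str
    right_label: str
    detectable_left: bool
    detectable_right: bool

    @property
    def target_deletion_bp(self) -> int:
        return self.right_breakpoint - self.left_breakpoint - 1


@dataclass(frozen=True)
class LayoutPiece:
    """Mapping of a modified-contig interval back to its source sequence.

    ``src`` is an original genome contig, the construct contig, or None for
    untemplated filler.  For strand '+', source position = ``a`` + offset
    from ``mod_start``; for '-', ``a`` - offset.
    """

    mod_start: int
    mod_end: int
    src: str | None
    a: int
    strand: str


@dataclass
class EventPlacement:
    """Modified-coordinate geometry of one implanted event."""

    event: InsertionEvent
    chrom: str
    ins_mod_start: int  # junction with the left genome flank
    ins_mod_end: int  # junction with the right genome flank
    left_bridge_mod: int | None  # modified coordinate of the facing bridge site
    right_bridge_mod: int | None
    truth: TruthRecord


@dataclass
class ImplantResult:
    contigs: dict[str, str]
    truth: list[TruthRecord]
    layout: dict[str, list[LayoutPiece]]
    placements: list[EventPlacement]


def _payload_pieces(
    event: InsertionEvent, construct: ConstructModel
) -> list[tuple[str, int, int]]:
    """Oriented, truncated payload as (strand, tdna_lo, tdna_hi) pieces."""
    L = construct.length
    pieces = [("+" if u == "F" else "-", 0, L) for u in event.units]
    left_t, right_t = event.outer_truncations()
    if left_t >= L or right_t >= L:
        raise SimulationError(f"{event.event_id}: truncation exceeds the construct length")
    s, lo, hi = pieces[0]
    pieces[0] = (s, lo + left_t, hi) if s == "+" else (s, lo, hi - left_t)
    s, lo, hi = pieces[-1]
    pieces[-1] = (s, lo, hi - right_t) if s == "+" else (s, lo + right_t, hi)
    if any(lo >= hi for _, lo, hi in pieces):
        raise SimulationError(f"{event.event_id}: truncations leave an empty payload piece")
    return pieces


def payload_sequence(event: InsertionEvent, construct: ConstructModel) -> str:
    parts = []
    for strand, lo, hi in _payload_pieces(event, construct):
        chunk = construct.tdna_seq[lo:hi]
        parts.append(chunk if strand == "+" else revcomp(chunk))
    return "".join(parts)


def event_labels(event: InsertionEvent) -> tuple[str, str]:
    """The 8-type labels of the event's two junctions, from payload geometry."""
    left_b, right_b = event.outer_borders()
    left_dir = "Forward" if event.units[0] == "F" else "Reverse"
    right_dir = "Forward" if event.units[-1] == "F" else "Reverse"
    return f"Left&{left_b}&{left_dir}", f"Right&{right_b}&{right_dir}"


def _bridge_geometry(
    pieces: list[tuple[str, int, int]], construct: ConstructModel
) -> tuple[bool, int | None, bool, int | None]:
    """Detectability and payload-offset of the bridge site facing each junction."""
    # left junction: first piece
    strand, lo, hi = pieces[0]
    if strand == "+":
        pos = construct.lb_bridge.pos
        left_ok = lo <= pos < hi
        left_off = pos - lo if left_ok else None
    else:
        pos = construct.rb_bridge.pos
        left_ok = lo <= pos < hi
        left_off = (hi - 1 - pos) if left_ok else None
    # right junction: last piece
    base = sum(h - l for _, l, h in pieces[:-1])
    strand, lo, hi = pieces[-1]
    if strand == "+":
        pos = construct.rb_bridge.pos
        right_ok = lo <= pos < hi
        right_off = base + (pos - lo) if right_ok else None
    else:
        pos = construct.lb_bridge.pos
        right_ok = lo <= pos < hi
        right_off = base + (hi - 1 - pos) if right_ok else None
    return left_ok, left_off, right_ok, right_off


def implant_insertions(
    genome: dict[str, str],
    construct: ConstructModel,
    events: Sequence[InsertionEvent],
    min_separation: int = 2000,
) -> ImplantResult:
    """Apply insertion events to a genome, returning the modified genome,
    truth records (original coordinates) and the coordinate layout used by
    the library simulator and the truth-SAM writer."""
    by_chrom: dict[str, list[InsertionEvent]] = {}
    for ev in events:
        if ev.target.contig not in genome:
            raise SimulationError(f"{ev.event_id}: unknown contig {ev.target.contig}")
        n = len(genome[ev.target.contig])
        if ev.target.end > n or ev.target.start < 1:
            raise SimulationError(f"{ev.event_id}: target interval outside the contig")
        by_chrom.setdefault(ev.target.contig, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e.target.start)
        for a, b in zip(evs, evs[1:]):
            if b.target.start - a.target.end < min_separation:
                raise SimulationError(
                    f"events {a.event_id} and {b.event_id} overlap within {min_separation} bp"
                )

    contigs: dict[str, str] = {}
    layout: dict[str, list[LayoutPiece]] = {}
    truth: list[TruthRecord] = []
    placements: list[EventPlacement] = []
    for chrom, seq in genome.items():
        evs = by_chrom.get(chrom, [])
        parts: list[str] = []
        pieces: list[LayoutPiece] = []
        mod = 0
        src = 0
        for ev in evs:
            ts, te = ev.target.start, ev.target.end
            # genome up to the insertion point
            if ts > src:
                parts.append(seq[src:ts])
                pieces.append(LayoutPiece(mod, mod + ts - src, chrom, src, "+"))
                mod += ts - src
            ins_mod_start = mod
            if ev.filler_left:
                parts.append(ev.filler_left)
                pieces.append(LayoutPiece(mod, mod + len(ev.filler_left), None, 0, "+"))
                mod += len(ev.filler_left)
            pp = _payload_pieces(ev, construct)
            for strand, lo, hi in pp:
                chunk = construct.tdna_seq[lo:hi]
                if strand == "+":
                    parts.append(chunk)
                    pieces.append(LayoutPiece(mod, mod + hi - lo, TDNA_CONTIG, lo, "+"))
                else:
                    parts.append(revcomp(chunk))
                    pieces.append(LayoutPiece(mod, mod + hi - lo, TDNA_CONTIG, hi - 1, "-"))
                mod += hi - lo
            if ev.filler_right:
                parts.append(ev.filler_right)
                pieces.append(LayoutPiece(mod, mod + len(ev.filler_right), None, 0, "+"))
                mod += len(ev.filler_right)
            ins_mod_end = mod
            src = te
            left_ok, left_off, right_ok, right_off = _bridge_geometry(pp, construct)
            left_label, right_label = event_labels(ev)
            rec = TruthRecord(
                event_id=ev.event_id, chrom=chrom,
                left_breakpoint=ts, right_breakpoint=te + 1,
                left_label=left_label, right_label=right_label,
                detectable_left=left_ok, detectable_right=right_ok,
            )
            truth.append(rec)
            payload_mod0 = ins_mod_start + len(ev.filler_left)
            placements.append(
                EventPlacement(
                    event=ev, chrom=chrom,
                    ins_mod_start=ins_mod_start, ins_mod_end=ins_mod_end,
                    left_bridge_mod=(payload_mod0 + left_off) if left_ok else None,
                    right_bridge_mod=(payload_mod0 + right_off) if right_ok else None,
                    truth=rec,
                )
            )
        if src < len(seq):
            parts.append(seq[src:])
            pieces.append(LayoutPiece(mod, mod + len(seq) - src, chrom, src, "+"))
            mod += len(seq) - src
        contigs[chrom] = "".join(parts)
        layout[chrom] = pieces
    return ImplantResult(contigs=contigs, truth=truth, layout=layout, placements=placements)


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

@dataclass
class LibraryParams:
    """Parameters of a simulated tagmentation / bridge-capture library."""

    fragment_len: tuple[int, int] = (150, 900)
    read_len: int = 150
    n_capturable_fragments_per_junction: int = 8
    n_background: int = 100
    substitution_rate: float = 0.0
    duplicate_rate: float = 0.1
    seed: int = 0
    include_me: bool = False
    #: true source segments shorter than this are not representable by the
    #: seeded aligner and are soft-clipped in the truth alignments
    min_truth_segment: int = 21
    #: fragments per junction forced into the short-amplicon (sequence-
    #: through) regime; None means max(2, n // 3)
    short_quota: int | None = None
    min_cut_distance: int = 25

    def __post_init__(self) -> None:
        if self.read_len > self.fragment_len[1]:
            raise SimulationError("read_len must not exceed the maximum fragment length")
        if not (0.0 <= self.substitution_rate < 0.1):
            raise SimulationError("substitution_rate must be in [0, 0.1)")


@dataclass
class SimulatedRead:
    read_id: str
    r1: str
    r2: str
    segs1: list[SegmentAlignment]
    segs2: list[SegmentAlignment]


@dataclass
class LibraryResult:
    reads: list[SimulatedRead]
    n_background: int
    n_junction: int
    n_duplicates: int


def _true_segments(
    pieces: list[LayoutPiece],
    mod_lo: int,
    mod_hi: int,
    reverse: bool,
    read_id: str,
    mate: str,
    min_seg: int,
    prefix: int = 0,
) -> list[SegmentAlignment]:
    """Oracle segments of a read covering modified span [mod_lo, mod_hi)."""
    segs = []
    for p in pieces:
        blo, bhi = max(mod_lo, p.mod_start), min(mod_hi, p.mod_end)
        if blo >= bhi or p.src is None:
            continue
        if p.strand == "+":
            src_lo = p.a + (blo - p.mod_start)
            src_hi = p.a + (bhi - p.mod_start)
            strand = "+"
        else:
            src_hi = p.a - (blo - p.mod_start) + 1
            src_lo = p.a - (bhi - 1 - p.mod_start)
            strand = "-"
        if not reverse:
            r_lo, r_hi = blo - mod_lo, bhi - mod_lo
        else:
            r_lo, r_hi = mod_hi - bhi, mod_hi - blo
            strand = "-" if strand == "+" else "+"
        if bhi - blo < min_seg:
            continue
        segs.append(
            SegmentAlignment(
                read_id=read_id, mate=mate, contig=p.src, ref_start=src_lo,
                ref_end=src_hi, strand=strand, read_start=prefix + r_lo,
                read_end=prefix + r_hi,
            )
        )
    segs.sort(key=lambda s: s.read_start)
    if len(segs) > 1:
        segs = [segs[0]] + [replace(s, is_supplementary=True) for s in segs[1:]]
    return segs


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for i in sorted(int(x) for x in pos):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _count_mismatches(seg: SegmentAlignment, read: str, merged: MergedReference) -> int:
    ref = merged.contigs[seg.contig][seg.ref_start : seg.ref_end]
    if seg.strand == "-":
        ref = revcomp(ref)
    sub = read[seg.read_start : seg.read_end]
    return sum(1 for a, b in zip(sub, ref) if a != b)


def simulate_capture_library(
    implant: ImplantResult,
    construct: ConstructModel,
    params: LibraryParams,
    sample: str = "sim",
) -> LibraryResult:
    """Generate the paired-end library for an implanted genome.

    For every detectable junction, ``n_capturable_fragments_per_junction``
    amplicons are emitted from the facing bridge site to a random Tn5 cut
    beyond the junction; a quota of them is drawn from the short-amplicon
    regime so the junction is sequenced through.  Background fragments map
    wholly to the genome.  PCR duplicates re-emit a fragment with the same
    cut site at ``duplicate_rate``.
    """
    rng = np.random.default_rng(params.seed)
    reads: list[SimulatedRead] = []
    serial = 0
    n_dup = 0
    n_junction = 0
    rl = params.read_len
    prefix = ME_SEQ if params.include_me else ""

    def emit(contig: str, fs: int, fe: int, bridge_high: bool | None, tag: str) -> None:
        nonlocal serial
        frag = implant.contigs[contig][fs:fe]
        pieces = implant.layout[contig]
        read_id = f"{sample}:{tag}:{serial:06d}"
        serial += 1
        if bridge_high is None:
            bridge_high = True
        if bridge_high:
            # R1 reads from the low (cut) end, R2 from the high (bridge) end
            r1_core_span = (fs, min(fe, fs + rl - len(prefix)))
            r1 = prefix + frag[: rl - len(prefix)]
            r2 = revcomp(frag)[:rl]
            segs1 = _true_segments(
                pieces, *r1_core_span, reverse=False, read_id=read_id, mate="R1",
                min_seg=params.min_truth_segment, prefix=len(prefix),
            )
            segs2 = _true_segments(
                pieces, max(fs, fe - rl), fe, reverse=True, read_id=read_id, mate="R2",
                min_seg=params.min_truth_segment,
            )
        else:
            r1 = prefix + revcomp(frag)[: rl - len(prefix)]
            r2 = frag[:rl]
            segs1 = _true_segments(
                pieces, max(fs, fe - (rl - len(prefix))), fe, reverse=True,
                read_id=read_id, mate="R1", min_seg=params.min_truth_segment,
                prefix=len(prefix),
            )
            segs2 = _true_segments(
                pieces, fs, min(fe, fs + rl), reverse=False, read_id=read_id, mate="R2",
                min_seg=params.min_truth_segment,
            )
        r1 = _apply_errors(r1, params.substitution_rate, rng)
        r2 = _apply_errors(r2, params.substitution_rate, rng)
        reads.append(SimulatedRead(read_id=read_id, r1=r1, r2=r2, segs1=segs1, segs2=segs2))

    def junction_fragments(
        junction_mod: int, bridge_mod: int, left_side: bool, contig: str, tag: str
    ) -> None:
        nonlocal n_dup, n_junction
        n = params.n_capturable_fragments_per_junction
        quota = params.short_quota
        if quota is None:
            quota = max(2, n // 3)
        quota = min(quota, n)
        tdna_side = (bridge_mod + 1 - junction_mod) if left_side else (junction_mod - bridge_mod)
        contig_len = len(implant.contigs[contig])
        short_lo = params.min_cut_distance
        short_hi = max(short_lo + 1, rl - len(prefix) - 45)
        used_short: set[int] = set()
        for i in range(n):
            if i < quota:
                for _ in range(50):
                    d = int(rng.integers(short_lo, short_hi + 1))
                    if d not in used_short:
                        break
                used_short.add(d)
            else:
                fraglen = int(rng.integers(params.fragment_len[0], params.fragment_len[1] + 1))
                d = max(fraglen - tdna_side, params.min_cut_distance)
            if left_side:
                cut = max(0, junction_mod - d)
                fs, fe, high = cut, bridge_mod + 1, True
            else:
                cut = min(contig_len, junction_mod + d)
                fs, fe, high = bridge_mod, cut, False
            emit(contig, fs, fe, high, tag)
            n_junction += 1
            if rng.random() < params.duplicate_rate:
                emit(contig, fs, fe, high, tag + "d")
                n_dup += 1
                n_junction += 1

    for pl in implant.placements:
        if pl.left_bridge_mod is not None:
            junction_fragments(pl.ins_mod_start, pl.left_bridge_mod, True, pl.chrom,
                               f"{pl.event.event_id}L")
        if pl.right_bridge_mod is not None:
            junction_fragments(pl.ins_mod_end, pl.right_bridge_mod, False, pl.chrom,
                               f"{pl.event.event_id}R")

    # background fragments wholly on the genome
    names = list(implant.contigs)
    lens = np.array([len(implant.contigs[c]) for c in names], dtype=float)
    weights = lens / lens.sum()
    n_bg = 0
    for _ in range(params.n_background):
        c = names[int(rng.choice(len(names), p=weights))]
        fraglen = int(rng.integers(params.fragment_len[0], params.fragment_len[1] + 1))
        fs = int(rng.integers(0, max(1, len(implant.contigs[c]) - fraglen)))
        emit(c, fs, fs + fraglen, bool(rng.random() < 0.5), "bg")
        n_bg += 1
    return LibraryResult(reads=reads, n_background=n_bg, n_junction=n_junction, n_duplicates=n_dup)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(result: LibraryResult, r1_path: str | Path, r2_path: str | Path) -> None:
    """Write the paired library as two FASTQ files (gzip if path ends .gz)."""

    def opener(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for rec in result.reads:
            f1.write(f"@{rec.read_id}/1\n{rec.r1}\n+\n{'I' * len(rec.r1)}\n")
            f2.write(f"@{rec.read_id}/2\n{rec.r2}\n+\n{'I' * len(rec.r2)}\n")


def write_truth_sam(
    result: LibraryResult, merged: MergedReference, path: str | Path
) -> None:
    """Write oracle alignments for every read, with NM computed per segment."""

    def gen():
        for rec in result.reads:
            segs1 = [
                replace(s, n_mismatches=_count_mismatches(s, rec.r1, merged)) for s in rec.segs1
            ]
            segs2 = [
                replace(s, n_mismatches=_count_mismatches(s, rec.r2, merged)) for s in rec.segs2
            ]
            yield rec.read_id, rec.r1, rec.r2, segs1, segs2

    write_sam(path, merged, gen())


TRUTH_TSV_COLUMNS = [
    "event_id", "chrom", "left_breakpoint", "right_breakpoint",
    "left_label", "right_label", "detectable_left", "detectable_right",
]


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_TSV_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.event_id}\t{t.chrom}\t{t.left_breakpoint}\t{t.right_breakpoint}\t"
                f"{t.left_label}\t{t.right_label}\t{int(t.detectable_left)}\t{int(t.detectable_right)}\n"
            )


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

UNIT_PATTERNS: tuple[tuple[str, ...], ...] = (
    ("F",), ("R",), ("F", "R"), ("R", "F"), ("F", "F"), ("R", "R"),
)
UNIT_PATTERN_WEIGHTS = (0.35, 0.35, 0.10, 0.05, 0.10, 0.05)


@dataclass
class Scenario:
    """A complete, self-consistent simulation fixture."""

    seed: int
    genome: dict[str, str]
    construct: ConstructModel
    events: list[InsertionEvent]
    implant: ImplantResult
    params: LibraryParams
    merged: MergedReference


def _walled_filler(
    rng: np.random.Generator, length: int, forbidden: dict[int, set[str]]
) -> str:
    """Random filler whose constrained positions avoid the forbidden bases.

    Junction microhomology is not modeled: the constraints force a mismatch
    wall on both sides of each junction so that ungapped extension stops at
    the true breakpoint and junctions are unambiguous.
    """
    out = []
    for i in range(length):
        bad = forbidden.get(i, set())
        choices = [b for b in "ACGT" if b not in bad]
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def _junction_walls(
    seq: str, ts: int, te: int, pieces: list[tuple[str, int, int]],
    construct: ConstructModel, fl: int, fr: int, wall: int = 3,
) -> tuple[dict[int, set[str]], dict[int, set[str]]]:
    """Forbidden-base maps for the left/right junction fillers."""
    L = construct.length
    tdna = construct.tdna_seq
    forb_left: dict[int, set[str]] = {}
    forb_right: dict[int, set[str]] = {}
    # genome-segment extension rightward across the left junction
    for i in range(min(wall, fl)):
        if ts + i < len(seq):
            forb_left.setdefault(i, set()).add(seq[ts + i])
    # tdna-segment extension leftward past the payload start
    strand, lo, hi = pieces[0]
    for i in range(1, min(wall, fl) + 1):
        if strand == "+" and lo - i >= 0:
            forb_left.setdefault(fl - i, set()).add(tdna[lo - i])
        elif strand == "-" and hi - 1 + i < L:
            forb_left.setdefault(fl - i, set()).add(_COMP[tdna[hi - 1 + i]])
    # tdna-segment extension rightward past the payload end
    strand, lo, hi = pieces[-1]
    for i in range(min(wall, fr)):
        if strand == "+" and hi + i < L:
            forb_right.setdefault(i, set()).add(tdna[hi + i])
        elif strand == "-" and lo - 1 - i >= 0:
            forb_right.setdefault(i, set()).add(_COMP[tdna[lo - 1 - i]])
    # genome-segment extension leftward across the right junction
    for i in range(1, min(wall, fr) + 1):
        if te - i >= 0:
            forb_right.setdefault(fr - i, set()).add(seq[te - i])
    return forb_left, forb_right


def random_events(
    rng: np.random.Generator,
    genome: dict[str, str],
    construct: ConstructModel,
    n_events: int,
    margin: int = 3000,
    spacing: int = 3000,
    max_deletion: int = 50,
    truncation_prob: float = 0.3,
) -> list[InsertionEvent]:
    """Random insertion events covering the junction-type vocabulary.

    Positions keep ``margin`` from contig ends and ``spacing`` between events;
    junction fillers (3-20 bp) are built with mismatch walls so breakpoints
    are unambiguous (microhomology is not modeled).
    """
    chroms = list(genome)
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    events = []
    for j in range(n_events):
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            seq = genome[chrom]
            if len(seq) < 2 * margin + spacing:
                continue
            ts = int(rng.integers(margin, len(seq) - margin))
            if all(abs(ts - p) >= spacing for p in placed[chrom]):
                break
        else:  # pragma: no cover - only with absurdly crowded genomes
            raise SimulationError("could not place events with the required spacing")
        placed[chrom].append(ts)
        units = UNIT_PATTERNS[
            int(rng.choice(len(UNIT_PATTERNS), p=np.array(UNIT_PATTERN_WEIGHTS)))
        ]
        deletion = int(rng.integers(0, max_deletion + 1))
        te = ts + deletion
        lb_t = int(rng.integers(40, 400)) if rng.random() < truncation_prob else 0
        rb_t = int(rng.integers(40, 400)) if rng.random() < truncation_prob else 0
        probe = InsertionEvent(
            event_id=f"ev{j + 1}", target=GenomeInterval(chrom, ts, te),
            units=units, lb_truncation=lb_t, rb_truncation=rb_t,
        )
        pieces = _payload_pieces(probe, construct)
        fl = int(rng.integers(3, 21))
        fr = int(rng.integers(3, 21))
        forb_left, forb_right = _junction_walls(seq, ts, te, pieces, construct, fl, fr)
        events.append(
            replace(
                probe,
                filler_left=_walled_filler(rng, fl, forb_left),
                filler_right=_walled_filler(rng, fr, forb_right),
            )
        )
    return events


def make_scenario(
    seed: int,
    n_contigs: int = 2,
    contig_len: int = 100_000,
    n_events: int | None = None,
    substitution_rate: float = 0.0,
    n_fragments_per_junction: int = 8,
    n_background: int = 100,
) -> Scenario:
    """Build a full simulation fixture: genome, construct, events, library
    parameters and the merged reference the caller aligns against."""
    rng = np.random.default_rng(seed)
    sub = [int(x) for x in rng.integers(0, 2**31 - 1, size=4)]
    genome = simulate_genome(n_contigs, [contig_len] * n_contigs, gc=0.4, seed=sub[0])
    construct = random_construct(seed=sub[1])
    if n_events is None:
        n_events = int(rng.integers(1, 4))
    events = random_events(np.random.default_rng(sub[2]), genome, construct, n_events)
    implant = implant_insertions(genome, construct, events)
    params = LibraryParams(
        seed=sub[3],
        substitution_rate=substitution_rate,
        n_capturable_fragments_per_junction=n_fragments_per_junction,
        n_background=n_background,
    )
    merged = build_merged_reference(genome, construct)
    return Scenario(
        seed=seed, genome=genome, construct=construct, events=events,
        implant=implant, params=params, merged=merged,
    )


def detectable_junctions(truth: Sequence[TruthRecord]) -> list[tuple[str, int, str]]:
    """(chrom, breakpoint, label) for every detectable junction in truth."""
    out = []
    for t in truth:
        if t.detectable_left:
            out.append((t.chrom, t.left_breakpoint, t.left_label))
        if t.detectable_right:
            out.append((t.chrom, t.right_breakpoint, t.right_label))
    return out
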