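"""Alignment layer: a small seed-and-extend aligner and SAM interop.

Two routes produce the per-read segment alignments the caller consumes:

* :func:`align_read` — an exact-k-mer seeded, ungapped (mismatches only)
  chimeric aligner adequate for simulated and small references.  At most two
  segments are emitted per read, mirroring the split-read extraction cap used
  with external tools; equally-best loci are kept as ``cohits`` so downstream
  code can flag multi-mapping calls instead of dropping them.
* :func:`read_alignment_file` — parse externally produced SAM/BAM (e.g. from
  bwa-mem) into the same segment records, using primary plus supplementary
  records; secondary alignments are ignored.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

from .construct import GenomeInterval, MergedReference, revcomp

logger = logging.getLogger(__name__)

# scoring for ungapped extension; mismatches are penalised strongly so that
# extension stops at junctions into foreign sequence instead of running
# through them
MATCH_SCORE = 1
MISMATCH_SCORE = -3
XDROP = 12

#: a second segment is attempted when at least this many bases remain
#: unaligned at a read end (the split-validity non-overlap threshold)
MIN_REMAINDER = 20


@dataclass(frozen=True)
class SegmentAlignment:
    """One ungapped aligned segment of one mate.

    ``read_start``/``read_end`` are 0-based half-open offsets on the original
    (as sequenced) read; ``ref_start``/``ref_end`` on the reference contig.
    ``cohits`` lists equally-scoring alternative loci as (contig, ref_start,
    strand) triples.
    """

    read_id: str
    mate: str  # "R1" | "R2"
    contig: str
    ref_start: int
    ref_end: int
    strand: str  # "+" | "-"
    read_start: int
    read_end: int
    n_mismatches: int = 0
    is_supplementary: bool = False
    cohits: tuple[tuple[str, int, str], ...] = ()

    @property
    def ref_interval(self) -> GenomeInterval:
        return GenomeInterval(self.contig, self.ref_start, self.ref_end, self.strand)

    @property
    def read_length_aligned(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ReadPairAlignment:
    """All aligned segments of one read pair, grouped per mate."""

    read_id: str
    segments_r1: list[SegmentAlignment] = field(default_factory=list)
    segments_r2: list[SegmentAlignment] = field(default_factory=list)

    def mate_segments(self, mate: str) -> list[SegmentAlignment]:
        return self.segments_r1 if mate == "R1" else self.segments_r2


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Exact k-mer -> (contig, position) lookup over the forward reference.

    Reads are queried in both orientations, which covers both reference
    strands without storing a reverse-strand copy.
    """

    def __init__(self, ref: MergedReference, k: int = 21):
        if k % 2 == 0 or not (11 <= k <= 31):
            raise ValueError(f"k must be odd and in [11, 31], got {k}")
        self.k = k
        self.ref = ref
        self.contigs: dict[str, str] = ref.contigs
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in ref.contigs.items():
            if len(seq) < k:
                logger.warning("contig %s shorter than k=%d, skipped from index", name, k)
                continue
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))
        self._index = dict(self._index)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def n_positions(self) -> int:
        return sum(len(v) for v in self._index.values())


def build_index(ref: MergedReference, k: int = 21) -> SeedIndex:
    """Build the exact k-mer seed index over a merged reference."""
    return SeedIndex(ref, k=k)


# ---------------------------------------------------------------------------
# Seed-and-extend alignment
# ---------------------------------------------------------------------------

def _extend(seq: str, ref: str, diag: int, seed_lo: int, seed_hi: int) -> tuple[int, int, int, int]:
    """X-drop ungapped extension of an exact seed along one diagonal.

    Returns (lo, hi, score, mismatches) with [lo, hi) offsets on ``seq``.
    The extension is trimmed to the maximal-scoring point nearest the seed,
    so a chance match beyond a mismatch wall does not creep the boundary out.
    """
    n, m = len(seq), len(ref)
    # extend right of the seed
    cur = 0
    best_delta = 0
    best_right = 0
    i = seed_hi
    while i < n and diag + i < m:
        cur += MATCH_SCORE if seq[i] == ref[diag + i] else MISMATCH_SCORE
        i += 1
        if cur > best_delta:
            best_delta = cur
            best_right = i - seed_hi
        elif best_delta - cur > XDROP:
            break
    hi = seed_hi + best_right
    # extend left of the seed
    cur = 0
    best_delta = 0
    best_left = 0
    i = seed_lo - 1
    while i >= 0 and diag + i >= 0:
        cur += MATCH_SCORE if seq[i] == ref[diag + i] else MISMATCH_SCORE
        if cur > best_delta:
            best_delta = cur
            best_left = seed_lo - i
        elif best_delta - cur > XDROP:
            break
        i -= 1
    lo = seed_lo - best_left
    mism = sum(1 for j in range(lo, hi) if seq[j] != ref[diag + j])
    score = (hi - lo - mism) * MATCH_SCORE + mism * MISMATCH_SCORE
    return lo, hi, score, mism


def _align_single(
    read: str, index: SeedIndex, max_mismatch_frac: float
) -> list[tuple[str, int, int, str, int, int, int, int]]:
    """Best ungapped alignment(s) of ``read`` (one segment).

    Returns the best-scoring hits (ties included) as tuples
    (contig, ref_start, ref_end, strand, read_start, read_end, score, mism)
    with read offsets on the original orientation of ``read``.
    """
    k = index.k
    n = len(read)
    if n < k:
        return []
    hits: list[tuple[str, int, int, str, int, int, int, int]] = []
    for strand in ("+", "-"):
        seq = read if strand == "+" else revcomp(read)
        # candidate diagonals: (contig, ref_start_of_read_origin)
        diags: dict[tuple[str, int], int] = {}
        for off in range(0, n - k + 1):
            for contig, pos in index.lookup(seq[off : off + k]):
                key = (contig, pos - off)
                if key not in diags:
                    diags[key] = off
        for (contig, diag), off in sorted(diags.items()):
            ref = index.contigs[contig]
            lo, hi, score, mism = _extend(seq, ref, diag, off, off + k)
            if mism > max_mismatch_frac * (hi - lo):
                continue
            if strand == "+":
                r_lo, r_hi = lo, hi
            else:
                r_lo, r_hi = n - hi, n - lo
            hits.append((contig, diag + lo, diag + hi, strand, r_lo, r_hi, score, mism))
    if not hits:
        return []
    best = max(h[6] for h in hits)
    top = [h for h in hits if h[6] == best]
    # collapse duplicates (same locus reachable from several seeds)
    top = sorted(set(top), key=lambda h: (h[0], h[1], h[3]))
    return top


def align_read(
    read: str,
    index: SeedIndex,
    max_mismatch_frac: float = 0.05,
    read_id: str = "",
    mate: str = "R1",
) -> list[SegmentAlignment]:
    """Greedy chimeric alignment of one read against the merged reference.

    The best seeded ungapped extension is taken first; if >= 20 bp of the read
    remain unaligned at either end, a second alignment of the remainder is
    attempted.  At most two segments are returned.  Among equally-best loci
    the primary is the lexicographically smallest (contig, position); the
    alternatives are recorded as ``cohits``.
    """
    read = read.upper()
    top = _align_single(read, index, max_mismatch_frac)
    if not top:
        return []
    primary = top[0]
    cohits = tuple((h[0], h[1], h[3]) for h in top[1:])
    contig, rs, re_, strand, q_lo, q_hi, _score, mism = primary
    segments = [
        SegmentAlignment(
            read_id=read_id, mate=mate, contig=contig, ref_start=rs, ref_end=re_,
            strand=strand, read_start=q_lo, read_end=q_hi, n_mismatches=mism,
            is_supplementary=False, cohits=cohits,
        )
    ]
    # second segment from the longer unaligned flank (split-read cap of 2)
    flanks = []
    if q_lo >= MIN_REMAINDER:
        flanks.append((0, q_lo))
    if len(read) - q_hi >= MIN_REMAINDER:
        flanks.append((q_hi, len(read)))
    best_second = None
    for f_lo, f_hi in flanks:
        sub = read[f_lo:f_hi]
        cand = _align_single(sub, index, max_mismatch_frac)
        if not cand:
            continue
        c = cand[0]
        if best_second is None or c[6] > best_second[0][6]:
            best_second = (c, f_lo, tuple((h[0], h[1], h[3]) for h in cand[1:]))
    if best_second is not None:
        c, f_lo, co2 = best_second
        contig2, rs2, re2, strand2, s_lo, s_hi, _sc2, mism2 = c
        segments.append(
            SegmentAlignment(
                read_id=read_id, mate=mate, contig=contig2, ref_start=rs2, ref_end=re2,
                strand=strand2, read_start=f_lo + s_lo, read_end=f_lo + s_hi,
                n_mismatches=mism2, is_supplementary=True, cohits=co2,
            )
        )
    segments.sort(key=lambda s: s.read_start)
    return segments


def align_pair(
    r1: str, r2: str, index: SeedIndex, read_id: str, max_mismatch_frac: float = 0.05
) -> ReadPairAlignment:
    """Align both mates of a pair."""
    return ReadPairAlignment(
        read_id=read_id,
        segments_r1=align_read(r1, index, max_mismatch_frac, read_id=read_id, mate="R1"),
        segments_r2=align_read(r2, index, max_mismatch_frac, read_id=read_id, mate="R2"),
    )


# ---------------------------------------------------------------------------
# SAM interop
# ---------------------------------------------------------------------------

def sam_header(ref: MergedReference) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in ref.contigs.items()],
    }


def write_sam(
    path: str | Path,
    ref: MergedReference,
    pairs: Iterable[tuple[str, str, str, list[SegmentAlignment], list[SegmentAlignment]]],
) -> None:
    """Write read pairs with their segment alignments to SAM.

    ``pairs`` yields (read_id, seq_r1, seq_r2, segments_r1, segments_r2).
    The first segment of each mate is written as the primary record, further
    segments as supplementary records; read offsets are encoded as soft clips.
    """
    header = pysam.AlignmentHeader.from_dict(sam_header(ref))
    tid = {name: i for i, name in enumerate(ref.contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, seq1, seq2, segs1, segs2 in pairs:
            for mate, seq, segs in (("R1", seq1, segs1), ("R2", seq2, segs2)):
                mate_flag = 0x40 if mate == "R1" else 0x80
                if not segs:
                    a = pysam.AlignedSegment(header)
                    a.query_name = read_id
                    a.flag = 0x1 | 0x4 | mate_flag
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    out.write(a)
                    continue
                for i, seg in enumerate(segs):
                    a = pysam.AlignedSegment(header)
                    a.query_name = read_id
                    flag = 0x1 | mate_flag
                    if seg.strand == "-":
                        flag |= 0x10
                    if i > 0:
                        flag |= 0x800
                    a.flag = flag
                    a.reference_id = tid[seg.contig]
                    a.reference_start = seg.ref_start
                    a.mapping_quality = 60
                    n = len(seq)
                    if seg.strand == "+":
                        clip5, clip3 = seg.read_start, n - seg.read_end
                        stored = seq
                    else:
                        clip5, clip3 = n - seg.read_end, seg.read_start
                        stored = revcomp(seq)
                    cigar = []
                    if clip5:
                        cigar.append((4, clip5))
                    cigar.append((0, seg.read_end - seg.read_start))
                    if clip3:
                        cigar.append((4, clip3))
                    a.cigartuples = cigar
                    a.query_sequence = stored
                    a.query_qualities = pysam.qualitystring_to_array("I" * n)
                    a.set_tag("NM", seg.n_mismatches)
                    out.write(a)


@dataclass
class SamReadStats:
    """Counters accumulated while parsing an alignment file."""

    n_pairs: int = 0
    n_skipped_contig: int = 0
    n_skipped_unpaired: int = 0


def read_alignment_file(
    path: str | Path,
    ref: MergedReference | None = None,
    stats: SamReadStats | None = None,
) -> Iterator[ReadPairAlignment]:
    """Parse a SAM/BAM file into read-pair alignments.

    Primary and supplementary records contribute segments; secondary records
    (flag 0x100) are ignored.  Records naming a contig absent from the merged
    reference are skipped with a counted warning; reads present with only one
    mate are skipped.  The file is buffered in memory (inputs at this tool's
    scale are small; name-collated input is not required).
    """
    stats = stats if stats is not None else SamReadStats()
    known = set(ref.contigs) if ref is not None else None
    by_name: dict[str, dict[str, list[SegmentAlignment]]] = {}
    seen_mates: dict[str, set[str]] = defaultdict(set)
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary:
                continue
            mate = "R1" if rec.is_read1 or not rec.is_paired else "R2"
            if rec.is_read2:
                mate = "R2"
            seen_mates[rec.query_name].add(mate)
            by_name.setdefault(rec.query_name, {"R1": [], "R2": []})
            if rec.is_unmapped:
                continue
            contig = rec.reference_name
            if known is not None and contig not in known:
                stats.n_skipped_contig += 1
                logger.warning("record %s maps to unknown contig %s; skipped", rec.query_name, contig)
                continue
            cig = rec.cigartuples or []
            clip5 = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            clip3 = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            aligned = rec.query_alignment_length
            total = clip5 + aligned + clip3
            if rec.is_reverse:
                read_start, read_end = clip3, clip3 + aligned
                strand = "-"
            else:
                read_start, read_end = clip5, clip5 + aligned
                strand = "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            seg = SegmentAlignment(
                read_id=rec.query_name, mate=mate, contig=contig,
                ref_start=rec.reference_start, ref_end=rec.reference_end,
                strand=strand, read_start=read_start, read_end=read_end,
                n_mismatches=int(nm), is_supplementary=rec.is_supplementary,
            )
            by_name[rec.query_name][mate].append(seg)
    for name in by_name:
        if seen_mates[name] != {"R1", "R2"}:
            stats.n_skipped_unpaired += 1
            continue
        segs1 = sorted(by_name[name]["R1"], key=lambda s: s.read_start)
        segs2 = sorted(by_name[name]["R2"], key=lambda s: s.read_start)
        stats.n_pairs += 1
        yield ReadPairAlignment(read_id=name, segments_r1=segs1, segments_r2=segs2)
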