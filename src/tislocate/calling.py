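"""Read classification, junction typing and TIS calling.

A read pair falls into one of four classes: invalid (genome-only or
T-DNA-only), split (one mate's alignment splits into a genome segment and a
T-DNA segment, pinpointing the junction base) or discordant (one mate on the
genome, the other on the T-DNA contig, corroborating a junction without
spanning it).  Valid pairs yield :class:`JunctionEvidence`; evidence is
deduplicated per tagmentation fragment, clustered into :class:`TISCall`
records with split/discordant support counts, filtered against a wild-type
control, and finally paired into full TISs (left + right junction).

Each junction is typed with one of eight labels ``RefSide&border&Direction``:
whether the genome flank lies Left or Right of the junction, whether the
T-DNA side is the LB or RB border region, and whether the integrated T-DNA
runs Forward (its forward strand co-linear with the genome forward strand)
or Reverse.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

from .align import ReadPairAlignment, SegmentAlignment
from .construct import ConstructModel, TDNA_CONTIG

logger = logging.getLogger(__name__)

#: minimum exclusive (non-overlapping) coverage per segment for a valid split
MIN_NON_OVERLAP = 20
#: a mate whose alignment fragments into more than this many segments
#: contributes no split evidence
MAX_SPLIT_SEGMENTS = 2

SIDES = ("Left", "Right")
BORDERS = ("LB", "RB")
DIRECTIONS = ("Forward", "Reverse")


class ReadClass(Enum):
    INVALID_GENOME_ONLY = "invalid_genome_only"
    INVALID_TDNA_ONLY = "invalid_tdna_only"
    SPLIT = "split"
    DISCORDANT = "discordant"


@dataclass(frozen=True)
class JunctionEvidence:
    """One read pair's evidence for one genome/T-DNA junction."""

    read_id: str
    chrom: str
    breakpoint: int  # 1-based; exact for split, outer bound for discordant
    ref_side: str
    border: str
    direction: str
    tdna_pos: int  # 1-based coordinate on the tDNA contig at/near the junction
    kind: str  # "split" | "discordant"
    fragment_sig: tuple[str, int, str]  # (contig, Tn5 cut coordinate, orientation)
    n_mismatches: int = 0
    mate: str = "R1"  # the mate carrying the junction signal
    cosites: tuple[tuple[str, int], ...] = ()

    @property
    def label(self) -> str:
        return f"{self.ref_side}&{self.border}&{self.direction}"


@dataclass
class TISCall:
    """A clustered, non-redundant T-DNA integration site call."""

    sample: str
    chrom: str
    breakpoint: int  # 1-based
    ref_side: str
    border: str
    direction: str
    split_supportN: int
    discort_supportN: int
    imprecise: bool = False
    ambiguous_sites: tuple[tuple[str, int], ...] = ()
    supporting_read_ids: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return f"{self.ref_side}&{self.border}&{self.direction}"

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.ambiguous_sites)


@dataclass
class FullTIS:
    """A paired left + right junction call at one integration locus."""

    left: TISCall
    right: TISCall
    target_deletion_bp: int
    pattern: str


def enumerate_insertion_types() -> list[str]:
    """The full 8-label vocabulary in stable order."""
    return [f"{s}&{b}&{d}" for s, b, d in product(SIDES, BORDERS, DIRECTIONS)]


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _exclusive_lengths(a: SegmentAlignment, b: SegmentAlignment) -> tuple[int, int]:
    ov = max(0, min(a.read_end, b.read_end) - max(a.read_start, b.read_start))
    return a.read_length_aligned - ov, b.read_length_aligned - ov


def _split_mate(segments: Sequence[SegmentAlignment]) -> tuple[SegmentAlignment, SegmentAlignment] | None:
    """Return (genome segment, tdna segment) if the mate is a valid split."""
    if len(segments) != MAX_SPLIT_SEGMENTS:
        return None
    a, b = segments
    a_t, b_t = a.contig == TDNA_CONTIG, b.contig == TDNA_CONTIG
    if a_t == b_t:
        return None
    ex_a, ex_b = _exclusive_lengths(a, b)
    if ex_a < MIN_NON_OVERLAP or ex_b < MIN_NON_OVERLAP:
        return None
    return (b, a) if a_t else (a, b)


def classify_read_pair(aln: ReadPairAlignment) -> ReadClass:
    """Assign a read pair to one of the four read classes."""
    for segs in (aln.segments_r1, aln.segments_r2):
        if _split_mate(segs) is not None:
            return ReadClass.SPLIT
    contigs1 = {s.contig == TDNA_CONTIG for s in aln.segments_r1}
    contigs2 = {s.contig == TDNA_CONTIG for s in aln.segments_r2}
    if contigs1 and contigs2:
        if contigs1 == {False} and contigs2 == {True}:
            return ReadClass.DISCORDANT
        if contigs1 == {True} and contigs2 == {False}:
            return ReadClass.DISCORDANT
    all_segs = aln.segments_r1 + aln.segments_r2
    tdna_bp = sum(s.read_length_aligned for s in all_segs if s.contig == TDNA_CONTIG)
    genome_bp = sum(s.read_length_aligned for s in all_segs if s.contig != TDNA_CONTIG)
    if tdna_bp > genome_bp:
        return ReadClass.INVALID_TDNA_ONLY
    return ReadClass.INVALID_GENOME_ONLY


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------

def _fragment_sig(aln: ReadPairAlignment) -> tuple[str, int, str]:
    """Signature of the tagmentation fragment: R1's outer (5') coordinate.

    Distinct Tn5 cut coordinates identify independent molecules; identical
    signatures mark PCR/optical duplicates.  Falls back to R2 and finally the
    read id so a missing mate never collapses unrelated evidence.
    """
    for segs in (aln.segments_r1, aln.segments_r2):
        if segs:
            prim = min(segs, key=lambda s: s.read_start)
            outer = prim.ref_start if prim.strand == "+" else prim.ref_end
            return (prim.contig, outer, prim.strand)
    return ("*", 0, aln.read_id)  # pragma: no cover - classify requires a segment


def _cosites_for(seg: SegmentAlignment, breakpoint: int) -> tuple[tuple[str, int], ...]:
    """Project a breakpoint through each equally-scoring alternative locus."""
    out = []
    length = seg.ref_end - seg.ref_start
    off = breakpoint - seg.ref_start  # 1-based offset within the segment
    for contig, start, strand in seg.cohits:
        if contig == TDNA_CONTIG:
            continue
        if strand == seg.strand:
            out.append((contig, start + off))
        else:
            out.append((contig, start + length - off + 1))
    return tuple(out)


def junction_from_split(
    aln: ReadPairAlignment, construct: ConstructModel
) -> JunctionEvidence | None:
    """Extract junction evidence from a split-mapped read pair.

    With the genome segment spanning reference interval [g1, g2) on strand s:
    if (s = + and the T-DNA segment follows the genome segment in read order)
    or (s = - and it precedes it), the junction adjoins the genome segment's
    high-coordinate end, so the genome flank is Left of the junction and the
    breakpoint is g2 (1-based last genome base); otherwise the flank is Right
    and the breakpoint is g1 + 1.  Direction is Forward iff both segments
    align to the same strand.  The border is assigned by proximity of the
    junction's tDNA coordinate to the two border repeats; exactly equidistant
    evidence is discarded.
    """
    for segs in (aln.segments_r1, aln.segments_r2):
        pair = _split_mate(segs)
        if pair is None:
            continue
        genome_seg, tdna_seg = pair
        tdna_after = tdna_seg.read_start >= genome_seg.read_start
        s = genome_seg.strand
        if (s == "+" and tdna_after) or (s == "-" and not tdna_after):
            ref_side = "Left"
            breakpoint = genome_seg.ref_end  # 1-based last genome base
        else:
            ref_side = "Right"
            breakpoint = genome_seg.ref_start + 1
        direction = "Forward" if genome_seg.strand == tdna_seg.strand else "Reverse"
        # tDNA coordinate at the junction: the tdna segment's boundary that
        # abuts the genome segment in read order
        if tdna_after:
            tdna_pos0 = tdna_seg.ref_start if tdna_seg.strand == "+" else tdna_seg.ref_end - 1
        else:
            tdna_pos0 = tdna_seg.ref_end - 1 if tdna_seg.strand == "+" else tdna_seg.ref_start
        border = construct.nearest_border(tdna_pos0)
        if border is None:
            logger.info("read %s: junction equidistant from both borders, discarded", aln.read_id)
            return None
        return JunctionEvidence(
            read_id=aln.read_id, chrom=genome_seg.contig, breakpoint=breakpoint,
            ref_side=ref_side, border=border, direction=direction,
            tdna_pos=tdna_pos0 + 1, kind="split", fragment_sig=_fragment_sig(aln),
            n_mismatches=genome_seg.n_mismatches + tdna_seg.n_mismatches,
            mate=genome_seg.mate, cosites=_cosites_for(genome_seg, breakpoint),
        )
    return None


def junction_from_discordant(
    aln: ReadPairAlignment, construct: ConstructModel
) -> JunctionEvidence | None:
    """Extract junction evidence from a discordant read pair.

    Mates of a fragment read toward each other, so the junction lies beyond
    the genome mate's 3' end: genome mate on + means the genome flank is Left
    of the junction (breakpoint bounded by the segment end), on - it is Right.
    Direction is Forward iff the two mates map to opposite strands (the
    normal inward-facing layout of a co-linear fragment).
    """
    segs1, segs2 = aln.segments_r1, aln.segments_r2
    tdna1 = {s.contig == TDNA_CONTIG for s in segs1}
    if tdna1 == {False}:
        genome_segs, tdna_segs = segs1, segs2
    else:
        genome_segs, tdna_segs = segs2, segs1
    g = max(genome_segs, key=lambda s: s.read_length_aligned)
    t = max(tdna_segs, key=lambda s: s.read_length_aligned)
    if g.strand == "+":
        ref_side, breakpoint = "Left", g.ref_end
    else:
        ref_side, breakpoint = "Right", g.ref_start + 1
    direction = "Forward" if g.strand != t.strand else "Reverse"
    # tDNA mate's 3' end points toward the junction
    tdna_pos0 = t.ref_end - 1 if t.strand == "+" else t.ref_start
    border = construct.nearest_border(tdna_pos0)
    if border is None:
        return None
    return JunctionEvidence(
        read_id=aln.read_id, chrom=g.contig,
        breakpoint=breakpoint, ref_side=ref_side, border=border, direction=direction,
        tdna_pos=tdna_pos0 + 1, kind="discordant", fragment_sig=_fragment_sig(aln),
        n_mismatches=g.n_mismatches + t.n_mismatches, mate=g.mate,
        cosites=_cosites_for(g, breakpoint),
    )


def extract_evidence(
    aln: ReadPairAlignment, construct: ConstructModel
) -> tuple[ReadClass, JunctionEvidence | None]:
    """Classify one pair and extract its junction evidence, if any."""
    cls = classify_read_pair(aln)
    if cls is ReadClass.SPLIT:
        return cls, junction_from_split(aln, construct)
    if cls is ReadClass.DISCORDANT:
        return cls, junction_from_discordant(aln, construct)
    return cls, None


# ---------------------------------------------------------------------------
# Deduplication and clustering
# ---------------------------------------------------------------------------

def dedupe_evidence(evidence: Iterable[JunctionEvidence]) -> list[JunctionEvidence]:
    """Collapse PCR/optical duplicates: one record per distinct fragment
    signature, keeping the fewest-mismatch record (ties by read id)."""
    best: dict[tuple, JunctionEvidence] = {}
    for ev in evidence:
        key = ev.fragment_sig
        cur = best.get(key)
        if cur is None or (ev.n_mismatches, ev.read_id) < (cur.n_mismatches, cur.read_id):
            best[key] = ev
    return sorted(best.values(), key=lambda e: (e.chrom, e.breakpoint, e.label, e.read_id))


def _modal_clusters(
    evs: list[JunctionEvidence], tol: int
) -> list[list[JunctionEvidence]]:
    """Greedy modal clustering of breakpoints within one evidence group."""
    remaining = list(evs)
    clusters = []
    while remaining:
        counts = Counter(e.breakpoint for e in remaining)
        # highest multiplicity, smallest breakpoint on ties
        mode = min(counts, key=lambda bp: (-counts[bp], bp))
        members = [e for e in remaining if abs(e.breakpoint - mode) <= tol]
        remaining = [e for e in remaining if abs(e.breakpoint - mode) > tol]
        clusters.append(members)
    return clusters


def cluster_calls(
    evidence: Sequence[JunctionEvidence],
    sample: str,
    tol: int = 5,
    min_split: int = 2,
    min_discordant_with_one_split: int = 3,
    max_fragment_len: int = 900,
) -> list[TISCall]:
    """Cluster deduplicated evidence into TIS calls with support counts.

    Split evidence is grouped by (chrom, ref_side, border, direction) and
    clustered around modal breakpoints within ``tol``.  Discordant evidence
    attaches to the nearest compatible split cluster within the library's
    maximum fragment length; unattached discordant evidence forms
    support-only clusters that are reported flagged imprecise.  Clusters are
    kept iff split support >= ``min_split``, or split support >= 1 with
    discordant support >= ``min_discordant_with_one_split``; imprecise
    clusters are kept at the same discordant threshold.
    """
    groups: dict[tuple, dict[str, list[JunctionEvidence]]] = defaultdict(
        lambda: {"split": [], "discordant": []}
    )
    for ev in evidence:
        groups[(ev.chrom, ev.ref_side, ev.border, ev.direction)][ev.kind].append(ev)

    calls: list[TISCall] = []
    for (chrom, side, border, direction), kinds in sorted(groups.items()):
        split_clusters = _modal_clusters(kinds["split"], tol)
        cluster_bp = []
        for members in split_clusters:
            counts = Counter(e.breakpoint for e in members)
            bp = min(counts, key=lambda b: (-counts[b], b))
            cluster_bp.append((bp, members, []))
        # attach discordant evidence to the nearest compatible split cluster
        orphans: list[JunctionEvidence] = []
        for ev in kinds["discordant"]:
            best = None
            for rec in cluster_bp:
                d = abs(ev.breakpoint - rec[0])
                if d <= max_fragment_len and (best is None or d < abs(ev.breakpoint - best[0])):
                    best = rec
            if best is not None:
                best[2].append(ev)
            else:
                orphans.append(ev)
        for bp, split_members, disc_members in cluster_bp:
            n_split, n_disc = len(split_members), len(disc_members)
            if n_split >= min_split or (n_split >= 1 and n_disc >= min_discordant_with_one_split):
                members = split_members + disc_members
                calls.append(
                    TISCall(
                        sample=sample, chrom=chrom, breakpoint=bp, ref_side=side,
                        border=border, direction=direction, split_supportN=n_split,
                        discort_supportN=n_disc, imprecise=False,
                        ambiguous_sites=_union_cosites(members),
                        supporting_read_ids=tuple(sorted(e.read_id for e in members)),
                    )
                )
            else:
                logger.info(
                    "cluster %s:%d %s&%s&%s filtered: split=%d discordant=%d below support thresholds",
                    chrom, bp, side, border, direction, n_split, n_disc,
                )
        # discordant-only support clusters, reported imprecise
        for members in _modal_clusters(orphans, max_fragment_len):
            if len(members) >= min_discordant_with_one_split:
                counts = Counter(e.breakpoint for e in members)
                bp = min(counts, key=lambda b: (-counts[b], b))
                calls.append(
                    TISCall(
                        sample=sample, chrom=chrom, breakpoint=bp, ref_side=side,
                        border=border, direction=direction, split_supportN=0,
                        discort_supportN=len(members), imprecise=True,
                        ambiguous_sites=_union_cosites(members),
                        supporting_read_ids=tuple(sorted(e.read_id for e in members)),
                    )
                )
            else:
                logger.info(
                    "discordant-only cluster %s %s&%s&%s with %d reads filtered",
                    chrom, side, border, direction, len(members),
                )
    calls.sort(key=lambda c: (c.chrom, c.breakpoint, c.label))
    return calls


def _union_cosites(members: Sequence[JunctionEvidence]) -> tuple[tuple[str, int], ...]:
    sites = set()
    for ev in members:
        sites.update(ev.cosites)
    return tuple(sorted(sites))


# ---------------------------------------------------------------------------
# Control subtraction, multimap resolution, full-TIS pairing
# ---------------------------------------------------------------------------

def subtract_control(
    calls: Sequence[TISCall], control_calls: Sequence[TISCall], radius: int = 10
) -> list[TISCall]:
    """Remove calls within ``radius`` bp of any wild-type control call."""
    kept = []
    for call in calls:
        hit = next(
            (
                c for c in control_calls
                if c.chrom == call.chrom and abs(c.breakpoint - call.breakpoint) <= radius
            ),
            None,
        )
        if hit is None:
            kept.append(call)
        else:
            logger.info(
                "call %s:%d %s removed: control call at %s:%d within %d bp",
                call.chrom, call.breakpoint, call.label, hit.chrom, hit.breakpoint, radius,
            )
    return kept


def resolve_multimap(calls: Sequence[TISCall]) -> list[TISCall]:
    """Keep every call; multi-mapping calls retain their deterministic primary
    site and carry all alternative sites for downstream PCR disambiguation."""
    out = []
    for call in calls:
        if call.ambiguous_sites:
            logger.info(
                "call %s:%d %s is ambiguous across %d candidate sites: %s",
                call.chrom, call.breakpoint, call.label,
                len(call.ambiguous_sites) + 1,
                ", ".join(f"{c}:{p}" for c, p in call.ambiguous_sites),
            )
        out.append(call)
    return out


def pair_full_tis(
    calls: Sequence[TISCall], window: int = 100
) -> tuple[list[FullTIS], list[TISCall]]:
    """Greedily pair Left calls with the nearest compatible Right call.

    A pair requires the same chromosome, right breakpoint >= left breakpoint
    - window and gap <= window; ``target_deletion_bp`` = right - left - 1 (a
    negative value means duplicated or filled sequence at the junction).
    Leftover calls are returned unpaired (half-TIS case).
    """
    lefts = sorted((c for c in calls if c.ref_side == "Left"), key=lambda c: (c.chrom, c.breakpoint))
    rights = [c for c in calls if c.ref_side == "Right"]
    used: set[int] = set()
    full: list[FullTIS] = []
    unpaired: list[TISCall] = []
    for left in lefts:
        best_i = None
        best_d = None
        for i, right in enumerate(rights):
            if i in used or right.chrom != left.chrom:
                continue
            gap = right.breakpoint - left.breakpoint - 1
            if right.breakpoint < left.breakpoint - window or gap > window:
                continue
            d = abs(gap)
            if best_d is None or d < best_d:
                best_i, best_d = i, d
        if best_i is None:
            unpaired.append(left)
            continue
        right = rights[best_i]
        used.add(best_i)
        full.append(
            FullTIS(
                left=left, right=right,
                target_deletion_bp=right.breakpoint - left.breakpoint - 1,
                pattern=f"{left.label} + {right.label}",
            )
        )
    unpaired.extend(r for i, r in enumerate(rights) if i not in used)
    unpaired.sort(key=lambda c: (c.chrom, c.breakpoint, c.label))
    return full, unpaired


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class CallStats:
    """Read-class bookkeeping for one sample run."""

    n_pairs: int = 0
    n_invalid_genome_only: int = 0
    n_invalid_tdna_only: int = 0
    n_split: int = 0
    n_discordant: int = 0
    n_discarded_ambiguous_border: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "pairs": self.n_pairs,
            "invalid_genome_only": self.n_invalid_genome_only,
            "invalid_tdna_only": self.n_invalid_tdna_only,
            "split": self.n_split,
            "discordant": self.n_discordant,
            "discarded_ambiguous_border": self.n_discarded_ambiguous_border,
        }


def call_sample(
    pairs: Iterable[ReadPairAlignment],
    construct: ConstructModel,
    sample: str,
    control_calls: Sequence[TISCall] = (),
    tol: int = 5,
    min_split: int = 2,
    min_discordant_with_one_split: int = 3,
    max_fragment_len: int = 900,
    subtract_radius: int = 10,
    stats: CallStats | None = None,
    evidence_out: list[JunctionEvidence] | None = None,
) -> list[TISCall]:
    """Run classification through control subtraction for one sample."""
    stats = stats if stats is not None else CallStats()
    evidence: list[JunctionEvidence] = []
    for aln in pairs:
        stats.n_pairs += 1
        cls, ev = extract_evidence(aln, construct)
        if cls is ReadClass.SPLIT:
            stats.n_split += 1
        elif cls is ReadClass.DISCORDANT:
            stats.n_discordant += 1
        elif cls is ReadClass.INVALID_GENOME_ONLY:
            stats.n_invalid_genome_only += 1
        else:
            stats.n_invalid_tdna_only += 1
        if cls in (ReadClass.SPLIT, ReadClass.DISCORDANT) and ev is None:
            stats.n_discarded_ambiguous_border += 1
        if ev is not None:
            evidence.append(ev)
    deduped = dedupe_evidence(evidence)
    if evidence_out is not None:
        evidence_out.extend(deduped)
    calls = cluster_calls(
        deduped, sample=sample, tol=tol, min_split=min_split,
        min_discordant_with_one_split=min_discordant_with_one_split,
        max_fragment_len=max_fragment_len,
    )
    calls = subtract_control(calls, control_calls, radius=subtract_radius)
    calls = resolve_multimap(calls)
    return calls
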