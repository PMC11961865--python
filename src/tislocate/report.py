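"""Output artifacts, PCR primer windows and gene-context annotation.

Four artifacts describe a sample's calls: the tab-separated summary table
(one row per call), a FASTA of supporting reads with a re-alignment table for
manual checking, 2 kb genomic flanks of every breakpoint for primer design,
and a full-TIS table pairing left and right junctions.  TISs are annotated
against gene models into promoter / exon / intron / downstream / distal
categories, and each call gets a recommended genomic primer window that,
combined with the matching LB/RB common primer, yields products in the
350-700 bp range used for PCR validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .align import SeedIndex, align_read
from .calling import FullTIS, TISCall
from .construct import ConstructModel, GenomeInterval

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "Sample", "Ref:Breakpoint", "RefSide", "tDNA", "Direction",
    "Split_supportN", "Discort_supportN",
]

ANNOTATION_CATEGORIES = [
    "exon", "intron", "promoter<=1kb", "promoter1-2kb", "promoter2-3kb",
    "downstream<=300bp", "distal>3kb",
]


# ---------------------------------------------------------------------------
# Summary table
# ---------------------------------------------------------------------------

def write_summary(calls: Sequence[TISCall], path: str | Path, sample: str | None = None) -> None:
    """Write the per-sample summary table (tab-separated, fixed columns,
    sorted by chromosome, breakpoint, label)."""
    rows = sorted(calls, key=lambda c: (c.chrom, c.breakpoint, c.label))
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                f"{c.sample}\t{c.chrom}:{c.breakpoint}\t{c.ref_side}\t{c.border}\t"
                f"{c.direction}\t{c.split_supportN}\t{c.discort_supportN}\n"
            )


def read_summary(path: str | Path) -> list[TISCall]:
    """Parse a summary table back into calls (scalar fields only)."""
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SUMMARY_COLUMNS:
            raise ValueError(f"unexpected summary header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, bp = f[1].rsplit(":", 1)
            calls.append(
                TISCall(
                    sample=f[0], chrom=chrom, breakpoint=int(bp), ref_side=f[2],
                    border=f[3], direction=f[4], split_supportN=int(f[5]),
                    discort_supportN=int(f[6]),
                )
            )
    return calls


def default_summary_name(sample: str) -> str:
    return f"{sample}.tDNA.summary"


# ---------------------------------------------------------------------------
# Supporting reads + re-alignment report
# ---------------------------------------------------------------------------

def write_supported_reads(
    calls: Sequence[TISCall],
    reads: Mapping[str, str],
    index: SeedIndex,
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write supporting-read sequences and their re-alignment report.

    ``reads`` maps read id to the junction-carrying mate's sequence.  Each
    supported read is re-aligned against the merged reference with the
    internal aligner; the companion TSV lists every aligned segment (one row
    per segment, blast-tabular-like) for manual inspection.
    """
    kind_by_read: dict[str, tuple[TISCall, str]] = {}
    for call in sorted(calls, key=lambda c: (c.chrom, c.breakpoint, c.label)):
        kind = "discordant" if call.split_supportN == 0 else "split"
        for rid in call.supporting_read_ids:
            kind_by_read.setdefault(rid, (call, kind))
    with open(fasta_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write("read_id\tcontig\tstart\tend\tstrand\tmismatches\n")
        for rid, (call, kind) in kind_by_read.items():
            seq = reads.get(rid)
            if seq is None:
                logger.warning("supporting read %s not found in read lookup; skipped", rid)
                continue
            header = f"{rid}|{call.sample}|{call.chrom}:{call.breakpoint}|{call.label}|{kind}"
            fa.write(f">{header}\n{seq}\n")
            for seg in align_read(seq, index, read_id=rid):
                tsv.write(
                    f"{rid}\t{seg.contig}\t{seg.ref_start + 1}\t{seg.ref_end}\t"
                    f"{seg.strand}\t{seg.n_mismatches}\n"
                )


# ---------------------------------------------------------------------------
# Flanking sequences
# ---------------------------------------------------------------------------

def extract_flanks(
    call: TISCall, genome: Mapping[str, str], flank: int = 2000
) -> list[tuple[str, str]]:
    """Extract the flanking genomic sequences of a breakpoint.

    Returns two (header, sequence) records: upstream covering 1-based
    positions [breakpoint - flank, breakpoint) and downstream covering
    [breakpoint, breakpoint + flank); records clipped at contig ends carry a
    "(truncated)" header suffix.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if call.chrom not in genome:
        raise KeyError(f"contig {call.chrom} not in genome")
    seq = genome[call.chrom]
    n = len(seq)
    if not (1 <= call.breakpoint <= n):
        raise ValueError(f"breakpoint {call.breakpoint} outside contig {call.chrom}")
    bp = call.breakpoint
    up_lo = max(0, bp - 1 - flank)
    up = seq[up_lo : bp - 1]
    down_hi = min(n, bp - 1 + flank)
    down = seq[bp - 1 : down_hi]
    records = []
    for label, sub, full in (("upstream", up, flank), ("downstream", down, flank)):
        suffix = "" if len(sub) == full else " (truncated)"
        header = f"{call.sample}|{call.chrom}:{bp}|{call.label}|{label}{suffix}"
        records.append((header, sub))
    return records


def write_flanks(
    calls: Sequence[TISCall], genome: Mapping[str, str], path: str | Path, flank: int = 2000
) -> None:
    with open(path, "w") as fh:
        for call in sorted(calls, key=lambda c: (c.chrom, c.breakpoint, c.label)):
            for header, seq in extract_flanks(call, genome, flank=flank):
                fh.write(f">{header}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Primer recommendation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerRecommendation:
    """A genomic primer window paired with the matching border common primer.

    The window sits ~300-700 bp from the breakpoint on the genome side of the
    junction so that, with the LB/RB common primer, the expected PCR product
    falls in the 350-700 bp validation range.
    """

    call: TISCall
    genome_window: GenomeInterval  # 0-based half-open
    genome_primer_sense: str  # "sense" | "antisense"
    common_primer: str  # "LB-common" | "RB-common"

    @property
    def window_1based(self) -> tuple[int, int]:
        return (self.genome_window.start + 1, self.genome_window.end)


def recommend_primers(
    call: TISCall, contig_lengths: Mapping[str, int], offset: tuple[int, int] = (300, 700)
) -> PrimerRecommendation:
    """Recommend the genomic primer window for one call.

    Left calls get a sense primer in [breakpoint-700, breakpoint-300]; Right
    calls an antisense primer in [breakpoint+300, breakpoint+700] (1-based
    inclusive).  Windows are shrunk, with a warning, at contig ends.
    """
    near, far = offset
    n = contig_lengths[call.chrom]
    if call.ref_side == "Left":
        lo1, hi1 = call.breakpoint - far, call.breakpoint - near
        sense = "sense"
    else:
        lo1, hi1 = call.breakpoint + near, call.breakpoint + far
        sense = "antisense"
    clipped_lo, clipped_hi = max(1, lo1), min(n, hi1)
    if (clipped_lo, clipped_hi) != (lo1, hi1):
        logger.warning(
            "primer window for %s:%d clipped to contig bounds [%d, %d]",
            call.chrom, call.breakpoint, clipped_lo, clipped_hi,
        )
    if clipped_lo > clipped_hi:
        raise ValueError(f"no usable primer window for {call.chrom}:{call.breakpoint}")
    return PrimerRecommendation(
        call=call,
        genome_window=GenomeInterval(call.chrom, clipped_lo - 1, clipped_hi),
        genome_primer_sense=sense,
        common_primer=f"{call.border}-common",
    )


# ---------------------------------------------------------------------------
# Gene-context annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationResult:
    call: TISCall
    category: str
    nearest_gene: str | None
    distance: int  # bp to the assigned gene's TSS (0 when no gene in reach)


@dataclass(frozen=True)
class _Gene:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


def load_genes(gff3: str | Path) -> list[_Gene]:
    """Load gene models (genes with their exons) from a GFF3 file."""
    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        strand = g.strand
        if strand not in ("+", "-"):
            logger.warning("gene %s has no strand; treated as +", g.id)
            strand = "+"
        exons = tuple(
            sorted((e.start, e.end) for e in db.children(g, featuretype="exon"))
        )
        genes.append(
            _Gene(gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
                  strand=strand, exons=exons)
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def classify_position(pos: int, chrom: str, genes: Sequence[_Gene]) -> tuple[str, str | None, int]:
    """Category of a single 1-based position under the bin precedence.

    Precedence: exon > intron > promoter bins (distance upstream of the TSS
    on the gene's strand) > downstream (<=300 bp of the 3' end) > distal
    (>3 kb).  The nearest gene is chosen by minimal distance to its TSS,
    ties by smaller gene id.
    """
    PROMOTER_BINS = ((1000, "promoter<=1kb"), (2000, "promoter1-2kb"), (3000, "promoter2-3kb"))
    candidates: dict[str, list[tuple[int, str]]] = {c: [] for c in ANNOTATION_CATEGORIES}
    for g in genes:
        if g.chrom != chrom:
            continue
        tss_dist = abs(pos - g.tss)
        if g.start <= pos <= g.end:
            in_exon = any(s <= pos <= e for s, e in g.exons)
            candidates["exon" if in_exon else "intron"].append((tss_dist, g.gene_id))
            continue
        upstream = (g.tss - pos) if g.strand == "+" else (pos - g.tss)
        if upstream > 0:
            for limit, cat in PROMOTER_BINS:
                if upstream <= limit:
                    candidates[cat].append((upstream, g.gene_id))
                    break
        downstream = (pos - g.three_prime) if g.strand == "+" else (g.three_prime - pos)
        if 0 < downstream <= 300:
            candidates["downstream<=300bp"].append((tss_dist, g.gene_id))
    for cat in ANNOTATION_CATEGORIES[:-1]:
        if candidates[cat]:
            dist, gid = min(candidates[cat])
            return cat, gid, dist
    return "distal>3kb", None, 0


def annotate_tis(calls: Sequence[TISCall], gff3: str | Path) -> list[AnnotationResult]:
    """Annotate each call's breakpoint against gene models."""
    genes = load_genes(gff3)
    out = []
    for call in calls:
        cat, gid, dist = classify_position(call.breakpoint, call.chrom, genes)
        out.append(AnnotationResult(call=call, category=cat, nearest_gene=gid, distance=dist))
    return out


def write_annotation(results: Sequence[AnnotationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Sample\tRef:Breakpoint\tcategory\tnearest_gene\tdistance\n")
        for r in results:
            fh.write(
                f"{r.call.sample}\t{r.call.chrom}:{r.call.breakpoint}\t{r.category}\t"
                f"{r.nearest_gene or '.'}\t{r.distance}\n"
            )


# ---------------------------------------------------------------------------
# Full-TIS table
# ---------------------------------------------------------------------------

def write_full_tis(
    full: Sequence[FullTIS], unpaired: Sequence[TISCall], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tleft_breakpoint\tright_breakpoint\ttarget_deletion_bp\tpattern\n"
        )
        for f in sorted(full, key=lambda f: (f.left.chrom, f.left.breakpoint)):
            fh.write(
                f"{f.left.chrom}\t{f.left.breakpoint}\t{f.right.breakpoint}\t"
                f"{f.target_deletion_bp}\t{f.pattern}\n"
            )
        for c in unpaired:
            side = "left" if c.ref_side == "Left" else "right"
            fh.write(f"{c.chrom}\t{c.breakpoint if side == 'left' else '.'}\t"
                     f"{c.breakpoint if side == 'right' else '.'}\t.\t{c.label} (half TIS)\n")
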