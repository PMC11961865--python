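"""End-to-end sample runs: align/parse, call, subtract, pair, report.

A run takes demultiplexed paired FASTQ (or a pre-computed SAM/BAM against
the merged reference), the construct description and the genome, and writes
the full artifact set for one sample into an output directory:

* ``<sample>.tDNA.summary`` — the call table
* ``supported_reads.fasta`` + ``realignment.tsv`` — evidence for manual checks
* ``flanks.fasta`` — 2 kb flanking sequences for primer design
* ``full_tis.tsv`` — paired left/right junctions with target deletion sizes
* ``run.log`` — read-class counts and every filtered item with its reason

Log lines carry no timestamps so that identical inputs and seed give
byte-identical output directories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam
import yaml

from . import align as _align
from . import calling as _calling
from . import report as _report
from . import simulate as _simulate
from .construct import (
    ConstructModel,
    MergedReference,
    build_merged_reference,
    load_construct,
    read_fasta,
    revcomp,
    write_fasta,
)

logger = logging.getLogger("tislocate")


@dataclass
class RunConfig:
    """Configuration of one sample run."""

    sample: str
    genome: str
    construct: str
    fastq1: str | None = None
    fastq2: str | None = None
    alignments: str | None = None  # SAM/BAM against the merged reference
    control_summary: str | None = None  # control calls from an identical run
    outdir: str = "."
    tol: int = 5
    min_split: int = 2
    min_discordant_with_one_split: int = 3
    max_fragment_len: int = 900
    pairing_window: int = 100
    subtract_radius: int = 10
    flank: int = 2000
    k: int = 21
    seed: int = 0

    def validate(self) -> None:
        if (self.fastq1 is None) != (self.fastq2 is None):
            raise ValueError("fastq1 and fastq2 must be given together")
        if self.fastq1 is None and self.alignments is None:
            raise ValueError("either a FASTQ pair or an alignment file is required")
        for label, p in (
            ("genome", self.genome), ("construct", self.construct),
            ("fastq1", self.fastq1), ("fastq2", self.fastq2),
            ("alignments", self.alignments), ("control_summary", self.control_summary),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        for label, v in (
            ("tol", self.tol), ("min_split", self.min_split),
            ("min_discordant_with_one_split", self.min_discordant_with_one_split),
            ("pairing_window", self.pairing_window), ("subtract_radius", self.subtract_radius),
            ("flank", self.flank),
        ):
            if v < 0:
                raise ValueError(f"{label} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_fastq_pairs(fastq1: str, fastq2: str) -> list[tuple[str, str, str]]:
    """Read mate-paired FASTQ into (read_id, r1, r2); ids strip /1 /2."""
    pairs = []
    with pysam.FastxFile(fastq1) as f1, pysam.FastxFile(fastq2) as f2:
        for rec1, rec2 in zip(f1, f2):
            name1 = rec1.name.removesuffix("/1")
            name2 = rec2.name.removesuffix("/2")
            if name1 != name2:
                raise ValueError(f"FASTQ pair out of sync: {rec1.name} vs {rec2.name}")
            pairs.append((name1, rec1.sequence.upper(), rec2.sequence.upper()))
    return pairs


def _sam_read_sequences(path: str) -> dict[str, dict[str, str]]:
    """Original-orientation read sequences per mate from primary records."""
    seqs: dict[str, dict[str, str]] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            mate = "R2" if rec.is_read2 else "R1"
            seq = rec.query_sequence
            if rec.is_reverse:
                seq = revcomp(seq)
            seqs.setdefault(rec.query_name, {})[mate] = seq
    return seqs


def _setup_run_logger(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tislocate")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def run_call(config: RunConfig) -> Path:
    """Execute the full calling pipeline for one sample; returns the output
    directory.  Zero calls is a successful outcome (e.g. wild-type controls)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logger(outdir / "run.log")
    try:
        construct = load_construct(config.construct)
        genome = read_fasta(config.genome)
        merged = build_merged_reference(genome, construct)
        index = _align.build_index(merged, k=config.k)
        read_lookup: dict[str, dict[str, str]] = {}
        if config.fastq1 is not None:
            fq_pairs = _read_fastq_pairs(config.fastq1, config.fastq2)
            logger.info("sample %s: %d read pairs from FASTQ", config.sample, len(fq_pairs))
            pairs = [
                _align.align_pair(r1, r2, index, read_id=rid) for rid, r1, r2 in fq_pairs
            ]
            read_lookup = {rid: {"R1": r1, "R2": r2} for rid, r1, r2 in fq_pairs}
        else:
            sam_stats = _align.SamReadStats()
            pairs = list(_align.read_alignment_file(config.alignments, merged, stats=sam_stats))
            logger.info(
                "sample %s: %d pairs from %s (%d skipped unknown-contig records, %d unpaired reads)",
                config.sample, sam_stats.n_pairs, config.alignments,
                sam_stats.n_skipped_contig, sam_stats.n_skipped_unpaired,
            )
            read_lookup = _sam_read_sequences(config.alignments)
        control_calls = (
            _report.read_summary(config.control_summary) if config.control_summary else []
        )
        stats = _calling.CallStats()
        evidence: list[_calling.JunctionEvidence] = []
        calls = _calling.call_sample(
            pairs, construct, sample=config.sample, control_calls=control_calls,
            tol=config.tol, min_split=config.min_split,
            min_discordant_with_one_split=config.min_discordant_with_one_split,
            max_fragment_len=config.max_fragment_len,
            subtract_radius=config.subtract_radius, stats=stats, evidence_out=evidence,
        )
        logger.info("read-class counts: %s", stats.as_dict())
        logger.info("%d calls after filtering and control subtraction", len(calls))
        full, unpaired = _calling.pair_full_tis(calls, window=config.pairing_window)

        _report.write_summary(calls, outdir / _report.default_summary_name(config.sample))
        ev_mate = {ev.read_id: ev.mate for ev in evidence}
        supp_reads = {
            rid: read_lookup[rid][ev_mate.get(rid, "R1")]
            for call in calls for rid in call.supporting_read_ids
            if rid in read_lookup and ev_mate.get(rid, "R1") in read_lookup.get(rid, {})
        }
        _report.write_supported_reads(
            calls, supp_reads, index,
            outdir / "supported_reads.fasta", outdir / "realignment.tsv",
        )
        _report.write_flanks(calls, genome, outdir / "flanks.fasta", flank=config.flank)
        _report.write_full_tis(full, unpaired, outdir / "full_tis.tsv")
        logger.info("%d full TISs, %d half TISs", len(full), len(unpaired))
        return outdir
    finally:
        logging.getLogger("tislocate").removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Fixture simulation
# ---------------------------------------------------------------------------

def run_simulate(
    outdir: str | Path,
    seed: int = 0,
    n_contigs: int = 2,
    contig_len: int = 100_000,
    n_events: int | None = None,
    substitution_rate: float = 0.0,
    n_fragments_per_junction: int = 8,
    n_background: int = 100,
) -> Path:
    """Generate a complete self-test fixture directory.

    Writes genome.fasta, modified.fasta, reads_R1.fastq, reads_R2.fastq,
    truth.sam, truth.tsv and construct.yaml; byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = _simulate.make_scenario(
        seed, n_contigs=n_contigs, contig_len=contig_len, n_events=n_events,
        substitution_rate=substitution_rate,
        n_fragments_per_junction=n_fragments_per_junction, n_background=n_background,
    )
    lib = _simulate.simulate_capture_library(scen.implant, scen.construct, scen.params)
    write_fasta(scen.genome, outdir / "genome.fasta")
    write_fasta(scen.implant.contigs, outdir / "modified.fasta")
    _simulate.write_fastq(lib, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    _simulate.write_truth_sam(lib, scen.merged, outdir / "truth.sam")
    _simulate.write_truth_tsv(scen.implant.truth, outdir / "truth.tsv")
    c = scen.construct
    with open(outdir / "construct.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "name": c.name,
                "sequence": c.tdna_seq,
                "lb_repeat": list(c.lb_repeat),
                "rb_repeat": list(c.rb_repeat),
                "lb_bridge": {"pos": c.lb_bridge.pos, "strand": c.lb_bridge.strand},
                "rb_bridge": {"pos": c.rb_bridge.pos, "strand": c.rb_bridge.strand},
            },
            fh, sort_keys=True,
        )
    return outdir
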