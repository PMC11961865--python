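"""T-DNA construct model and merged reference construction.

The construct model describes the region of a binary vector between the left
border (LB) and right border (RB) repeats, written 5'->3' as the upper
(forward, ``+``) strand with LB at low coordinates.  Two bridge-primer sites,
one interior of each border repeat and oriented toward it, define where the
T-DNA side of every library amplicon begins.

All internal coordinates are 0-based half-open; user-facing breakpoints are
reported 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Reserved name of the construct contig in the merged reference.
TDNA_CONTIG = "tDNA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ConstructError(ValueError):
    """Raised for an inconsistent construct description."""


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open interval on a contig (may be empty: start == end)."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BridgeSite:
    """A bridge-primer site on the construct.

    ``pos`` is the 0-based coordinate where read 2 of every amplicon from this
    site begins; ``strand`` is the primer extension direction on the construct
    forward strand (``-`` reads toward LB at low coordinates, ``+`` toward RB).
    """

    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bridge strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class ConstructModel:
    """The T-DNA payload (LB..RB region) with border repeats and bridge sites."""

    name: str
    tdna_seq: str
    lb_repeat: tuple[int, int]
    rb_repeat: tuple[int, int]
    lb_bridge: BridgeSite
    rb_bridge: BridgeSite

    def __post_init__(self) -> None:
        n = len(self.tdna_seq)
        for label, (s, e) in (("lb_repeat", self.lb_repeat), ("rb_repeat", self.rb_repeat)):
            if not (0 <= s < e <= n):
                raise ConstructError(f"{label} [{s},{e}) outside construct of length {n}")
        if self.lb_repeat[1] > self.rb_repeat[0]:
            raise ConstructError(
                "lb_repeat must precede rb_repeat on the forward strand "
                f"(got LB {self.lb_repeat}, RB {self.rb_repeat})"
            )
        if self.lb_bridge.strand != "-":
            raise ConstructError("lb_bridge must be oriented toward the LB repeat (- strand)")
        if self.rb_bridge.strand != "+":
            raise ConstructError("rb_bridge must be oriented toward the RB repeat (+ strand)")
        if not (self.lb_repeat[1] <= self.lb_bridge.pos < self.rb_repeat[0]):
            raise ConstructError(
                f"lb_bridge at {self.lb_bridge.pos} must lie interior of the LB repeat"
            )
        if not (self.lb_repeat[1] < self.rb_bridge.pos < self.rb_repeat[0]):
            raise ConstructError(
                f"rb_bridge at {self.rb_bridge.pos} must lie interior of the RB repeat"
            )
        if self.lb_bridge_distance <= 0:
            raise ConstructError("distance from lb_bridge to the LB repeat must be positive")
        if self.rb_bridge_distance <= 0:
            raise ConstructError("distance from rb_bridge to the RB repeat must be positive")

    @property
    def length(self) -> int:
        return len(self.tdna_seq)

    @property
    def lb_bridge_distance(self) -> int:
        """Distance from the LB bridge site to the LB repeat inner edge."""
        return self.lb_bridge.pos - self.lb_repeat[1] + 1

    @property
    def rb_bridge_distance(self) -> int:
        """Distance from the RB bridge site to the RB repeat inner edge."""
        return self.rb_repeat[0] - self.rb_bridge.pos

    def border_midpoint(self) -> float:
        """Coordinate equidistant from both border repeats (tie point)."""
        return (self.lb_repeat[1] + self.rb_repeat[0]) / 2.0

    def nearest_border(self, pos0: int) -> str | None:
        """Return 'LB' or 'RB' by proximity of a 0-based construct coordinate
        to the two border repeats; None if exactly equidistant."""
        d_lb = max(0, self.lb_repeat[0] - pos0, pos0 - (self.lb_repeat[1] - 1))
        d_rb = max(0, self.rb_repeat[0] - pos0, pos0 - (self.rb_repeat[1] - 1))
        if d_lb < d_rb:
            return "LB"
        if d_rb < d_lb:
            return "RB"
        return None


# ---------------------------------------------------------------------------
# FASTA helpers (60-column wrapping, the conventional layout)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) multi-FASTA file into an ordered name->sequence mapping."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ConstructError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    return contigs


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write contigs to FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    writer_path = str(path)
    with open(writer_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Construct loading
# ---------------------------------------------------------------------------

def _locate_primer(tdna_seq: str, primer: str, target_strand: str, label: str) -> BridgeSite:
    """Locate a bridge primer given as sequence.

    The primer is written 5'->3'.  A primer extending toward LB anneals to the
    forward strand and its sequence matches the reverse complement strand, so
    we search for its reverse complement on the forward sequence; the bridge
    position is the primer's 5' end (where read 2 starts).
    """
    primer = primer.upper()
    if target_strand == "-":
        needle = revcomp(primer)
    else:
        needle = primer
    hits = []
    start = 0
    while True:
        i = tdna_seq.find(needle, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    if not hits:
        raise ConstructError(f"{label}: bridge primer sequence not found on the construct")
    if len(hits) > 1:
        raise ConstructError(f"{label}: ambiguous bridge site (primer found {len(hits)} times)")
    occ = hits[0]
    if target_strand == "-":
        pos = occ + len(primer) - 1  # 5' end maps to the high coordinate
    else:
        pos = occ
    return BridgeSite(pos=pos, strand=target_strand)


def _parse_bridge(value, tdna_seq: str, target_strand: str, label: str) -> BridgeSite:
    if isinstance(value, str):
        return _locate_primer(tdna_seq, value, target_strand, label)
    if isinstance(value, Mapping):
        if "primer" in value:
            return _locate_primer(tdna_seq, value["primer"], target_strand, label)
        return BridgeSite(pos=int(value["pos"]), strand=str(value.get("strand", target_strand)))
    if isinstance(value, int):
        return BridgeSite(pos=value, strand=target_strand)
    raise ConstructError(f"{label}: cannot interpret bridge description {value!r}")


def _flip_model(name, seq, lb, rb, lbb, rbb):
    """Reverse-complement a construct description so LB comes first."""
    n = len(seq)

    def flip_iv(iv):
        return (n - iv[1], n - iv[0])

    def flip_bridge(b: BridgeSite) -> BridgeSite:
        return BridgeSite(pos=n - 1 - b.pos, strand="+" if b.strand == "-" else "-")

    return name, revcomp(seq), flip_iv(lb), flip_iv(rb), flip_bridge(lbb), flip_bridge(rbb)


def load_construct(config: str | Path | Mapping) -> ConstructModel:
    """Load and validate a construct description.

    ``config`` is a YAML file path or an equivalent mapping with keys ``name``,
    ``sequence`` (or ``sequence_file``), ``lb_repeat``/``rb_repeat`` as
    ``[start, end)`` pairs, and ``lb_bridge``/``rb_bridge`` given either as a
    coordinate (``{pos, strand}``) or as a primer sequence to be located by
    exact, unique match.  Either plasmid-map orientation is accepted: if the RB
    repeat precedes the LB repeat the whole description is reverse-complemented
    so LB sits at low coordinates.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    name = cfg.get("name", "construct")
    if "sequence" in cfg:
        seq = str(cfg["sequence"]).upper()
    elif "sequence_file" in cfg:
        contigs = read_fasta(cfg["sequence_file"])
        if len(contigs) != 1:
            raise ConstructError("sequence_file must contain exactly one record")
        seq = next(iter(contigs.values()))
    else:
        raise ConstructError("construct config requires 'sequence' or 'sequence_file'")
    for key in ("lb_repeat", "rb_repeat", "lb_bridge", "rb_bridge"):
        if key not in cfg:
            raise ConstructError(f"construct config missing field {key!r}")
    lb = tuple(int(x) for x in cfg["lb_repeat"])
    rb = tuple(int(x) for x in cfg["rb_repeat"])
    flipped = lb[0] > rb[0]
    lb_strand, rb_strand = ("+", "-") if flipped else ("-", "+")
    lbb = _parse_bridge(cfg["lb_bridge"], seq, lb_strand, "lb_bridge")
    rbb = _parse_bridge(cfg["rb_bridge"], seq, rb_strand, "rb_bridge")
    if flipped:
        name, seq, lb, rb, lbb, rbb = _flip_model(name, seq, lb, rb, lbb, rbb)
    return ConstructModel(
        name=name, tdna_seq=seq, lb_repeat=lb, rb_repeat=rb, lb_bridge=lbb, rb_bridge=rbb
    )


# ---------------------------------------------------------------------------
# Merged reference
# ---------------------------------------------------------------------------

@dataclass
class MergedReference:
    """Genome contigs plus the construct appended last as contig ``tDNA``."""

    contigs: dict[str, str] = field(default_factory=dict)
    tdna_contig_name: str = TDNA_CONTIG

    def __post_init__(self) -> None:
        if self.tdna_contig_name not in self.contigs:
            raise ConstructError(f"merged reference must contain a {TDNA_CONTIG!r} contig")

    @property
    def tdna_seq(self) -> str:
        return self.contigs[self.tdna_contig_name]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def is_tdna(self, contig: str) -> bool:
        return contig == self.tdna_contig_name

    def write(self, path: str | Path, width: int = 60) -> None:
        write_fasta(self.contigs, path, width=width)

    @classmethod
    def read(cls, path: str | Path) -> "MergedReference":
        return cls(contigs=read_fasta(path))


def build_merged_reference(
    genome: str | Path | Mapping[str, str], construct: ConstructModel
) -> MergedReference:
    """Merge genome contigs with the construct contig (named ``tDNA``, last).

    The genome may be a FASTA path or an in-memory name->sequence mapping.
    A genome contig named ``tDNA`` is rejected: the name is reserved for the
    construct.
    """
    if isinstance(genome, (str, Path)):
        contigs = read_fasta(genome)
    else:
        contigs = {k: v.upper() for k, v in genome.items()}
    if not contigs:
        raise ConstructError("no contigs in genome input")
    if TDNA_CONTIG in contigs:
        raise ConstructError(
            f"genome already contains a contig named {TDNA_CONTIG!r}; the name is reserved"
        )
    merged = dict(contigs)
    merged[TDNA_CONTIG] = construct.tdna_seq
    return MergedReference(contigs=merged)
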