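"""Genomic safe harbor (GSH) prediction by buffered interval exclusion.

A base is a safe-harbor candidate when its distance to every annotated
feature exceeds that feature class's buffer: by default 10 kb from
centromeres, 20 kb from lncRNAs, 10 kb from gene-encoding regions, 30 kb
from miRNAs and 20 kb from tRNAs.  Each feature interval is expanded by its
class buffer on both sides (clamped at chromosome ends), the union of all
expanded intervals is subtracted from each chromosome, and complement
intervals of at least ``min_length`` are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


class GSHError(ValueError):
    pass


@dataclass(frozen=True)
class GSHParams:
    """Per-class exclusion buffers (bp) and the minimum reportable length."""

    buffer_centromere: int = 10_000
    buffer_lncRNA: int = 20_000
    buffer_gene: int = 10_000
    buffer_miRNA: int = 30_000
    buffer_tRNA: int = 20_000
    min_length: int = 1_000

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.buffers().values()) or self.min_length < 0:
            raise GSHError("buffers and min_length must be >= 0")

    def buffers(self) -> dict[str, int]:
        return {
            "centromere": self.buffer_centromere,
            "lncRNA": self.buffer_lncRNA,
            "gene": self.buffer_gene,
            "miRNA": self.buffer_miRNA,
            "tRNA": self.buffer_tRNA,
        }


@dataclass(frozen=True)
class GSHInterval:
    chrom: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GSHSummary:
    count: int
    total_bp: int


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file (3+ columns) into (chrom, start, end) tuples."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    return list(df.itertuples(index=False, name=None))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "size"])
    return dict(df.itertuples(index=False, name=None))


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def predict_gsh(
    chrom_sizes: Mapping[str, int],
    tracks: Mapping[str, Sequence[tuple[str, int, int]] | str | Path],
    params: GSHParams = GSHParams(),
) -> tuple[list[GSHInterval], GSHSummary]:
    """Predict safe-harbor intervals from per-class annotation tracks.

    ``tracks`` maps a feature class (a key of ``GSHParams.buffers``) to a BED
    path or an in-memory interval list.  Unknown track classes or records on
    unknown chromosomes are an error.  Returns the sorted intervals plus a
    summary (count, total bp).
    """
    buffers = params.buffers()
    excluded: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for cls, track in tracks.items():
        if cls not in buffers:
            raise GSHError(f"unknown track class {cls!r}; expected one of {sorted(buffers)}")
        buf = buffers[cls]
        intervals = read_bed(track) if isinstance(track, (str, Path)) else track
        for chrom, start, end in intervals:
            if chrom not in chrom_sizes:
                raise GSHError(f"track {cls!r}: unknown chromosome in record {chrom}:{start}-{end}")
            n = chrom_sizes[chrom]
            if not (0 <= start < end <= n):
                raise GSHError(f"track {cls!r}: interval {chrom}:{start}-{end} outside chromosome")
            excluded[chrom].append((max(0, start - buf), min(n, end + buf)))
    out: list[GSHInterval] = []
    for chrom in chrom_sizes:
        n = chrom_sizes[chrom]
        pos = 0
        for s, e in _merge(excluded[chrom]):
            if s - pos >= params.min_length:
                out.append(GSHInterval(chrom, pos, s))
            pos = max(pos, e)
        if n - pos >= params.min_length:
            out.append(GSHInterval(chrom, pos, n))
    out.sort(key=lambda g: (g.chrom, g.start))
    summary = GSHSummary(count=len(out), total_bp=sum(g.length for g in out))
    return out, summary


def write_gsh(
    intervals: Sequence[GSHInterval], summary: GSHSummary,
    bed_path: str | Path, summary_path: str | Path | None = None,
) -> None:
    with open(bed_path, "w") as fh:
        for g in intervals:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            fh.write("count\ttotal_bp\n")
            fh.write(f"{summary.count}\t{summary.total_bp}\n")
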