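"""Summary tables, flanks, primer windows and gene-context annotation."""

import numpy as np
import pytest

from tislocate.calling import TISCall
from tislocate.report import (
    ANNOTATION_CATEGORIES,
    annotate_tis,
    classify_position,
    extract_flanks,
    load_genes,
    read_summary,
    recommend_primers,
    write_summary,
    write_supported_reads,
)


def call(bp=5000, side="Left", chrom="chr1", border="LB", direction="Forward",
         ns=3, nd=1, sample="s", reads=()):
    return TISCall(
        sample=sample, chrom=chrom, breakpoint=bp, ref_side=side, border=border,
        direction=direction, split_supportN=ns, discort_supportN=nd,
        supporting_read_ids=tuple(reads),
    )


class TestSummary:
    def test_exact_row_rendering(self, tmp_path):
        c = call(bp=408_235_032, chrom="chr4B", sample="Ta_28", ns=6, nd=4)
        path = tmp_path / "Ta_28.tDNA.summary"
        write_summary([c], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "Sample\tRef:Breakpoint\tRefSide\ttDNA\tDirection\tSplit_supportN\tDiscort_supportN"
        assert lines[1] == "Ta_28\tchr4B:408235032\tLeft\tLB\tForward\t6\t4"

    def test_empty_calls_header_only(self, tmp_path):
        path = tmp_path / "empty.summary"
        write_summary([], path)
        assert path.read_text().splitlines() == [
            "Sample\tRef:Breakpoint\tRefSide\ttDNA\tDirection\tSplit_supportN\tDiscort_supportN"
        ]

    def test_sorted_and_round_trip(self, tmp_path):
        calls = [call(bp=9000), call(bp=100), call(bp=5000, chrom="chr2")]
        path = tmp_path / "s.summary"
        write_summary(calls, path)
        back = read_summary(path)
        assert [(c.chrom, c.breakpoint) for c in back] == [
            ("chr1", 100), ("chr1", 9000), ("chr2", 5000)
        ]
        for a in calls:
            b = next(c for c in back if (c.chrom, c.breakpoint) == (a.chrom, a.breakpoint))
            assert (b.sample, b.ref_side, b.border, b.direction,
                    b.split_supportN, b.discort_supportN) == (
                a.sample, a.ref_side, a.border, a.direction,
                a.split_supportN, a.discort_supportN)


class TestFlanks:
    def test_exact_2kb_records(self, toy_genome):
        big = {"chr1": toy_genome["chr1"] * 12}  # 120 kb
        up, down = extract_flanks(call(bp=5000, chrom="chr1"), big, flank=2000)
        assert len(up[1]) == 2000 and len(down[1]) == 2000
        assert "(truncated)" not in up[0] and "(truncated)" not in down[0]
        assert up[1] == big["chr1"][2999:4999]
        assert down[1] == big["chr1"][4999:6999]

    def test_truncated_near_start(self, toy_genome):
        up, down = extract_flanks(call(bp=900), toy_genome, flank=2000)
        assert len(up[1]) == 899
        assert "(truncated)" in up[0]
        assert len(down[1]) == 2000

    def test_flank_must_be_positive(self, toy_genome):
        with pytest.raises(ValueError):
            extract_flanks(call(), toy_genome, flank=0)

    def test_breakpoint_outside_contig(self, toy_genome):
        with pytest.raises(ValueError):
            extract_flanks(call(bp=99_999), toy_genome)


class TestPrimerWindows:
    def test_left_call_sense_window(self):
        rec = recommend_primers(call(bp=5000, side="Left"), {"chr1": 100_000})
        assert rec.window_1based == (4300, 4700)
        assert rec.genome_primer_sense == "sense"
        assert rec.common_primer == "LB-common"

    def test_right_call_antisense_window(self):
        rec = recommend_primers(call(bp=5000, side="Right", border="RB"), {"chr1": 100_000})
        assert rec.window_1based == (5300, 5700)
        assert rec.genome_primer_sense == "antisense"
        assert rec.common_primer == "RB-common"

    def test_window_shrunk_at_contig_start(self):
        rec = recommend_primers(call(bp=400, side="Left"), {"chr1": 100_000})
        assert rec.window_1based == (1, 100)


GFF = """\
##gff-version 3
chr1\ttest\tgene\t10000\t14000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t10000\t14000\t.\t+\t.\tID=mA;Parent=geneA
chr1\ttest\texon\t10000\t11000\t.\t+\t.\tID=mA.e1;Parent=mA
chr1\ttest\texon\t13000\t14000\t.\t+\t.\tID=mA.e2;Parent=mA
chr1\ttest\tgene\t30000\t33000\t.\t-\t.\tID=geneB
chr1\ttest\tmRNA\t30000\t33000\t.\t-\t.\tID=mB;Parent=geneB
chr1\ttest\texon\t30000\t33000\t.\t-\t.\tID=mB.e1;Parent=mB
"""


@pytest.fixture()
def gff3(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    return path


class TestAnnotate:
    @pytest.mark.parametrize(
        "bp,expected",
        [
            (10_500, "exon"),
            (12_000, "intron"),
            (9_500, "promoter<=1kb"),     # 500 bp upstream of + strand TSS
            (8_500, "promoter1-2kb"),
            (7_500, "promoter2-3kb"),
            (14_200, "downstream<=300bp"),
            (50_000, "distal>3kb"),
            (33_500, "promoter<=1kb"),    # upstream of the - strand gene
            (29_800, "downstream<=300bp"),
        ],
    )
    def test_category_bins(self, gff3, bp, expected):
        (res,) = annotate_tis([call(bp=bp)], gff3)
        assert res.category == expected

    def test_every_call_gets_exactly_one_category(self, gff3):
        calls = [call(bp=bp) for bp in range(9_000, 15_200, 97)]
        results = annotate_tis(calls, gff3)
        assert len(results) == len(calls)
        assert all(r.category in ANNOTATION_CATEGORIES for r in results)

    def test_brute_force_oracle_agreement(self, gff3):
        """An independent per-base classifier over a window agrees everywhere."""
        genes = load_genes(gff3)

        def oracle(pos):
            # independent re-derivation of the precedence rules
            cats = []
            for g in genes:
                if g.start <= pos <= g.end:
                    if any(s <= pos <= e for s, e in g.exons):
                        cats.append("exon")
                    else:
                        cats.append("intron")
                    continue
                tss = g.start if g.strand == "+" else g.end
                d_up = (tss - pos) if g.strand == "+" else (pos - tss)
                if 0 < d_up <= 1000:
                    cats.append("promoter<=1kb")
                elif 1000 < d_up <= 2000:
                    cats.append("promoter1-2kb")
                elif 2000 < d_up <= 3000:
                    cats.append("promoter2-3kb")
                end3 = g.end if g.strand == "+" else g.start
                d_dn = (pos - end3) if g.strand == "+" else (end3 - pos)
                if 0 < d_dn <= 300:
                    cats.append("downstream<=300bp")
            for cat in ANNOTATION_CATEGORIES[:-1]:
                if cat in cats:
                    return cat
            return "distal>3kb"

        for pos in range(6_500, 36_000, 23):
            got, _, _ = classify_position(pos, "chr1", genes)
            assert got == oracle(pos), pos


class TestSupportedReads:
    def test_fasta_and_realignment_rows(self, tmp_path, toy_genome, toy_construct, toy_index):
        split_read = toy_construct.tdna_seq[400:470] + toy_genome["chr1"][4000:4080]
        reads = {"r1": split_read, "r2": toy_genome["chr1"][2000:2150],
                 "r3": toy_genome["chr1"][3000:3150]}
        c = call(reads=("r1", "r2", "r3"))
        fa, tsv = tmp_path / "sup.fasta", tmp_path / "re.tsv"
        write_supported_reads([c], reads, toy_index, fa, tsv)
        assert fa.read_text().count(">") == 3
        rows = tsv.read_text().splitlines()[1:]
        assert len(rows) >= 3
        r1_rows = [r for r in rows if r.startswith("r1\t")]
        assert len(r1_rows) == 2
        assert any("\ttDNA\t" in r for r in r1_rows)

    def test_missing_read_skipped(self, tmp_path, toy_index):
        c = call(reads=("ghost",))
        fa, tsv = tmp_path / "sup.fasta", tmp_path / "re.tsv"
        write_supported_reads([c], {}, toy_index, fa, tsv)
        assert fa.read_text() == ""
        assert len(tsv.read_text().splitlines()) == 1
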