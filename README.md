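# tislocate

Detection, typing and reporting of **T-DNA integration sites (TISs)** from
paired-end sequencing of Tn5-tagmentation / bridge-primer capture libraries,
for researchers characterizing Agrobacterium-transformed plants. The package
also bundles a ground-truth library simulator (so the whole pipeline is
testable without any sequencing data), gene-context annotation of called
sites, and genomic safe harbor (GSH) prediction.

## The problem and the method

Agrobacterium-mediated transformation integrates the T-DNA segment of a
binary vector — the region between the ~25 bp left-border (LB) and
right-border (RB) repeats — at essentially random genomic positions. Knowing
each line's integration sites matters for genotyping, safety assessment and
expression interpretation. In a bridge-primer capture library, genomic DNA is
fragmented by adaptor-loaded Tn5 transposase and amplified between a bridge
primer (annealing 150–200 bp interior of the LB or RB repeat, reading toward
the border) and the Tn5 adaptor, so every informative fragment spans a
genome/T-DNA junction.

Reads are aligned to a merged reference: the genome plus the construct as one
extra contig named `tDNA`. Each read pair then falls into one of three
classes:

* **invalid** — both mates wholly on the genome or wholly on the T-DNA;
* **split** — one mate's alignment splits into a genome segment and a `tDNA`
  segment (each covering ≥ 20 bp of the read exclusively, at most two
  segments per read), pinpointing the junction base;
* **discordant** — one mate on the genome, the other on `tDNA`, corroborating
  a junction without spanning it.

Writing the construct's upper strand between LB and RB as its forward strand,
every junction is typed as `RefSide&border&Direction`: the genome flank lies
*Left* or *Right* of the junction, the T-DNA side is the *LB* or *RB* border
region, and the integrated T-DNA runs *Forward* or *Reverse* relative to the
genome forward strand — eight possible insertion types. For a split read with
genome segment `[g1, g2)` on strand *s*, the junction adjoins the segment's
high-coordinate end (ref side Left, breakpoint `g2`, 1-based) when *s* = `+`
and the T-DNA follows the genome in read order, or *s* = `−` and it precedes
it; otherwise ref side Right with breakpoint `g1 + 1`. Direction is Forward
iff both segments align to the same strand.

Evidence is deduplicated per tagmentation fragment (distinct Tn5 cut
coordinates are independent molecules; identical ones are PCR duplicates),
clustered around modal breakpoints, filtered by support (≥ 2 non-redundant
split reads, or 1 split plus ≥ 3 discordant), subtracted against a wild-type
control, and finally paired into **full TISs** — a Left call plus a Right
call whose breakpoint gap `right − left − 1` is the bp of target-site
deletion. Multi-mapping calls (e.g. in polyploid genomes with near-identical
subgenomes) are kept, flagged, and reported with all candidate loci for PCR
disambiguation.

GSH prediction takes per-class annotation tracks (genes, lncRNAs, miRNAs,
tRNAs, centromeres) and reports every interval further than a per-class
buffer (10/20/30/20/10 kb) from all features, above a minimum length.

## Worked example

Simulate a two-insertion fixture and call it back:

```bash
tislocate simulate --out demo/fx --seed 11 --events 2
tislocate call --sample line07 \
    --genome demo/fx/genome.fasta --construct demo/fx/construct.yaml \
    --fastq1 demo/fx/reads_R1.fastq --fastq2 demo/fx/reads_R2.fastq \
    --out demo/out
cat demo/out/line07.tDNA.summary
```

```
Sample	Ref:Breakpoint	RefSide	tDNA	Direction	Split_supportN	Discort_supportN
line07	chr1:17692	Left	LB	Forward	3	5
line07	chr1:17698	Right	LB	Reverse	2	6
line07	chr2:54498	Left	LB	Forward	3	5
line07	chr2:54544	Right	RB	Forward	5	3
```

Each row is one junction call: `chr1:17692` is the 1-based genome coordinate
of the last (Left) or first (Right) genome base at the junction; `tDNA` and
`Direction` give the border region and T-DNA orientation; the two support
columns count non-redundant split and discordant read pairs. `full_tis.tsv`
pairs the junctions:

```
chrom	left_breakpoint	right_breakpoint	target_deletion_bp	pattern
chr1	17692	17698	5	Left&LB&Forward + Right&LB&Reverse
chr2	54498	54544	45	Left&LB&Forward + Right&RB&Forward
```

The chr1 event is a head-to-head arrangement exposing LB at both junctions
with a 5 bp target deletion; the chr2 event is the canonical single forward
insertion (`Left&LB&Forward + Right&RB&Forward`) deleting 45 bp. Both match
the simulator's truth table (`demo/fx/truth.tsv`) exactly. The output
directory also contains supporting-read sequences with a re-alignment table
for manual checks, and 2,000 bp flanking sequences of every breakpoint for
validation-primer design (a site-specific primer ~300–700 bp from the
breakpoint combined with an LB/RB common primer yields 350–700 bp products).

Pre-computed alignments against the merged reference (e.g. from `bwa mem`)
can be supplied instead of FASTQ via `--alignments aln.sam`.

## Scope notes

Samples are processed one invocation each: barcode demultiplexing is a
sequencing-facility step, and reads are assumed adapter/quality-trimmed
(leftover mosaic-end bases are tolerated because alignment soft-clips them).
The built-in aligner is an exact-k-mer seeded, ungapped chimeric aligner
adequate for simulated and small references; for real datasets align with a
production aligner and use the SAM route. See `docs/methods.md` for the
model, parameter and design details.
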