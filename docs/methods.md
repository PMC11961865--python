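# Methods

## Reference and coordinate model

The merged reference is the unmodified genome plus the construct's LB→RB
region as one extra contig, fixed name `tDNA`; a genome contig with that name
is rejected. The construct model stores the region written 5′→3′ as the
upper/forward strand with LB at low coordinates; a configuration drawn in the
other orientation is normalized by reverse-complementing. The border repeats
themselves are included in the `tDNA` contig — junction reads must be able to
align across the repeat — and bridge sites are stored as the position where
read 2 of an amplicon begins, oriented toward their border (LB bridge on the
minus strand, RB bridge on the plus strand). Bridge sites given as primer
sequences are located by exact, unique match on the appropriate strand;
zero or multiple matches are errors.

All internal coordinates are 0-based half-open; user-facing breakpoints are
1-based. A Left junction reports the last genome base before the insertion,
a Right junction the first genome base after it, so for a paired full TIS
`target_deletion_bp = right − left − 1` counts deleted target bases directly
(negative values indicate junction overlap/duplication).

## Junction typing

Direction is defined as T-DNA(+)/genome(+) co-linearity, not relative to the
read. For split evidence both segments belong to one mate, so Direction is
Forward iff the two segments share a strand. For discordant evidence the
mates face each other across the fragment, so the rule inverts: Forward iff
the genome mate and the T-DNA mate map to opposite strands, and the genome
mate's strand gives the ref side (junction beyond its 3′ end). Border is
assigned by proximity of the junction-side `tDNA` coordinate to the two
repeat intervals; exactly equidistant evidence is discarded with a counter.
PCR-of-origin is never used for border assignment: the two border PCRs are
pooled into one library and read names carry no reliable identity.

## Split validity and the internal aligner

A mate yields split evidence only when it has exactly two segments, one on
the genome and one on `tDNA`, each covering ≥ 20 bp of the read exclusive of
their overlap; mates fragmenting into three or more segments contribute no
split evidence. These two constants reproduce the published extraction
filters for split reads (maximum of two split segments, 20 bp minimum
non-overlap).

The internal aligner is deliberately small: an exact k-mer index (k = 21,
odd, 11–31) over the forward reference, queried with the read and its
reverse complement; candidate diagonals are extended ungapped with X-drop
scoring (match +1, mismatch −3, drop 12), trimmed to the maximal-scoring
point nearest the seed so a chance match beyond a junction does not creep
the boundary outward. If ≥ 20 bp remain unaligned at either read end a
second alignment of the remainder is attempted; at most two segments are
returned. Equally-best loci are recorded as cohits (the primary is the
lexicographically smallest (contig, position) for determinism) and propagate
to calls as candidate alternative sites — mapping quality is not modeled;
ambiguity is carried explicitly instead, matching how multi-mapping sites
are resolved downstream by PCR. Gaps are not modeled (the simulator
introduces no indels); real datasets should be aligned externally and read
through the SAM route, which consumes primary plus supplementary records and
ignores secondary ones.

## Support counting and calling

Evidence is deduplicated by fragment signature — the (contig, coordinate,
orientation) of read 1's outer end, i.e. the Tn5 cut. Distinct cuts are
independent molecules; identical signatures are PCR/optical duplicates, of
which the fewest-mismatch record is kept. Split evidence is grouped by
(chrom, ref side, border, direction) and clustered greedily around modal
breakpoints within a 5 bp tolerance (tie → smallest); the reported
breakpoint is the cluster mode. Discordant evidence attaches to the nearest
compatible cluster within the library's maximum fragment length (default
900 bp). Clusters are kept with ≥ 2 split support, or 1 split plus ≥ 3
discordant. Discordant-only clusters meeting the same discordant threshold
are reported but flagged imprecise (their breakpoint is an outer bound, not
a base-exact position); they are never silently suppressed, because
discordant pairs are corroborating evidence and pipelines differ on whether
they may stand alone. All three thresholds are configuration-exposed; the
support thresholds are this package's defaults, chosen where the underlying
method states none.

Control subtraction removes any call within 10 bp of a call made by the
identical pipeline on a wild-type sample. Full-TIS pairing greedily matches
each Left call to the nearest Right call on the same chromosome within a
100 bp window; leftovers are reported as half TISs (the expected outcome
when a truncated border lost its bridge-primer site).

## The simulator: what it emulates and what it does not

The generator reproduces the library chemistry: every informative amplicon
runs from a bridge site, across the (possibly truncated) border and the
junction, to a Tn5 cut in the flanking genome; read 2 starts at the bridge
site reading toward the border, read 1 at the cut reading inward. Defaults
follow the method's stated conditions: bridge sites 150–200 bp from the
border repeats, PE150 reads, fragment lengths uniform on 150–900 bp, eight
capturable fragments per junction, PCR duplicates re-emitted at rate 0.1,
constant quality strings. With those distances read 2 cannot reach the
genome within 150 bp, so sequence-through (split) evidence comes from read 1
when the cut lands within a read length of the junction. Because PCR
strongly favors short amplicons, a fixed quota (max(2, n/3)) of each
junction's capturable fragments is drawn from the short-amplicon regime with
distinct cut sites; this emulates the size bias and means every detectable
junction is sequenced through by at least two independent molecules.

Insertion events support tandem/inverted multi-unit concatemers, border
truncations, 0–50 bp target deletions and 3–20 bp untemplated junction
filler. Truth records carry breakpoints on the *original* genome
coordinates, the two junction labels computed from payload geometry with the
same 8-type vocabulary the caller uses, and detectability flags (false when
a truncation removed the facing bridge site). A truth SAM provides oracle
alignments; segments shorter than the seed length (21 bp) are not
representable by the aligner and are soft-clipped there too, which keeps the
truth-SAM route and the aligner route exactly equivalent on error-free data.

Not modeled: sequencing errors beyond uniform substitution (no indels, no
quality decay), Tn5 insertion bias, barcodes/indices, vector backbone
outside LB–RB (backbone integrations are undetectable by design, as the
reference excludes the backbone), and junction microhomology. The scenario
generator in fact enforces the absence of microhomology — junction fillers
are built so the three bases on each side of every junction mismatch both
reference continuations — because with microhomology the breakpoint is
genuinely ambiguous at base resolution and no caller could be scored for
exactness. Consequently, passing round-trip tests demonstrate correctness of
the junction arithmetic and support accounting, not tolerance to
microhomologous or gapped junctions in real data.

Simulated problem sizes used by the test and acceptance suites — two 100 kb
contigs, one to three events per scenario, eight capturable fragments per
junction, 100 background fragments — are chosen as the smallest sizes at
which every junction geometry, truncation and deletion regime is exercised
with effectively unique 21-mers.

## Annotation and safe harbors

TIS annotation uses precedence exon > intron > promoter bins (≤ 1 kb, 1–2 kb,
2–3 kb upstream of the TSS, measured on the gene's strand — the TSS, not the
gene start field) > downstream ≤ 300 bp of the 3′ end > distal (> 3 kb).
Positions 0.3–3 kb downstream of a gene fall to a neighboring gene's
promoter bin when within 3 kb of its TSS, else distal; this closes the gap
left by bins that are not by themselves exhaustive. The nearest gene is
chosen by minimal TSS distance, ties by smaller gene id; strandless genes
are treated as + with a warning.

Safe harbors are the complement of buffered feature unions: each feature
expanded by its class buffer (defaults 10 kb centromere, 20 kb lncRNA, 10 kb
gene, 30 kb miRNA, 20 kb tRNA) and clamped at chromosome ends; complement
intervals of at least `min_length` (default 1 kb, a package default — no
minimum reportable length is stated by the method) are reported with a
count/total-bp summary. "Away from" means exclusive distance from the
feature's nearest edge, the semantics verified base-by-base by the oracle
tests. Producing the annotation tracks themselves (tRNA/miRNA/lncRNA/
centromere discovery) is out of scope; tracks are consumed as BED.

## Determinism and degenerate inputs

All randomness flows from explicit integer seeds through NumPy generators;
run logs carry no timestamps, so identical inputs give byte-identical output
directories. Zero calls is a successful run (wild-type controls). Degenerate
cases are defined rather than left to chance: empty evidence lists pass
through every stage; clustering tie-breaks prefer smaller breakpoints;
flanks and primer windows are clipped at contig ends with explicit
truncation markers/warnings; reads aligning nowhere simply yield no
segments. The blast-style check table of supported reads is produced by
re-aligning them with the internal aligner, preserving the original
artifact's purpose (manual verification) without invoking an external
binary.
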