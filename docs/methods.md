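# Methods

This note documents the models, rules and numerical choices behind each
stage, what the simulator does and does not emulate, and the known
limitations.

## Read model

Every read is a full-length cDNA consensus with the layout

```
[adapter][cell barcode][UMI][poly(A/T)][transcript][splint backbone]
```

The adapter is the constant PCR priming site of the oligo(dT) primer
(default: the 22 nt Illumina/10x read-1 priming sequence); the 16 nt cell
barcode and 10 nt unique molecular identifier (UMI) sit directly adjacent
to it and to the oligo(dT) stretch, so they can only be located by their
distance from the adapter. The splint backbone — retained from the DNA
splint that circularized the cDNA — carries a second molecular
identifier (the *splint-UMI*, default 10 nt) between two constant 18 nt
flank anchors. The splint oligo's true sequence is
protocol-specific, so both the flanks and the UMI length are
configuration (`ChemistryConfig`), and extraction is anchor-based rather
than positional. Reads may come from either strand; all stages detect
orientation themselves.

## Demultiplexing

**Whitelist.** Observed barcodes (the 16 bases immediately 3′ of the
best adapter hit) are counted exactly; the `expected_cells` most frequent
(ties broken lexicographically) form the whitelist. The default of 1500
matches a typical droplet run loading ~1500 cells; no knee-point
detection is attempted. Error-bearing barcode variants are rarer than any
true barcode whenever per-cell coverage is tens of reads or more, which
the tests verify at 1% substitution error.

**Adapter location** uses semi-global (infix) alignment of the adapter
against both strands with an edit budget of 20% of the adapter length
(`int(0.2·len)` = 4 edits for the default adapter). This budget keeps the
false-location rate on random 1 kb sequence below 1% (measured 0/1000)
while tolerating the ~2% per-base error regime of accurate long-read
consensus data. If both strands match equally well the read is flagged
ambiguous; if the adapter sits too close to the read end for a full
barcode+UMI, the read counts as adapter-less.

**Assignment rule.** With L1 and L2 the Levenshtein distances from the
observed barcode to the nearest and second-nearest whitelist entries, a
read is assigned iff `L1 < 3` and `L1 < L2 − 1`. Distances are computed
over the barcode window only (not barcode+UMI). Two whitelist entries
tied at L1 give L2 = L1, so rule 2 fails and the read is *ambiguous*;
`L1 ≥ 3` is *too distant*. With a single-entry whitelist L2 is defined
as +∞. The implementation (edlib) is checked against a brute-force
dynamic-programming oracle applying the rules literally on 1000 random
cases.

## UMI merging

Merging runs within each cell-assignment group, in two sequential
stages: first by splint-UMI (reads from the same circularization event),
then the stage-1 representatives by 10X-UMI (reads from the same RNA
molecule). "Similar UMIs" is quantified as Levenshtein distance ≤ 1
(`umi_max_edits`, exposed as a flag): at 10 nt and ~98% read accuracy
most UMI errors are single events. Grouping is single-linkage via
union-find; group membership is provably independent of input order, and
representatives are chosen deterministically (highest subread count,
then longest sequence, then smallest read id). The package selects a
representative rather than re-polishing a consensus from subreads; this
is a deliberate simplification — sufficient for molecule counting and
downstream grouping — and is documented as a divergence from re-consensus
approaches.

Merged groups whose members carry more than one distinct cell assignment
are discarded afterwards, exactly as the rule is stated. Because merging
operates within assignment groups, such conflicts can only arise from
externally supplied groupings or deliberate collision fixtures; the
discard operation accepts an explicit read→cell mapping for that reason.

The Illumina-style dedup collapses exact (barcode, UMI) pairs and keeps
those with raw read coverage strictly greater than 3, mirroring how
short-read data from the same cDNA are typically condensed.

## Isoform merging and differential usage

Transcript models enter as 21-column PSL; coordinates are 0-based
half-open throughout and comparisons are strand-aware within one
chromosome. Two models link iff

* their splice chains are equivalent: equal length and every
  corresponding site identical, or exactly 1 bp apart when the minority
  site's support × 5 ≤ the majority site's support (the `abundance_ratio`
  of 5 quantifies "much less abundant" and is configurable; support is
  summed per site over all input models), and
* both genomic start and end differ by ≤ 10 nt (`end_window`).

Grouping is single-linkage, so two members of a group may individually
be further than 10 nt apart when a third isoform connects them — this
chaining is intentional. The grouping is validated against a brute-force
transitive-closure oracle on random instances. Group representatives are
the highest-support member (ties: longest span, then smallest id), and a
group's cell count is the number of distinct source cells.

**Differential usage.** Per-cell isoform supports are summed into a gene
× isoform × cell-type table. Genes expressed in fewer than 2 cell types
or with fewer than 2 expressed isoforms are skipped. Each remaining gene
is tested with the Pearson chi-square statistic Σ(O−E)²/E (expected
counts from row/column marginals, df = (r−1)(c−1), upper-tail p); the
statistic is implemented in-package and verified against an independent
reference to 1e-8 on random tables, plus a closed-form 2×2 check.
P-values are corrected across tested genes with Benjamini–Hochberg (the
`correction` parameter accepts any statsmodels method id), and a gene is
called significant when its *corrected* p falls below α = 0.01. Whether
such a threshold applies to raw or corrected p is ambiguous in common
usage, so both values are always reported and either reading is
recoverable from the output. No pseudo-counts are added; cells
contributing zero isoforms for a gene contribute nothing.

## Immune receptor analysis

Reads are taken per cell from the IGH, IGK, IGL, TRA and TRB loci either
by alignment overlap (primary SAM records overlapping a user-supplied
BED interval by ≥1 base; unmapped/secondary/supplementary ignored; cell
identity from a `CB`-style tag or a one-file-per-cell layout) or — when
no genome alignments exist, e.g. in simulator-driven runs — by routing
each read to the locus whose V references it best matches.

**V filter.** A read passes when its best Smith–Waterman local alignment
(match 2, mismatch −2, gap open −4, gap extend −1) to any V reference on
either strand reaches identity ≥ 0.80 over ≥ 100 gapless aligned
columns. Identity is identities / aligned columns *including internal
gaps*; the length requirement counts only gapless columns. Both choices
are deliberate: chains of short spurious matches connected by gaps score
high on gap-free identity, and counting gap columns is what pushes
random-sequence hits below threshold (0/100 random 1.5 kb sequences pass
at the defaults). Candidate segments are ranked with a fast infix
edit-distance prefilter; only the winner gets the full alignment.

**Isotype split.** IGH reads are grouped by their best-scoring constant
region (isotypes IGHM, IGHD, IGHG1-4, IGHA1-2, with optional
membrane/secreted forms when the references distinguish them) before
consensus building, so alternative splicing products of one rearrangement
yield separate consensuses whose V-segment consistency can be checked.

**Consensus.** The medoid (minimum summed edit distance, ties by read
id) anchors a column space; every member is globally aligned to it and
votes per column for a base, a deletion, or an insertion; majority wins,
and insertions require support from more than half the members.
Medoid + majority vote was chosen over partial-order alignment because it
is simple, fully deterministic, order-independent, and accurate at the
supported error rates (consensus identity ≥ 99.9% at 2% substitution +
1% indel with 10 reads). This may diverge from graph-based consensus
tools at higher error rates.

**Annotation and pairing.** The best V/(D)/J/C segment per class is
called by local alignment (per-class minimum length: the smaller of
100 nt and half the reference length, so short D and J segments remain
callable); calls must appear in V→(D)→J→C order along the consensus or
the violating call is dropped and flagged; a consensus without both V
and J is reported unannotated with the reason. A cell is IG-paired when
it has an annotated IGH plus an annotated IGK or IGL (the
higher-support light chain wins if both exist; IGK on a tie), and
TCR-paired with TRA + TRB. Cells with several IGH isotype consensuses
additionally report whether all isotypes share one V call.

## The simulator

The generator exists to give every stage a ground truth. It emulates:
the exact read layout above, per-base substitution/insertion/deletion
errors at configurable rates (defaults exercise the ~98%-accuracy
regime: 1% substitutions + 1% indels), random read strand, duplication
as two independent Bernoulli layers (an extra read of the same molecule
with probability `tenx_dup_rate`; an extra copy of the same
circularization event with probability `splint_dup_rate` — matching the
two sequential merge steps), and recombined V(–D–)J–C receptor
transcripts with 0–8 random junction nucleotides per junction (enough to
exercise segment-assignment robustness; junction biology is not
modelled).

It deliberately does **not** emulate: base-quality score distributions
(qualities are constant), transcriptome-scale expression realism,
subread-level structure, chimeras, or UMI collisions — molecular
identifiers within a cell are drawn at pairwise edit distance ≥ 2 so
that exact molecule recovery is a meaningful target, and collisions are
exercised by dedicated constructed fixtures instead. Consequently,
passing tests demonstrate the correctness of the rules and algorithms
under their stated assumptions, not the error profile of any particular
sequencing chemistry.

Barcode whitelists are drawn by rejection sampling at a minimum pairwise
Levenshtein distance (default 5), which is what makes the <3-edit
assignment rule collision-safe in simulation.

## Validation problem sizes

The shipped tests and the acceptance script use: 1000 random cases for
the assignment oracle; a 100-cell, 50,000-read run at 1% substitutions +
0.5%/0.5% indels for demultiplexing recovery (≥95% assigned, <0.5%
misassigned); 20 cells × 50 molecules with both duplication layers at
0.5 for exact molecule recovery; 100 random 50-isoform instances for the
merge oracle; 1000 random tables plus a 2000-gene null simulation for
the chi-square test; and 20 B + 20 T cells at 10 reads per chain
(error-free and at 2% substitutions + 1% indels) for receptor recovery.
These sizes were chosen as the smallest at which the binomial/multinomial
sampling noise is well below the thresholds being checked.

## Known limitations

* Merged reads keep a representative sequence; no re-polishing from
  members (affects downstream consumers wanting maximal per-read
  accuracy, not molecule counts).
* The isoform stage consumes existing transcript models (PSL); it does
  not discover isoforms from reads, convert to GTF, or classify against
  an annotation.
* Receptor analysis stops at segment assignment and pairing: no CDR3
  junction analysis, somatic hypermutation, clonal lineages, or
  AIRR-schema export.
* The chi-square test assumes independent counts; UMI-merged molecule
  counts satisfy this better than raw reads, but residual duplicates
  (unmergeable UMI errors) slightly inflate evidence.
* Locus BED coordinates and segment references are user inputs; the
  shipped GRCh38 BED is an example, not a maintained database.
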