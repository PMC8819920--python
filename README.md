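# sclrtools

Toolkit for processing highly multiplexed single-cell **long-read** cDNA
sequencing data — the kind produced when full-length droplet (10x-style)
cDNA is sequenced with accurate long-read consensus protocols (R2C2/ONT)
instead of being fragmented for short reads. It is aimed at groups who
want to demultiplex such data *without* companion short-read sequencing,
recover unique molecules via two layers of molecular identifiers, compare
transcript-isoform repertoires across cells and cell types, and
reconstruct paired adaptive immune receptor (antibody and T-cell
receptor) transcripts per cell.

The package covers five stages, each usable as a library module or CLI
subcommand:

1. **Demultiplexing** (`demux`). A whitelist of the most frequent 16 nt
   cell barcodes is built by exact counting. Each read's observed barcode
   is compared to the whitelist by Levenshtein distance and assigned to
   the nearest entry iff

   ```
   L1 < 3   and   L1 < L2 − 1
   ```

   where *L1* and *L2* are the distances to the most and second-most
   similar whitelist entries. A tie at *L1* forces *L2 = L1*, so rule 2
   fails and the read is ambiguous.

2. **UMI merging** (`umi_merge`). Reads sharing a splint-backbone UMI
   (same circularization event) are merged first; the surviving
   representatives are then merged by the 10 nt cellular UMI (same RNA
   molecule). "Similar UMIs" means single-linkage grouping within
   Levenshtein distance ≤ 1. Merged groups spanning more than one cell
   assignment are discarded. An exact-match (barcode, UMI) dedup with a
   raw-coverage > 3 filter mirrors short-read processing for
   cross-platform comparison.

3. **Isoform tools** (`isoforms`). Transcript models (21-column PSL) from
   many cells merge when they use all the same splice sites — sites 1 bp
   apart count as the same site when the minority site is ≥5× less
   abundant — and their start/end positions are within 10 nt. Grouping is
   single-linkage, so chained members may individually lie further apart.
   Per-gene differential isoform usage between cell types is tested with
   a Pearson chi-square contingency test
   (χ² = Σ (O − E)² / E over the isoform × cell-type table), with
   Benjamini–Hochberg correction and a corrected-p < 0.01 call.

4. **Immune receptors** (`air`). Reads from the IGH/IGK/IGL/TRA/TRB loci
   (selected by alignment overlap with user-supplied BED intervals, or
   routed by best V-segment match) are filtered for a high-quality
   V-segment hit, split by IGH isotype, collapsed into a per-cell,
   per-locus medoid + majority-vote consensus, annotated with
   V/(D)/J/constant segments by Smith–Waterman local alignment against
   IMGT-style FASTA references, and paired (IGH with IGK/IGL; TRB with
   TRA).

5. **Simulator** (`simulate`). Generates barcode+UMI+transcript reads
   with configurable substitution/insertion/deletion errors, duplication
   at both the circularization and RNA-molecule level, random read
   strand, recombined V(D)J receptor transcripts — and a complete ground
   truth table, so every stage can be validated against known answers.

## Worked example

Simulate a small run (10 cells, 30 molecules each, 30% duplication at
both UMI levels, ~2% total error) and process it end to end:

```bash
sclrtools simulate --cells 10 --molecules-per-cell 30 \
    --splint-dup-rate 0.3 --tenx-dup-rate 0.3 \
    --sub-rate 0.01 --ins-rate 0.005 --del-rate 0.005 \
    --seed 1 --out-prefix run/sim
# -> wrote 500 reads for 10 cells

cat > config.yaml <<EOF
reads: run/sim.fastq
out_dir: run/out
seed: 1
whitelist:
  expected_cells: 10
EOF
sclrtools run config.yaml
```

which prints:

```json
{
  "stages": {
    "input_reads": 500,
    "whitelist_size": 10,
    "demux_assigned": 486,
    "demux_ambiguous": 0,
    "demux_too_distant": 14,
    "demux_no_adapter": 0,
    "after_splint_merge": 392,
    "after_tenx_merge": 330,
    "cross_cell_discarded": 0,
    "final_molecules": 330
  },
  "fractions": {
    "assigned_fraction": 0.972,
    "splint_merged_fraction": 0.1934156378600823,
    "tenx_merged_fraction": 0.15816326530612246
  }
}
```

Reading this: 500 simulated reads yielded a 10-barcode whitelist; 97.2%
of reads passed the two Levenshtein rules (14 barcodes were pushed past
the edit budget by simulated errors); splint-UMI merging collapsed 500
reads into 392 circularization events, 10X-UMI merging collapsed those to
330 molecules, and no merged group mixed cells. The per-cell FASTQs,
assignment table, and merge tables are under `run/out/`.

The same stages are available individually (`sclrtools whitelist`,
`demux`, `merge-umis`, `merge-isoforms`, `diff-isoforms`, `diversity`,
`air`); `examples/` contains a ready-made config and a GRCh38 receptor
locus BED.

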