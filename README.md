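# yy2scan

A windowed ChIP enrichment analysis toolkit: sliding-window IP-vs-control
scoring with depth normalization and pseudocounts, peak calling and ranking,
nearest-feature annotation with a five-class location scheme and
lncRNA-proximity tiers, greedy consensus motif discovery with exact match
p-values, qPCR quantification arithmetic (comparative-Ct expression, percent
input, fold enrichment, primer-efficiency QC), and a fully seeded synthetic
data generator with truth tables for end-to-end recovery testing.

## Method summary

Reads are counted into overlapping fixed-width windows (default 100 bp,
step 50 bp); a read increments every window it overlaps by at least 1 bp.
IP counts are multiplied by the ratio of mapped control reads to mapped IP
reads (held unrounded internally), zero counts are substituted by 1 on both
sides so ratios are always defined, and each window is scored as scaled-IP
over control. Windows at or above the score threshold (default 2) seed
peaks; overlapping or abutting seeds merge, and each merged area is
re-scored from the reads it contains, each read counted once per area.
Ranked peaks are annotated with the closest feature within 100 kb and
classified TSS / O / DU / DD / I (promoter-proximal within 2.5 kb of a TSS,
overlapping, distal-upstream, distal-downstream, intergenic), plus a
lncRNA-proximity tier (<= 5 kb, <= 100 kb, other). The sequences of the
top-ranked peaks (default 20) feed a greedy matrix-building consensus motif
search that maximizes information content, with per-sequence best-match
p-values computed by exact convolution of the null score distribution.

Coordinates are 0-based half-open internally; peak tables and feature TSVs
serialize as 1-based inclusive.

## Command line

```sh
# generate a synthetic dataset with planted peaks, motif and truth tables
yy2scan simulate -c sim.yaml -o data/

# full pipeline: reads -> stats -> windows -> peaks -> annotation -> motif
yy2scan run -c run.yaml

# qPCR arithmetic from a Ct CSV (sample,target,role,ct)
yy2scan qpcr ct.csv -o results.csv --calibrator control

# mapping statistics for one alignment file
yy2scan stats ip.bed --initial 14746400
```

A minimal `sim.yaml`:

```yaml
seed: 17
n_genes: 2
peaks:
  - {location_class: O, fold: 8.0, width: 300}
  - {location_class: TSS, fold: 6.0, width: 300}
ct_design:
  true_folds: {geneA: 0.2}
```

A minimal `run.yaml` (alignments are BED6 with the score column encoding
the mapping class, 0 = unique / 1 = repeated; a minimal SAM dialect is also
supported, where MAPQ 0 means repeated):

```yaml
ip: data/ip.bed
control: data/control.bed
features: data/features.tsv
genome: data/genome.fa   # optional; enables the motif stage
outdir: out/
threshold: 2.0
```

Outputs: `peaks.tsv` (ranked, annotated, 1-based inclusive coordinates),
`class_summary.tsv`, `window_scores.bedgraph`, `motif.txt`, `report.json`.
Reruns with the same inputs and settings are byte-identical.

## Layout

```
src/yy2scan/
  io_genomics.py        interval/read/feature types, BED/SAM/GFF3/TSV/FASTA I/O
  enrichment_scoring.py windows, counting, scaling, scoring, peak calling
  feature_annotation.py nearest feature, location classes, lncRNA tiers
  motif_consensus.py    greedy consensus search, IC, exact match p-values
  qpcr_quant.py         comparative-Ct, percent input, fold enrichment, QC
  synthetic_data.py     seeded genome/reads/Ct generator with truth tables
  pipeline_cli.py       stage orchestration and reports
  cli.py                click entry points
```
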