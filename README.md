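# ftcooc

Genome-wide transcription-factor footprinting and co-occupancy analysis on
ATAC-seq-like cut-count tracks, exercised end-to-end on synthetic data.

The pipeline mirrors a standard regulatory-genomics workflow:

1. **Peak calling** (`peakcall`) — simplified MACS-style sliding-window
   Poisson enrichment against local backgrounds, BH-corrected at q ≤ 0.01,
   emitting ENCODE narrowPeak.
2. **Motif scanning** (`motifscan`) — PWM log-odds scanning on both strands
   with min-max-normalized relative scores (default threshold 0.90) and an
   information-content (8-bit) specificity filter.
3. **Footprinting** (`footprint`) — an unsupervised two-component
   hierarchical mixture over per-site cut profiles (negative-binomial totals
   × binned multinomial positional profiles × logistic prior on the motif
   score), fit by EM; sites with posterior ≥ 0.99 are called bound.
4. **Regulatory annotation** (`reganno`) — promoters (−2000/+300 around the
   TSS), intragenic enhancers from a cis-element BED, region occupancy and
   the two-category gene classification (focal-only vs focal-and-partner).
5. **Co-occupancy enrichment** (`cooccur`) — the focal TF's co-binding rate
   with a partner over focal-footprinted regions, a background-TF panel
   null (mean ± sample SD), fold/z enrichment, and a two-age contrast.
6. **Promoter over-representation** (`promoter_enrich`) — oPOSSUM-style
   per-TF nucleotide-rate Z-scores (flagged at z ≥ 10) and one-sided Fisher
   exact tests over −1000/+300 promoter scans.

A first-class synthetic generator (`synthetic_cortex`) produces the full
dataset — annotation, PWMs, planted motif instances, per-age bound/unbound
truth with controllable region-level co-occupancy, and simulated cut tracks
in which bound sites show central cut depletion with flanking enrichment —
so every stage is testable without downloads.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (arithmetic
identities, footprint recovery, 50-replicate null calibration and power,
oracle equivalences, EM monotonicity, peak-caller FDR); it takes ~3 minutes,
the rest of the suite under a minute.

## CLI

Every stage is a subcommand of `ftcooc`:

```sh
ftcooc simulate --outdir data --seed 1            # synthetic dataset
ftcooc callpeaks --bedgraph data/cuts_P0.bedGraph \
    --chrom-sizes data/chrom.sizes --q 0.01 --out peaks.narrowPeak
ftcooc scan --fasta genome.fa --pwm motifs.jaspar \
    --regions peaks.bed --rel-threshold 0.90 --out sites.bed
ftcooc footprint --sites sites.bed --bedgraph cuts.bedGraph \
    --chrom-sizes data/chrom.sizes --threshold 0.99 --out calls.tsv
ftcooc annotate --tss data/tss.tsv --enhancers data/enhancers.bed --out regions.bed
ftcooc cooccur --occupancy occ.tsv --focal KLF6L --partner STAT3L \
    --panel panel.txt --out summary.json
ftcooc enrich --fg fg.txt --bg bg.txt --tss tss.tsv --fasta genome.fa \
    --pwms motifs.jaspar --out enrich.tsv
ftcooc run --config cfg.yaml --outdir out      # the whole pipeline + report
```

`ftcooc run` writes a `report.json` that is byte-identical across reruns of
the same config and seed.

## Layout

```
src/ftcooc/
  formats_io.py        # BED/bedGraph/narrowPeak/JASPAR/Cis-BP/FASTA/TSS I/O
  synthetic_cortex.py  # synthetic dataset generator with planted truth
  peakcall.py          # sliding-window Poisson peak caller
  motifscan.py         # PWM scanning and information content
  footprint.py         # EM mixture footprint classifier
  reganno.py           # promoters, enhancers, occupancy, gene categories
  cooccur.py           # co-occupancy rate, background null, enrichment
  promoter_enrich.py   # promoter motif over-representation
  pipeline.py, cli.py  # orchestration and the ftcooc CLI
```
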