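# tadbound

Toolkit for comparative chromatin-architecture analysis of a two-TAD locus
with a boundary of tunable strength. It covers the full path from mapped
interaction data to boundary phenotypes:

- **`tadbound.alleles`** — in silico mutant chromosomes from an edit script
  (ordered deletions/insertions on a backbone), with exact bidirectional
  position liftover and re-framing of binned contact matrices onto the
  wild-type grid (deleted bins are masked, never partially lifted).
- **`tadbound.hic`** — Hi-C pair records to matrices: restriction-fragment
  assignment with the 3-bp cut-site shift, strand-geometry pair filtering
  (dangling ends / self-circles / error pairs), duplicate removal,
  fragment-midpoint binning, low-coverage bin masking, iterative-correction
  (ICE) balancing, matrix subtraction, and rank-sum comparison of
  within-domain contact intensities.
- **`tadbound.boundaries`** — insulation-diamond signal (e.g. window 6 at
  40-kb bins = a ±240-kb diamond), TopDom-style domain calling
  (signal → turning points → rank-sum filter), consensus TADs across window
  sizes 3–15 (kept when the exact coordinates recur in ≥ 40% of windows),
  and boundary-shift measurement between genotypes.
- **`tadbound.fourc`** — 4C-seq viewpoint quantification: 11-fragment
  smoothing, ±5-Mb viewpoint normalization, inter-domain contact
  percentages with exclusion zones, per-region sums, cumulative contact
  curves, and Euclidean/Ward clustering of curves across genotypes.
- **`tadbound.synth`** — ground-truthed synthetic locus generator (power-law
  decay, TAD blocks, permeable boundary, per-bin biases, Poisson counts,
  4C viewpoint profiles, deletion alleles) used to validate every stage.
- **`tadbound.cli`** — the `tadbound` command and per-stage aliases.

## CLI

All stages are subcommands of `tadbound` (also installed as standalone
aliases `hic-bin`, `hic-ice`, `tads-consensus`, `fourc-quant`, …):

```sh
tadbound simulate --preset wildtype --seed 0 --out-prefix wt
tadbound hic-ice --matrix wt.matrix.tsv --max-iter 1000 --out wt.iced.tsv
tadbound tads-consensus --matrix wt.iced.tsv --windows 3:15 --out wt.tads.bed
```

An end-to-end wild-type vs. deletion-allele comparison runs from a plain
`key=value` config:

```sh
cat > run.cfg <<EOF
preset=del-full
seed=0
outdir=report
EOF
tadbound run --config run.cfg   # matrices, subtraction, consensus BEDs, summary.txt
```

Matrices travel as dense TSV (or sparse triplets) with a JSON sidecar
(grid, mask, biases); tracks and calls use bedGraph/BED; pairs and edit
scripts are TSV; sequences are FASTA.

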