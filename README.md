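# cistrack

Stage-resolved multi-omic integration of transcription-factor binding,
chromatin state, and gene expression across a three-stage differentiation
time course (D0 → D15 → D35), for wild-type vs. mutant genotype contrasts.

The pipeline implements, as tested reusable components:

- **Replicate-consensus peak calling** under a reciprocal-fraction overlap
  predicate (`-f 0.25 -F 0.25`, either-mode), keeping regions supported by
  ≥ 2 of 4 replicates (`cistrack.intervals`).
- **Temporal binding classification** of consensus peaks into the 7 nonempty
  subsets of {D0, D15, D35} via cross-stage overlap components
  (`cistrack.temporal`).
- **Peak annotation** against gene models: nearest-TSS assignment, a ±2 kb
  promoter window, and precedence-resolved genomic categories.
- **Expression analysis**: CPM/RPKM normalisation, a 1.5-fold dynamic-gene
  filter, K = 12 k-means temporal archetypes in D0-relative space, and an
  in-repo negative-binomial Wald test (pooled method-of-moments dispersion,
  median-of-ratios size factors) with 2-fold / 1 CPM / BH-FDR 0.05
  differential-expression thresholds (`cistrack.expression`).
- **Chromatin states**: per-peak, per-stage H3K4me3/H3K27ac/H3K27me3 flags,
  derived bivalency (K4me3 ∩ K27me3), state-transition tabulation, and
  differential binding on per-peak counts (`cistrack.chromatin`).
- **Integration**: hypergeometric cluster-distribution enrichment, curated
  gene-list overlap, and the direction-concordant DBR × DEG × binding-kinetics
  join (`cistrack.integrate`).
- **Motif enrichment**: PWM log-odds scanning on both strands and Fisher
  exact foreground/background enrichment with GC-binned, length-matched
  backgrounds (`cistrack.motifs`).
- **Synthetic data**: a full multi-layer study generator with planted
  temporal classes, mark coupling, 12 expression archetypes, genotype
  effects, and motif instances — all recorded in a machine-readable truth
  ledger (`cistrack.simulate`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, planted-truth recovery, null calibrations, determinism); the
remaining files are per-module unit and property tests. The committed
`tests/data/tiny_fixture/` is regenerated deterministically by
`cistrack.simulate.export_fixture("tiny", ..., seed=0)`.

## CLI

```sh
cistrack simulate --seed 7 --size tiny --out study/
cistrack consensus --peaks r1.bed --peaks r2.bed --peaks r3.bed --peaks r4.bed --out consensus.bed
cistrack classify --d0 c0.bed --d15 c15.bed --d35 c35.bed --out classes.tsv
cistrack annotate --peaks consensus.bed --genes genes.tsv --exons exons.tsv --out ann.tsv
cistrack cluster --counts rna_counts.tsv --samples rna_samples.tsv --gene-lengths gene_lengths.tsv --out clusters.tsv
cistrack de --counts rna_counts.tsv --samples rna_samples.tsv --stage D35 --out degs.tsv
cistrack states --chd2 consensus.bed --histone H3K4me3:D0:k4_d0.bed ... --out states.tsv
cistrack dbr --counts k27ac_counts.tsv --samples k27ac_samples.tsv --out dbrs.tsv
cistrack integrate --dbrs dbrs.tsv --degs degs.tsv --classes classes.tsv --peaks peaks.bed --genes genes.tsv --out concordance.tsv
cistrack motif --fasta genome.fa --fg fg.bed --pwms motifs.jaspar --out enrichment.tsv
cistrack pipeline --study study/ --seed 7 --out results/
```

All thresholds live in a YAML config mirroring `AnalysisConfig`
(`--config cfg.yaml`).
Every stochastic stage is seeded (`--seed`), and identical seeds give
byte-identical outputs.

## Formats

BED6 / ENCODE narrowPeak for peaks, TSV with header for count matrices and
result tables, FASTA for sequences, JASPAR-style plain-text count matrices
for PWMs, YAML for configs and the synthetic truth ledger. Coordinates are
0-based half-open throughout.
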