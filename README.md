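# nptrap

Simulation and analysis toolkit for metabolic-labeling transcriptome and
translatome sequencing. The package models the full desk-scale workflow for
4sU/SLAM-seq-style experiments with paired cytosolic-RNA and ribosome-IP
(TRAP) libraries:

- **`nptrap.synthetic_data`** — ground-truth transcript models (first-order
  labeling kinetics, per-read uridine content, translation efficiency,
  ribosome-loading lag), planted regulation modes
  (forwarded / exclusive / intensified / buffered), negative-binomial count
  simulation with a T>C detection channel, and read-level simulation with
  per-uridine conversions plus a background error channel.
- **`nptrap.conversion_counting`** — read trimming (5' clip + poly(A)
  removal), per-read substitution counting against the reference, T>C read
  classification, per-gene tcount tables (ReadCount / TcReadCount /
  coverageOnTs / conversionsOnTs / readsCPM) and conversion-rate QC.
- **`nptrap.decomposition`** — per-gene nascent proportions, a detection
  sensitivity estimator based on the most strongly induced genes, sensitivity
  correction, non-T>C (pre-existing) counts and bulk proportions.
- **`nptrap.differential_expression`** — median-of-ratios size factors,
  cross-assay normalization (labeled-read counts are always modelled with
  offsets from *total* reads), trend-shrunk NB dispersion, a vectorized NB-GLM
  Wald test, BH adjustment and DEG calling.
- **`nptrap.delta_te`** — joint RNA/TRAP modelling with a condition x assay
  interaction and classification of genes into the four regulation modes,
  plus a recovery report against planted truth.
- **`nptrap.category_stats`** — Mann-Whitney ECDF shift tests for gene sets,
  pairwise nascent-proportion comparisons, ORF-length stratification with a
  Spearman trend statistic, and hypergeometric over-representation analysis
  against GMT gene sets.
- **`nptrap.io` / `nptrap.cli` / `nptrap.pipeline`** — TSV/FASTA/SAM/GMT
  readers and writers, validated YAML configuration and the end-to-end
  pipeline with a run manifest.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (counting oracle
equivalence, conversion-rate recovery, sensitivity-estimator recovery,
decomposition recovery, DE calibration, cross-normalization correctness,
deltaTE mode recovery, category statistics, end-to-end determinism). One
sub-test (`test_8a_mw_worst_case_agreement`) asserts a worst-case
approximation bound that is mathematically unattainable and fails by design;
everything else is green.

## CLI

```sh
nptrap run --out results/run --seed 1                # full synthetic pipeline
nptrap simulate --outdir sim --seed 1 --reads        # counts + SAM/FASTA
nptrap count --sam sim/rna_control_rep1.sam --ref sim/reference.fasta \
    --min-bq 27 --min-tc 1 --out counts.tsv
nptrap decompose --control c1.tsv --control c2.tsv \
    --treated t1.tsv --treated t2.tsv --top-k 3 --outdir dec
nptrap de --counts tc.tsv --meta samples.tsv --read-class tc \
    --norm-from total.tsv --alpha 0.05 --lfc 1.5 --out de.tsv
nptrap deltate --rna rna.tsv --trap trap.tsv --meta samples.tsv \
    --norm-from total.tsv --out deltate.tsv
nptrap genesets --lfc lfc.tsv --gmt sets.gmt --outdir gs
```

All commands take `--config` (YAML; unknown keys are rejected) where
applicable, and the pipeline writes a `manifest.json` recording the effective
configuration, seed and every output. Re-running with the same seed
reproduces all numeric outputs byte-for-byte.

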