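# immunorep

Adaptive immune repertoire analysis for bulk RNA-seq cohorts: clone
identification from AIRR rearrangement tables, per-chain diversity metrics,
phenotype-stratified nonparametric statistics, survival modelling, and a
synthetic-cohort generator so the whole pipeline is testable fully offline.

## What it does

- **airr_io** — reads/writes AIRR Rearrangement TSVs and the TRUST4-style
  simple-report dialect; productivity filter (in-frame, stop-free, complete
  CDR3).
- **clonotyping** — clones as single-linkage components over CDR3 nucleotide
  Hamming identity within (locus, V gene, J gene, CDR3 length) groups;
  inclusive thresholds 0.90 (BCR: IGH/IGK/IGL) and 0.95 (TCR:
  TRA/TRB/TRD/TRG); deterministic, order-independent output.
- **metrics** — per (sample, chain): abundance, unique clones, CPK (clones
  per kiloread of library, or per-million mode), Shannon entropy (nats or
  bits), clonality `1 − H/ln R`. Undefined values are NA, never 0.
- **stats** — Mann-Whitney (exact for small tie-free samples),
  Kruskal-Wallis + Dunn, Benjamini-Hochberg FDR within labelled families,
  Spearman correlation of chain metrics vs marker genes / signature scores,
  `log2(value + 1)` transform.
- **survival** — median-dichotomized Kaplan-Meier with log-rank tests
  (ties at the median go Low), multivariate Cox PH adjusted for phenotype
  (LSP vs HSP reference) and stage, with chain-interaction covariates;
  Efron tie handling; metric covariates enter on the log2(value+1) scale.
- **synthetic** — cohort generator with phenotype-dependent read abundance,
  Zipf clone-size concentration (controls the LSP/HSP entropy gap), marker
  expression coupled to chain abundance, and exponential survival with a
  designed protective phenotype effect (default HR 0.1). A `null` preset
  switches all phenotype effects off for calibration studies.
- **pipeline / cli** — end-to-end orchestration with a YAML config, a
  hashed artifact manifest, and a cohort detection summary
  (BCR-only / TCR-only / both / neither).

## CLI

```sh
# generate a synthetic cohort (AIRR TSVs + clinical + expression + truth)
immunorep simulate --seed 1 --n-lsp 31 --n-hsp 47 --preset paper-like --out cohort/

# individual stages
immunorep clonotype --repertoire-dir cohort/repertoires --out clones.tsv
immunorep metrics --repertoire-dir cohort/repertoires \
    --library-reads cohort/library_reads.tsv --out metrics.tsv

# full pipeline from a YAML config (see immunorep.pipeline.PipelineConfig)
immunorep run-all --config config.yaml
```

A minimal config:

```yaml
repertoire_dir: cohort/repertoires
clinical_path: cohort/clinical.tsv
expression_path: cohort/expression.tsv
library_reads_path: cohort/library_reads.tsv
output_dir: out
```

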