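# kopathbench

Knockout-pathway benchmarking pipeline for bulk transcriptomics:

- **Automatic DEG selection** — network edge scores combine per-gene
  fold-change and p-value evidence (`ES = sqrt(w_u * w_v)` with
  `w_g = |lfc| * (-log10 p)`); a single change point (Gaussian mean+variance
  model, MBIC-penalized scan) on the descending-sorted score distribution
  yields the high-edge-score (HES1) cutoff, and genes incident to retained
  edges form the DEG set.
- **Signed-topology pathway perturbation scoring** — per pathway, a
  normalized signed influence matrix `B` propagates DEG fold-changes
  (`PF = dE + B @ PF`); the accumulated perturbation `tA = sum(PF - dE)` is
  tested against a bootstrap null (`pPERT`), combined with a hypergeometric
  over-representation p-value (`pNDE`) into `pG = c - c*ln(c)`, and
  BH-adjusted across pathways (`pGFdr`).
- **Knockout ground-truth ROC benchmarking** — pathways containing the
  knockout gene are positives; any method's per-pathway p-values are scored
  with AUC + DeLong 95% CI, partial AUCs over the 90–100% specificity and
  sensitivity bands (original and McClish-corrected), and the Youden-optimal
  threshold.
- **Multi-contrast DEG intersection** — the three contrasts' DEG sets are
  partitioned into the seven Venn regions with per-region ranking by best
  edge score.
- **Synthetic-data generator** — signed pathway DAGs over a shared gene
  universe with a planted knockout gene, matching KGML fixture files, and a
  three-group expression design (untreated WT, septic WT, septic KO) with
  sign-propagated treatment shifts, so every stage is testable end to end
  without external data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(formatting worked examples, perturbation/path-enumeration oracle,
statistical-machinery oracles, change-point recovery, end-to-end parameter
recovery, DeLong CI calibration).

## CLI

```sh
# synthetic study -> expression.tsv, metadata.tsv, kgml/, truth.json
kopathbench simulate --seed 7 --n-pathways 30 --n-positive 5 --out sim/

# full pipeline from a YAML config
kopathbench run --config cfg.yaml --out out/

# individual stages
kopathbench stats --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --contrast C --out stats_C.tsv
kopathbench degs --stats stats_C.tsv --kgml-dir sim/kgml --out degs_C/
kopathbench roc --scores pg.json --kgml-dir sim/kgml --ko-gene G0001 --out roc.json
kopathbench report --spia out/contrast_C/spia_results.tsv
```

A minimal config:

```yaml
ko_gene: G0001
seed: 7
n_boot: 2000
simulate:
  n_genes: 2000
  n_pathways: 30
  n_positive_pathways: 5
  delta_treatment: 1.5
  delta_ko: 1.5
  noise_sd: 0.25
  n_replicates: 3
```

Real data instead of simulation: replace the `simulate` block with
`expression`, `metadata` (TSVs) and `kgml_dir` (a directory of KGML files).
Contrasts are fixed to `A` (septic KO vs septic WT), `B` (septic KO vs
untreated WT) and `C` (septic WT vs untreated WT).

Outputs per contrast: `stats.tsv`, `edge_scores.tsv`, `hes.json`,
`degs.tsv`, `high_edges.tsv`, `edge_histogram.json`, `spia_results.tsv`,
`report.txt`, `roc_summary.json`, `roc_points.tsv`; across contrasts
`venn.tsv`; plus `manifest.json` (sha256 per file) and `run.log`.

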