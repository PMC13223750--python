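# kynpath

A tested, reusable pipeline for locating metabolic bottlenecks in de novo
NAD+ synthesis from tryptophan, from longitudinal clinical omics:

* **Targeted-metabolomics preprocessing** — missingness filtering (80% rule,
  inclusive boundary), half-minimum imputation of left-censored values,
  log10 transform + autoscaling, and the derived kynurenine-pathway ratio
  panel (Kyn:Trp, PA:QA, QA:Trp, QA:sumIDO, QA:3OHAnth; ratios always
  computed on raw concentrations).
* **GPR → RAS scoring** — a parser for boolean gene–protein–reaction rules
  and expression-conditioned reaction activity scores (AND → min,
  OR → sum, with a `max` alternative) over a packaged tryptophan-degradation
  subnetwork that includes the QPRT-gated QA → NAMN reaction (`R24a`), the
  serotonin branch, and the nicotinamide salvage entry.
* **Longitudinal association** — linear mixed models
  (`response ~ sex * activity + covariates + (1 | patient)`, REML, Wald
  normal inference), logarithmic-decline imputation of missing HBI/Mayo
  scores, Benjamini–Hochberg correction, remitter vs. non-remitter per-week
  contrasts, and Spearman correlations with FDR.
* **Enrichment & signatures** — t-value ranking construction, permutation
  GSEA (weighted KS running sum, gene-label null), hypergeometric
  overrepresentation, rank-based single-sample gene-set scoring, GMT I/O,
  and a built-in IFN-γ signature.
* **Synthetic cohorts** — deterministic generators for longitudinal UC/CD
  cohorts with planted IDO1/QPRT activity effects, pathway-coupled serum
  metabolomes, and below-LOD left-censoring, so the whole chain is testable
  without any external data.
* **Orchestration** — a YAML-configured end-to-end pipeline
  (simulate-or-load → preprocess → RAS → associate → enrich → bottleneck
  report) whose runs are byte-for-byte reproducible under a fixed seed.

UC/CD disease-activity scales (total Mayo 0–12, HBI 0–16) are z-scored
within scale before pooling; planted effects are per standardized activity
unit.

## CLI

```sh
# end-to-end from a YAML config
kynpath run --config config.yaml --outdir results/run1 --seed 7

# individual stages
kynpath simulate --seed 7 --outdir results/sim
kynpath prep --metabolome results/sim/metabolome.tsv --outdir results/prep
kynpath ras --expression results/sim/expression.tsv --outdir results/ras
kynpath associate --responses results/ras/ras.tsv --cohort results/sim/cohort.tsv --outdir results/assoc
kynpath enrich --ranking results/run1/ranking.tsv --gmt sets.gmt --outdir results/enrich
kynpath report --outdir results/run1
```

Minimal config:

```yaml
mode: simulate          # or "load" with a paths: block
seed: 7
synthetic:
  n_patients: 60
  weeks: [0, 2, 6, 14]
  beta_ido1: 0.15       # activity effect on log-IDO1 TPM
  beta_qprt: -0.15      # activity effect on log-QPRT TPM (suppression)
covariates: [age, bmi, diagnosis]
n_perm: 1000
```

In `load` mode, supply `paths: {cohort: ..., metabolome: ..., expression:
..., model: ..., gene_sets: ...}` — TSV matrices (samples × features, empty
cell = missing), a pathway-model JSON, and optional GMT gene sets.

The report (`report.json`) lists per-reaction/metabolite/ratio activity
effects and the flagged bottleneck reactions: reactions with a significant
negative activity association lying downstream (directed substrate→product
reachability) of at least one significant positive reaction. This decision
rule is artifact-defined; spontaneous (GPR-less) reactions conduct
reachability but are never flagged.

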