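# protarget

Proteogenomic target discovery for paired tumor/normal proteomic cohorts:

- **preprocess** — per-sample MAD normalization (unit MAD), missingness
  filtering, and RNA FPKM normalization (zero filter → log2 → quantile).
- **diffexp** — paired tumor-vs-normal differential expression on within-pair
  differences with mean-centered covariates (age, gender, optionally batch),
  empirical-Bayes variance moderation and Benjamini–Hochberg FDR.
- **oppti** — outlier-overexpression detection: each marker's expected
  abundance per tumor sample is inferred from its top-k positively
  co-expressed markers (correlation-weighted KNN); observed-minus-inferred
  dysregulation scores are robustly restandardized, thresholded into
  overexpression calls (PRO = called / quantified samples), and marker-level
  enrichment is tested against a pooled within-sample permutation null.
- **proteogenomics** — driver-mutation filtering (truncating + recurrent
  missense), per-gene DNA mutation fraction vs mRNA/protein overexpression
  rates, druggable-candidate intersection and cross-cohort PRO concordance.
- **dependency** — per (drug, target) OLS regression of cell viability on
  baseline protein expression across a cell-line panel; negative slopes mark
  expression-driven dependencies.
- **simulate** — seeded generators for every input with recorded ground
  truth: co-expressed paired proteomes (latent-factor blocks), planted fold
  changes and outlier events, protein-coupled RNA, mutation tables with a
  recurrence catalog, gene lists and drug screens with planted slopes.

## CLI

Every stage is a subcommand of the `protarget` entry point:

```bash
# write a synthetic input bundle with ground truth
protarget simulate --out bundle/ --seed 1 --n-de 25 --n-outlier-markers 20

# individual stages
protarget preprocess --matrix bundle/proteome_tumor.tsv --out tumor_norm.tsv
protarget oppti --matrix tumor_norm.tsv --out oppti.tsv --k 10 --threshold 2.0 \
    --nperm 100 --seed 1
protarget diffexp --matrix combined_norm.tsv --meta bundle/sample_meta.tsv --out dep.tsv
protarget mutfilter --mutations bundle/mutations.tsv \
    --catalog bundle/recurrence_catalog.tsv --out kept.tsv
protarget compare --mutations kept.tsv --oppti-protein oppti.tsv \
    --oppti-rna oppti_rna.tsv --samples bundle/sample_meta.tsv --out summary.tsv
protarget candidates --diffexp dep.tsv --oppti oppti.tsv \
    --druggable bundle/druggable.txt --out candidates.tsv
protarget concordance --oppti-a oppti_a.tsv --oppti-b oppti_b.tsv --out conc.tsv
protarget dependency --viability bundle/screen_viability.tsv \
    --expression bundle/screen_expression.tsv \
    --drug-targets bundle/drug_targets.tsv --out deps.tsv

# full pipeline from a YAML config (simulate block or explicit input paths)
protarget run-all --config config.yaml --out run/
```

A minimal `config.yaml`:

```yaml
seed: 1
simulate:
  n_markers: 500
  n_subjects: 150
  n_de: 25
  n_outlier_markers: 20
  missing_rate: 0.05
params:
  oppti: {k: 10, threshold_T: 2.0, n_perm: 100}
  fdr_max: 0.05
  fc_min: 1.0
  pro_min: 0.10
  min_recurrence: 3
```

`run-all` writes per-stage TSVs, a human-readable `summary.txt` and a
`manifest.json` recording parameters, per-stage seeds and input digests;
re-running the same config reproduces every output byte-for-byte.

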