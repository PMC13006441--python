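# serumscape

Cross-system serum proteome profiling for aptamer affinity proteomics:
from raw sample × aptamer intensity matrices (relative fluorescence units)
through QC, duplicate-aptamer resolution, covariate-adjusted differential
abundance, multivariate group tests, compartment/tissue/secretome footprint
statistics, correlation networks, and cross-platform (immunoassay)
validation.  A seeded synthetic-data generator emulates the statistical
structure of a case/control serum cohort so every stage is testable without
external data.

## Modules

| module                   | role |
|--------------------------|------|
| `serumscape.types`, `serumscape.io` | core data types (`IntensityMatrix`, `AptamerAnnotation`, `SampleMetadata`) and TSV/CSV readers/writers |
| `serumscape.synth`       | seeded generator: log-normal intensities, duplicated aptamers at tunable correlation, class-conditional group effects, covariate effects, injected outliers, noisy cross-platform replicate |
| `serumscape.qc`          | chi-square outlier flagging on PC-space Mahalanobis distances; per-aptamer z-score masking with min/max imputation |
| `serumscape.dedup`       | aptamer-pair Pearson categories, ≥80% directional consensus, decision-tree duplicate resolution |
| `serumscape.diff`        | per-aptamer OLS with covariates, empirical-Bayes variance moderation, BH FDR, Welch tests, rank-classifier metrics |
| `serumscape.multivariate`| PCA, PERMANOVA, covariate projection onto PC coordinates, drop-one variance partitioning |
| `serumscape.profiling`   | subcellular/tissue/immune/secretome panel proportions, two-sample KS and Hodges–Lehmann shift statistics |
| `serumscape.network`     | semi-partial correlation network, clinical-interaction communities, hypergeometric ORA, ligand–receptor concordance |
| `serumscape.xplat`       | cross-platform concordance classes, signal consistency, metabotype-stratified statistics, low-abundance filter |
| `serumscape.pipeline`, `serumscape.cli` | orchestration, config, seeded reproducible runs |

## CLI

```bash
# generate a seeded synthetic dataset (4 TSV artifacts)
serumscape synth --seed 1 --outdir data/

# QC, then covariate-adjusted differential abundance
serumscape qc   --matrix data/intensities.tsv --outdir qc/
serumscape diff --matrix qc/intensities_clean.tsv --metadata data/metadata.tsv \
                --outdir diff/

# duplicate resolution, multivariate tests, footprint profiles, network
serumscape dedup  --matrix qc/intensities_clean.tsv \
                  --annotations data/annotations.tsv --diff diff/diff.tsv \
                  --outdir dedup/
serumscape mvar   --matrix qc/intensities_clean.tsv \
                  --metadata data/metadata.tsv --outdir mvar/
serumscape profile --diff diff/diff.tsv --annotations data/annotations.tsv \
                  --outdir profile/

# or run everything end-to-end on synthetic input
serumscape run --seed 1 --outdir run/
```

`serumscape run` accepts a YAML config mirroring `pipeline.RunConfig`
(thresholds `alpha`, `q_alpha`, `z_cut`, `r_cut`, `consensus`,
`max_missing`, permutation counts, stage toggles) with a `synthetic:`
section mirroring `synth.GeneratorConfig`.

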