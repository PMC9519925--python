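# imgtx

Imaging-transcriptomics analysis pipeline linking regional gene expression to
sex-specific resting-state functional-connectivity (rsFC) case-control
effects. The package implements the full analysis chain — donor microarray
mapping to a parcellation, group contrasts with empirical-Bayes site
harmonization, NIPALS partial least squares with bootstrap loading-weight
ranking, spatially constrained (spin) and uniform permutation nulls,
cross-validated reproducibility testing, preranked gene-set enrichment,
genotype-based validation, and sample-composition / classifier power
simulations — and a synthetic-data module that generates every input with
known ground truth so the whole chain is testable offline.

## Modules

| module | role |
| --- | --- |
| `imgtx.synthetic_data` | Parcellation geometry, donor microarray sample sets, subject-level rsFC with factorial effects, planted gene-map associations, gene sets, genotypes — all seeded and truth-recording |
| `imgtx.expression_atlas` | Probe collapse → 2 mm sample-to-parcel assignment → per-donor Z → hemisphere mirroring → cross-donor aggregation into the parcels × genes Z matrix |
| `imgtx.connectivity_stats` | Fisher-z rsFC, parametric ComBat harmonization, two-way factorial ANOVA, sex-stratified post-hoc t maps, BH-FDR, shared/specific classification, sex-label permutation test, seed effect maps |
| `imgtx.pls_core` | NIPALS PLS1, component correlations, bootstrap loading-weight SDs and z-ranking |
| `imgtx.null_models_cv` | Spin permutations (mirrored hemispheric rotations + bijective reassignment), spin/random significance tests, ten-times ten-fold CV with the corrected resampled t-test and Bonferroni omnibus |
| `imgtx.enrichment` | Weighted-KS enrichment scores, gene-sampling null NES/p/q, decile counts and simulated decile confidence bands |
| `imgtx.genotype_validation` | Hardy-Weinberg chi-square, SNP QC, convergent-gene selection, risk-allele scores, sex-stratified score→rsFC OLS |
| `imgtx.power_sims` | Sex-composition bootstrap of case-control contrasts; elastic-net logistic classifiers over a regularization path with per-ROI weight aggregation |
| `imgtx.pipeline_runner` | Config validation, seed substreams, end-to-end workflow driver with manifests and checksums |

## CLI

All stages are exposed under one entry point:

```bash
imgtx run --config cfg.yaml --out run/ --seed 1      # full synthetic workflow
imgtx simulate --out fixtures/ --seed 1              # write fixture files
imgtx map-expression --atlas-dir fixtures/ --geometry fixtures/geometry.tsv --out X.tsv
imgtx contrast --rsfc rsfc.tsv --meta meta.tsv --seed-roi L001 --sex M --out Y.tsv
imgtx pls --x X.tsv --y Y.tsv --nboot 10000 --seed 1 --out pls/
imgtx spin --x X.tsv --y Y.tsv --geometry geometry.tsv --nperm 10000 --seed 1 --out spin.json
imgtx cv --x X.tsv --rsfc rsfc.tsv --meta meta.tsv --seed-roi L001 --sex M --out cv.json
imgtx gsea --ranks ranked_genes.tsv --gmt sets.gmt --nperm 10000 --seed 1 --out gsea.json
imgtx genetics --genotypes g.tsv --rsfc rsfc.tsv --meta meta.tsv --feature "L001|L002" --sex M --out gen.json
imgtx power --rsfc rsfc.tsv --meta meta.tsv --mode composition --out power.json
```

Config keys and their defaults live in `imgtx.pipeline_runner.DEFAULTS`;
unknown keys are rejected. Every run directory receives the verbatim config,
per-stage timings, and a checksum manifest; reruns with the same config and
seed produce byte-identical numeric artifacts.

## File formats

Everything is plain text: TSV matrices (expression, rsFC, effect maps,
contrast tables, rankings), AHBA-dialect CSV triplets per donor
(`SampleAnnot.csv`, `MicroarrayExpression.csv`, `Probes.csv`), GMT gene
sets, tab-delimited `{0,1,2,NA}` genotype matrices with a JSON annotation
sidecar, and JSON for truth records, null distributions, and CV results.
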