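# twindiscord

Analysis pipeline for disease-discordant monozygotic-twin cohorts that
combine methylome (450K-style array plus targeted amplicon assays) and
transcriptome (RNA-seq count) data, together with a synthetic-data module
that generates full cohorts with planted truth so every stage is testable
offline.

## Stages

| module | contents |
| --- | --- |
| `twindiscord.core` | domain types (sample sheet, β/M/detection-p/count matrices, probe annotation, clock model), TSV/CSV I/O, β↔M transform, matrix/sheet alignment |
| `twindiscord.simulate` | twin cohorts with planted Δβ effects, case-control cohorts, amplicon plates with structured missingness, synthetic epigenetic clocks with an exactly invertible age embedding, cell-type references and mixtures, negative-binomial counts with planted fold changes |
| `twindiscord.epityper` | amplicon CpG-unit QC: site averaging, duplicate averaging, two-step missingness filter (≥90% then ≥15%, inclusive), unit-mean imputation, between-plate CV |
| `twindiscord.array_qc` | sample detection filter (<99% detected removed), probe detection filter (p > 0.05), technical-replicate variance filter, blacklist removal, clock-correlation sample gate (r < 0.85) |
| `twindiscord.features` | global and CpG-density-stratified (HC/IC/ICshore/LC) mean methylation, DNAm age (identity or piecewise exp/linear anti-transform), constrained least-squares cell deconvolution (w ≥ 0, Σw ≤ 1) |
| `twindiscord.models` | twin-structured linear mixed models with ML likelihood-ratio tests, logit-scale proportion models for cell fractions (+0.001 offset), per-probe case-control linear models, BH-FDR |
| `twindiscord.dmp` | per-individual collapsing, paired t-test on M-values, ranked magnitude-significance DMP procedure with direction-consistency truncation, within-set \|Δβ\| ≥ 0.25 calling, gene aggregation and cross-set overlaps |
| `twindiscord.expression` | CPM filtering (strictly greater), TMM normalisation factors, log2-CPM, paired longitudinal differential expression with mean–variance precision weights and trend-pooled variance, FDR + fold-change gating, case-control validation on a gene subset |
| `twindiscord.integration` | cross-platform gene-list overlap with universe restriction, Fisher-exact gene-set enrichment (GMT) with fold-enrichment and direction, hierarchical clustering (manhattan/ward, spearman/average), PCA |

## Command line

```sh
twindiscord simulate    --config sim.yaml --out cohort/
twindiscord epityper-qc --plate plate.tsv --sheet sheet.csv --out qc/
twindiscord array-qc    --beta beta.tsv --detp detp.tsv --sheet sheet.csv \
                        --annot annot.tsv --blacklist-flags all --out qc/
twindiscord features    --beta beta.tsv --annot annot.tsv --clock clock.csv \
                        --cell-reference ref.tsv --out features.tsv
twindiscord dmp         --beta beta.tsv --sheet sheet.csv --annot annot.tsv --out dmp/
twindiscord deg         --counts counts.tsv --sheet sheet.csv \
                        --min-cpm 0.3 --min-samples 3 --fdr 0.05 --fc 1.5 --out deg/
twindiscord enrich      --genes genes.txt --gmt sets.gmt --background bg.txt --out enrich.tsv
twindiscord integrate   --dmp-genes a.txt --deg-genes b.txt \
                        --methylation-universe mu.txt --expression-universe eu.txt \
                        --out overlap.json
```

A minimal `sim.yaml`:

```yaml
n_twin_sets: 4
triplet_sets: [4]
n_probes: 5000
n_planted_dmps_shared: 20
delta_beta: 0.3
n_collections: 2
n_replicates: 2
seed: 1
clock: {n_clock_cpgs: 20, transform: horvath, seed: 1}
counts: {n_genes: 1000, n_planted_degs: 20, seed: 2}
```

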