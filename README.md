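# prsgxe

Refined polygenic-score construction and gene-by-environment (GxE)
interaction analysis, with a synthetic twin-cohort generator so the whole
pipeline is testable without restricted cohort data.

The workflow:

1. **geno_io** — read GWAS summary TSVs, VCF (GT/DS) or dosage-TSV
   genotypes; align counted alleles to GWAS effect alleles (flipping or
   dropping strand-ambiguous SNPs); QC-filter on call rate / MAF / HWE;
   LD pruning and principal components for population structure.
2. **prs_core** — greedy LD clumping by ascending GWAS p; polygenic scores
   over a 100-cutoff p-value grid; selection of the best-predicting cutoff
   against a training phenotype; per-SNP refinement (keep SNPs individually
   associated with the phenotype at raw p < 0.05); transfer of the refined
   weighted score to an independent cohort, standardized there.
3. **phenotypes** — cumulative adversity score (binary components plus
   continuous components dichotomized at the empirical 15th/85th
   percentile), delay-task trial scoring (behavior code 1–7 + latency code
   1–2, totals 2–9, global-cooperation filter), and hot-deck multiple
   imputation (default 30 sets).
4. **gxe_stats** — the three pre-registered OLS models
   (`outcome ~ sex + PC1–3 + X`, `… + M`, `… + X * M`), simple slopes at
   moderator mean ± 1 SD, Johnson–Neyman regions of significance,
   crossover/PoI/PA susceptibility indices, non-parametric case-resampling
   bootstrap of the interaction coefficient, and Rubin's-rules pooling.
5. **synthetic_data** — two cohorts drawn from shared allele frequencies
   with block LD, a phenotype at configurable heritability, reference-style
   GWAS summary statistics, adversity components with missing-at-random
   gaps, and an outcome with a planted score-by-adversity interaction.
6. **cli / pipeline** — stage subcommands plus an all-in-one `run` that
   writes a JSON report.

## CLI

```bash
# end-to-end demo on packaged config (synthetic cohorts)
prsgxe run --config src/prsgxe/data/demo_config.yaml --out out/

# individual stages
prsgxe simulate --config cfg.yaml --out simdir/
prsgxe qc --geno simdir/test_dosage.tsv --snp-meta simdir/snp_meta.tsv --out qc.tsv
prsgxe scan --geno qc.tsv --snp-meta qc.tsv.meta.tsv --gwas simdir/gwas.tsv \
    --pheno simdir/discovery_phenotype.tsv --out scan.tsv
prsgxe refine --geno qc.tsv --snp-meta qc.tsv.meta.tsv --gwas simdir/gwas.tsv \
    --pheno simdir/discovery_phenotype.tsv --threshold 0.24 --out refined.tsv
prsgxe score --geno qc.tsv --snp-meta qc.tsv.meta.tsv --refined refined.tsv --out scores.tsv
prsgxe gxe --table analysis_table.tsv --bootstrap 1000 --out gxe.json
```

The `run` report contains every stage summary (QC counts, clump/scan
tables, the refined SNP set and its content hash, standardized score
checks, adversity summaries, model coefficients, simple slopes, regions of
significance, PoI/PA, and optional bootstrap/imputation results).

## Data notes

- `src/prsgxe/data/refined_snp_table.tsv` carries the published refined
  SNP list (rsID + original-GWAS p-value). Coordinates, alleles and weights
  in that file are placeholders — the published table contains only the two
  informative columns.
- Individual-level cohort data are access-restricted; all analyses here run
  on the synthetic generator, which reproduces the statistical structure
  the method assumes (shared allele frequencies, planted heritability and
  interaction).
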