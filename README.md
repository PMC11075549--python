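# vernaliza

Analysis toolkit for dissecting vernalization-response phenotypes and
polygenic selection signals in structured, highly selfing plant panels.

The package implements the full inference chain as reusable, tested
components:

| Module | What it does |
| --- | --- |
| `vernaliza.genomics_io` | Dosage-coded genotype matrix, VCF read/write (GT-only VCFv4.2 subset), BED regions, sample maps, the site-filter chain (biallelic / missing-count / quality / heterozygous-site screen), thinning, MAF filtering, heterozygosity fraction |
| `vernaliza.synthdata` | Forward Wright–Fisher simulator (selfing, splits, bottlenecks, mutation, optional standing variation with controllable LD), trait architectures, vernalization-response curves with censoring, structure-correlated environments |
| `vernaliza.traits` | Extraction of the four flowering traits — minimum threshold duration (MTD) of vernalization, days to flower at MTD, vernalization saturation, days to flower at saturation — from replicated, censorable measurements |
| `vernaliza.ordination` | Redundancy analysis, Ezekiel-adjusted R², permutation tests, double-stopping (Pin + adjusted-R² scope) forward selection, PCA, Kendall tau |
| `vernaliza.popdiff` | Per-SNP Weir–Cockerham F_ST with a forward-simulation neutral null; covariance-aware X^T^X differentiation statistic with pseudo-observed-dataset (POD) quantile calibration |
| `vernaliza.ldscan` | Genotype-correlation r², LD-decay curves with bootstrap CIs, inter-chromosomal resampled-mean LD nulls for focal gene sets, perfect-LD pruning |
| `vernaliza.assoc` | Mixed-model GWAS (centered kinship, per-SNP REML variance ratio, Wald tests), Benjamini–Hochberg FDR, sliding-window peak calling |

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(estimator–oracle equivalence, analytic drift calibration, POD closed-loop
calibration, power and error-rate simulations). The acceptance report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## CLI

The `vernaliza` entry point groups one subcommand per pipeline stage:

```bash
# filter chain and thinning
vernaliza vcf filter in.vcf out.vcf --max-missing-count 200 --min-qual 20 --drop-het
vernaliza vcf thin in.vcf out.vcf --bp 20000
vernaliza vcf maf in.vcf out.vcf --min-maf 0.05

# trait extraction from a long-format response table
vernaliza traits extract response.tsv traits.tsv --tol-days 2

# forward-selected RDA of one trait against covariates
vernaliza rda select traits.tsv covariates.tsv trace.tsv --trait mtd_weeks \
    --pin 0.01 --nperm 1000 --scope

# differentiation scans
vernaliza fst panel.vcf samples.tsv fst.tsv --level lineage
vernaliza xtx panel.vcf samples.tsv xtx.tsv --pods 100000 --quantile 0.99

# linkage disequilibrium
vernaliza ld decay panel.vcf decay.tsv --thin 20000 --maf 0.05
vernaliza ld internull panel.vcf null.json --k 8 --resamples 50000

# mixed-model association with windowed peak calling
vernaliza gwas run panel.vcf pheno.tsv assoc.tsv --peaks-out peaks.bed \
    --maf 0.05 --fdr 0.05 --window 8000 --step 4000 --min-markers 4
```

Formats: VCF (diploid GT), BED (0-based half-open, named regions),
tab-separated sample maps (`sample_id`, `clade`, `lineage`), long-format
response tables (`accession`, `duration_weeks`, `replicate`,
`days_after_return`, `flowered`).

## Conventions

- Dosage codes: 0 hom-ref, 1 het, 2 hom-alt, −1 missing. Statistics never
  impute silently; each states its own missing-data policy (kinship
  mean-imputes for its own computation only, LD is pairwise-complete,
  F_ST skips under-called sites).
- VCF positions are 1-based, BED half-open 0-based; a VCF site at position
  p falls in BED region (start, end] iff start < p ≤ end.
- All stochastic components are seeded and reproduce bit-identically.
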