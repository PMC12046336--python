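# dqtl

Germline–somatic **driver QTL (dQTL)** analysis toolkit: discovery scans of
germline SNPs against binary somatic driver calls, replication and
random-effects meta-analysis, analytic power and extrapolation, somatic driver
co-occurrence/mutual-exclusivity statistics, and downstream characterization
(molecular QTLs, ancestry VAF bias, p-value diagnostics, clinical genetic-model
selection) — plus a synthetic-cohort generator so the whole pipeline is testable
end-to-end without any access-controlled data.

## Modules

| module | what it does |
| --- | --- |
| `dqtl.simulate` | synthetic cohorts: block-LD genotypes, logistic driver model with planted per-allele effects, covariates, loop anchors, molecular traits, ancestry panels |
| `dqtl.regions` | SNP search spaces per driver: linear ±flank windows, spatial (ChIA-PET, ≥2 cell lines) and enhancer (HiChIP) loop partners; loop-anchor enrichment permutation |
| `dqtl.ld` | EM two-locus LD with likelihood-profile D′ CIs; Gabriel-style haplotype blocks (the multiple-testing unit) |
| `dqtl.association` | per-SNP logistic scans with PC/age/burden covariates, Firth fallback on separation, block-Bonferroni and BH grids, tag-SNP selection, index-event adjustment |
| `dqtl.replication` | replication testing (FDR < 0.1 + sign concordance), distal candidate screening, REML random-effects meta-analysis |
| `dqtl.power` | χ² non-centrality analytic power, power grids, undiscovered-dQTL extrapolation |
| `dqtl.cooccurrence` | pairwise hypergeometric co-occurrence/exclusivity with extreme-case power and minimum-cohort solver |
| `dqtl.downstream` | meQTL/eQTL/pQTL linear models, tumor specificity, permutation enrichment, ancestry VAF Fisher tests, explained fractions, skew/π₀ diagnostics, AIC genetic-model selection |
| `dqtl.io` | VCF/BED/BEDPE/TSV readers and writers with strict 0-based↔1-based conversion |
| `dqtl.pipeline` / `dqtl.cli` | one-config orchestration with deterministic per-stage seeding and a run manifest |

## CLI

```bash
dqtl simulate --seed 1 --out-dir out/          # synthetic cohort artifacts
dqtl run --config cfg.yaml --seed 1 --out-dir out/   # full pipeline + manifest
dqtl power --n-total 427 --alpha 3.7e-4
dqtl cooccur --drivers drivers.tsv
dqtl characterize --vaf-table data/population_vaf.tsv
dqtl validate --vcf genotypes.vcf --drivers drivers.tsv
```

A YAML config mirrors `dqtl.pipeline.RunConfig`, e.g.

```yaml
simulation:
  n_patients: 427
  n_snps: 200
  n_drivers: 4
  driver_freqs: [0.1, 0.2, 0.3, 0.5]
  seed: 1
min_maf: 0.05
alpha_bonferroni: 0.1
```

## Conventions

* Coordinates are 1-based inclusive in memory (VCF-style); BED/BEDPE are
  converted at I/O boundaries only. Overlap means ≥ 1 shared base.
* Genotypes are additive dosages {0,1,2} with NaN for missing; analyses are
  complete-case per test.
* Every source of randomness takes an explicit integer seed; a fixed seed fixes
  every emitted byte.
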