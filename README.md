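# xokit

Toolkit for gamete-level meiotic crossover analysis on SNP-array-scale
data, built around a synthetic meiosis simulator so every stage is testable
without proprietary breeding data:

- **genome** — chromosome definitions (metacentric/acrocentric, centromeres)
  and sex-specific bp↔cM genetic maps with piecewise-linear interpolation.
- **simulate** — pedigrees, gametes under a stationary gamma-renewal
  crossover process with an optional interference-escaping (Poisson) class,
  SNP genotypes with error/missingness, and pedigree-structured phenotypes
  with an optional large-effect QTL. Fully seeded and reproducible.
- **calling** — genotype QC (MAF / call rate / Hardy-Weinberg χ²),
  inheritance-vector inference from phased parental haplotypes, and
  deterministic crossover calling with short-run error absorption.
- **phenotypes** — per-gamete crossover count, intra-chromosomal allelic
  shuffling `Σ 2p_k(1−p_k)L_k²`, distance-to-telomere (one crossover per
  arm), per-individual means, Welch t-tests and Pearson correlations.
- **interference** — the gamma-escape ("sprinkling") likelihood for
  single-gamete crossover positions on the genetic scale: exact 2^m
  class-assignment sum with stationary start and right-censoring, and
  per-individual maximum-likelihood fits of (ν, p) or the ν-only submodel.
- **quantgen** — Henderson sparse A⁻¹, univariate animal-model REML with a
  permanent-environment effect, VanRaden-style GRM, mixed-linear-model
  leave-one-chromosome-out GWAS with genomic control and Bonferroni
  thresholds.
- **tables / cli / pipeline** — plain-TSV readers/writers with commented
  headers, and an end-to-end driver with a run manifest.

## CLI

```bash
xokit simulate --out run/sim --seed 1 --nu 8.5 --p-escape 0.05
xokit call --geno run/sim/genotypes.tsv --haps run/sim/haplotypes.tsv \
    --ped run/sim/pedigree.tsv --panel run/sim/panel.tsv \
    --min-support 3 --out run/called
xokit phenotype --xo run/called/crossovers.tsv --iv run/called/inheritance.tsv \
    --genome run/sim/genome.tsv --ped run/sim/pedigree.tsv --out run/pheno
xokit interference --xo run/called/crossovers.tsv \
    --pheno run/pheno/gamete_phenotypes.tsv --map run/sim/map.tsv \
    --ped run/sim/pedigree.tsv --out run/interference.tsv
xokit h2 --pheno run/pheno/gamete_phenotypes.tsv --ped run/sim/pedigree.tsv \
    --trait crossover_count --repeated --out run/h2.json
xokit gwas --pheno run/pheno/fid_phenotypes.tsv --geno run/sim/genotypes.tsv \
    --panel run/sim/panel.tsv --trait crossover_count --out run/gwas.tsv
xokit run --out run/full --seed 1            # whole pipeline + manifest
```

Exit codes: 0 success, 1 usage error, 2 data error. Logs go to stderr.

## Notes and limitations

- Crossover calling expects phase-known focal parents (the simulator
  provides truth haplotypes); real-data use requires external phasing.
- The caller's `min_support` run filter needs SNP-array-like marker
  density (~tens of kb) for accurate counts; at sparse densities the
  end-run rule systematically drops near-terminal crossovers.
- Founders are simulated in linkage equilibrium, so GWAS power/LD patterns
  are conservative relative to real breeding populations.
- Chromatid interference, obligate-crossover constraints, multivariate
  REML and genotype imputation are out of scope.
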