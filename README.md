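# epipath

Case/control genetic-interaction analysis for SNP panels: a genome-wide
pairwise epistasis screen, haplotype-based association over short SNP
windows, and permutation-based gene-set (pathway) enrichment — plus
synthetic-cohort generators so every stage can be exercised end to end
without external data.

## What it does

- **genotype_io** — PLINK 1.x text (`ped`/`map`) and binary
  (`bed`/`bim`/`fam`) readers and writers, empirical minor-allele coding,
  exact Hardy-Weinberg test, and MAF/HWE/missingness QC filtering.
- **epistasis** — allele-based Z screen for the difference in SNP1-SNP2
  odds ratio between cases and controls (with a calibrated variance for
  the smoothed allele-pair tables), dosage-logistic interaction refinement
  (IRLS with step halving and Wald tests), the exact unordered-pair count,
  and Bonferroni thresholds.
- **locus_mapping** — BED4 annotation, SNP-to-locus mapping with optional
  flanks, and interaction-cluster filtering: drop pairs where either SNP
  is unannotated, group by locus pair, and keep pairs supported by
  multiple interactions with at least two distinct SNPs per side.
- **haplotype** — EM haplotype-frequency estimation over 2-4 SNP windows
  from unphased genotypes, D' linkage disequilibrium, and per-haplotype
  case/control chi-square tests.
- **pathway** — per-SNP allelic chi-square, per-gene maxima within a
  ±flank window, weighted KS enrichment scores, phenotype-permutation
  NES/empirical-P/FDR/FWER, a precomputed-P pathway z test with BH-FDR,
  and GMT I/O.
- **simulate** — reproducible generators: null cohorts, planted logistic
  interactions (with case/control ascertainment), LD blocks with
  case-stratum haplotype shifts, and gene/pathway panels with one
  signal-bearing set.
- **cli / pipeline** — a `click` CLI (`epipath`) with subcommands
  `simulate qc scan refine map haplotype gsea gsa run`, YAML config
  validation, and a manifest-writing end-to-end pipeline with
  byte-stable TSV outputs.

## Quick start

```sh
# simulate a cohort with one planted interaction and scan it
epipath simulate --kind epistatic --n-cases 493 --n-controls 537 \
    --m-snps 200 --b3 1.2 --seed 7 --out cohort
epipath scan --bfile cohort --p-screen 1e-8 --out scan.tsv

# map screened pairs to loci and test haplotype windows
epipath map --interactions scan.tsv --bfile cohort \
    --annotation genes.bed --min-support 2 --out pairs.tsv
epipath haplotype --bfile cohort --snps rs1,rs2,rs3 \
    --window-sizes 2,3,4 --out haps.tsv

# pathway enrichment with 1000 phenotype permutations
epipath gsea --bfile cohort --gmt sets.gmt --annotation genes.bed \
    --flank 20000 --n-perm 1000 --seed 7 --out pathways.tsv

# or drive everything from one YAML config
epipath run --config analysis.yaml
```

A minimal config:

```yaml
genotypes: cohort          # prefix for .ped/.map or .bed/.bim/.fam
annotation: genes.bed
gene_sets: sets.gmt
seed: 7
scan: {p_screen: 1.0e-8}
gsea: {n_perm: 1000}
```

## Packaged fixtures

`src/epipath/data/` ships three small plain-text fixtures used by the
tests and the acceptance report: a 39-row SNP-SNP interaction cluster
(`interaction_cluster.tsv`), its two-locus annotation
(`cluster_loci.bed`), and a 19-gene immune-signalling gene set
(`tob1_pathway.gmt`).
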