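# b12prs

Ancestry-aware candidate-gene analysis of plasma vitamin B12 for three-way
admixed cohorts, built as a tested, reusable pipeline with a synthetic-cohort
generator for validation.

Plasma cobalamin (B12) varies strongly between individuals, and in admixed
populations part of that variation tracks genetic ancestry: a locus inherited
on a European, African, or Native-American haplotype carries different allele
frequencies at B12-related genes. This package implements the full analysis
chain used to dissect that signal in a cohort of admixed children and
adolescents:

1. **Local-ancestry summaries** — per-gene and genome-wide means of diploid
   local-ancestry dosages (AFR/AMR/EUR, summing to 1 at every SNP), with an
   iterative 1-kb border-growth search for genes without informative SNPs.
2. **Permutation correlation scores** — Spearman correlation r between a
   gene's ancestry dosage and B12, a two-sided permutation p-value
   p_perm = (#{|r_b| ≥ |r_obs|} + 1)/(B + 1) over B phenotype permutations
   (B = 10,000), and the signed score −log10(p_perm)·sign(r); significance at
   p_perm < 0.1.
3. **SNP association** — QC (Hardy–Weinberg exact test p ≥ 1e−3, MAF ≥ 0.01),
   per-SNP estimating-equation regression of log2 B12 on minor-allele dosage
   with covariates (sex, age, BMI, diet-quality score, mean AFR and AMR
   ancestry), robust sandwich variance, greedy LD clumping (r² > 0.2 within
   ±250 kb) to a representative SNP_ref per clump, and Benjamini–Hochberg FDR
   control at p_adj < 0.1.
4. **Polygenic risk score** — PRS_i = Σ_k dosage_ik · β_k over significant
   SNP_ref effects, variance explained as the R² of the univariate regression
   of log2 B12 on the PRS, tercile stratification, Kruskal–Wallis and
   chi-square/Fisher tercile-difference tests, and an explicitly hypothetical
   counseling lookup.
5. **Synthetic cohorts** — a Markov tract model (Poisson recombination
   breakpoints at rate g per Morgan since admixture, i.i.d. tract origins)
   with per-component allele frequencies, optional block-copula LD, covariate
   and phenotype generation on the log2 scale with a tunable genetic-score
   R², so every stage has a parameter-recovery test.

The published per-gene correlation table, the 36-SNP association table and
the 90-gene candidate list ship as machine-readable fixtures under
`src/b12prs/data/` (gene coordinates there are synthetic toy placements; the
symbols and statistics are authentic).

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
study-sized cohort (168 samples, 300 LD-blocked SNPs, 36 causal variants,
genetic score tuned to 42% of phenotype variance):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_gene_ancestry.py
python analysis/03_ancestry_correlation.py
python analysis/04_snp_association.py
python analysis/05_prs_report.py
python analysis/06_published_tables.py
```

Output of the run committed here:

```
wrote cohort: 168 samples x 300 variants
residual noise SD solved for 42% score R^2: 3.003
profiled 30 genes over 168 samples
cohort mean global ancestry (AFR, AMR, EUR): 0.249, 0.166, 0.584
synthetic cohort significant gene counts at p_perm < 0.1: {'AFR': 11, 'AMR': 2, 'EUR': 7, 'union': 15}
variants: 300; pass QC: 300; clumps: 279; significant SNP_ref (p_adj < 0.1): 3
PRS from 3 SNP_ref effects
variance of log2 B12 explained: 0.159
tercile sizes: {'T1': 56, 'T2': 56, 'T3': 56}
```

Reading this: the generator reproduces the intended admixture proportions;
at n = 168 the per-gene ancestry–phenotype correlations pick up a minority of
signals, and single-SNP association has little power (three significant
SNP_refs survive the FDR), so the desk-scale PRS explains only ~16% of
log2-B12 variance — the power ceiling of a 168-sample cohort with realistic
effect sizes. The same pipeline at n = 2,000 recovers the generated 42% (see the
acceptance script below). Step 06 re-derives the published-table totals: 17
AFR / 28 AMR / 39 EUR ancestry-correlated genes (union 51), 36 significant
SNP_refs in 26 genes (21 positive, 15 negative effects), and the 90-gene
candidate set.

The same stages are available as a CLI (`b12prs simulate|ancestry|corr|assoc|prs|run-all`)
and as plain library calls:

```python
import b12prs as b
cohort, truth = b.simulate_cohort(n_samples=168, n_variants=300, h2=0.42, seed=1)
run = b.run_association(cohort)
profile = b.prs_profile(cohort, run.significant_effects(0.1))
```

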