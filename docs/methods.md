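# Methods

## Scope and model

The package analyses the relationship between genetic ancestry, genotype and
plasma vitamin B12 in a three-way admixed cohort (African, Native-American
and European components, abbreviated AFR/AMR/EUR). The phenotype is modelled
on the log2 scale:

    log2(B12_i) = μ + Σ_k G_ik β_k + C_i γ + θ_i δ + ε_i,   ε_i ~ N(0, σ²)

with G the minor/alternate-allele dosages, C the covariates (sex, age, BMI,
diet-quality score) and θ the per-individual genome-wide mean ancestry
fractions. All inference modules treat B12 on the log2 scale; the synthetic
generator inverts the transform so phenotypes are strictly positive pmol/L
values.

## Synthetic cohort generator

**Ancestry tracts.** Each haplotype is a Markov mosaic: recombination
breakpoints form a Poisson process of rate g per Morgan (g = 15 admixing
generations by default) and the origin of each tract is drawn i.i.d. from
the global admixture proportions (default AFR/AMR/EUR = 0.25/0.15/0.60, the
midpoints of the autosomal ranges reported for the study population). This
reproduces the admixture-LD decay that local-ancestry HMMs assume — mean
tract length 1/g Morgans — without a pedigree or ancestral recombination
graph, which the downstream statistics do not need. The genetic map is
uniform 1 cM/Mb.

**Genotypes.** A haplotype's allele at a SNP is Bernoulli with the allele
frequency of its local ancestral component (panel frequencies default to
i.i.d. Uniform(0.05, 0.95) per component, giving ancestry-informative
markers). Within-panel LD is optional, via a Gaussian block copula: variants
in a block share a latent factor with loading √ρ, so within-block allele
correlation is ≈ ρ while marginal frequencies are untouched. This is enough
to exercise clumping; it does not model realistic LD decay with distance.
Diploid local-ancestry dosages are the true tract origins, i.e. the
generator emits what a local-ancestry tool would estimate, without its
inference error.

**Covariates and phenotype.** Sex ~ Bernoulli(0.5); age ~ Uniform(9, 13.99)
years; BMI ~ Normal(20, 4.3) kg/m² truncated above 10; diet score ~
Normal(54, 10) clipped to [0, 100] — moments taken from the study cohort's
descriptive table. Default effect directions follow the observed pattern
(AFR and AMR ancestry lowering log2 B12 relative to EUR). 36 causal SNPs
with |β| ~ Uniform(0.3, 1.0) and random signs mirror the published effect
range. When a target score-R² `h2` is requested (default 0.42, the study's
headline figure), σ is solved from the realized cohort so that
corr(score, log2 phenotype)² = h2 in expectation:
σ² = cov(g, lp)²/(h2·var(g)) − var(lp), where g is the true genetic score
and lp the full linear predictor; an unattainable target raises an error
rather than silently clamping. Missing genotypes are an optional MCAR mask
(default 0). All randomness derives from one seed via named sub-streams, so
runs are bit-reproducible.

**What passing tests do and do not show.** The generator matches the
statistical structure the analysis assumes (exchangeable samples, clean
local-ancestry dosages, block LD, log-normal phenotype). Real data add
local-ancestry inference error, relatedness and population stratification
beyond the three components, genotyping error, and LD with distance-dependent
decay — none of which are emulated, so passing recovery tests certify the
pipeline's arithmetic and calibration, not robustness to those artefacts.

## Per-gene ancestry and the growth search

A gene region's profile is the mean of local-ancestry dosages over
informative SNPs inside its flanked interval (5 kb before the start
coordinate, 1.5 kb past the end, coordinate-relative regardless of strand;
applied exactly once). If the interval contains no informative SNP, both
borders grow symmetrically 1 kb per step until a SNP is found, recording the
step count; growth stops at a configurable cap (default 1 Mb total) with an
explicit failure rather than looping on sparse data. Whether the original
analysis grew one border or both is not documented; symmetric growth was
chosen and is flagged here. The ancestry-informative SNP set is an input
separate from the association SNP set.

## Permutation correlation score

Spearman r (average ranks for ties) between an ancestry component and the
phenotype, with the two-sided permutation p-value
p = (#{|r_b| ≥ |r_obs|} + 1)/(B + 1), B = 10,000 by default. The add-one
estimator keeps p in (0, 1], capping the score magnitude at log10(B + 1).
Sidedness is not documented for the original analysis; two-sided was chosen
because both signs are reported with symmetric treatment. One permutation
stream is drawn per scan and shared across genes and components: p-values
are comparable across the whole scan, and identical profiles give identical
results. Constant inputs are excluded with a recorded reason, never silently
scored 0. A genomic-bin scan (`scan_bins`) generalizes the per-gene scan to
fixed windows along chromosomes.

## SNP association

**QC.** The Hardy–Weinberg exact test is the standard conditional
formulation (no mid-p): given the allele counts, heterozygote counts of the
same parity are weighted hypergeometrically and all configurations no more
probable than the observed one are summed. Variants fail QC when HWE p <
1e−3 or MAF < 0.01 (strict inequalities; MAF exactly 0.01 passes). MAF is
computed from non-missing dosages.

**Fit.** Per SNP, linear estimating equations with independence working
correlation and one cluster per individual: point estimates equal least
squares and the variance is the robust sandwich. Implementation is
statsmodels GEE (Gaussian family). The covariance uses the bias-reduced
(Mancl–DeRouen) sandwich: with singleton clusters the plain sandwich is the
HC0 estimator, which measured anticonservative at cohort scale (rejection
0.070 at nominal 0.05, n = 168, 1000 null replicates), while the
bias-reduced form measured 0.053 — the small-sample correction is standard
practice and keeps Wald tests calibrated. Effects are reported per
minor-allele copy (the sign flips when the alternate allele is the major
one). Missing dosages are mean-imputed (equivalently 2·MAF), standard at low
missingness. Covariate collinearity: the three ancestry fractions sum to 1,
so EUR is dropped as the reference component (configurable); the original
report lists all three, but a full-rank design requires dropping one.
Singular or degenerate designs skip the SNP with a recorded reason.

**Clumping.** Greedy: repeatedly take the unassigned SNP with smallest p as
index (SNP_ref) and absorb unassigned SNPs within ±250 kb on the same
chromosome with r² > 0.2 (composite LD: squared Pearson correlation of
dosage vectors, no phasing). Ties in p break by smaller position then
lexicographic id, for determinism. Every SNP lands in exactly one clump;
the SNP_ref holds the minimum p of its clump.

**FDR.** Benjamini–Hochberg step-up over the SNP_ref p-values
(statsmodels), significance at p_adj < 0.1.

## PRS and tercile report

PRS_i = Σ_k dosage_ik β_k over significant SNP_ref effects, with dosage
counting the tested (minor) allele and β keeping its sign — the published
tercile score ranges span negative and positive values, confirming signed
weighting rather than risk-allele flipping. Effect SNPs absent from a cohort
contribute their expected dosage 2·MAF with a warning. Variance explained is
the R² of the univariate regression of log2 B12 on the PRS; whether the
published 42% was covariate-adjusted is not stated, and the simple
regression reading is the default (a partial-R² variant can be computed from
the association covariates if wanted). Terciles are rank-based with stable
ties and largest-remainder sizing (168 → 56/56/56; 7 → 3/2/2), T1 = lowest
scores. Group differences use tie-corrected Kruskal–Wallis for continuous
variables; categorical tables use chi-square when all expected counts are
≥ 5, otherwise an exact conditional test (2×2 hypergeometric; r×c by
enumeration of margin-preserving tables under the probability-mass
criterion, feasible at report-table sizes). Metabolite columns (folate,
pyridoxal, riboflavin, tHcy) are report-only and never model inputs. The
counseling lookup (tercile × measured status → monitor / assess intake /
refer) is a configurable table whose outputs are always labelled
hypothetical.

## Numerical and design choices

- Coordinates are 1-based inclusive in memory (VCF convention); BED fixtures
  convert on read. Multi-gene variant assignment is kept (overlapping loci),
  association being per-SNP avoids double counting.
- Permutation p-value comparisons use a 1e−12 slack so ties in |r| count as
  exceedances; HWE probability comparisons use a relative 1e−12 slack.
- The h2 solver, tercile sizing, clump tie-breaks and permutation streams are
  all deterministic given the seed; pipeline runs with equal config + seed
  are bit-identical (the output directory is excluded from the config hash).
- Degenerate inputs: constant phenotype/ancestry vectors raise typed errors;
  all-identical Kruskal–Wallis groups return (H = 0, p = 1); monomorphic
  variants fail MAF QC rather than erroring.

## Problem sizes in tests and the acceptance script

Test simulations use cohorts of 120–200 samples for unit checks, 2,000
samples for recovery of the 42% score-R² and the end-to-end PRS rank
correlation (3 seeds each), 2,000 replicates for type-I calibration of the
association fit at n = 168, and 1,000 random instances (≤ 50 SNPs) for the
clumping-oracle equivalence. These sizes give Monte-Carlo error well inside
the asserted 3-SE bands while keeping the default suite to a few minutes.

## Known limitations

- The study's real genotype/phenotype data are not publicly deposited, so
  the published headline quantities are validated as re-derivations from the
  printed tables plus parameter-recovery on synthetic cohorts, not as a
  re-analysis of the raw data.
- The packaged gene coordinates are synthetic placements keyed by symbol;
  any BED on the right build can be substituted.
- Local-ancestry inference itself (two-layer HMMs, global-ancestry
  likelihood methods) is out of scope; the generator emits truth dosages.
- No kinship/mixed-model correction and no imputation to a reference panel;
  the exact windowing of the original chromosome-wide correlation scan is
  under-documented and is generalized here as user-set genomic binning.
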