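"""SNP-level association pipeline on log2-transformed B12 levels.

Stages: QC (Hardy-Weinberg exact test and minor-allele-frequency filters),
per-SNP estimating-equation regression with robust sandwich variance and
covariates (sex, age, BMI, diet score, mean AFR and AMR ancestry — EUR is
the reference component, dropped for full rank), greedy LD clumping to a
representative SNP per clump (``SNP_ref``), and Benjamini-Hochberg control
of the false discovery rate across the SNP_ref p-values.

Default thresholds: HWE exact p >= 1e-3, MAF >= 0.01, clump r^2 > 0.2 within
±250 kb of the index SNP, FDR 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .simulate import AdmixedCohort
from .ancestry import mean_global_ancestry

HWE_P_MIN = 1e-3
MAF_MIN = 0.01
CLUMP_R2 = 0.2
CLUMP_KB = 250
FDR_ALPHA = 0.1


class DegenerateGenotypeError(ValueError):
    """Constant dosage vector: association model is unidentifiable."""


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts: among all heterozygote counts of
    the same parity, sums the hypergeometric-weighted probabilities of those
    configurations no more probable than the observed one (standard exact
    formulation, no mid-p adjustment).
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # work with the rarer allele
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((n_minor - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (n_minor + hets) / 2 + 1)
        + hets * math.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def minor_allele_frequency(dosage: np.ndarray) -> float:
    """MAF from non-missing dosages (alt-allele dosage 0/1/2)."""
    d = dosage[~np.isnan(dosage)]
    if len(d) == 0:
        return np.nan
    f_alt = d.mean() / 2.0
    return float(min(f_alt, 1.0 - f_alt))


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(hom-major, het, hom-minor) counts from hard-call dosages."""
    d = np.round(dosage[~np.isnan(dosage)]).astype(int)
    n2 = int((d == 2).sum())
    n1 = int((d == 1).sum())
    n0 = int((d == 0).sum())
    if n2 > n0:  # alt is the major allele; swap so homozygotes are major-first
        n0, n2 = n2, n0
    return n0, n1, n2


def qc_filter(
    cohort: AdmixedCohort,
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
) -> pd.DataFrame:
    """Per-variant QC report: MAF, HWE exact p, pass flag and fail reason.

    A variant passes iff HWE p >= ``hwe_p_min`` and MAF >= ``maf_min``.
    """
    rows = []
    for i, snp in enumerate(cohort.variants["snp_id"]):
        d = cohort.dosages[:, i]
        maf = minor_allele_frequency(d)
        if np.isnan(maf):
            rows.append((snp, np.nan, np.nan, False, "all_missing"))
            continue
        p_hwe = hwe_exact(*genotype_counts(d))
        reasons = []
        if p_hwe < hwe_p_min:
            reasons.append("HWE")
        if maf < maf_min:
            reasons.append("MAF")
        rows.append((snp, maf, p_hwe, not reasons, "+".join(reasons)))
    return pd.DataFrame(rows, columns=["snp_id", "maf", "hwe_p", "pass", "fail_reason"])


# ---------------------------------------------------------------------------
# estimating-equation association
# ---------------------------------------------------------------------------

def association_covariates(cohort: AdmixedCohort, ancestry_snp_mask: np.ndarray | None = None,
                           drop_component: str = "EUR") -> pd.DataFrame:
    """Covariate design: sex (0/1), age, BMI, HEI and two mean-ancestry
    fractions.  The three ancestry fractions sum to 1, so one component
    (``drop_component``, default EUR) is dropped for a full-rank design."""
    from .simulate import COMPONENTS

    theta = mean_global_ancestry(cohort, ancestry_snp_mask)
    cov = pd.DataFrame(
        {
            "sex": (cohort.samples["sex"].to_numpy() == "M").astype(float),
            "age": cohort.samples["age"].to_numpy(float),
            "bmi": cohort.samples["bmi"].to_numpy(float),
            "hei": cohort.samples["hei"].to_numpy(float),
        }
    )
    for c, comp in enumerate(COMPONENTS):
        if comp != drop_component:
            cov[f"anc_{comp.lower()}"] = theta[:, c]
    return cov


@dataclass
class AssocFit:
    beta: float
    se: float
    p: float


def fit_association(dosage: np.ndarray, log2_phenotype: np.ndarray, covariates: pd.DataFrame) -> AssocFit:
    """Estimating-equation fit of log2 phenotype on one SNP dosage.

    Independence working correlation with one cluster per individual, so the
    point estimate equals least squares and the variance is the robust
    sandwich estimator; two-sided Wald p.  Missing dosages are mean-imputed.
    The bias-reduced (Mancl-DeRouen) sandwich is used: with singleton
    clusters the plain sandwich is anticonservative at cohort-scale n.
    """
    d = np.asarray(dosage, float).copy()
    nan = np.isnan(d)
    if nan.all():
        raise DegenerateGenotypeError("all dosages missing")
    if nan.any():
        d[nan] = d[~nan].mean()
    if np.ptp(d) == 0:
        raise DegenerateGenotypeError("degenerate genotype: constant dosage")
    y = np.asarray(log2_phenotype, float)
    X = np.column_stack([np.ones_like(d), d, covariates.to_numpy(float)])
    if len(y) <= X.shape[1] + 1:
        raise ValueError("too few samples for the number of parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    model = sm.GEE(
        y,
        X,
        groups=np.arange(len(y)),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Independence(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(cov_type="bias_reduced")
    return AssocFit(beta=float(res.params[1]), se=float(res.bse[1]), p=float(res.pvalues[1]))


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

def ld_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors."""
    a = np.asarray(dosage_i, float).copy()
    b = np.asarray(dosage_j, float).copy()
    for v in (a, b):
        nan = np.isnan(v)
        if nan.any():
            v[nan] = v[~nan].mean()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateGenotypeError("constant dosage vector: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(
    results: pd.DataFrame,
    dosages: np.ndarray,
    r2_threshold: float = CLUMP_R2,
    window_kb: float = CLUMP_KB,
) -> pd.DataFrame:
    """Greedy LD clumping: repeatedly index the smallest-p unassigned SNP.

    ``results`` needs columns snp_id, chrom, pos, p aligned with the columns
    of ``dosages``.  Unassigned SNPs within ±``window_kb`` of the index on the
    same chromosome with r^2 > ``r2_threshold`` join its clump.  Ties in p
    break by smaller position, then lexicographic id.  Adds columns clump_id,
    is_snp_ref, n_ld_partners.
    """
    df = results.reset_index(drop=True)
    m = len(df)
    if dosages.shape[1] != m:
        raise ValueError("dosage matrix does not match results table")
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    pvals = df["p"].to_numpy(float)
    snp_ids = df["snp_id"].astype(str).to_numpy()
    window_bp = window_kb * 1000.0

    order = sorted(range(m), key=lambda i: (pvals[i], pos[i], snp_ids[i]))
    clump_id = np.full(m, -1, int)
    is_ref = np.zeros(m, bool)
    next_id = 0
    for i in order:
        if clump_id[i] >= 0:
            continue
        clump_id[i] = next_id
        is_ref[i] = True
        near = (
            (clump_id < 0)
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            try:
                r2 = ld_r2(dosages[:, i], dosages[:, j])
            except DegenerateGenotypeError:
                continue
            if r2 > r2_threshold:
                clump_id[j] = next_id
        next_id += 1

    out = df.copy()
    out["clump_id"] = clump_id
    out["is_snp_ref"] = is_ref
    sizes = pd.Series(clump_id).value_counts()
    out["n_ld_partners"] = [sizes[c] - 1 for c in clump_id]
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [p, 1])."""
    p = np.asarray(pvals, float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class AssociationRun:
    """End-to-end association output."""

    qc: pd.DataFrame
    results: pd.DataFrame  # per tested SNP: beta, se, p, clump, p_adj (refs)
    skipped: list[dict] = field(default_factory=list)

    @property
    def snp_refs(self) -> pd.DataFrame:
        return self.results[self.results["is_snp_ref"]].reset_index(drop=True)

    def significant_effects(self, fdr: float = FDR_ALPHA) -> pd.DataFrame:
        refs = self.snp_refs
        return refs[refs["p_adj"] < fdr].reset_index(drop=True)


def run_association(
    cohort: AdmixedCohort,
    maf_min: float = MAF_MIN,
    hwe_p_min: float = HWE_P_MIN,
    r2_threshold: float = CLUMP_R2,
    window_kb: float = CLUMP_KB,
    fdr: float = FDR_ALPHA,
    ancestry_snp_mask: np.ndarray | None = None,
) -> AssociationRun:
    """QC -> per-SNP estimating-equation fits -> clump -> BH on SNP_ref.

    The phenotype is log2 transformed before fitting.  SNPs with singular or
    degenerate designs are skipped with a reason.
    """
    qc = qc_filter(cohort, maf_min=maf_min, hwe_p_min=hwe_p_min)
    keep = qc["pass"].to_numpy()
    y = np.log2(cohort.phenotype)
    cov = association_covariates(cohort, ancestry_snp_mask)

    rows, skipped, kept_cols = [], [], []
    for i in np.flatnonzero(keep):
        snp = cohort.variants.iloc[i]
        d = cohort.dosages[:, i]
        try:
            fit = fit_association(d, y, cov)
        except (DegenerateGenotypeError, np.linalg.LinAlgError, ValueError) as err:
            skipped.append({"snp_id": snp["snp_id"], "reason": str(err)})
            continue
        maf = minor_allele_frequency(d)
        f_alt = np.nanmean(d) / 2.0
        # report the effect per minor-allele copy (flip if alt is major)
        flip = f_alt > 0.5
        rows.append(
            {
                "snp_id": snp["snp_id"],
                "chrom": str(snp["chrom"]),
                "pos": int(snp["pos"]),
                "tested_allele": snp["ref"] if flip else snp["alt"],
                "maf": maf,
                "beta": -fit.beta if flip else fit.beta,
                "se": fit.se,
                "p": fit.p,
            }
        )
        kept_cols.append(i)

    results = pd.DataFrame(rows)
    if len(results) == 0:
        results = results.reindex(
            columns=["snp_id", "chrom", "pos", "tested_allele", "maf", "beta", "se", "p",
                     "clump_id", "is_snp_ref", "n_ld_partners", "p_adj", "significant"]
        )
        return AssociationRun(qc=qc, results=results, skipped=skipped)

    results = clump(results, cohort.dosages[:, kept_cols], r2_threshold, window_kb)
    results["p_adj"] = np.nan
    refs = results["is_snp_ref"]
    results.loc[refs, "p_adj"] = bh_adjust(results.loc[refs, "p"].to_numpy())
    results["significant"] = refs & (results["p_adj"] < fdr)
    return AssociationRun(qc=qc, results=results, skipped=skipped)
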