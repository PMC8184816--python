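"""Weighted-allele polygenic risk score (PRS), terciles and group tests.

The PRS of an individual is the sum over significant clump-representative
SNPs of the tested (minor) allele count (0, 1 or 2) weighted by its signed
estimating-equation effect on log2 B12, so scores span negative and positive
values.  Cohorts are stratified into terciles of the score, group differences
across terciles are tested with Kruskal-Wallis (continuous) or
chi-square/Fisher (categorical), and the fraction of log2-phenotype variance
explained is the squared Pearson correlation from the univariate regression
of log2 phenotype on the score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import gammaln

from .io import classify_b12
from .simulate import AdmixedCohort

TERCILE_LABELS = ("T1", "T2", "T3")


@dataclass
class PRSProfile:
    """Per-sample PRS with tercile assignment and fit summary."""

    scores: np.ndarray
    terciles: np.ndarray  # labels "T1".."T3", T1 = lowest scores
    boundaries: dict[str, tuple[float, float]]  # (min, max) score per tercile
    r_squared: float


def compute_prs(cohort: AdmixedCohort, effects: pd.DataFrame) -> np.ndarray:
    """Score_i = sum_k dosage_ik * beta_k over the effect SNPs.

    ``effects`` needs columns ``snp_id`` and ``beta``; an optional
    ``tested_allele`` column flips the dosage to count the tested allele when
    it is the reference allele.  Effect SNPs absent from the cohort contribute
    their mean dosage (2*MAF from the effects table's ``maf`` column when
    available, else nothing), with a warning either way.  Missing dosage
    values are mean-imputed per variant.
    """
    if len(effects) == 0:
        raise ValueError("empty effect set: no significant SNPs to score")
    idx = {s: i for i, s in enumerate(cohort.variants["snp_id"].astype(str))}
    alt = cohort.variants["alt"].astype(str).to_numpy()
    scores = np.zeros(cohort.n_samples)
    missing = []
    for row in effects.itertuples(index=False):
        i = idx.get(str(row.snp_id))
        if i is None:
            maf = getattr(row, "maf", None)
            if maf is not None and not pd.isna(maf):
                scores += row.beta * 2.0 * float(maf)
            missing.append(str(row.snp_id))
            continue
        d = cohort.dosages[:, i].copy()
        nan = np.isnan(d)
        if nan.any():
            d[nan] = d[~nan].mean()
        tested = getattr(row, "tested_allele", None)
        if tested is not None and not pd.isna(tested) and str(tested) != alt[i]:
            d = 2.0 - d
        scores += row.beta * d
    if missing:
        warnings.warn(
            f"compute_prs: {len(missing)} effect SNP(s) absent from cohort "
            f"(mean-dosage contribution): {missing[:5]}"
        )
    return scores


def variance_explained(scores: np.ndarray, log2_phenotype: np.ndarray) -> float:
    """R^2 of the univariate regression of log2 phenotype on the score."""
    s = np.asarray(scores, float)
    y = np.asarray(log2_phenotype, float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(s) == 0:
        raise ValueError("constant score: variance explained undefined")
    r = np.corrcoef(s, y)[0, 1]
    return float(r * r)


def stratify_terciles(scores: np.ndarray) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Rank-based tercile split, T1 = lowest scores.

    Sizes follow the largest-remainder rule: each tercile gets floor(N/3),
    with the remainder going to the earliest terciles (N=7 -> 3/2/2).  Ties
    are broken by sample order (stable sort).
    """
    s = np.asarray(scores, float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 samples to form terciles")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    order = np.argsort(s, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = {}
    start = 0
    for lab, size in zip(TERCILE_LABELS, sizes):
        members = order[start : start + size]
        labels[members] = lab
        bounds[lab] = (float(s[members].min()), float(s[members].max()))
        start += size
    return labels, bounds


def prs_profile(cohort: AdmixedCohort, effects: pd.DataFrame) -> PRSProfile:
    """Convenience: scores, terciles and variance explained in one object."""
    scores = compute_prs(cohort, effects)
    labels, bounds = stratify_terciles(scores)
    r2 = variance_explained(scores, np.log2(cohort.phenotype))
    return PRSProfile(scores=scores, terciles=labels, boundaries=bounds, r_squared=r2)


# ---------------------------------------------------------------------------
# group-difference tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    All-identical values across groups give (H=0, p=1) rather than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def categorical_group_test(table: np.ndarray) -> tuple[float, str]:
    """Homogeneity p for a tercile x category count table.

    Chi-square when every expected count is >= 5, otherwise an exact
    conditional (Fisher) test: 2x2 via the hypergeometric, larger tables by
    enumeration of all tables with the observed margins (probability-mass
    definition).  Returns (p, method).
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.size == 0 or t.sum() == 0:
        raise ValueError("need a non-empty 2-D contingency table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    # drop all-zero rows/columns: they carry no information
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0, "degenerate"
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(t)
        return float(p), "chi2"
    if t.shape == (2, 2):
        _, p = stats.fisher_exact(t)
        return float(p), "fisher"
    return _fisher_rxc(t), "fisher"


def _log_table_prob(t: np.ndarray) -> float:
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def _iter_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """All integer tables with the given margins (recursive row fill)."""
    r = len(row_sums)
    if r == 1:
        yield col_sums[None, :].copy()
        return
    first = row_sums[0]

    def fill(j: int, remaining: int, row: list[int]):
        if j == len(col_sums) - 1:
            if remaining <= col_sums[j]:
                yield row + [remaining]
            return
        hi = min(col_sums[j], remaining)
        for v in range(hi + 1):
            yield from fill(j + 1, remaining - v, row + [v])

    for row in fill(0, int(first), []):
        rest_cols = col_sums - np.array(row)
        if (rest_cols < 0).any():
            continue
        for sub in _iter_tables(row_sums[1:], rest_cols):
            yield np.vstack([np.array(row)[None, :], sub])


def _fisher_rxc(t: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Exact conditional homogeneity p by enumerating all margin-preserving
    tables no more probable than the observed one."""
    logp_obs = _log_table_prob(t)
    total = 0.0
    count = 0
    for tab in _iter_tables(t.sum(axis=1), t.sum(axis=0)):
        count += 1
        if count > max_tables:
            raise ValueError("contingency table too large for exact enumeration")
        lp = _log_table_prob(tab)
        if lp <= logp_obs + 1e-9:
            total += np.exp(lp)
    return float(min(1.0, total))


# ---------------------------------------------------------------------------
# tercile report and counseling lookup
# ---------------------------------------------------------------------------

CONTINUOUS_REPORT_COLUMNS = (
    "age", "bmi", "hei", "b12_pmol_l", "folate_nmol_l", "pyridoxal_nmol_l",
    "riboflavin_nmol_l", "thcy_umol_l",
)
CATEGORICAL_REPORT_COLUMNS = ("sex", "socioeconomic")


def tercile_summary(cohort: AdmixedCohort, profile: PRSProfile) -> pd.DataFrame:
    """Mean ± SD (continuous) or counts (categorical) per tercile, with the
    matching group-difference test p-value.  Metabolite columns (folate,
    pyridoxal, riboflavin, tHcy) appear only if present in the covariate
    table; they are report-only, never model inputs.
    """
    df = cohort.samples.copy()
    df["tercile"] = profile.terciles
    rows = []
    for col in CONTINUOUS_REPORT_COLUMNS:
        if col not in df.columns:
            continue
        groups = [df.loc[df["tercile"] == t, col].dropna().to_numpy(float) for t in TERCILE_LABELS]
        if any(len(g) == 0 for g in groups):
            continue
        _, p = kruskal_wallis(groups)
        row = {"variable": col, "test": "kruskal-wallis", "p": p}
        for t, g in zip(TERCILE_LABELS, groups):
            row[f"{t}_n"] = len(g)
            row[f"{t}_mean"] = g.mean()
            row[f"{t}_sd"] = g.std(ddof=1)
        rows.append(row)
    for col in CATEGORICAL_REPORT_COLUMNS:
        if col not in df.columns:
            continue
        ct = pd.crosstab(df["tercile"], df[col])
        p, method = categorical_group_test(ct.to_numpy())
        row = {"variable": col, "test": method, "p": p}
        for t in TERCILE_LABELS:
            if t in ct.index:
                row[f"{t}_n"] = int(ct.loc[t].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def load_counseling_table(path: str | None = None) -> dict:
    """Counseling lookup config: tercile -> B12 status -> advisory label."""
    if path is None:
        ref = resources.files("b12prs.data").joinpath("counseling_default.yaml")
        with resources.as_file(ref) as p:
            cfg = yaml.safe_load(open(p))
    else:
        cfg = yaml.safe_load(open(path))
    for t in TERCILE_LABELS:
        if t not in cfg:
            raise ValueError(f"counseling table missing tercile {t}")
    return cfg


def counsel_bucket(tercile: str, b12_status: str, table: dict | None = None) -> str:
    """Deterministic advisory lookup — explicitly hypothetical, not clinical.

    ``tercile`` follows the PRS convention (T1 = genetically lowest B12);
    ``b12_status`` is low/normal/above from the 148/295 pmol/L cut-offs.
    """
    if table is None:
        table = load_counseling_table()
    if tercile not in TERCILE_LABELS:
        raise ValueError(f"unknown tercile {tercile!r}")
    if b12_status not in ("low", "normal", "above"):
        raise ValueError(f"unknown B12 status {b12_status!r}")
    return f"{table[tercile][b12_status]} (hypothetical)"


def counseling_report(cohort: AdmixedCohort, profile: PRSProfile, table: dict | None = None) -> pd.DataFrame:
    """Per-sample advisory labels from tercile x measured B12 status."""
    if table is None:
        table = load_counseling_table()
    status = [classify_b12(v) for v in cohort.phenotype]
    advice = [counsel_bucket(t, s, table) for t, s in zip(profile.terciles, status)]
    return pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "prs": profile.scores,
            "tercile": profile.terciles,
            "b12_status": status,
            "advice": advice,
        }
    )
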