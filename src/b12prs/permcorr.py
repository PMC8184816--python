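"""Permutation-based Spearman correlation between ancestry and phenotype.

For each unit (gene region or genomic bin) and each ancestry component, the
Spearman correlation ``r`` with the phenotype is tested by permuting the
phenotype ``B`` times; the two-sided permutation p-value uses the add-one
estimator p = (#{|r_b| >= |r_obs|} + 1) / (B + 1), so p is never 0 and lies
in (0, 1].  Results are summarized by the signed correlation score
``-log10(p_perm) * sign(r)``; with B = 10,000 its magnitude is capped at
log10(10001) ~ 4.0.

Significance is declared at p_perm < 0.1 (no multiple-testing correction is
applied at this stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ancestry import GeneAncestryProfile
from .simulate import COMPONENTS, AdmixedCohort

DEFAULT_N_PERM = 10_000
PERM_ALPHA = 0.1


class DegenerateInputError(ValueError):
    """Constant ancestry or phenotype vector: Spearman r is undefined."""


@dataclass
class CorrScoreResult:
    """Correlation-score result for one (unit, ancestry component) pair."""

    unit: str
    component: str
    r: float
    p_perm: float
    score: float
    n_perm: int

    @property
    def significant(self) -> bool:
        return self.p_perm < PERM_ALPHA


def correlation_score(r: float, p_perm: float) -> float:
    """Signed correlation score: -log10(p_perm) * sign(r)."""
    if not 0 < p_perm <= 1:
        raise ValueError("p_perm must lie in (0, 1]")
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    return float(-np.log10(p_perm) * np.sign(r))


def _check_nondegenerate(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: Spearman correlation undefined")


def _rank_center(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    return r - r.mean()


def _corr_of_ranks(xr: np.ndarray, yr: np.ndarray) -> float:
    return float(xr @ yr / np.sqrt((xr @ xr) * (yr @ yr)))


def spearman_perm(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Spearman r between x and y with a two-sided permutation p-value.

    Ties get average ranks; the null is generated by permuting ``y``.
    Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    _check_nondegenerate(x, y)
    rng = np.random.default_rng(seed)
    xr = _rank_center(x)
    yr = _rank_center(y)
    r_obs = _corr_of_ranks(xr, yr)
    perms = _permuted_rank_matrix(yr, n_perm, rng)
    r_null = _null_correlations(xr, perms)
    p = _perm_pvalue(r_obs, r_null)
    return r_obs, p


def _permuted_rank_matrix(yr: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    perms = np.tile(yr, (n_perm, 1))
    return rng.permuted(perms, axis=1)


def _null_correlations(xr: np.ndarray, perm_ranks: np.ndarray) -> np.ndarray:
    denom = np.sqrt((xr @ xr) * (perm_ranks[0] @ perm_ranks[0]))
    return perm_ranks @ xr / denom


def _perm_pvalue(r_obs: float, r_null: np.ndarray) -> float:
    n_ge = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return (n_ge + 1) / (len(r_null) + 1)


def scan_genes(
    cohort: AdmixedCohort,
    profiles: list[GeneAncestryProfile],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation scores for every (gene, ancestry component).

    One shared permutation stream: the phenotype is permuted once per
    replicate and the same permuted ranks are reused for every gene and all
    three components, keeping p-values comparable across the scan (and making
    identical profiles give identical results).  Per-gene failures (e.g. a
    constant ancestry vector) are recorded, not fatal.
    """
    y = cohort.phenotype
    yr = _rank_center(y)
    rng = np.random.default_rng(seed)
    perms = _permuted_rank_matrix(yr, n_perm, rng)
    rows, failures = [], []
    for prof in profiles:
        for c, comp in enumerate(COMPONENTS):
            x = prof.means[:, c]
            try:
                _check_nondegenerate(x, y)
            except DegenerateInputError as err:
                failures.append({"gene": prof.symbol, "component": comp, "reason": str(err)})
                continue
            xr = _rank_center(x)
            r_obs = _corr_of_ranks(xr, yr)
            p = _perm_pvalue(r_obs, _null_correlations(xr, perms))
            rows.append(
                {
                    "gene": prof.symbol,
                    "component": comp,
                    "r": r_obs,
                    "p_perm": p,
                    "score": correlation_score(r_obs, p),
                    "n_perm": n_perm,
                    "significant": p < PERM_ALPHA,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["failures"] = failures
    return out


def scan_bins(
    cohort: AdmixedCohort,
    bin_size_bp: int = 5_000_000,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Chromosome-scan variant: correlation scores on fixed genomic bins.

    Variants are grouped into ``bin_size_bp`` windows per chromosome; each
    window's mean local ancestry is tested like a gene profile.  Units are
    labelled ``chrom:start-end``.
    """
    chroms = cohort.variants["chrom"].astype(str).to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    profiles = []
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        for b0 in range(0, int(pos[on].max()) + 1, bin_size_bp):
            inside = on & (pos >= b0 + 1) & (pos <= b0 + bin_size_bp)
            if not inside.any():
                continue
            means = cohort.local_ancestry[:, inside].mean(axis=1)
            label = f"{chrom}:{b0 + 1}-{b0 + bin_size_bp}"
            profiles.append(GeneAncestryProfile(label, means, int(inside.sum()), 0))
    return scan_genes(cohort, profiles, n_perm=n_perm, seed=seed)


def count_significant(table: pd.DataFrame, alpha: float = PERM_ALPHA) -> dict[str, int]:
    """Per-component counts of significant genes plus their union.

    Accepts either a long scan table (gene/component/p_perm) or a wide
    published-style table with ``p_perm_afr`` etc. columns.
    """
    counts: dict[str, int] = {}
    union: set[str] = set()
    if "component" in table.columns:
        for comp in COMPONENTS:
            sub = table[(table["component"] == comp) & (table["p_perm"] < alpha)]
            counts[comp] = len(sub)
            union |= set(sub["gene"])
    else:
        for comp in COMPONENTS:
            col = f"p_perm_{comp.lower()}"
            sig = table[table[col] < alpha]
            counts[comp] = len(sig)
            union |= set(sig["gene"])
    counts["union"] = len(union)
    return counts
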