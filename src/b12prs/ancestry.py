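"""Per-gene and genome-wide local-ancestry summaries.

A gene's ancestry profile is the mean of the diploid local-ancestry dosages
over the ancestry-informative SNPs inside its flanked interval.  Genes whose
interval contains no informative SNP have their borders grown symmetrically
by 1 kb at a time until one is found (or a configurable cap is reached), with
the number of growth steps recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneRegion, GeneSet
from .simulate import COMPONENTS, AdmixedCohort

DEFAULT_GROWTH_STEP_BP = 1000
DEFAULT_GROWTH_CAP_BP = 1_000_000


@dataclass
class GeneAncestryProfile:
    """Per-sample mean ancestry dosages for one gene region."""

    symbol: str
    means: np.ndarray  # (N, 3); rows sum to 1
    n_snps_used: int
    expansions_applied: int


class NoInformativeSNPError(ValueError):
    """No ancestry-informative SNP found within the growth cap."""


def mean_global_ancestry(cohort: AdmixedCohort, snp_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-sample genome-wide mean ancestry (N, 3): simple average of local
    dosages over all (or masked) informative SNPs."""
    la = cohort.local_ancestry
    if snp_mask is not None:
        la = la[:, np.asarray(snp_mask)]
    if la.shape[1] == 0:
        raise ValueError("cohort has no ancestry-informative SNPs")
    return la.mean(axis=1)


def gene_mean_ancestry(
    cohort: AdmixedCohort,
    region: GeneRegion,
    snp_mask: np.ndarray | None = None,
    step_bp: int = DEFAULT_GROWTH_STEP_BP,
    cap_bp: int = DEFAULT_GROWTH_CAP_BP,
) -> GeneAncestryProfile:
    """Mean local ancestry over informative SNPs in the flanked gene interval.

    If the interval holds no informative SNP, both borders grow by ``step_bp``
    per iteration (symmetrically) until at least one SNP falls inside or total
    growth reaches ``cap_bp``, in which case :class:`NoInformativeSNPError`
    explains the failure.  ``snp_mask`` restricts which cohort variants count
    as ancestry-informative (the informative set need not equal the
    association set).
    """
    chroms = cohort.variants["chrom"].astype(str).to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    informative = np.ones(len(pos), bool) if snp_mask is None else np.asarray(snp_mask, bool)
    on_chrom = informative & (chroms == region.chrom)

    expansions = 0
    while True:
        grow = expansions * step_bp
        lo = max(1, region.flanked_start - grow)
        hi = region.flanked_end + grow
        inside = on_chrom & (pos >= lo) & (pos <= hi)
        if inside.any():
            break
        if (expansions + 1) * step_bp > cap_bp:
            raise NoInformativeSNPError(
                f"{region.symbol}: no informative SNP within "
                f"[{region.flanked_start}, {region.flanked_end}] grown up to ±{cap_bp} bp"
            )
        expansions += 1

    means = cohort.local_ancestry[:, inside].mean(axis=1)
    return GeneAncestryProfile(
        symbol=region.symbol,
        means=means,
        n_snps_used=int(inside.sum()),
        expansions_applied=expansions,
    )


def gene_ancestry_table(
    cohort: AdmixedCohort,
    genes: GeneSet,
    snp_mask: np.ndarray | None = None,
    step_bp: int = DEFAULT_GROWTH_STEP_BP,
    cap_bp: int = DEFAULT_GROWTH_CAP_BP,
) -> tuple[list[GeneAncestryProfile], pd.DataFrame]:
    """Profiles for every gene plus the long (gene x sample) report table.

    Genes with no reachable SNP are skipped with a ``reason`` row instead of
    aborting the scan.
    """
    profiles, rows, failures = [], [], []
    for region in genes:
        try:
            prof = gene_mean_ancestry(cohort, region, snp_mask, step_bp, cap_bp)
        except NoInformativeSNPError as err:
            failures.append({"gene": region.symbol, "reason": str(err)})
            continue
        profiles.append(prof)
        for j, sid in enumerate(cohort.sample_ids):
            rows.append(
                {
                    "gene": prof.symbol,
                    "sample": sid,
                    **{comp.lower(): prof.means[j, c] for c, comp in enumerate(COMPONENTS)},
                    "n_snps": prof.n_snps_used,
                    "expansions": prof.expansions_applied,
                }
            )
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    return profiles, table
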