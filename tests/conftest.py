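import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import b12prs as b

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


def make_cohort(
    dosages: np.ndarray,
    b12: np.ndarray,
    positions: np.ndarray | None = None,
    chrom: str = "1",
    local_ancestry: np.ndarray | None = None,
    snp_ids: list[str] | None = None,
    ref: str = "A",
    alt: str = "G",
    covariates: pd.DataFrame | None = None,
) -> b.AdmixedCohort:
    """Hand-built cohort for unit fixtures."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if local_ancestry is None:
        local_ancestry = np.tile(np.array([0.5, 0.25, 0.25]), (n, m, 1))
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(m)]
    if covariates is None:
        rng = np.random.default_rng(0)
        covariates = pd.DataFrame(
            {
                "sample_id": [f"S{i + 1:03d}" for i in range(n)],
                "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
                "age": rng.uniform(9, 14, n),
                "bmi": rng.normal(20, 4, n),
                "hei": rng.normal(54, 10, n),
            }
        )
    covariates = covariates.copy()
    covariates["b12_pmol_l"] = np.asarray(b12, float)
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": np.asarray(positions, int),
            "ref": ref,
            "alt": alt,
        }
    )
    cohort = b.AdmixedCohort(
        samples=covariates, variants=variants, dosages=dosages, local_ancestry=local_ancestry
    )
    cohort.validate()
    return cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 120-sample simulated cohort shared by read-only tests."""
    cohort, truth = b.simulate_cohort(
        n_samples=120, n_variants=80, n_causal=8, seed=11, chrom_length_mb=20
    )
    return cohort, truth
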