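"""QC, estimating-equation fits, LD clumping and FDR control."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from conftest import make_cohort
from hypothesis import given
from hypothesis import strategies as st

import b12prs as b
from b12prs.assoc import (
    DegenerateGenotypeError,
    association_covariates,
    genotype_counts,
    minor_allele_frequency,
)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Direct enumeration of the conditional heterozygote distribution."""
    n = n_hom_major + n_het + n_hom_minor
    na = 2 * n_hom_minor + n_het
    na = min(na, 2 * n - na)

    def prob(h):
        hom_minor = (na - h) // 2
        hom_major = n - h - hom_minor
        return (
            math.factorial(n)
            / (math.factorial(hom_major) * math.factorial(h) * math.factorial(hom_minor))
            * 2**h
            * math.factorial(na)
            * math.factorial(2 * n - na)
            / math.factorial(2 * n)
            * math.comb(2 * n, na) ** 0  # weights already conditional
        )

    hets = range(na % 2, na + 1, 2)
    probs = {h: prob(h) for h in hets}
    z = sum(probs.values())
    p_obs = probs[n_het] / z
    return min(1.0, sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_monomorphic_is_one(self):
        assert b.hwe_exact(100, 0, 0) == 1.0

    def test_two_hets_is_modal(self):
        assert b.hwe_exact(0, 2, 0) == 1.0

    def test_matches_enumeration_for_all_small_triples(self):
        for n in range(1, 31):
            for het in range(n + 1):
                for hom_minor in range(n - het + 1):
                    hom_major = n - het - hom_minor
                    if hom_major < hom_minor:
                        continue
                    got = b.hwe_exact(hom_major, het, hom_minor)
                    want = hwe_oracle(hom_major, het, hom_minor)
                    assert got == pytest.approx(want, rel=1e-9), (hom_major, het, hom_minor)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            b.hwe_exact(-1, 0, 1)
        with pytest.raises(ValueError):
            b.hwe_exact(0, 0, 0)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def _cohort(self, columns):
        dos = np.column_stack(columns).astype(float)
        n = dos.shape[0]
        return make_cohort(dos, np.full(n, 250.0))

    def test_monomorphic_fails_maf(self):
        n = 100
        cohort = self._cohort([np.zeros(n), np.r_[np.ones(5), np.zeros(n - 5)]])
        qc = b.qc_filter(cohort)
        assert not qc.loc[0, "pass"] and qc.loc[0, "fail_reason"] == "MAF"
        assert qc.loc[1, "pass"]

    def test_maf_exactly_at_threshold_passes(self):
        # 100 samples, 2 minor alleles in hets -> MAF exactly 0.01
        d = np.zeros(100)
        d[:2] = 1.0
        cohort = self._cohort([d])
        qc = b.qc_filter(cohort)
        assert qc.loc[0, "maf"] == pytest.approx(0.01)
        assert qc.loc[0, "pass"]

    def test_hwe_violation_flagged(self):
        # all heterozygous at a common allele: strong HWE violation
        d = np.ones(100)
        assert b.hwe_exact(*genotype_counts(d)) < 1e-3
        cohort = self._cohort([d])
        qc = b.qc_filter(cohort)
        assert not qc.loc[0, "pass"] and qc.loc[0, "fail_reason"] == "HWE"

    def test_maf_uses_nonmissing_only(self):
        d = np.array([0, 0, 1, 2, np.nan, np.nan])
        assert minor_allele_frequency(d) == pytest.approx(3 / 8)


# ---------------------------------------------------------------------------
# estimating-equation fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(1)
        n = 60
        cohort, _ = b.simulate_cohort(n_samples=n, n_variants=10, n_causal=0, h2=None, seed=2)
        cov = association_covariates(cohort)
        d = cohort.dosages[:, 0]
        y = 0.5 * d + 0.1 * cov["age"].to_numpy()
        fit = b.fit_association(d, y, cov)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.se >= 0

    def test_constant_dosage_rejected(self):
        cov = pd.DataFrame({"age": np.arange(30.0)})
        with pytest.raises(DegenerateGenotypeError, match="degenerate genotype"):
            b.fit_association(np.ones(30), np.arange(30.0), cov)

    def test_singular_design_raises(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, 40).astype(float)
        cov = pd.DataFrame({"a": np.arange(40.0), "b": 2 * np.arange(40.0)})
        with pytest.raises(np.linalg.LinAlgError):
            b.fit_association(d, rng.normal(size=40), cov)

    def test_missing_dosages_mean_imputed(self):
        rng = np.random.default_rng(4)
        n = 80
        d = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * d + rng.normal(0, 0.1, n)
        cov = pd.DataFrame({"age": rng.uniform(9, 14, n)})
        d_miss = d.copy()
        d_miss[:5] = np.nan
        fit = b.fit_association(d_miss, y, cov)
        assert fit.beta == pytest.approx(0.3, abs=0.1)


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

class TestLD:
    def test_identical_vectors(self):
        d = np.array([0.0, 1, 2, 1, 0, 2])
        assert b.ld_r2(d, d) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = np.array([0.0, 2, 0, 2])
        bb = np.array([0.0, 0, 2, 2])
        assert b.ld_r2(a, bb) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pair(self):
        a = np.array([0.0, 1, 2, 2, 1, 0])
        c = np.array([1.0, 1, 2, 2, 0, 0])
        # hand: cov = 3, var_a = var_c = 4 -> r = 3/4, r^2 = 9/16
        r = np.corrcoef(a, c)[0, 1]
        assert b.ld_r2(a, c) == pytest.approx(r * r)
        assert b.ld_r2(a, c) == pytest.approx(9 / 16, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateGenotypeError):
            b.ld_r2(np.ones(5), np.arange(5.0))


def clump_oracle(snp_ids, chrom, pos, pvals, dosages, r2=0.2, window_bp=250_000):
    """Brute-force greedy clumping reimplementation."""
    m = len(snp_ids)
    unassigned = set(range(m))
    assignment = {}
    refs = []
    while unassigned:
        i = min(unassigned, key=lambda k: (pvals[k], pos[k], snp_ids[k]))
        unassigned.discard(i)
        assignment[i] = i
        refs.append(i)
        for j in list(unassigned):
            if chrom[j] != chrom[i] or abs(pos[j] - pos[i]) > window_bp:
                continue
            a, bb = dosages[:, i], dosages[:, j]
            if np.ptp(a) == 0 or np.ptp(bb) == 0:
                continue
            if np.corrcoef(a, bb)[0, 1] ** 2 > r2:
                assignment[j] = i
                unassigned.discard(j)
    return assignment, refs


def random_instance(rng, m, n=40):
    pos = np.sort(rng.choice(1_000_000, m, replace=False))
    base = rng.binomial(2, rng.uniform(0.1, 0.5), (n, m)).astype(float)
    # correlate random adjacent pairs to create non-trivial clumps
    for j in range(1, m):
        if rng.random() < 0.4:
            base[:, j] = np.where(rng.random(n) < 0.85, base[:, j - 1], base[:, j])
    keep = [j for j in range(m) if np.ptp(base[:, j]) > 0]
    df = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in keep],
            "chrom": "1",
            "pos": pos[keep],
            "p": rng.uniform(size=len(keep)),
        }
    )
    return df, base[:, keep]


class TestClump:
    def test_uncorrelated_snps_become_singletons(self):
        rng = np.random.default_rng(5)
        n, m = 200, 6
        dos = np.column_stack([rng.binomial(2, 0.5, n) for _ in range(m)]).astype(float)
        df = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)], "chrom": "1",
                           "pos": np.arange(m) * 10_000, "p": rng.uniform(size=m)})
        out = b.clump(df, dos)
        # with n=200, random pairs have r^2 near 0; all clumps singletons
        assert out["is_snp_ref"].all()
        assert out["clump_id"].nunique() == m

    def test_perfect_proxies_share_a_clump(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, 50).astype(float)
        dos = np.column_stack([d, d])
        df = pd.DataFrame({"snp_id": ["lead", "proxy"], "chrom": "1",
                           "pos": [10_000, 11_000], "p": [1e-6, 1e-3]})
        out = b.clump(df, dos).set_index("snp_id")
        assert out["clump_id"].nunique() == 1
        assert out.loc["lead", "is_snp_ref"] and not out.loc["proxy", "is_snp_ref"]

    def test_window_limits_absorption(self):
        d = np.tile([0.0, 1, 2, 1, 0], 10)
        dos = np.column_stack([d, d])
        df = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "1",
                           "pos": [1, 300_000], "p": [0.01, 0.5]})
        out = b.clump(df, dos)
        assert out["clump_id"].nunique() == 2  # r^2 = 1 but 300 kb apart

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            m = int(rng.integers(2, 31))
            df, dos = random_instance(rng, m)
            out = b.clump(df, dos)
            oracle_assign, oracle_refs = clump_oracle(
                df["snp_id"].to_numpy(), df["chrom"].to_numpy(), df["pos"].to_numpy(),
                df["p"].to_numpy(), dos,
            )
            # identical partitions
            got = {}
            for cid, grp in out.groupby("clump_id"):
                got[frozenset(grp.index)] = grp.index[grp["is_snp_ref"]][0]
            want = {}
            for j, ref in oracle_assign.items():
                want.setdefault(ref, set()).add(j)
            assert {frozenset(v) for v in want.values()} == set(got.keys())
            # SNP_ref has minimal p within its clump
            for cid, grp in out.groupby("clump_id"):
                assert grp.loc[grp["is_snp_ref"], "p"].item() == grp["p"].min()


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_applied_step_up(self):
        got = b.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert b.bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (b.bh_adjust(np.ones(5)) == 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            b.bh_adjust(np.array([0.0, 0.5]))

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_properties(self, pvals):
        p = np.array(pvals)
        adj = b.bh_adjust(p)
        assert ((adj >= p - 1e-12) & (adj <= 1 + 1e-12)).all()
        # permutation invariance
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(b.bh_adjust(p[perm]), adj[perm])

    def test_empirical_fdr_controlled_on_null(self):
        rng = np.random.default_rng(8)
        K, m = 1_000, 20
        fdp = np.empty(K)
        for k in range(K):
            p = rng.uniform(size=m)
            rejected = b.bh_adjust(p) < 0.1
            fdp[k] = rejected.sum() / max(rejected.sum(), 1) if rejected.any() else 0.0
        se = fdp.std(ddof=1) / np.sqrt(K)
        assert fdp.mean() <= 0.1 + 3 * se


# ---------------------------------------------------------------------------
# end-to-end association run
# ---------------------------------------------------------------------------

class TestRunAssociation:
    def test_pipeline_invariants(self):
        cohort, _ = b.simulate_cohort(n_samples=150, n_variants=60, n_causal=6, seed=13,
                                      chrom_length_mb=10, ld=b.LDBlocks(5, 0.7))
        run = b.run_association(cohort)
        res = run.results
        refs = res[res["is_snp_ref"]]
        # one SNP_ref per clump, holding the minimum p
        for cid, grp in res.groupby("clump_id"):
            assert grp["is_snp_ref"].sum() == 1
            assert grp.loc[grp["is_snp_ref"], "p"].item() == grp["p"].min()
        assert (refs["p_adj"] >= refs["p"] - 1e-12).all()
        sig = res[res["significant"]]
        assert sig["is_snp_ref"].all()
        # betas are reported per minor-allele copy
        assert ((res["maf"] > 0) & (res["maf"] <= 0.5)).all()
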