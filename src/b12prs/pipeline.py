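"""Reproducible end-to-end pipeline: simulate -> ancestry -> correlation ->
association -> PRS, writing a directory of TSVs plus a manifest.

The run layout is a plain directory of stage outputs (auditability over
orchestration); the manifest records the config hash, seed, package version
and per-stage row counts, and re-running with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import gene_ancestry_table
from .assoc import CLUMP_KB, CLUMP_R2, FDR_ALPHA, HWE_P_MIN, MAF_MIN, run_association
from .io import synthetic_gene_regions, write_cohort
from .permcorr import DEFAULT_N_PERM, PERM_ALPHA, scan_genes
from .prs import counseling_report, prs_profile, tercile_summary
from .simulate import DEFAULT_GENERATIONS, DEFAULT_PROPORTIONS, LDBlocks, simulate_cohort

log = logging.getLogger("b12prs")

STAGES = ("simulate", "ancestry", "corr", "assoc", "prs")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis' canonical thresholds."""

    seed: int = 0
    out_dir: str = "b12prs_run"
    # cohort
    n_samples: int = 168
    n_variants: int = 300
    n_genes: int = 30
    generations: int = DEFAULT_GENERATIONS
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    n_causal: int = 36
    h2: float = 0.42
    ld_block_size: int = 10
    ld_rho: float = 0.6
    missing_rate: float = 0.0
    # thresholds
    hwe_p: float = HWE_P_MIN
    maf: float = MAF_MIN
    p_perm: float = PERM_ALPHA
    clump_r2: float = CLUMP_R2
    clump_kb: float = CLUMP_KB
    fdr: float = FDR_ALPHA
    n_perm: int = DEFAULT_N_PERM
    # stage toggles
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("hwe_p", 0, 1), ("maf", 0, 0.5), ("p_perm", 0, 1),
            ("clump_r2", 0, 1), ("fdr", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "proportions" in raw:
            raw["proportions"] = tuple(raw["proportions"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self, include_out_dir: bool = True) -> dict:
        d = asdict(self)
        d["proportions"] = list(d["proportions"])
        d["stages"] = list(d["stages"])
        if not include_out_dir:
            d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        # out_dir is a run location, not part of the scientific configuration
        blob = json.dumps(self.to_dict(include_out_dir=False), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure aborts with a stage-tagged error; outputs of completed
    stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(include_out_dir=False),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    cohort = truth = genes = None
    stage = "simulate"
    try:
        ld = LDBlocks(config.ld_block_size, config.ld_rho) if config.ld_rho > 0 else None
        cohort, truth = simulate_cohort(
            n_samples=config.n_samples,
            n_variants=config.n_variants,
            generations=config.generations,
            proportions=config.proportions,
            n_causal=config.n_causal,
            h2=config.h2,
            ld=ld,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        genes = synthetic_gene_regions(cohort.variants, config.n_genes)
        if "simulate" in config.stages:
            write_cohort(cohort, out / "cohort", genotype_format="vcf")
            with open(out / "cohort" / "truth.json", "w") as fh:
                json.dump(
                    {
                        "causal_betas": truth.causal_betas.tolist(),
                        "covariate_effects": truth.covariate_effects,
                        "ancestry_effects": truth.ancestry_effects.tolist(),
                        "intercept": truth.intercept,
                        "noise_sd": truth.noise_sd,
                        "seed": truth.seed,
                    },
                    fh,
                    indent=1,
                )
            manifest["stages"]["simulate"] = {"n_samples": cohort.n_samples, "n_variants": cohort.n_variants}
            log.info("simulate: %d samples x %d variants", cohort.n_samples, cohort.n_variants)

        profiles = None
        if "ancestry" in config.stages:
            stage = "ancestry"
            profiles, table = gene_ancestry_table(cohort, genes)
            table.to_csv(out / "gene_ancestry.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages"]["ancestry"] = {"n_genes": len(profiles), "rows": len(table)}
            log.info("ancestry: %d gene profiles", len(profiles))

        if "corr" in config.stages:
            stage = "corr"
            if profiles is None:
                profiles, _ = gene_ancestry_table(cohort, genes)
            corr = scan_genes(cohort, profiles, n_perm=config.n_perm, seed=config.seed)
            corr.to_csv(out / "corr_scores.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages"]["corr"] = {
                "rows": len(corr),
                "significant": int(corr["significant"].sum()),
            }
            log.info("corr: %d significant of %d", int(corr["significant"].sum()), len(corr))

        run = None
        if "assoc" in config.stages:
            stage = "assoc"
            run = run_association(
                cohort,
                maf_min=config.maf,
                hwe_p_min=config.hwe_p,
                r2_threshold=config.clump_r2,
                window_kb=config.clump_kb,
                fdr=config.fdr,
            )
            run.qc.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
            run.results.to_csv(out / "assoc_results.tsv", sep="\t", index=False, float_format="%.6g")
            manifest["stages"]["assoc"] = {
                "tested": len(run.results),
                "clumps": int(run.results["is_snp_ref"].sum()) if len(run.results) else 0,
                "significant": int(run.results["significant"].sum()) if len(run.results) else 0,
            }
            log.info("assoc: %s", manifest["stages"]["assoc"])

        if "prs" in config.stages:
            stage = "prs"
            if run is None:
                raise RuntimeError("prs stage requires assoc stage outputs")
            effects = run.significant_effects(config.fdr)
            profile = prs_profile(cohort, effects)  # raises on empty effect set
            report = counseling_report(cohort, profile)
            report.to_csv(out / "prs_report.tsv", sep="\t", index=False, float_format="%.6g")
            summary = tercile_summary(cohort, profile)
            summary.to_csv(out / "tercile_summary.tsv", sep="\t", index=False, float_format="%.6g")
            with open(out / "prs_summary.json", "w") as fh:
                json.dump(
                    {
                        "n_effect_snps": len(effects),
                        "r_squared": profile.r_squared,
                        "tercile_boundaries": profile.boundaries,
                    },
                    fh,
                    indent=1,
                )
            manifest["stages"]["prs"] = {"n_effect_snps": len(effects), "r_squared": profile.r_squared}
            log.info("prs: %s", manifest["stages"]["prs"])
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"[stage {stage}] {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
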