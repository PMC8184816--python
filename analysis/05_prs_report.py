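#!/usr/bin/env python
"""PRS construction, tercile stratification and the counseling lookup.

Builds the weighted-allele score from the significant association effects of
step 04, stratifies the cohort into terciles, tests tercile differences and
writes results/prs_report.tsv, results/tercile_summary.tsv and
results/prs_summary.json.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

import b12prs as b
from b12prs.simulate import true_genetic_score

OUT = Path(__file__).resolve().parent.parent / "results"

spec = importlib.util.spec_from_file_location("step02", Path(__file__).parent / "02_gene_ancestry.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)


def main() -> None:
    cohort = step02.load_working_cohort()
    assoc = pd.read_csv(OUT / "assoc_results.tsv", sep="\t")
    effects = assoc[assoc["significant"] == True]  # noqa: E712
    if effects.empty:
        raise SystemExit("no significant effects at this cohort size; nothing to score")
    profile = b.prs_profile(cohort, effects)
    report = b.counseling_report(cohort, profile)
    report.to_csv(OUT / "prs_report.tsv", sep="\t", index=False, float_format="%.6g")
    summary = b.tercile_summary(cohort, profile)
    summary.to_csv(OUT / "tercile_summary.tsv", sep="\t", index=False, float_format="%.6g")

    truth = json.load(open(OUT / "cohort" / "truth.json"))
    true_score = cohort.dosages @ np.array(truth["causal_betas"])
    from scipy.stats import spearmanr
    rho = spearmanr(profile.scores, true_score).statistic

    payload = {
        "n_effect_snps": int(len(effects)),
        "r_squared": profile.r_squared,
        "tercile_boundaries": profile.boundaries,
        "rank_corr_with_true_score": float(rho),
    }
    with open(OUT / "prs_summary.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    sizes = pd.Series(profile.terciles).value_counts().to_dict()
    print(f"PRS from {len(effects)} SNP_ref effects")
    print(f"variance of log2 B12 explained: {profile.r_squared:.3f}")
    print(f"tercile sizes: {sizes}")
    print(f"rank correlation with true genetic score: {rho:.3f}")


if __name__ == "__main__":
    main()
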