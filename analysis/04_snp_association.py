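#!/usr/bin/env python
"""SNP association on the working cohort: QC, estimating equations, LD
clumping and FDR.

Writes results/qc_report.tsv and results/assoc_results.tsv and prints the
funnel (variants -> post-QC -> clumps -> significant SNP_ref at p_adj<0.1).
"""

import importlib.util
from pathlib import Path

import b12prs as b

OUT = Path(__file__).resolve().parent.parent / "results"

spec = importlib.util.spec_from_file_location("step02", Path(__file__).parent / "02_gene_ancestry.py")
step02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step02)


def main() -> None:
    cohort = step02.load_working_cohort()
    run = b.run_association(cohort)
    run.qc.to_csv(OUT / "qc_report.tsv", sep="\t", index=False, float_format="%.6g")
    run.results.to_csv(OUT / "assoc_results.tsv", sep="\t", index=False, float_format="%.6g")
    n_pass = int(run.qc["pass"].sum())
    n_clump = int(run.results["is_snp_ref"].sum())
    n_sig = int(run.results["significant"].sum())
    print(f"variants: {len(run.qc)}; pass QC: {n_pass}; clumps: {n_clump}; "
          f"significant SNP_ref (p_adj < 0.1): {n_sig}")
    if run.skipped:
        print(f"skipped {len(run.skipped)} SNPs (degenerate/singular fits)")


if __name__ == "__main__":
    main()
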