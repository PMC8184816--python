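"""Cohort and gene-set I/O.

On-disk dialects
----------------
* genotypes: VCF with GT fields, or a dosage TSV
  (``snp_id chrom pos ref alt <sample...>``, one row per variant, missing = NA);
* local ancestry: TSV, one row per variant, three columns per sample named
  ``<sample>.AFR / <sample>.AMR / <sample>.EUR`` holding diploid dosages;
* covariates/phenotype: TSV with header
  ``sample_id sex age bmi hei b12_pmol_l`` (extra columns such as folate or
  tHcy are carried through as report-only fields);
* gene regions: BED-like (chrom, 0-based start, end, symbol, source),
  converted to 1-based inclusive coordinates on read.

All genomic coordinates in memory are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import COMPONENTS, AdmixedCohort

#: candidate-gene flanking rule: promoter side / downstream side, in bp.
FLANK_UPSTREAM = 5000
FLANK_DOWNSTREAM = 1500

B12_LOW_CUTOFF = 148.0  # pmol/L
B12_ABOVE_CUTOFF = 295.0  # pmol/L


class CohortIOError(ValueError):
    """Malformed or inconsistent cohort input files."""


@dataclass(frozen=True)
class GeneRegion:
    """Named genomic interval with the candidate-gene flanking rule applied.

    ``start``/``end`` are 1-based inclusive transcript bounds; the flanked
    interval extends 5 kb before ``start`` (floored at 1) and 1.5 kb past
    ``end``, coordinate-relative regardless of strand.
    """

    symbol: str
    chrom: str
    start: int
    end: int
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.symbol}: coordinates are 1-based")

    @property
    def flanked_start(self) -> int:
        return max(1, self.start - FLANK_UPSTREAM)

    @property
    def flanked_end(self) -> int:
        return self.end + FLANK_DOWNSTREAM

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.flanked_start <= pos <= self.flanked_end


@dataclass
class GeneSet:
    """Unique-symbol collection of gene regions with provenance."""

    regions: list[GeneRegion]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        symbols = [r.symbol for r in self.regions]
        if len(symbols) != len(set(symbols)):
            raise ValueError("gene symbols must be unique within a GeneSet")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def symbols(self) -> list[str]:
        return [r.symbol for r in self.regions]


def classify_b12(b12_pmol_l: float) -> str:
    """Classify a plasma B12 level: low (<148), normal (148-295), above (>=295)."""
    if not b12_pmol_l > 0:
        raise ValueError("B12 level must be strictly positive")
    if b12_pmol_l < B12_LOW_CUTOFF:
        return "low"
    if b12_pmol_l < B12_ABOVE_CUTOFF:
        return "normal"
    return "above"


def merge_gene_lists(primary: list[GeneRegion], supplement: list[GeneRegion]) -> GeneSet:
    """Union of two candidate-gene lists by symbol, provenance retained.

    Symbols present in both lists keep the primary entry; duplicates are
    deduplicated with a warning giving their count.
    """
    if not primary or not supplement:
        raise ValueError("both gene lists must be non-empty")
    seen: dict[str, GeneRegion] = {}
    dups = 0
    for region in list(primary) + list(supplement):
        if region.symbol in seen:
            dups += 1
        else:
            seen[region.symbol] = region
    if dups:
        warnings.warn(f"merge_gene_lists: deduplicated {dups} shared symbol(s)")
    provenance = {r.symbol: r.source for r in seen.values()}
    return GeneSet(regions=list(seen.values()), provenance=provenance)


def annotate_variants(cohort: AdmixedCohort, genes: GeneSet) -> pd.DataFrame:
    """Assign every variant to each gene whose flanked interval contains it.

    Returns a long DataFrame (variant_index, snp_id, gene); variants falling
    in no gene appear once with gene = NaN so nothing is silently dropped.
    Multi-gene assignment is intentional: overlapping loci share signals and
    association is per-SNP, so there is no double counting.
    """
    chroms = cohort.variants["chrom"].astype(str).to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    rows = []
    hit = np.zeros(len(pos), dtype=bool)
    for region in genes:
        in_gene = (chroms == region.chrom) & (pos >= region.flanked_start) & (pos <= region.flanked_end)
        for i in np.flatnonzero(in_gene):
            rows.append((i, cohort.variants["snp_id"].iat[i], region.symbol))
        hit |= in_gene
    for i in np.flatnonzero(~hit):
        rows.append((i, cohort.variants["snp_id"].iat[i], np.nan))
    out = pd.DataFrame(rows, columns=["variant_index", "snp_id", "gene"])
    return out.sort_values(["variant_index", "gene"]).reset_index(drop=True)


def synthetic_gene_regions(
    variants: pd.DataFrame, n_genes: int, margin_bp: int = 100, source: str = "synthetic"
) -> GeneSet:
    """Partition simulated variants into ``n_genes`` consecutive gene regions.

    Convenience for simulated cohorts, which have no annotation of their own:
    contiguous runs of variants become gene bodies named g001, g002, ...
    """
    if n_genes < 1 or n_genes > len(variants):
        raise ValueError("n_genes must be in [1, n_variants]")
    order = variants.sort_values(["chrom", "pos"]).reset_index()
    groups = np.array_split(np.arange(len(order)), n_genes)
    regions = []
    for k, idx in enumerate(groups):
        sub = order.iloc[idx]
        regions.append(
            GeneRegion(
                symbol=f"g{k + 1:03d}",
                chrom=str(sub["chrom"].iloc[0]),
                start=max(1, int(sub["pos"].min()) - margin_bp),
                end=int(sub["pos"].max()) + margin_bp,
                source=source,
            )
        )
    return GeneSet(regions=regions, provenance={r.symbol: source for r in regions})


# ---------------------------------------------------------------------------
# cohort writers
# ---------------------------------------------------------------------------

def write_cohort(cohort: AdmixedCohort, out_dir: str | Path, genotype_format: str = "vcf") -> dict[str, Path]:
    """Write a cohort as its on-disk trio (+genotype format of choice).

    Returns the mapping of file kinds to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": out / "covariates.tsv",
        "ancestry": out / "local_ancestry.tsv",
    }
    cohort.samples.to_csv(paths["covariates"], sep="\t", index=False, float_format="%.10g")

    anc_cols = {}
    for j, sid in enumerate(cohort.sample_ids):
        for c, comp in enumerate(COMPONENTS):
            anc_cols[f"{sid}.{comp}"] = cohort.local_ancestry[j, :, c]
    anc = pd.DataFrame({"snp_id": cohort.variants["snp_id"], **anc_cols})
    anc.to_csv(paths["ancestry"], sep="\t", index=False, float_format="%.10g")

    if genotype_format == "vcf":
        paths["genotypes"] = out / "genotypes.vcf"
        _write_vcf(cohort, paths["genotypes"])
    elif genotype_format == "tsv":
        paths["genotypes"] = out / "dosages.tsv"
        dos = pd.DataFrame(cohort.dosages.T, columns=cohort.sample_ids)
        pd.concat([cohort.variants.reset_index(drop=True), dos], axis=1).to_csv(
            paths["genotypes"], sep="\t", index=False, na_rep="NA", float_format="%.10g"
        )
    else:
        raise ValueError(f"unknown genotype format: {genotype_format}")
    return paths


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(cohort: AdmixedCohort, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids)
            + "\n"
        )
        for i, row in cohort.variants.reset_index(drop=True).iterrows():
            gts = [
                "./." if np.isnan(d) else _GT[int(round(d))]
                for d in cohort.dosages[:, i]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# cohort readers
# ---------------------------------------------------------------------------

def load_cohort(genotype_path: str | Path, ancestry_path: str | Path, covariate_path: str | Path) -> AdmixedCohort:
    """Assemble and validate a cohort from its three on-disk sources.

    Sample IDs must agree across all files (hard error listing offenders);
    ancestry dosages must sum to 1 within 1e-6 per (sample, variant); variants
    are sorted by (chrom, pos).
    """
    genotype_path = Path(genotype_path)
    samples = pd.read_csv(covariate_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "sex", "age", "bmi", "hei", "b12_pmol_l"}
    missing_cols = required - set(samples.columns)
    if missing_cols:
        raise CohortIOError(f"covariate file missing columns: {sorted(missing_cols)}")

    if genotype_path.suffix == ".vcf" or genotype_path.name.endswith(".vcf.gz"):
        variants, dosages, geno_ids = _read_vcf(genotype_path)
    else:
        variants, dosages, geno_ids = _read_dosage_tsv(genotype_path)

    anc = pd.read_csv(ancestry_path, sep="\t")
    anc_samples = []
    for col in anc.columns:
        if "." in col:
            sid = col.rsplit(".", 1)[0]
            if sid not in anc_samples:
                anc_samples.append(sid)

    cov_ids = list(samples["sample_id"])
    for name, ids in (("genotype", geno_ids), ("ancestry", anc_samples)):
        extra = sorted(set(ids) ^ set(cov_ids))
        if extra:
            raise CohortIOError(f"sample ID mismatch between covariate and {name} files: {extra}")

    la = np.empty((len(cov_ids), len(anc), 3))
    for j, sid in enumerate(cov_ids):
        for c, comp in enumerate(COMPONENTS):
            col = f"{sid}.{comp}"
            if col not in anc.columns:
                raise CohortIOError(f"ancestry file missing column {col}")
            la[j, :, c] = anc[col].to_numpy(float)
    sums = la.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = np.argwhere(np.abs(sums - 1.0) > 1e-6)
        raise CohortIOError(
            f"ancestry dosages do not sum to 1 at {len(bad)} (sample, variant) cells, first: {tuple(bad[0])}"
        )

    if "snp_id" in anc.columns and not anc["snp_id"].astype(str).equals(variants["snp_id"].astype(str)):
        raise CohortIOError("ancestry and genotype files list different variants")

    # reorder genotype columns to covariate order, then sort variants
    order = [geno_ids.index(sid) for sid in cov_ids]
    dosages = dosages[order]

    sort_idx = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    variants = variants.loc[sort_idx].reset_index(drop=True)
    dosages = dosages[:, sort_idx]
    la = la[:, sort_idx]

    cohort = AdmixedCohort(samples=samples, variants=variants, dosages=dosages, local_ancestry=la)
    cohort.validate()
    return cohort


def _read_vcf(path: Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = list(vcf.samples)
    rows, dosage_rows = [], []
    for var in vcf:
        rows.append((var.ID, str(var.CHROM), var.POS, var.REF, var.ALT[0] if var.ALT else "."))
        gt = var.gt_types.astype(float)  # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        dosage_rows.append(gt)
    variants = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return variants, np.asarray(dosage_rows).T, ids


def _read_dosage_tsv(path: Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise CohortIOError(f"dosage TSV missing columns: {missing}")
    ids = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str)
    return variants, df[ids].to_numpy(float).T, ids


# ---------------------------------------------------------------------------
# gene-region files and packaged fixtures
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneRegion]:
    """Read a BED-like gene file (chrom, start0, end, symbol[, source])."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, end, symbol = parts[0], int(parts[1]), int(parts[2]), parts[3]
            source = parts[4] if len(parts) > 4 else "unknown"
            regions.append(GeneRegion(symbol=symbol, chrom=str(chrom), start=start0 + 1, end=end, source=source))
    return regions


def _data_path(name: str):
    return resources.files("b12prs.data").joinpath(name)


def load_published_gene_correlations() -> pd.DataFrame:
    """Published per-gene ancestry-correlation table (r and permutation p
    for AFR/AMR/EUR across the 90 candidate genes)."""
    with resources.as_file(_data_path("published_gene_ancestry_corr.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_published_snp_effects() -> pd.DataFrame:
    """Published clump-representative SNP association table (36 SNPs, effect
    on log2 B12 per minor-allele copy, BH-adjusted p)."""
    with resources.as_file(_data_path("published_snp_assoc.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_gene_lists() -> tuple[list[GeneRegion], list[GeneRegion]]:
    """Packaged candidate-gene lists: 76 disease-database genes + 14 from a
    targeted review.  Coordinates are synthetic toy placements (the study's
    exact build-37 intervals are not published); the symbols are authentic.
    """
    with resources.as_file(_data_path("gene_regions_synthetic.bed")) as p:
        regions = read_gene_bed(p)
    primary = [r for r in regions if r.source == "DISEASES"]
    supplement = [r for r in regions if r.source == "review"]
    return primary, supplement


def load_gene_set() -> GeneSet:
    """The merged 90-gene candidate set."""
    primary, supplement = load_gene_lists()
    return merge_gene_lists(primary, supplement)
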