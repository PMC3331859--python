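"""On-disk formats: TSV dialects and minimal VCF (GT-only) support.

All tabular outputs are TSV with a fixed column order, floats at six
significant digits and p-values in scientific notation, so regression
diffs stay stable.  Genomic coordinates are 1-based and fully closed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Panel, PoolDesign, RASMatrix

FLOAT_FMT = "%.6g"

SNP_MAP_COLS = ["snp_id", "chrom", "pos", "allele_A", "allele_B",
                "control_maf", "allelic_or", "ld_block"]
MANIFEST_COLS = ["sample_id", "group", "sex", "age", "cohort"]
POOL_COLS = ["pool_id", "group", "members"]
INTENSITY_COLS = ["snp_id", "pool_id", "replicate", "intensity_A", "intensity_B"]


def _write(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="NA")


# --- SNP map ---------------------------------------------------------------

def write_snp_map(panel: Panel, path) -> None:
    _write(panel.snps[SNP_MAP_COLS], path)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = set(SNP_MAP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP map missing columns {missing}")
    return df


# --- sample manifest -------------------------------------------------------

def write_manifest(samples: pd.DataFrame, path) -> None:
    out = samples.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    for col in MANIFEST_COLS:
        if col not in out.columns:
            out[col] = "NA"
    _write(out[MANIFEST_COLS], path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError("manifest needs sample_id and group columns")
    return df.set_index("sample_id")


# --- pool design -----------------------------------------------------------

def write_pool_design(design: PoolDesign, path) -> None:
    out = design.pools.copy()
    out["members"] = out["members"].map(",".join)
    _write(out[POOL_COLS], path)


def read_pool_design(path, pool_size: int | None = None) -> PoolDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(POOL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pool design missing columns {missing}")
    df = df.copy()
    df["members"] = df["members"].map(lambda s: s.split(","))
    size = pool_size or len(df["members"].iloc[0])
    return PoolDesign(pools=df, pool_size=size)


# --- intensities -----------------------------------------------------------

def write_intensities(panel_df: pd.DataFrame, path) -> None:
    _write(panel_df[INTENSITY_COLS], path)


def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "pool_id": str})
    missing = set(INTENSITY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {missing}")
    return df


# --- RAS matrix ------------------------------------------------------------

def write_ras_matrix(ras: RASMatrix, path) -> None:
    out = ras.values.copy()
    out.index.name = "pool_id"
    _write(out, path, index=True)


def read_ras_matrix(path, pool_groups: pd.Series | None = None,
                    n_subjects_per_pool: int = 15) -> RASMatrix:
    values = pd.read_csv(path, sep="\t", index_col="pool_id")
    if pool_groups is None:
        pool_groups = pd.Series({p: str(p).rsplit("_p", 1)[0] for p in values.index})
    return RASMatrix(values=values, pool_groups=pool_groups,
                     n_subjects_per_pool=n_subjects_per_pool)


# --- genotype dosage TSV ---------------------------------------------------

def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    out = genotypes.dosage.copy()
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t", na_rep="NA",
               float_format="%g")  # dosages are whole numbers


def read_dosage_tsv(path, manifest: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id", na_values=["NA"])
    return GenotypeMatrix(df.astype(float), manifest.loc[df.columns])


# --- VCF (GT only, unphased) -----------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, snp_map: pd.DataFrame, path) -> None:
    """Minimal VCF 4.2 with GT only.  REF = allele_B (major), ALT =
    allele_A (the counted minor allele), so ALT dosage equals the
    stored minor-allele dosage."""
    info = snp_map.set_index("snp_id")
    samples = list(genotypes.sample_ids)
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp in genotypes.snp_ids:
            row = info.loc[snp]
            d = genotypes.dosage.loc[snp]
            gts = "\t".join("./." if np.isnan(v) else gt_of[float(v)] for v in d)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                     f"{row['allele_B']}\t{row['allele_A']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, manifest: pd.DataFrame) -> GenotypeMatrix:
    """Read a VCF (GT field) into minor-allele dosages.

    ALT-allele dosage is computed per biallelic record (multi-allelic
    records are skipped with a warning); the counted allele is then
    flipped to the minor allele wherever the overall ALT frequency
    exceeds 0.5.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(g)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records")
    dosage = pd.DataFrame(rows, index=snp_ids, columns=samples, dtype=float)
    freq = dosage.sum(axis=1) / (2.0 * dosage.notna().sum(axis=1))
    flip = freq > 0.5
    dosage.loc[flip] = 2.0 - dosage.loc[flip]
    return GenotypeMatrix(dosage, manifest.loc[samples])


def read_genotypes(path, fmt: str, manifest: pd.DataFrame) -> GenotypeMatrix:
    """Dispatch on ``fmt`` in {"dosage-tsv", "vcf"}."""
    if fmt == "dosage-tsv":
        return read_dosage_tsv(path, manifest)
    if fmt == "vcf":
        return read_vcf(path, manifest)
    raise ValueError(f"unknown genotype format {fmt!r}")


# --- study effects (meta-analysis input) -----------------------------------

def read_study_effects(path):
    """TSV with study_id, or, and either se or ci_low/ci_high."""
    from .meta import StudyEffect, se_from_ci

    df = pd.read_csv(path, sep="\t")
    if "study_id" not in df.columns or "or" not in df.columns:
        raise ValueError("effects table needs study_id and or columns")
    effects = []
    for _, row in df.iterrows():
        if "se" in df.columns and not pd.isna(row.get("se")):
            se = float(row["se"])
        else:
            se = se_from_ci(float(row["ci_low"]), float(row["ci_high"]))
        effects.append(StudyEffect(study_id=str(row["study_id"]),
                                   log_or=float(np.log(row["or"])),
                                   se_log_or=se))
    return effects


def write_table(df: pd.DataFrame, path, p_cols: tuple[str, ...] = ()) -> None:
    """Generic TSV writer; p-value columns forced to scientific notation."""
    out = df.copy()
    for col in p_cols:
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.6E}")
    _write(out, path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
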