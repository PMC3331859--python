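"""Pooled-array allelotyping: RAS computation and pooled association.

RAS (relative allele signal) = A/(A+B) for the two allele channels of
a probe set; on an array hybridized with an equimolar DNA pool its
mean over technical replicates estimates the pool's allele frequency.
Association between groups of pools is tested twice: a two-sample
equal-variance Student's t-test on pool-level mean RAS (sensitive to
between-pool variation) and a 1-df χ² on the group mean frequencies
converted to allele counts (sensitive to the mean difference alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import CASE, CONTROL, RASMatrix


@dataclass
class RASQCReport:
    n_entries: int
    n_invalid: int  # A+B <= 0, marked missing


def compute_ras(intensities: pd.DataFrame) -> tuple[pd.DataFrame, RASQCReport]:
    """Per-(SNP, pool, replicate) RAS = A/(A+B).

    Entries with A+B <= 0 are marked missing and counted in the QC
    report.  Negative intensities are an input error (they cannot come
    from an array scanner) and are rejected with the offending row.
    """
    required = {"snp_id", "pool_id", "replicate", "intensity_A", "intensity_B"}
    if not required.issubset(intensities.columns):
        raise ValueError(f"intensity table missing columns {required - set(intensities.columns)}")
    a = intensities["intensity_A"].to_numpy(dtype=float)
    b = intensities["intensity_B"].to_numpy(dtype=float)
    neg = np.where((a < 0) | (b < 0))[0]
    if neg.size:
        row = intensities.iloc[neg[0]]
        raise ValueError(
            f"negative intensity at snp_id={row['snp_id']} pool_id={row['pool_id']} "
            f"replicate={row['replicate']}"
        )
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ras = np.where(total > 0, a / total, np.nan)
    out = intensities[["snp_id", "pool_id", "replicate"]].copy()
    out["ras"] = ras
    return out, RASQCReport(n_entries=len(out), n_invalid=int((~(total > 0)).sum()))


def average_replicates(
    ras_table: pd.DataFrame,
    min_replicates: int = 2,
    pool_groups: pd.Series | None = None,
    n_subjects_per_pool: int = 15,
) -> RASMatrix:
    """Mean RAS per (SNP, pool) over non-missing replicates.

    Cells with fewer than ``min_replicates`` non-missing replicates
    become missing.  ``pool_groups`` maps pool id → group label; when
    omitted, pools named ``<group>_p...`` are labelled by prefix.
    """
    grouped = ras_table.groupby(["pool_id", "snp_id"])["ras"]
    mean = grouped.mean()
    count = grouped.count()
    mean[count < min_replicates] = np.nan
    values = mean.unstack("snp_id")
    # preserve input SNP order
    snp_order = list(dict.fromkeys(ras_table["snp_id"]))
    pool_order = list(dict.fromkeys(ras_table["pool_id"]))
    values = values.reindex(index=pool_order, columns=snp_order)
    if pool_groups is None:
        pool_groups = pd.Series({p: str(p).rsplit("_p", 1)[0] for p in values.index})
    return RASMatrix(values=values, pool_groups=pool_groups,
                     n_subjects_per_pool=n_subjects_per_pool)


def pca_pool_filter(
    ras: RASMatrix, z_threshold: float = 3.5
) -> tuple[RASMatrix, list[str], pd.DataFrame]:
    """Exclude outlier pools on the first two principal components.

    The pool × SNP matrix is column-centered (missing cells imputed
    with the per-SNP mean for the decomposition only) and a pool is
    excluded when the robust z-score — (x − median)/(1.4826·MAD) — of
    its PC1 or PC2 coordinate exceeds ``z_threshold``.  Single pass.
    """
    values = ras.values
    if len(values) < 3:
        warnings.warn("fewer than 3 pools: PCA filter skipped, all pools kept")
        pcs = pd.DataFrame(0.0, index=values.index, columns=["PC1", "PC2"])
        return ras, [], pcs

    x = values.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(x), col_mean[None, :], x)
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0.0):
        pcs = pd.DataFrame(0.0, index=values.index, columns=["PC1", "PC2"])
        return ras, [], pcs

    coords = PCA(n_components=2, svd_solver="full").fit_transform(x)
    pcs = pd.DataFrame(coords, index=values.index, columns=["PC1", "PC2"])

    outlier = np.zeros(len(values), dtype=bool)
    for col in ("PC1", "PC2"):
        v = pcs[col].to_numpy()
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad > 0:
            outlier |= np.abs(v - med) / mad > z_threshold
    excluded = list(values.index[outlier])
    kept = ras.subset_pools([p for p in values.index if p not in set(excluded)])
    return kept, excluded, pcs


def _chi2_2x2(x1: float, n1: float, x2: float, n2: float) -> tuple[float, float]:
    """Pearson 1-df χ² on the 2×2 table [[x1, n1-x1], [x2, n2-x2]],
    no continuity correction; counts may be continuous."""
    a, b, c, d = x1, n1 - x1, x2, n2 - x2
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return np.nan, np.nan
    stat = n * (a * d - b * c) ** 2 / denom
    return stat, float(stats.chi2.sf(stat, df=1))


def pooled_association(ras: RASMatrix,
                       case_group: str = CASE,
                       control_group: str = CONTROL) -> pd.DataFrame:
    """Dual t-test / χ² association on pool-level RAS per SNP.

    p_ttest: two-sample equal-variance Student's t on pool RAS values
    (df = n1+n2−2).  p_chi2: 1-df χ² on continuous allele counts
    (group mean RAS × 2·N subjects represented by non-missing pools).
    A SNP needs ≥ 2 non-missing pools in each group to be testable;
    if both groups have zero variance the t p-value is 1 when the
    means agree and the SNP is untestable otherwise.
    """
    case = ras.group_values(case_group).to_numpy(dtype=float)
    ctrl = ras.group_values(control_group).to_numpy(dtype=float)
    snp_ids = ras.values.columns
    m = ras.n_subjects_per_pool

    n1 = (~np.isnan(case)).sum(axis=0)
    n2 = (~np.isnan(ctrl)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean1 = np.nanmean(case, axis=0)
        mean2 = np.nanmean(ctrl, axis=0)
        var1 = np.nanvar(case, axis=0, ddof=1)
        var2 = np.nanvar(ctrl, axis=0, ddof=1)

    rows = []
    for j, snp in enumerate(snp_ids):
        rec = {"snp_id": snp, "mean_ras_case": np.nan, "mean_ras_control": np.nan,
               "p_ttest": np.nan, "p_chi2": np.nan, "testable": False}
        if n1[j] < 2 or n2[j] < 2:
            rows.append(rec)
            continue
        zero_var = var1[j] == 0 and var2[j] == 0
        if zero_var and not np.isclose(mean1[j], mean2[j]):
            rows.append(rec)
            continue
        rec["mean_ras_case"] = mean1[j]
        rec["mean_ras_control"] = mean2[j]
        if zero_var:
            rec["p_ttest"] = 1.0
        else:
            df = n1[j] + n2[j] - 2
            sp2 = ((n1[j] - 1) * var1[j] + (n2[j] - 1) * var2[j]) / df
            t = (mean1[j] - mean2[j]) / np.sqrt(sp2 * (1 / n1[j] + 1 / n2[j]))
            rec["p_ttest"] = float(2 * stats.t.sf(abs(t), df))
        big_n1 = 2.0 * m * n1[j]
        big_n2 = 2.0 * m * n2[j]
        _, p = _chi2_2x2(mean1[j] * big_n1, big_n1, mean2[j] * big_n2, big_n2)
        rec["p_chi2"] = 1.0 if np.isnan(p) and np.isclose(mean1[j], mean2[j]) else p
        rec["testable"] = True
        rows.append(rec)
    return pd.DataFrame(rows)
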