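"""Individual-genotype association stage.

Covers the QC filters applied before any test (per-SNP missingness,
per-sample missingness, exact HWE in controls), the allelic χ² test
with odds ratio and log-normal CI, logistic regression under additive /
dominant / recessive codings, Benjamini-Hochberg correction, the
pooled-vs-individual concordance call, and the case-only age-at-onset
scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .containers import CASE, CONTROL, GenotypeMatrix

MODELS = ("allelic", "additive", "dominant", "recessive")


@dataclass
class QCConfig:
    """Keep thresholds are exclusive: a SNP/sample survives only when
    its missingness is < the threshold and the control HWE exact
    p-value is >= hwe_p_min."""

    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.05
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for v in (self.max_snp_missing, self.max_ind_missing, self.hwe_p_min):
            if not 0 < v < 1:
                raise ValueError("QC thresholds must lie in (0, 1)")


@dataclass
class AgeOnsetConfig:
    cutoff_years: int = 65
    young_code: int = 1
    old_code: int = 0
    models: tuple[str, ...] = ("additive", "dominant", "recessive")


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test (two-sided, conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more probable
    than the observed one, given the minor-allele and sample totals.
    Probabilities are built by recurrence from the mode, which is
    numerically stable up to totals of 1e5.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0

    # probabilities over heterozygote counts h with h ≡ n_minor (mod 2),
    # 0 <= h <= n_minor, built in log space from the step ratio
    # P(h+2)/P(h) = 4·hom_minor·hom_major / ((h+2)(h+1))
    h_vals = np.arange(n_minor % 2, n_minor + 1, 2)
    h = h_vals[:-1].astype(float)
    hom_min = (n_minor - h) / 2.0
    hom_maj = n - hom_min - h
    log_ratio = (np.log(4.0) + np.log(hom_min) + np.log(hom_maj)
                 - np.log(h + 2.0) - np.log(h + 1.0))
    logp = np.concatenate([[0.0], np.cumsum(log_ratio)])
    logp -= logsumexp(logp)
    probs = np.exp(logp)

    obs = np.searchsorted(h_vals, n_Aa)
    if obs >= len(h_vals) or h_vals[obs] != n_Aa:
        raise ValueError("heterozygote count incompatible with allele counts")
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_exact_p_dosage(dosage: np.ndarray) -> float:
    """HWE exact p from a dosage vector (NaN ignored)."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return 1.0
    return hwe_exact_p(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def qc_filter(
    genotypes: GenotypeMatrix,
    config: QCConfig = QCConfig(),
    control_group: str = CONTROL,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Single-pass QC: SNP missingness → sample missingness → control HWE.

    Returns the filtered matrix and a report listing every exclusion
    with its reason (kind, id, value).
    """
    report_rows = []

    snp_miss = genotypes.missingness_per_snp()
    drop_snps = snp_miss[snp_miss >= config.max_snp_missing]
    for snp, v in drop_snps.items():
        report_rows.append({"kind": "snp", "id": snp, "reason": "missingness", "value": v})
    g = genotypes.subset(snps=[s for s in genotypes.snp_ids if s not in set(drop_snps.index)])

    ind_miss = g.missingness_per_sample()
    drop_ind = ind_miss[ind_miss >= config.max_ind_missing]
    for samp, v in drop_ind.items():
        report_rows.append({"kind": "sample", "id": samp, "reason": "missingness", "value": v})
    g = g.subset(samples=[s for s in g.sample_ids if s not in set(drop_ind.index)])

    controls = g.group_samples(control_group)
    if not controls:
        raise ValueError(f"no samples in control group {control_group!r}: "
                         "cannot apply the HWE filter")
    ctrl = g.dosage[controls]
    hwe_p = ctrl.apply(lambda row: hwe_exact_p_dosage(row.to_numpy()), axis=1)
    drop_hwe = hwe_p[hwe_p < config.hwe_p_min]
    for snp, v in drop_hwe.items():
        report_rows.append({"kind": "snp", "id": snp, "reason": "hwe", "value": v})
    g = g.subset(snps=[s for s in g.snp_ids if s not in set(drop_hwe.index)])

    report = pd.DataFrame(report_rows, columns=["kind", "id", "reason", "value"])
    return g, report


# ---------------------------------------------------------------------------
# Allelic association
# ---------------------------------------------------------------------------

def odds_ratio_from_freq(f1: float, f2: float) -> float:
    """Allelic OR from the two minor-allele frequencies:
    OR = F1(1−F2) / (F2(1−F1))."""
    return f1 * (1.0 - f2) / (f2 * (1.0 - f1))


def orient_minor_allele(genotypes: GenotypeMatrix,
                        control_group: str = CONTROL) -> GenotypeMatrix:
    """Recode dosages so the counted allele is the minor allele of the
    combined control group (dosage → 2 − dosage where needed)."""
    ctrl_freq = genotypes.allele_frequency(control_group)
    flip = ctrl_freq > 0.5
    d = genotypes.dosage.copy()
    d.loc[flip] = 2.0 - d.loc[flip]
    return GenotypeMatrix(d, genotypes.samples.copy())


def allelic_assoc(
    genotypes: GenotypeMatrix,
    case_group: str = CASE,
    control_group: str = CONTROL,
    comparison: str = "case vs control",
) -> pd.DataFrame:
    """Allelic χ² test per SNP with OR and 95% CI.

    Allele counts come from dosage sums over non-missing samples.  The
    OR is the 2×2 cross-product; when any cell is zero, 0.5 is added
    to every cell (Haldane-Anscombe) for OR and CI.  The χ² p-value is
    the 1-df Pearson statistic on the raw counts without continuity
    correction.  SNPs monomorphic in both groups are untestable.
    """
    cases = genotypes.dosage[genotypes.group_samples(case_group)]
    ctrls = genotypes.dosage[genotypes.group_samples(control_group)]
    rows = []
    for snp in genotypes.snp_ids:
        c = cases.loc[snp].to_numpy(dtype=float)
        t = ctrls.loc[snp].to_numpy(dtype=float)
        c, t = c[~np.isnan(c)], t[~np.isnan(t)]
        a = float(c.sum()); b = 2.0 * len(c) - a        # case minor / major
        cc = float(t.sum()); d = 2.0 * len(t) - cc      # control minor / major
        rec = {"snp_id": snp, "model": "allelic", "comparison": comparison,
               "f_case": np.nan, "f_control": np.nan, "odds_ratio": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "p_raw": np.nan,
               "testable": False}
        if len(c) == 0 or len(t) == 0 or (a + cc == 0) or (b + d == 0):
            rows.append(rec)
            continue
        rec["f_case"] = a / (2.0 * len(c))
        rec["f_control"] = cc / (2.0 * len(t))
        aa, bb, ccc, dd = (a, b, cc, d)
        if min(aa, bb, ccc, dd) == 0:
            aa, bb, ccc, dd = aa + 0.5, bb + 0.5, ccc + 0.5, dd + 0.5
        orr = (aa * dd) / (bb * ccc)
        se = math.sqrt(1 / aa + 1 / bb + 1 / ccc + 1 / dd)
        rec["odds_ratio"] = orr
        rec["ci_low"] = math.exp(math.log(orr) - 1.96 * se)
        rec["ci_high"] = math.exp(math.log(orr) + 1.96 * se)
        n = a + b + cc + d
        denom = (a + b) * (cc + d) * (a + cc) * (b + d)
        stat = n * (a * d - b * cc) ** 2 / denom
        rec["p_raw"] = float(stats.chi2.sf(stat, df=1))
        rec["testable"] = True
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogitFit:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    separation: bool
    testable: bool = True


def code_genotype(dosage: np.ndarray, model: str) -> np.ndarray:
    """Genetic coding of minor-allele dosage: additive 0/1/2, dominant
    carrier 0/1, recessive minor-homozygote 0/1."""
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        return d
    if model == "dominant":
        return np.where(np.isnan(d), np.nan, (d > 0).astype(float))
    if model == "recessive":
        return np.where(np.isnan(d), np.nan, (d == 2).astype(float))
    raise ValueError(f"unknown genetic model {model!r}")


def fit_logistic(x: np.ndarray, y: np.ndarray,
                 covariates: np.ndarray | None = None) -> LogitFit:
    """Binomial logistic regression of a binary outcome on one coded
    genotype predictor (plus optional covariate columns).

    Fit by maximum likelihood (statsmodels Newton/IRLS); complete
    separation — non-convergence or |beta| > 15 — is flagged and no
    p-value is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        ok &= ~np.isnan(covariates).any(axis=1)
    xs, ys = x[ok], y[ok]
    if set(np.unique(ys)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    nan = LogitFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                   converged=False, separation=False, testable=False)
    if xs.size == 0 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return nan

    design = [np.ones_like(xs), xs]
    if covariates is not None:
        design.extend(covariates[ok].T)
    X = np.column_stack(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(ys, X).fit(disp=0, maxiter=100, tol=1e-10)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return LogitFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            converged=False, separation=True)
    beta = float(res.params[1])
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or abs(beta) > 15:
        return LogitFit(beta, np.nan, np.nan, np.nan, np.nan, np.nan,
                        converged=converged, separation=True)
    se = float(res.bse[1])
    return LogitFit(
        beta=beta, se=se, odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se), ci_high=math.exp(beta + 1.96 * se),
        p=float(2 * stats.norm.sf(abs(beta / se))),
        converged=True, separation=False,
    )


def logistic_assoc(
    genotypes: GenotypeMatrix,
    model: str = "additive",
    case_group: str = CASE,
    control_group: str = CONTROL,
    comparison: str = "case vs control",
    covariate_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-SNP logistic regression association under one genetic coding."""
    if model not in ("additive", "dominant", "recessive"):
        raise ValueError(f"unknown genetic model {model!r}")
    case_ids = genotypes.group_samples(case_group)
    ctrl_ids = genotypes.group_samples(control_group)
    ids = case_ids + ctrl_ids
    y = np.array([1.0] * len(case_ids) + [0.0] * len(ctrl_ids))
    cov = None
    if covariate_cols:
        cov = genotypes.samples.loc[ids, list(covariate_cols)].to_numpy(dtype=float)
    sub = genotypes.dosage[ids]
    case_sub = genotypes.dosage[case_ids]
    ctrl_sub = genotypes.dosage[ctrl_ids]
    rows = []
    for snp in genotypes.snp_ids:
        x = code_genotype(sub.loc[snp].to_numpy(dtype=float), model)
        fit = fit_logistic(x, y, covariates=cov)
        rows.append({
            "snp_id": snp, "model": model, "comparison": comparison,
            "f_case": float(np.nansum(case_sub.loc[snp]) /
                            (2 * case_sub.loc[snp].notna().sum())),
            "f_control": float(np.nansum(ctrl_sub.loc[snp]) /
                               (2 * ctrl_sub.loc[snp].notna().sum())),
            "odds_ratio": fit.odds_ratio, "ci_low": fit.ci_low,
            "ci_high": fit.ci_high, "p_raw": fit.p,
            "testable": fit.testable and not fit.separation,
            "separation": fit.separation,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multiple testing, concordance, age-at-onset
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def add_bh_column(table: pd.DataFrame, by: tuple[str, ...] = ("comparison", "model"),
                  p_col: str = "p_raw", out_col: str = "p_bh") -> pd.DataFrame:
    """BH within each comparison family (one family per comparison × model)."""
    table = table.copy()
    table[out_col] = np.nan
    for _, idx in table.groupby(list(by)).groups.items():
        table.loc[idx, out_col] = bh_adjust(table.loc[idx, p_col])
    return table


def validate_concordance(
    pooled: pd.DataFrame,
    individual: pd.DataFrame,
    p_eligible: float = 0.01,
) -> pd.DataFrame:
    """Label each candidate SNP by pooled-vs-individual agreement.

    ``pooled`` needs snp_id + pooled_or (OR derived from group mean
    RAS); ``individual`` needs snp_id, odds_ratio, p_raw.  Labels:
    confirmed (same OR direction and p_raw < p_eligible),
    discordant-direction (p significant, direction flipped),
    not-significant.
    """
    merged = individual.merge(pooled[["snp_id", "pooled_or"]], on="snp_id", how="inner")
    labels = []
    for _, row in merged.iterrows():
        if not (row["p_raw"] < p_eligible):
            labels.append("not-significant")
        elif np.sign(np.log(row["odds_ratio"])) == np.sign(np.log(row["pooled_or"])):
            labels.append("confirmed")
        else:
            labels.append("discordant-direction")
    merged["concordance"] = labels
    return merged


def age_onset_scan(
    genotypes: GenotypeMatrix,
    config: AgeOnsetConfig = AgeOnsetConfig(),
    case_group: str = CASE,
) -> pd.DataFrame:
    """Case-only logistic scan for age-at-diagnosis effects.

    Outcome = ``young_code`` (default 1) when age at diagnosis ≤
    cutoff_years, else ``old_code``; each SNP is fitted under every
    configured genetic model and BH is applied across the whole scan.
    """
    cases = genotypes.group_samples(case_group)
    if not cases:
        raise ValueError("no case samples available")
    ages = genotypes.samples.loc[cases, "age"].to_numpy(dtype=float)
    if not (ages.min() <= config.cutoff_years <= ages.max()):
        raise ValueError("age cutoff lies outside the observed age range")
    young = ages <= config.cutoff_years
    if young.all() or (~young).all():
        raise ValueError("all cases fall on one side of the age cutoff")
    y = np.where(young, config.young_code, config.old_code).astype(float)

    sub = genotypes.dosage[cases]
    rows = []
    for snp in genotypes.snp_ids:
        d = sub.loc[snp].to_numpy(dtype=float)
        for model in config.models:
            fit = fit_logistic(code_genotype(d, model), y)
            rows.append({
                "snp_id": snp, "model": model, "comparison": "young vs old cases",
                "odds_ratio": fit.odds_ratio, "ci_low": fit.ci_low,
                "ci_high": fit.ci_high, "p_raw": fit.p,
                "testable": fit.testable and not fit.separation,
            })
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p_raw"])
    return out


def pick_tagging_snp(genotypes: GenotypeMatrix, ld_set,
                     control_group: str = CONTROL) -> str:
    """Among a user-declared LD set, pick the tagging SNP with the
    lowest missingness; ties broken by the largest control HWE p."""
    ld_set = [s for s in ld_set if s in set(genotypes.snp_ids)]
    if not ld_set:
        raise ValueError("no SNPs of the LD set present in the matrix")
    miss = genotypes.missingness_per_snp().loc[ld_set]
    controls = genotypes.group_samples(control_group)
    hwe = {s: hwe_exact_p_dosage(genotypes.dosage.loc[s, controls].to_numpy())
           for s in ld_set}
    return min(ld_set, key=lambda s: (miss[s], -hwe[s], s))
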