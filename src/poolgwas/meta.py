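"""Heterogeneity statistics and DerSimonian-Laird random-effects pooling.

Study effects enter as log odds ratios with standard errors.  Cochran's
Q is the inverse-variance weighted sum of squared deviations from the
fixed-effect mean; I² = max(0, (Q − (k−1))/Q) × 100.  The DL moment
estimator gives the between-study variance τ², the pooled log OR is the
τ²-reweighted mean, and its significance is a two-sided Z test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class StudyEffect:
    study_id: str
    log_or: float
    se_log_or: float
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if not self.se_log_or > 0:
            raise ValueError(f"{self.study_id}: se_log_or must be positive")


@dataclass
class MetaResult:
    k: int
    q: float
    q_p: float
    i2: float          # percent
    tau2: float
    pooled_or: float
    ci_low: float
    ci_high: float
    z_p: float


def se_from_ci(ci_low: float, ci_high: float, level_z: float = 1.96) -> float:
    """Recover the SE of a log OR from its reported CI bounds."""
    if not 0 < ci_low <= ci_high:
        raise ValueError("CI bounds must be positive with ci_low <= ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * level_z)


def heterogeneity(effects: list[StudyEffect]) -> tuple[float, float, float]:
    """Cochran's Q, its χ²(k−1) p-value, and I² (percent).

    A single study is degenerate: Q = 0, I² = 0, p = 1 (warned).
    """
    k = len(effects)
    if k < 1:
        raise ValueError("at least one study required")
    if k == 1:
        warnings.warn("heterogeneity undefined for a single study")
        return 0.0, 1.0, 0.0
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se_log_or ** 2 for e in effects])
    fixed = float((w * theta).sum() / w.sum())
    q = float((w * (theta - fixed) ** 2).sum())
    q_p = float(stats.chi2.sf(q, df=k - 1))
    i2 = 0.0 if q == 0 else max(0.0, (q - (k - 1)) / q) * 100.0
    return q, q_p, i2


def dl_random_effects(effects: list[StudyEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled OR with 95% CI and Z test.

    τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)); study weights are then
    1/(se² + τ²).  With one study the result reduces to that study.
    """
    k = len(effects)
    if k < 1:
        raise ValueError("at least one study required")
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se_log_or ** 2 for e in effects])

    if k == 1:
        q, q_p, i2, tau2 = 0.0, 1.0, 0.0, 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q, q_p, i2 = heterogeneity(effects)
        denom = w.sum() - (w ** 2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (np.array([e.se_log_or ** 2 for e in effects]) + tau2)
    pooled = float((w_star * theta).sum() / w_star.sum())
    se = float(1.0 / math.sqrt(w_star.sum()))
    z_p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    return MetaResult(
        k=k, q=q, q_p=q_p, i2=i2, tau2=tau2,
        pooled_or=math.exp(pooled),
        ci_low=math.exp(pooled - 1.96 * se),
        ci_high=math.exp(pooled + 1.96 * se),
        z_p=z_p,
    )
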