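"""Analytic power for the case/control allelic comparison.

Two-proportion normal-approximation power (Casagrande/Fleiss lineage,
as in Dupont-style sample-size software): the case frequency implied by
the odds ratio is p1 = OR·p0/(1 + p0·(OR − 1)) and

    power = Φ( (|p1 − p0| − z_{α/2}·SE0) / SE1 )

with SE0 the null (pooled) and SE1 the alternative standard error.
``counting="subjects"`` treats the allele frequency as a per-subject
proportion (n = number of individuals); ``"alleles"`` doubles the
denominators (n = number of chromosomes) and gives uniformly higher
power.  The subjects convention with two-sided α and no continuity
correction is the package default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerSpec:
    p0: float
    odds_ratio: float
    n_case: int
    n_control: int
    alpha: float = 1e-3
    counting: str = "subjects"
    continuity_correction: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 0.5:
            raise ValueError("p0 must lie in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.counting not in ("subjects", "alleles"):
            raise ValueError("counting must be 'subjects' or 'alleles'")
        if min(self.n_case, self.n_control) < 1:
            raise ValueError("group sizes must be >= 1")
        p1 = self.p1
        if not 0 < p1 < 1:
            raise ValueError("implied case frequency out of (0, 1)")

    @property
    def p1(self) -> float:
        return self.odds_ratio * self.p0 / (1.0 + self.p0 * (self.odds_ratio - 1.0))


def allelic_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-proportion test at ``spec.alpha``."""
    mult = 2 if spec.counting == "alleles" else 1
    n1 = mult * spec.n_case
    n2 = mult * spec.n_control
    p0, p1 = spec.p0, spec.p1
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
    se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    se1 = np.sqrt(p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n2)
    delta = abs(p1 - p0)
    if spec.continuity_correction:
        delta = max(0.0, delta - (1.0 / n1 + 1.0 / n2) / 2.0)
    # both rejection tails: the far tail is negligible at any real effect
    # size but makes the null case exact (power -> alpha as OR -> 1)
    return float(stats.norm.cdf((delta - z * se0) / se1)
                 + stats.norm.cdf((-delta - z * se0) / se1))


def power_grid(template: PowerSpec, p0_grid, or_grid) -> pd.DataFrame:
    """Evaluate :func:`allelic_power` on a grid of (p0, odds ratio)."""
    rows = []
    for p0, orr in product(p0_grid, or_grid):
        spec = PowerSpec(p0=float(p0), odds_ratio=float(orr),
                         n_case=template.n_case, n_control=template.n_control,
                         alpha=template.alpha, counting=template.counting,
                         continuity_correction=template.continuity_correction)
        rows.append({"p0": float(p0), "odds_ratio": float(orr),
                     "power": allelic_power(spec)})
    return pd.DataFrame(rows, columns=["p0", "odds_ratio", "power"])
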