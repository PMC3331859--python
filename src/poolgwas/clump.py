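"""LD-proxy candidate selection (greedy clumping).

A candidate locus is kept only when a significant index SNP is
corroborated by at least one correlated proxy SNP nearby: index
p < p_index in *both* pooled tests (the conservative reading of
"combined"; a flag allows χ²-only indices), proxy p_chi2 < p_proxy,
r² > r2_min (strict) and index–proxy distance ≤ window_bp.  Indices
are processed greedily in ascending p_chi2, and each SNP may appear in
at most one clump, mirroring PLINK-style clumping semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


@dataclass
class ClumpConfig:
    p_index: float = 1e-3
    p_proxy: float = 1e-3
    r2_min: float = 0.7          # strict: proxies need r2 > r2_min
    window_bp: int = 100_000
    index_rule: str = "both"     # "both" = t AND chi2; "chi2" = chi2 only

    def __post_init__(self) -> None:
        if not (0 < self.p_index < 1 and 0 < self.p_proxy < 1):
            raise ValueError("p thresholds must be in (0, 1)")
        if not 0 <= self.r2_min < 1:
            raise ValueError("r2_min must be in [0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.index_rule not in ("both", "chi2"):
            raise ValueError("index_rule must be 'both' or 'chi2'")


@dataclass
class Clump:
    index_snp: str
    index_p_ttest: float
    index_p_chi2: float
    proxies: list[tuple[str, float, int]] = field(default_factory=list)
    # proxies: (snp_id, r2, distance bp)


def dosage_r2(x, y, min_pairs: int = 10) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples (composite LD on unphased
    genotypes).  Monomorphic vectors and vectors with fewer than
    ``min_pairs`` complete pairs yield 0 (with a warning for the
    latter).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < min_pairs:
        warnings.warn(f"fewer than {min_pairs} complete pairs: r2 undefined, using 0")
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def clump_select(
    pooled: pd.DataFrame,
    snp_map: pd.DataFrame,
    reference: GenotypeMatrix,
    config: ClumpConfig = ClumpConfig(),
) -> list[Clump]:
    """Greedy one-assignment clumping of pooled association results.

    ``pooled`` must carry snp_id / p_ttest / p_chi2 / testable;
    ``snp_map`` must carry snp_id / chrom / pos.  ``reference``
    provides the genotypes used for r².  Ties among candidate indices
    are broken by ascending position, then lexicographic snp id.
    """
    info = snp_map.set_index("snp_id")
    ref_ids = set(reference.snp_ids)
    ref = reference.dosage

    tab = pooled[pooled["testable"].astype(bool)].copy()
    in_ref = tab["snp_id"].isin(ref_ids)
    n_absent = int((~in_ref).sum())
    if n_absent:
        warnings.warn(f"{n_absent} SNPs absent from the LD reference; ignored")
    tab = tab[in_ref]
    tab = tab.drop(columns=[c for c in ("chrom", "pos") if c in tab.columns])
    tab = tab.join(info[["chrom", "pos"]], on="snp_id")

    if config.index_rule == "both":
        is_index = (tab["p_ttest"] < config.p_index) & (tab["p_chi2"] < config.p_index)
    else:
        is_index = tab["p_chi2"] < config.p_index
    candidates = tab[is_index].sort_values(
        ["p_chi2", "pos", "snp_id"], kind="mergesort")

    p_chi2 = tab.set_index("snp_id")["p_chi2"]
    claimed: set[str] = set()
    clumps: list[Clump] = []
    for _, row in candidates.iterrows():
        idx = row["snp_id"]
        if idx in claimed:
            continue
        near = tab[(tab["chrom"] == row["chrom"])
                   & ((tab["pos"] - row["pos"]).abs() <= config.window_bp)
                   & (tab["snp_id"] != idx)]
        idx_vec = ref.loc[idx].to_numpy(dtype=float)
        proxies = []
        for _, prow in near.iterrows():
            pid = prow["snp_id"]
            if pid in claimed:
                continue
            if not p_chi2[pid] < config.p_proxy:
                continue
            r2 = dosage_r2(idx_vec, ref.loc[pid].to_numpy(dtype=float))
            if r2 > config.r2_min:
                proxies.append((pid, r2, int(abs(prow["pos"] - row["pos"]))))
        if proxies:
            clumps.append(Clump(index_snp=idx,
                                index_p_ttest=float(row["p_ttest"]),
                                index_p_chi2=float(row["p_chi2"]),
                                proxies=proxies))
            claimed.add(idx)
            claimed.update(p for p, _, _ in proxies)
    return clumps


def clump_report(clumps: list[Clump], snp_map: pd.DataFrame) -> pd.DataFrame:
    """Flatten clumps into the report table written to disk."""
    info = snp_map.set_index("snp_id")
    rows = []
    for c in clumps:
        best = max(c.proxies, key=lambda t: t[1])
        rows.append({
            "index_snp": c.index_snp,
            "chrom": info.loc[c.index_snp, "chrom"],
            "pos": int(info.loc[c.index_snp, "pos"]),
            "index_p_ttest": c.index_p_ttest,
            "index_p_chi2": c.index_p_chi2,
            "n_proxies": len(c.proxies),
            "best_proxy_id": best[0],
            "best_r2": best[1],
        })
    return pd.DataFrame(rows, columns=["index_snp", "chrom", "pos", "index_p_ttest",
                                       "index_p_chi2", "n_proxies", "best_proxy_id",
                                       "best_r2"])
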