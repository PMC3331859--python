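"""In-memory containers shared by all pipeline stages.

Conventions used throughout the package:

* genotypes are *minor-allele dosages* — 0, 1 or 2 copies of the minor
  allele, ``NaN`` for a missing call — stored SNP × sample;
* the two array channels are named A and B, with channel A carrying the
  minor allele, so RAS = A/(A+B) estimates the minor-allele frequency;
* genomic coordinates are 1-based and fully closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with its sample annotations.

    Parameters
    ----------
    dosage : DataFrame, shape (n_snps, n_samples)
        Index = SNP id, columns = sample id, values in {0, 1, 2, NaN}.
    samples : DataFrame indexed by sample id
        Must carry a ``group`` column; ``sex``, ``age`` and ``cohort``
        are optional annotations.
    """

    dosage: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.samples.columns:
            raise ValueError("samples table must have a 'group' column")
        missing = [s for s in self.dosage.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples missing from manifest: {missing[:5]}")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.columns

    def group_samples(self, group: str) -> list[str]:
        members = self.samples.index[self.samples["group"] == group]
        return [s for s in self.dosage.columns if s in set(members)]

    def subset(self, snps=None, samples=None) -> "GenotypeMatrix":
        d = self.dosage
        if snps is not None:
            d = d.loc[list(snps)]
        if samples is not None:
            d = d[list(samples)]
        return GenotypeMatrix(d.copy(), self.samples.loc[d.columns].copy())

    def allele_frequency(self, group: str | None = None) -> pd.Series:
        """Observed minor-allele frequency per SNP (optionally one group)."""
        d = self.dosage
        if group is not None:
            d = d[self.group_samples(group)]
        return d.sum(axis=1, skipna=True) / (2.0 * d.notna().sum(axis=1))

    def missingness_per_snp(self) -> pd.Series:
        return self.dosage.isna().mean(axis=1)

    def missingness_per_sample(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0)


@dataclass
class Panel:
    """A simulated SNP map plus its LD reference panel.

    ``snps`` columns: snp_id, chrom, pos, allele_A, allele_B,
    control_maf, allelic_or, ld_block.  ``copy_prob`` is the latent
    haplotype-copying probability between adjacent SNPs of a block
    (r² between adjacent block SNPs equals ``copy_prob ** 2``).
    ``reference`` holds genotypes of an independent panel of subjects
    drawn at the control frequencies, used for LD (r²) lookups.
    """

    snps: pd.DataFrame
    copy_prob: float
    reference: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos", "allele_A", "allele_B",
                    "control_maf", "allelic_or", "ld_block"}
        if not required.issubset(self.snps.columns):
            raise ValueError(f"panel table missing columns {required - set(self.snps.columns)}")
        for chrom, sub in self.snps.groupby("chrom"):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"positions must strictly increase within chromosome {chrom}")

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(self.snps["snp_id"])


@dataclass
class PoolDesign:
    """Assignment of samples to phenotype-homogeneous pools.

    ``pools`` columns: pool_id, group, members (list of sample ids).
    ``unpooled`` lists leftover samples that did not fill a pool.
    """

    pools: pd.DataFrame
    pool_size: int
    unpooled: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        all_members = [s for m in self.pools["members"] for s in m]
        if len(all_members) != len(set(all_members)):
            raise ValueError("a sample may belong to at most one pool")

    @property
    def pool_ids(self) -> list[str]:
        return list(self.pools["pool_id"])

    @property
    def pool_groups(self) -> pd.Series:
        return pd.Series(self.pools["group"].to_numpy(), index=self.pools["pool_id"].to_numpy())

    def members(self, pool_id: str) -> list[str]:
        row = self.pools.loc[self.pools["pool_id"] == pool_id]
        if row.empty:
            raise KeyError(pool_id)
        return list(row["members"].iloc[0])


@dataclass
class RASMatrix:
    """Pool × SNP relative allele signal matrix.

    ``values``: DataFrame indexed by pool id, columns SNP ids, entries
    the replicate-averaged RAS in [0, 1] (NaN = missing).
    """

    values: pd.DataFrame
    pool_groups: pd.Series
    n_subjects_per_pool: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        bad = (v < 0) | (v > 1)
        if np.nansum(bad):
            raise ValueError("RAS values must lie in [0, 1]")
        missing = [p for p in self.values.index if p not in self.pool_groups.index]
        if missing:
            raise ValueError(f"pools without a group label: {missing[:5]}")

    def group_values(self, group: str) -> pd.DataFrame:
        pools = [p for p in self.values.index if self.pool_groups[p] == group]
        return self.values.loc[pools]

    def subset_pools(self, pool_ids) -> "RASMatrix":
        keep = [p for p in self.values.index if p in set(pool_ids)]
        return RASMatrix(self.values.loc[keep].copy(),
                         self.pool_groups, self.n_subjects_per_pool)
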