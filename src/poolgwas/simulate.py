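"""Synthetic cohorts, DNA pools and pooled-array intensities.

The generator reproduces the statistical structure a pooled-DNA GWAS
relies on:

* control genotypes at stated minor-allele frequencies under HWE,
  case genotypes at the frequency implied by a stated allelic odds
  ratio, F1 = OR·F2 / (1 + F2·(OR − 1));
* blockwise LD via latent-uniform haplotype copying, so high-r² proxy
  SNPs exist for clump-based candidate selection;
* equimolar pools of (default) 15 samples measured in (default) 3
  technical replicates with multiplicative channel noise, with
  optional aberrant (outlier) pools shifted on the frequency scale;
* degraded individual genotype tables (missingness, call errors,
  injected HWE violations) so downstream QC filters have work to do.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical inputs give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CASE, CONTROL, GenotypeMatrix, Panel, PoolDesign


@dataclass
class SNPSpec:
    """One simulated biallelic SNP (allele A = minor allele)."""

    snp_id: str
    chrom: str
    pos: int
    control_maf: float
    allelic_or: float = 1.0
    ld_block: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.control_maf <= 0.5:
            raise ValueError(f"{self.snp_id}: control_maf must be in (0, 0.5]")
        if self.allelic_or <= 0:
            raise ValueError(f"{self.snp_id}: allelic_or must be positive")


@dataclass
class CohortSpec:
    """Case/control cohort and pooling design parameters."""

    n_cases: int
    n_controls: int
    pool_size: int = 15
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1 or self.n_replicates < 1:
            raise ValueError("pool_size and n_replicates must be >= 1")
        if min(self.n_cases, self.n_controls) < self.pool_size:
            raise ValueError("each group needs at least pool_size samples")


@dataclass
class IntensityModel:
    """Two-channel array intensity model for a pooled hybridization.

    Channel A has expectation gain·f + background and channel B
    gain·(1−f) + background, where f is the pool minor-allele
    frequency; both channels carry independent multiplicative
    log-normal noise with coefficient of variation ``noise_cv``.
    ``pooling_concentration`` is the Dirichlet concentration governing
    unequal sample contributions (``inf`` = exactly equimolar).
    """

    gain: float = 1000.0
    noise_cv: float = 0.05
    background: float = 0.0
    outlier_shift: float = 0.1
    pooling_concentration: float = math.inf

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_cv < 0 or self.background < 0:
            raise ValueError("noise_cv and background must be >= 0")


def case_frequency(control_maf: float, odds_ratio: float) -> float:
    """Case minor-allele frequency implied by an allelic odds ratio."""
    f2 = control_maf
    return odds_ratio * f2 / (1.0 + f2 * (odds_ratio - 1.0))


# ---------------------------------------------------------------------------
# SNP panel and LD reference
# ---------------------------------------------------------------------------

def generate_panel(
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_length: int = 4,
    within_block_r2: float = 0.8,
    spacing: int = 25_000,
    seed: int = 0,
    chrom: str = "1",
    n_reference: int = 200,
) -> Panel:
    """Lay out ``n_snps`` SNPs in fixed-length LD blocks at fixed spacing.

    Every SNP of a block shares one control MAF drawn uniformly from
    ``maf_range``; adjacent SNPs of a block then have population r²
    equal to ``within_block_r2`` exactly under the latent-uniform
    copying mechanism (copy probability = sqrt(r²)).  Blocks are
    mutually independent.  An LD reference of ``n_reference`` control
    subjects is simulated alongside for r² lookups.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5) or (lo == hi and lo == 0):
        raise ValueError("maf_range must be a non-degenerate subset of (0, 0.5]")
    if not 0 <= within_block_r2 <= 1:
        raise ValueError("within_block_r2 must be in [0, 1]")
    if block_length < 1 or spacing <= 0:
        raise ValueError("block_length >= 1 and spacing > 0 required")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_blocks = -(-n_snps // block_length)
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    blocks = np.repeat(np.arange(n_blocks), block_length)[:n_snps]
    rows = []
    for i in range(n_snps):
        rows.append({
            "snp_id": f"snp{i:05d}",
            "chrom": chrom,
            "pos": (i + 1) * spacing,
            "allele_A": "A",
            "allele_B": "B",
            "control_maf": float(block_maf[blocks[i]]),
            "allelic_or": 1.0,
            "ld_block": int(blocks[i]),
        })
    snps = pd.DataFrame(rows)
    panel = Panel(snps=snps, copy_prob=math.sqrt(within_block_r2))

    ref_rng = np.random.default_rng(np.random.SeedSequence([seed, 7151]))
    dosage = _sample_dosages(panel, snps["control_maf"].to_numpy(), n_reference, ref_rng)
    ref_ids = [f"ref{i:04d}" for i in range(n_reference)]
    ref_samples = pd.DataFrame({"group": "reference"}, index=pd.Index(ref_ids, name="sample_id"))
    panel.reference = GenotypeMatrix(
        pd.DataFrame(dosage, index=snps["snp_id"].to_numpy(), columns=ref_ids, dtype=float),
        ref_samples,
    )
    return panel


def plant_effects(panel: Panel, block_ids, allelic_or: float) -> Panel:
    """Assign ``allelic_or`` to every SNP of the given LD blocks (in place)."""
    if allelic_or <= 0:
        raise ValueError("allelic_or must be positive")
    mask = panel.snps["ld_block"].isin(set(block_ids))
    panel.snps.loc[mask, "allelic_or"] = float(allelic_or)
    return panel


def _sample_haplotypes(panel: Panel, freq: np.ndarray, n_hap: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw haplotypes with per-SNP marginal frequency ``freq`` and
    within-block LD from latent-uniform copying.

    A latent uniform is carried along each block; at each SNP it is
    kept with probability ``copy_prob`` or redrawn, and the allele is
    the indicator (latent < freq).  When consecutive SNPs share a
    frequency the allele correlation equals copy_prob, hence r² =
    copy_prob².
    """
    n_snps = len(freq)
    blocks = panel.snps["ld_block"].to_numpy()
    u = np.empty((n_hap, n_snps))
    fresh = rng.uniform(size=(n_hap, n_snps))
    keep = rng.uniform(size=(n_hap, n_snps)) < panel.copy_prob
    u[:, 0] = fresh[:, 0]
    for j in range(1, n_snps):
        if blocks[j] != blocks[j - 1]:
            u[:, j] = fresh[:, j]
        else:
            u[:, j] = np.where(keep[:, j], u[:, j - 1], fresh[:, j])
    return (u < freq[None, :]).astype(np.int8)


def _sample_dosages(panel: Panel, freq: np.ndarray, n_ind: int,
                    rng: np.random.Generator) -> np.ndarray:
    h1 = _sample_haplotypes(panel, freq, n_ind, rng)
    h2 = _sample_haplotypes(panel, freq, n_ind, rng)
    return (h1 + h2).T.astype(float)  # SNP x sample


def simulate_genotypes(panel: Panel, cohort: CohortSpec) -> GenotypeMatrix:
    """Simulate HWE genotypes for a case/control cohort.

    Controls are drawn at ``control_maf``; cases at the frequency
    implied by each SNP's ``allelic_or``.  Each genotype is
    Binomial(2, f) marginally; LD within blocks is preserved through
    haplotype sampling.  Sex is drawn 50/50 and age uniformly on
    [40, 80] (cases) / [35, 80] (controls) as neutral annotations.
    """
    if panel.snps.empty:
        raise ValueError("panel must be non-empty")
    ss = np.random.SeedSequence([cohort.seed, 11])
    rng_case, rng_ctrl, rng_meta = [np.random.default_rng(s) for s in ss.spawn(3)]

    f2 = panel.snps["control_maf"].to_numpy()
    f1 = np.array([case_frequency(f, orr) for f, orr in
                   zip(f2, panel.snps["allelic_or"].to_numpy())])

    case_d = _sample_dosages(panel, f1, cohort.n_cases, rng_case)
    ctrl_d = _sample_dosages(panel, f2, cohort.n_controls, rng_ctrl)

    case_ids = [f"case{i:05d}" for i in range(cohort.n_cases)]
    ctrl_ids = [f"ctrl{i:05d}" for i in range(cohort.n_controls)]
    dosage = pd.DataFrame(
        np.hstack([case_d, ctrl_d]),
        index=panel.snps["snp_id"].to_numpy(),
        columns=case_ids + ctrl_ids,
        dtype=float,
    )
    n = cohort.n_cases + cohort.n_controls
    samples = pd.DataFrame(
        {
            "group": [CASE] * cohort.n_cases + [CONTROL] * cohort.n_controls,
            "sex": rng_meta.choice(["F", "M"], size=n),
            "age": np.concatenate([
                rng_meta.integers(40, 81, size=cohort.n_cases),
                rng_meta.integers(35, 81, size=cohort.n_controls),
            ]),
            "cohort": "sim",
        },
        index=pd.Index(case_ids + ctrl_ids, name="sample_id"),
    )
    return GenotypeMatrix(dosage, samples)


def simulate_cohort(panel: Panel, cohort: CohortSpec) -> GenotypeMatrix:
    """Alias of :func:`simulate_genotypes` (cohort-level entry point)."""
    return simulate_genotypes(panel, cohort)


# ---------------------------------------------------------------------------
# Pool construction and array intensities
# ---------------------------------------------------------------------------

def build_pools(manifest: pd.DataFrame, cohort: CohortSpec) -> PoolDesign:
    """Partition samples into phenotype-homogeneous pools of ``pool_size``.

    Samples are taken in manifest order within each group; leftovers
    that cannot fill a pool are excluded and recorded in ``unpooled``.
    """
    if "group" not in manifest.columns:
        raise ValueError("manifest must carry a 'group' column")
    rows, unpooled = [], []
    for group, sub in manifest.groupby("group", sort=True):
        ids = list(sub.index)
        if len(ids) < cohort.pool_size:
            raise ValueError(f"group {group!r} has fewer samples than pool_size")
        n_pools = len(ids) // cohort.pool_size
        for k in range(n_pools):
            members = ids[k * cohort.pool_size:(k + 1) * cohort.pool_size]
            rows.append({"pool_id": f"{group}_p{k:03d}", "group": group,
                         "members": members})
        unpooled.extend(ids[n_pools * cohort.pool_size:])
    return PoolDesign(pools=pd.DataFrame(rows), pool_size=cohort.pool_size,
                      unpooled=unpooled)


def simulate_intensities(
    design: PoolDesign,
    genotypes: GenotypeMatrix,
    model: IntensityModel,
    n_replicates: int = 3,
    outlier_pools: set | frozenset = frozenset(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the two-channel intensity table for every (SNP, pool, replicate).

    The pool frequency is the equimolar mean of member allele
    frequencies (or a Dirichlet-weighted mean when
    ``pooling_concentration`` is finite).  Pools named in
    ``outlier_pools`` have their frequency shifted by
    ``model.outlier_shift`` (clamped to [0, 1]) before intensities are
    generated, emulating aberrant DNA quality / hybridization.
    """
    for pid in design.pool_ids:
        absent = [s for s in design.members(pid) if s not in genotypes.dosage.columns]
        if absent:
            raise ValueError(f"pool {pid} members missing from genotypes: {absent[:3]}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    snp_ids = genotypes.snp_ids
    n_snps = len(snp_ids)

    if model.noise_cv > 0:
        sigma = math.sqrt(math.log1p(model.noise_cv ** 2))
    else:
        sigma = 0.0

    records = []
    for pid in design.pool_ids:
        members = design.members(pid)
        d = genotypes.dosage[members].to_numpy(dtype=float)
        if math.isinf(model.pooling_concentration):
            f = np.nanmean(d, axis=1) / 2.0
        else:
            w = rng.dirichlet([model.pooling_concentration] * len(members))
            f = np.nansum(d * w[None, :], axis=1) / 2.0
        if pid in outlier_pools:
            f = np.clip(f + model.outlier_shift, 0.0, 1.0)
        for rep in range(1, n_replicates + 1):
            if sigma > 0:
                noise_a = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=n_snps)
                noise_b = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=n_snps)
            else:
                noise_a = noise_b = np.ones(n_snps)
            a = np.maximum(model.gain * f * noise_a + model.background, 0.0)
            b = np.maximum(model.gain * (1.0 - f) * noise_b + model.background, 0.0)
            records.append(pd.DataFrame({
                "snp_id": snp_ids, "pool_id": pid, "replicate": rep,
                "intensity_A": a, "intensity_B": b,
            }))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Genotype degradation (missingness, call errors, HWE violations)
# ---------------------------------------------------------------------------

def degrade_genotypes(
    genotypes: GenotypeMatrix,
    snp_missing_rate: float = 0.0,
    ind_missing_rate: float = 0.0,
    error_rate: float = 0.0,
    hwe_violating_snps: set | frozenset = frozenset(),
    het_inflation: float = 1.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Return a copy with realistic genotyping defects injected.

    Entries go missing independently at ``snp_missing_rate`` (applied
    per cell, realising per-SNP missingness around the rate) plus
    ``ind_missing_rate`` (per cell, realising per-sample missingness).
    Genotyping errors flip the dosage by ±1 within {0, 1, 2}.  SNPs in
    ``hwe_violating_snps`` are redrawn with the heterozygote
    probability inflated ``het_inflation``-fold (homozygote classes
    rescaled), giving the HWE control filter true positives.
    """
    for r in (snp_missing_rate, ind_missing_rate, error_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    d = genotypes.dosage.to_numpy(dtype=float).copy()
    n_snps, n_samp = d.shape

    unknown = set(hwe_violating_snps) - set(genotypes.snp_ids)
    if unknown:
        raise ValueError(f"hwe_violating_snps not in matrix: {sorted(unknown)[:3]}")
    for snp in hwe_violating_snps:
        i = genotypes.snp_ids.get_loc(snp)
        obs = d[i][~np.isnan(d[i])]
        p = obs.sum() / (2.0 * len(obs)) if len(obs) else 0.0
        het = 2.0 * p * (1.0 - p)
        het_new = min(1.0, het_inflation * het)
        rest = 1.0 - het
        scale = (1.0 - het_new) / rest if rest > 0 else 0.0
        probs = np.array([(1 - p) ** 2 * scale, het_new, p ** 2 * scale])
        probs = probs / probs.sum()
        d[i] = rng.choice([0.0, 1.0, 2.0], size=n_samp, p=probs)

    if error_rate > 0:
        flip = rng.uniform(size=d.shape) < error_rate
        direction = rng.choice([-1.0, 1.0], size=d.shape)
        with np.errstate(invalid="ignore"):
            flipped = d + direction
            # at the boundary the only legal move is inward
            flipped = np.where(flipped < 0, 1.0, flipped)
            flipped = np.where(flipped > 2, 1.0, flipped)
            d = np.where(flip & ~np.isnan(d), flipped, d)

    if snp_missing_rate > 0:
        d[rng.uniform(size=d.shape) < snp_missing_rate] = np.nan
    if ind_missing_rate > 0:
        d[rng.uniform(size=d.shape) < ind_missing_rate] = np.nan

    out = pd.DataFrame(d, index=genotypes.dosage.index,
                       columns=genotypes.dosage.columns, dtype=float)
    return GenotypeMatrix(out, genotypes.samples.copy())
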