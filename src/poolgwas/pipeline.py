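"""End-to-end orchestration: simulate → allelotype → select → validate →
replicate → meta, with a reproducible run manifest.

The run mirrors the funnel of a pooled-DNA GWAS: pooled association on
simulated array intensities, clump-based candidate selection against
the LD reference, technical validation of candidates by individual
genotyping of the same cohort (with QC and concordance calls), logistic
replication in an independent cohort with BH correction, and a per-SNP
two-study heterogeneity / random-effects summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .allelotype import average_replicates, compute_ras, pca_pool_filter, pooled_association
from .assoc import (
    QCConfig,
    add_bh_column,
    allelic_assoc,
    logistic_assoc,
    odds_ratio_from_freq,
    qc_filter,
    validate_concordance,
)
from .clump import ClumpConfig, clump_report, clump_select
from .containers import CASE, CONTROL
from .meta import StudyEffect, dl_random_effects, se_from_ci
from .simulate import (
    CohortSpec,
    IntensityModel,
    build_pools,
    degrade_genotypes,
    generate_panel,
    plant_effects,
    simulate_genotypes,
    simulate_intensities,
)

log = logging.getLogger("poolgwas")

_DEFAULTS: dict = {
    "seed": 1,
    "panel": {"n_snps": 2000, "maf_range": [0.2, 0.5], "block_length": 4,
              "within_block_r2": 0.9, "spacing": 25_000, "n_reference": 200},
    "effects": {"n_blocks": 10, "allelic_or": 2.0},
    "gwas": {"n_cases": 630, "n_controls": 690, "pool_size": 15,
             "n_replicates": 3, "noise_cv": 0.05, "gain": 1000.0,
             "n_outlier_pools": 1, "outlier_shift": 0.1},
    "replication": {"n_cases": 890, "n_controls": 2190},
    "degradation": {"snp_missing_rate": 0.01, "ind_missing_rate": 0.005,
                    "error_rate": 0.001, "n_hwe_violating": 5},
    "thresholds": {"z_threshold": 3.5, "p_index": 1e-3, "p_proxy": 1e-3,
                   "r2_min": 0.7, "window_bp": 100_000, "p_eligible": 0.01,
                   "max_snp_missing": 0.05, "max_ind_missing": 0.05,
                   "hwe_p_min": 1e-3, "bh_alpha": 0.05},
}

_RANGES = {
    ("thresholds", "p_index"): (0.0, 1.0),
    ("thresholds", "p_proxy"): (0.0, 1.0),
    ("thresholds", "p_eligible"): (0.0, 1.0),
    ("thresholds", "max_snp_missing"): (0.0, 1.0),
    ("thresholds", "max_ind_missing"): (0.0, 1.0),
    ("thresholds", "hwe_p_min"): (0.0, 1.0),
    ("thresholds", "bh_alpha"): (0.0, 1.0),
}


class RunConfig(dict):
    """Validated configuration for :func:`run_pipeline`.

    Built from nested dicts / YAML; unknown keys are rejected and every
    threshold is checked against its documented range.
    """

    @classmethod
    def from_dict(cls, user: dict | None = None) -> "RunConfig":
        user = user or {}
        cfg = {}
        unknown = set(user) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, defaults in _DEFAULTS.items():
            if isinstance(defaults, dict):
                sub = dict(defaults)
                extra = set(user.get(section, {})) - set(defaults)
                if extra:
                    raise ValueError(f"unknown keys in {section!r}: {sorted(extra)}")
                sub.update(user.get(section, {}))
                cfg[section] = sub
            else:
                cfg[section] = user.get(section, defaults)
        for (section, key), (lo, hi) in _RANGES.items():
            v = cfg[section][key]
            if not lo < v < hi:
                raise ValueError(f"{section}.{key}={v} outside ({lo}, {hi})")
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | dict, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the run manifest (also written
    to ``out_dir/manifest.json`` along with every stage's TSV)."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    if seed is not None:
        config = RunConfig.from_dict({**{k: v for k, v in config.items()}, "seed": seed})
    out = pio.ensure_dir(out_dir)
    seed = int(config["seed"])
    child = np.random.SeedSequence(seed).generate_state(8) % (2 ** 31)
    counts: dict = {}
    thr = config["thresholds"]

    # --- stage 1: panel + planted effects ----------------------------------
    pan_cfg = config["panel"]
    panel = generate_panel(
        n_snps=pan_cfg["n_snps"], maf_range=tuple(pan_cfg["maf_range"]),
        block_length=pan_cfg["block_length"],
        within_block_r2=pan_cfg["within_block_r2"],
        spacing=pan_cfg["spacing"], seed=int(child[0]),
        n_reference=pan_cfg["n_reference"],
    )
    eff = config["effects"]
    rng = np.random.default_rng(int(child[1]))
    blocks = sorted(panel.snps["ld_block"].unique())
    effect_blocks = sorted(rng.choice(blocks, size=eff["n_blocks"], replace=False).tolist())
    plant_effects(panel, effect_blocks, eff["allelic_or"])
    pio.write_snp_map(panel, out / "snp_map.tsv")
    counts["snps_simulated"] = len(panel.snps)
    counts["effect_blocks"] = effect_blocks
    log.info("panel: %d SNPs, effect blocks %s", len(panel.snps), effect_blocks)

    # --- stage 2: GWAS cohort, pools, intensities ---------------------------
    g = config["gwas"]
    gwas_cohort = CohortSpec(n_cases=g["n_cases"], n_controls=g["n_controls"],
                             pool_size=g["pool_size"], n_replicates=g["n_replicates"],
                             seed=int(child[2]))
    gwas_geno = simulate_genotypes(panel, gwas_cohort)
    pio.write_manifest(gwas_geno.samples, out / "gwas_manifest.tsv")
    design = build_pools(gwas_geno.samples, gwas_cohort)
    pio.write_pool_design(design, out / "pool_design.tsv")
    counts["pools"] = len(design.pools)
    counts["unpooled_samples"] = len(design.unpooled)

    model = IntensityModel(gain=g["gain"], noise_cv=g["noise_cv"],
                           outlier_shift=g["outlier_shift"])
    outliers = set(rng.choice(design.pool_ids, size=g["n_outlier_pools"],
                              replace=False).tolist()) if g["n_outlier_pools"] else set()
    intensities = simulate_intensities(design, gwas_geno, model,
                                       n_replicates=g["n_replicates"],
                                       outlier_pools=outliers, seed=int(child[3]))
    pio.write_intensities(intensities, out / "intensities.tsv")
    counts["outlier_pools_injected"] = sorted(outliers)

    # --- stage 3: allelotyping ----------------------------------------------
    ras_table, ras_qc = compute_ras(intensities)
    ras = average_replicates(ras_table, pool_groups=design.pool_groups,
                             n_subjects_per_pool=design.pool_size)
    kept, excluded, pcs = pca_pool_filter(ras, z_threshold=thr["z_threshold"])
    pcs.to_csv(out / "pool_pcs.tsv", sep="\t", index_label="pool_id")
    pd.DataFrame({"pool_id": excluded}).to_csv(out / "excluded_pools.tsv",
                                               sep="\t", index=False)
    pio.write_ras_matrix(kept, out / "ras_matrix.tsv")
    counts["ras_invalid_entries"] = ras_qc.n_invalid
    counts["pools_excluded_pca"] = excluded

    pooled = pooled_association(kept)
    pooled = pooled.merge(panel.snps[["snp_id", "chrom", "pos"]], on="snp_id")
    pio.write_table(pooled, out / "pooled_assoc.tsv", p_cols=("p_ttest", "p_chi2"))
    counts["snps_testable_pooled"] = int(pooled["testable"].sum())

    # --- stage 4: clump selection -------------------------------------------
    clump_cfg = ClumpConfig(p_index=thr["p_index"], p_proxy=thr["p_proxy"],
                            r2_min=thr["r2_min"], window_bp=thr["window_bp"])
    clumps = clump_select(pooled, panel.snps, panel.reference, clump_cfg)
    creport = clump_report(clumps, panel.snps)
    pio.write_table(creport, out / "clumps.tsv",
                    p_cols=("index_p_ttest", "index_p_chi2"))
    candidates = [c.index_snp for c in clumps]
    counts["gwas_candidates"] = len(candidates)
    log.info("clumping: %d candidate loci", len(candidates))

    deg = config["degradation"]
    qc_cfg = QCConfig(max_snp_missing=thr["max_snp_missing"],
                      max_ind_missing=thr["max_ind_missing"],
                      hwe_p_min=thr["hwe_p_min"])

    def _individual_stage(cohort_geno, stage_seed, prefix):
        null_snps = panel.snps.loc[panel.snps["allelic_or"] == 1.0, "snp_id"]
        hwe_bad = set(rng.choice(null_snps, size=min(deg["n_hwe_violating"],
                                                     len(null_snps)),
                                 replace=False).tolist())
        degraded = degrade_genotypes(
            cohort_geno, snp_missing_rate=deg["snp_missing_rate"],
            ind_missing_rate=deg["ind_missing_rate"],
            error_rate=deg["error_rate"], hwe_violating_snps=hwe_bad,
            seed=stage_seed)
        filtered, qc_rep = qc_filter(degraded, qc_cfg)
        pio.write_table(qc_rep, out / f"{prefix}_qc_report.tsv")
        n_in = len(degraded.snp_ids)
        n_dropped = (qc_rep["kind"] == "snp").sum()
        assert n_in == len(filtered.snp_ids) + n_dropped, "SNP count not conserved"
        return filtered, qc_rep, hwe_bad

    # --- stage 5: technical validation (same cohort, individual typing) -----
    val_geno, val_qc, hwe_injected = _individual_stage(gwas_geno, int(child[4]), "validation")
    counts["hwe_snps_injected"] = sorted(hwe_injected)
    counts["validation_snps_post_qc"] = len(val_geno.snp_ids)
    val_candidates = [s for s in candidates if s in set(val_geno.snp_ids)]
    counts["candidates_lost_to_qc"] = len(candidates) - len(val_candidates)

    val_assoc = allelic_assoc(val_geno.subset(snps=val_candidates),
                              comparison="validation")
    pooled_idx = pooled.set_index("snp_id")
    pooled_or = {}
    for s in val_candidates:
        f1 = pooled_idx.loc[s, "mean_ras_case"]
        f2 = pooled_idx.loc[s, "mean_ras_control"]
        pooled_or[s] = odds_ratio_from_freq(min(max(f1, 1e-6), 1 - 1e-6),
                                            min(max(f2, 1e-6), 1 - 1e-6))
    pooled_or_df = pd.DataFrame({"snp_id": list(pooled_or),
                                 "pooled_or": list(pooled_or.values())})
    concordance = validate_concordance(pooled_or_df, val_assoc,
                                       p_eligible=thr["p_eligible"])
    pio.write_table(concordance, out / "concordance.tsv", p_cols=("p_raw",))
    confirmed = list(concordance.loc[concordance["concordance"] == "confirmed",
                                     "snp_id"])
    counts["candidates_confirmed"] = len(confirmed)
    log.info("validation: %d/%d candidates confirmed", len(confirmed),
             len(val_candidates))

    # --- stage 6: replication (independent cohort, logistic additive) -------
    rep = config["replication"]
    rep_cohort = CohortSpec(n_cases=rep["n_cases"], n_controls=rep["n_controls"],
                            pool_size=g["pool_size"], seed=int(child[5]))
    rep_geno_full = simulate_genotypes(panel, rep_cohort)
    rep_geno, rep_qc, _ = _individual_stage(rep_geno_full, int(child[6]), "replication")
    rep_candidates = [s for s in confirmed if s in set(rep_geno.snp_ids)]
    rep_sub = rep_geno.subset(snps=rep_candidates) if rep_candidates else None

    if rep_sub is not None and rep_candidates:
        rep_add = logistic_assoc(rep_sub, model="additive", comparison="replication")
        rep_allelic = allelic_assoc(rep_sub, comparison="replication")
        rep_all = add_bh_column(pd.concat([rep_add, rep_allelic], ignore_index=True))
    else:
        rep_all = pd.DataFrame(columns=["snp_id", "model", "comparison", "f_case",
                                        "f_control", "odds_ratio", "ci_low",
                                        "ci_high", "p_raw", "testable", "p_bh"])
    pio.write_table(rep_all, out / "replication_assoc.tsv", p_cols=("p_raw", "p_bh"))
    sig = rep_all[(rep_all["model"] == "additive")
                  & (rep_all["p_bh"] < thr["bh_alpha"])]
    counts["replicated_bh_significant"] = len(sig)
    counts["replicated_snps"] = sorted(sig["snp_id"])
    log.info("replication: %d BH-significant hits", len(sig))

    # --- stage 7: per-SNP meta across validation + replication --------------
    meta_rows = []
    val_idx = val_assoc.set_index("snp_id")
    rep_idx = rep_all[rep_all["model"] == "allelic"].set_index("snp_id")
    for s in rep_candidates:
        effects = []
        for label, table in (("validation", val_idx), ("replication", rep_idx)):
            if s in table.index and table.loc[s, "testable"]:
                orr = float(table.loc[s, "odds_ratio"])
                se = se_from_ci(float(table.loc[s, "ci_low"]),
                                float(table.loc[s, "ci_high"]))
                effects.append(StudyEffect(label, math.log(orr), se))
        if len(effects) == 2:
            m = dl_random_effects(effects)
            meta_rows.append({"snp_id": s, "k": m.k, "pooled_or": m.pooled_or,
                              "ci_low": m.ci_low, "ci_high": m.ci_high,
                              "z_p": m.z_p, "q": m.q, "q_p": m.q_p,
                              "i2": round(m.i2, 1), "tau2": m.tau2})
    meta_df = pd.DataFrame(meta_rows, columns=["snp_id", "k", "pooled_or", "ci_low",
                                               "ci_high", "z_p", "q", "q_p", "i2",
                                               "tau2"])
    pio.write_table(meta_df, out / "meta.tsv", p_cols=("z_p", "q_p"))

    # --- manifest ------------------------------------------------------------
    from . import __version__

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "version": __version__,
        "counts": counts,
        "input_checksums": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.tsv"))
            if p.name in ("snp_map.tsv", "gwas_manifest.tsv", "pool_design.tsv",
                          "intensities.tsv")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return manifest
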