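"""Individual-genotype stage: HWE exact test, QC filters, allelic and
logistic association, BH, concordance and the age-at-onset scan."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from poolgwas import (
    AgeOnsetConfig,
    CohortSpec,
    QCConfig,
    age_onset_scan,
    allelic_assoc,
    bh_adjust,
    fit_logistic,
    generate_panel,
    hwe_exact_p,
    odds_ratio_from_freq,
    pick_tagging_snp,
    plant_effects,
    qc_filter,
    simulate_genotypes,
    validate_concordance,
)
from poolgwas.assoc import code_genotype, logistic_assoc

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# HWE exact test vs full enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Closed-form conditional probability of every heterozygote count,
    summed over outcomes no more probable than the observed one."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0

    def log_prob(h):
        hom_min = (n_minor - h) // 2
        hom_maj = n - hom_min - h
        return (gammaln(n + 1) - gammaln(hom_min + 1) - gammaln(hom_maj + 1)
                - gammaln(h + 1) + h * math.log(2)
                + gammaln(n_minor + 1) + gammaln(2 * n - n_minor + 1)
                - gammaln(2 * n + 1))

    hs = list(range(n_minor % 2, n_minor + 1, 2))
    probs = {h: math.exp(log_prob(h)) for h in hs}
    obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


class TestHWEExact:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (0, 20, 0), (57, 14, 50),
                                        (1, 0, 99), (10, 1, 0), (3, 4, 3)])
    def test_matches_enumeration(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-10)

    def test_all_het_outcomes_at_fixed_allele_counts(self):
        # every heterozygote outcome with 50 minor alleles in 50 samples
        for h in range(0, 51, 2):
            counts = ((50 - h) // 2, h, 50 - (50 - h) // 2 - h)
            n_aa, n_het = counts[0], counts[1]
            n_AA = 50 - n_aa - n_het
            assert hwe_exact_p(n_AA, n_het, n_aa) == pytest.approx(
                hwe_enumeration_oracle(n_AA, n_het, n_aa), abs=1e-10)

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(100, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 250) == 1.0

    def test_large_totals_stable(self):
        p = hwe_exact_p(49_000, 2_000, 49_000)  # far too few hets
        assert 0 <= p < 1e-10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

class TestQCFilter:
    def _matrix(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 3, size=(6, 100)).astype(float)
        groups = ["case"] * 50 + ["control"] * 50
        return make_genotypes(rows.tolist(), groups)

    def test_snp_missingness_threshold(self):
        g = self._matrix()
        g.dosage.iloc[0, :6] = np.nan  # 6% missing -> dropped
        g.dosage.iloc[1, :4] = np.nan  # 4% -> kept
        filtered, report = qc_filter(g)
        assert "m0" not in filtered.snp_ids and "m1" in filtered.snp_ids
        assert ((report["kind"] == "snp") & (report["id"] == "m0")).any()

    def test_individual_boundary_exactly_5pct_dropped(self):
        rng = np.random.default_rng(1)
        rows = rng.integers(0, 3, size=(20, 40)).astype(float)
        g = make_genotypes(rows.tolist(), ["case"] * 20 + ["control"] * 20)
        g.dosage.iloc[0, 0] = np.nan  # sample s0: 1/20 = 5% missing
        filtered, report = qc_filter(g)
        assert "s0" not in filtered.sample_ids

    def test_hwe_filter_in_controls(self):
        # all-heterozygote SNP in controls violates HWE grossly
        rng = np.random.default_rng(2)
        base = rng.binomial(2, 0.4, size=(3, 400)).astype(float)
        g = make_genotypes(base.tolist(), ["case"] * 200 + ["control"] * 200)
        g.dosage.iloc[0, 200:] = 1.0
        filtered, report = qc_filter(g)
        assert "m0" not in filtered.snp_ids
        assert (report["reason"] == "hwe").any()

    def test_no_controls_refused(self):
        g = make_genotypes([[0, 1, 2, 1]], ["case"] * 4)
        with pytest.raises(ValueError, match="control"):
            qc_filter(g)

    def test_idempotent(self):
        g = self._matrix()
        g.dosage.iloc[0, :10] = np.nan
        once, _ = qc_filter(g)
        twice, report2 = qc_filter(once)
        assert report2.empty
        pd.testing.assert_frame_equal(once.dosage, twice.dosage)


# ---------------------------------------------------------------------------
# Allelic association
# ---------------------------------------------------------------------------

class TestAllelicAssoc:
    @pytest.mark.parametrize("f1,f2,expected", [
        (0.464, 0.356, 1.57), (0.373, 0.233, 1.96), (0.289, 0.174, 1.93),
        (0.154, 0.081, 2.07), (0.117, 0.153, 0.73), (0.072, 0.123, 0.55),
        (0.261, 0.316, 0.76), (0.418, 0.450, 0.88),
    ])
    def test_or_from_frequencies_worked_examples(self, f1, f2, expected):
        assert round(odds_ratio_from_freq(f1, f2), 2) == expected

    def test_null_or_is_one(self):
        assert odds_ratio_from_freq(0.3, 0.3) == pytest.approx(1.0)

    @staticmethod
    def _from_counts(a, b, c, d):
        """Genotype matrix realizing allele counts (a,b) cases, (c,d) controls
        via het/hom composition (all counts even for simplicity)."""
        def dosages(minor, major):
            n = (minor + major) // 2
            n_hom = minor // 2
            return [2.0] * n_hom + [0.0] * (n - n_hom) if minor % 2 == 0 else None
        case = dosages(a, b)
        ctrl = dosages(c, d)
        row = case + ctrl
        return make_genotypes([row], ["case"] * len(case) + ["control"] * len(ctrl))

    def test_counts_oracle(self):
        a, b, c, d = 30, 70, 20, 80
        g = self._from_counts(a, b, c, d)
        rec = allelic_assoc(g).iloc[0]
        assert rec["odds_ratio"] == pytest.approx((a * d) / (b * c), abs=1e-12)
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        from scipy import stats
        assert rec["p_raw"] == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)
        assert rec["f_case"] == pytest.approx(a / (a + b), abs=1e-12)

    def test_or_from_freq_equals_or_from_counts(self):
        a, b, c, d = 30, 70, 20, 80
        g = self._from_counts(a, b, c, d)
        rec = allelic_assoc(g).iloc[0]
        assert rec["odds_ratio"] == pytest.approx(
            odds_ratio_from_freq(rec["f_case"], rec["f_control"]), abs=1e-12)

    def test_label_swap_inverts_or(self):
        g = self._from_counts(30, 70, 20, 80)
        fwd = allelic_assoc(g, case_group="case", control_group="control").iloc[0]
        rev = allelic_assoc(g, case_group="control", control_group="case").iloc[0]
        assert rev["odds_ratio"] == pytest.approx(1 / fwd["odds_ratio"], rel=1e-12)
        assert rev["p_raw"] == pytest.approx(fwd["p_raw"], rel=1e-12)

    def test_zero_cell_haldane_correction(self):
        g = self._from_counts(0, 100, 20, 80)
        rec = allelic_assoc(g).iloc[0]
        expected = (0.5 * 80.5) / (100.5 * 20.5)
        assert rec["odds_ratio"] == pytest.approx(expected, rel=1e-12)

    def test_monomorphic_untestable(self):
        g = make_genotypes([[0.0] * 40], ["case"] * 20 + ["control"] * 20)
        rec = allelic_assoc(g).iloc[0]
        assert not rec["testable"]


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

class TestFitLogistic:
    def test_dominant_matches_carrier_table_or(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, size=600).astype(float)
        x = code_genotype(d, "dominant")
        logit = -0.5 + 0.8 * x
        y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
        fit = fit_logistic(x, y)
        a = ((x == 1) & (y == 1)).sum(); b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum(); dd = ((x == 0) & (y == 0)).sum()
        assert fit.odds_ratio == pytest.approx((a * dd) / (b * c), rel=1e-6)

    def test_null_predictor_small_beta(self):
        rng = np.random.default_rng(5)
        betas, ps = [], []
        for _ in range(60):
            x = rng.binomial(2, 0.3, size=2000).astype(float)
            y = rng.binomial(1, 0.5, size=2000).astype(float)
            fit = fit_logistic(x, y)
            betas.append(fit.beta)
            ps.append(fit.p)
        assert np.mean(np.abs(betas)) < 0.1
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_separation_flagged(self):
        x = np.array([0.0] * 20 + [2.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        fit = fit_logistic(x, y)
        assert fit.separation
        assert np.isnan(fit.p)

    def test_constant_predictor_untestable(self):
        fit = fit_logistic(np.ones(50), np.r_[np.zeros(25), np.ones(25)])
        assert not fit.testable

    def test_codings(self):
        d = np.array([0, 1, 2, np.nan])
        np.testing.assert_array_equal(code_genotype(d, "additive"), d)
        np.testing.assert_array_equal(code_genotype(d, "dominant")[:3], [0, 1, 1])
        np.testing.assert_array_equal(code_genotype(d, "recessive")[:3], [0, 0, 1])
        assert np.isnan(code_genotype(d, "dominant")[3])
        with pytest.raises(ValueError):
            code_genotype(d, "codominant")


# ---------------------------------------------------------------------------
# BH, concordance, age-at-onset, tagging
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_adjusted_ge_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestConcordance:
    def _individual(self, or_, p):
        return pd.DataFrame([{"snp_id": "m0", "odds_ratio": or_, "p_raw": p}])

    def _pooled(self, or_):
        return pd.DataFrame([{"snp_id": "m0", "pooled_or": or_}])

    @pytest.mark.parametrize("pooled_or,ind_or,p,label", [
        (1.5, 1.3, 0.005, "confirmed"),
        (1.5, 0.8, 0.001, "discordant-direction"),
        (1.5, 1.3, 0.02, "not-significant"),
    ])
    def test_labels(self, pooled_or, ind_or, p, label):
        out = validate_concordance(self._pooled(pooled_or),
                                   self._individual(ind_or, p))
        assert out["concordance"].iloc[0] == label


class TestAgeOnsetScan:
    def _cases(self, rng, n=400, carrier_or_old=1 / 0.6):
        # dominant effect: carriers enriched among OLD cases (young OR 0.6)
        d = rng.binomial(2, 0.3, size=n).astype(float)
        carrier = (d > 0).astype(float)
        logit = 0.0 + np.log(0.6) * carrier
        young = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        ages = np.where(young == 1, 55, 75)
        return make_genotypes([d.tolist()], ["case"] * n, ages=ages.tolist())

    def test_planted_dominant_effect_recovered(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            g = self._cases(rng)
            out = age_onset_scan(g)
            dom = out[out["model"] == "dominant"].iloc[0]
            hits += dom["odds_ratio"] < 1.0
        assert hits >= 0.9 * n_runs

    def test_bh_applied_across_scan(self):
        rng = np.random.default_rng(8)
        g = self._cases(rng)
        out = age_onset_scan(g)
        ok = out["p_raw"].notna()
        assert (out.loc[ok, "p_bh"] >= out.loc[ok, "p_raw"] - 1e-15).all()

    def test_cutoff_outside_range_rejected(self):
        g = self._cases(np.random.default_rng(9))
        with pytest.raises(ValueError, match="outside"):
            age_onset_scan(g, AgeOnsetConfig(cutoff_years=120))

    def test_all_one_side_rejected(self):
        d = np.random.default_rng(10).binomial(2, 0.3, 50).astype(float)
        g = make_genotypes([d.tolist()], ["case"] * 50, ages=[50] * 50)
        with pytest.raises(ValueError, match="one side"):
            age_onset_scan(g, AgeOnsetConfig(cutoff_years=50))


class TestTaggingSNP:
    def test_lowest_missingness_wins(self):
        rng = np.random.default_rng(11)
        rows = rng.binomial(2, 0.3, size=(3, 100)).astype(float)
        g = make_genotypes(rows.tolist(), ["case"] * 50 + ["control"] * 50)
        g.dosage.iloc[0, :10] = np.nan
        g.dosage.iloc[2, :5] = np.nan
        assert pick_tagging_snp(g, ["m0", "m1", "m2"]) == "m1"

    def test_tie_broken_by_hwe(self):
        base = np.array([[0, 1, 2, 1] * 25, [1, 1, 1, 1] * 25], dtype=float)
        g = make_genotypes(base.tolist(), ["control"] * 100)
        # equal (zero) missingness; m1 is all-het -> tiny HWE p -> m0 wins
        assert pick_tagging_snp(g, ["m0", "m1"]) == "m0"


class TestParameterRecovery:
    def test_allelic_or_recovery(self):
        # n = 1000 + 1000, F2 = 0.3, OR = 1.5: mean estimate near truth
        panel = generate_panel(1, (0.3, 0.3001), block_length=1, seed=12)
        plant_effects(panel, [0], 1.5)
        ors = []
        for s in range(40):
            g = simulate_genotypes(panel, CohortSpec(1000, 1000, seed=1000 + s))
            ors.append(allelic_assoc(g)["odds_ratio"].iloc[0])
        assert np.mean(ors) == pytest.approx(1.5, rel=0.05)
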