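"""Wald ratios, IVW, Cochran's Q, harmonisation, per-SNP estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from inflamr import generate_cohort
from inflamr.mr import (
    cochran_q,
    estimate_snp_associations,
    harmonize,
    ivw,
    run_mr,
    validate_instruments,
    wald_ratio,
)
from inflamr.simulate import SimulationConfig


def _ivw_oracle(bx, by, sy):
    """Independent closed form: weighted least squares through the origin."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    w = 1.0 / sy**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return beta, se


class TestWaldRatio:
    def test_arithmetic(self):
        theta, se = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(0.1)
        assert wald_ratio(1.0, 0.1, 0.3, 0.2) == (0.3, 0.2)
        assert wald_ratio(0.2, 0.1, 0.0, 0.2)[0] == 0.0

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.2, 0.1)


class TestIVW:
    # fixture values chosen arbitrarily; expectations frozen from the
    # weighted-least-squares closed form evaluated independently
    BX = np.array([0.12, 0.08, 0.20])
    BY = np.array([0.030, 0.028, 0.055])
    SY = np.array([0.010, 0.012, 0.015])

    def test_three_snp_fixture_matches_oracle(self):
        res = ivw(self.BX, self.BY, self.SY)
        beta, se = _ivw_oracle(self.BX, self.BY, self.SY)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        # frozen values from the closed form
        assert res.beta == pytest.approx(0.27427184466019416, abs=1e-10)
        assert res.se == pytest.approx(0.05225497607187132, abs=1e-10)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(100):
            J = rng.integers(1, 12)
            bx = rng.normal(0.1, 0.05, J)
            bx[np.abs(bx) < 1e-3] = 0.05
            by = rng.normal(0.0, 0.05, J)
            sy = rng.uniform(0.005, 0.05, J)
            res = ivw(bx, by, sy)
            beta, se = _ivw_oracle(bx, by, sy)
            assert res.beta == pytest.approx(beta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_single_snp_reduces_to_wald_ratio(self):
        res = ivw([0.1], [0.05], [0.02])
        theta, se = wald_ratio(0.1, 0.0, 0.05, 0.02)
        assert res.beta == pytest.approx(theta)
        assert res.se == pytest.approx(se)
        assert np.isnan(res.q) and res.q_df == 0

    def test_equal_ratios_give_that_ratio_and_zero_q(self):
        bx = np.array([0.1, 0.2, 0.05])
        res = ivw(bx, 0.7 * bx, np.array([0.01, 0.03, 0.02]))
        assert res.beta == pytest.approx(0.7, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.q_p == pytest.approx(1.0)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = np.array([0.01, 0.05, -0.02, 0.09])
        sy = np.full(4, 0.005)
        fixed = ivw(bx, by, sy)
        rand = ivw(bx, by, sy, random_effects=True)
        assert rand.se > fixed.se
        assert rand.beta == pytest.approx(fixed.beta)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ivw([], [], [])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=15), st.integers(min_value=0, max_value=9999))
def test_ivw_is_weighted_mean_of_wald_ratios(J, seed):
    """Algebraic identity: IVW = sum(w theta)/sum(w), w = bx^2/sy^2."""
    rng = np.random.default_rng(seed)
    bx = np.where(np.abs(b := rng.normal(0.1, 0.08, J)) < 1e-3, 0.05, b)
    by = rng.normal(0, 0.05, J)
    sy = rng.uniform(0.004, 0.06, J)
    res = ivw(bx, by, sy)
    w = bx**2 / sy**2
    assert res.beta == pytest.approx(np.sum(w * (by / bx)) / np.sum(w), abs=1e-12)


class TestCochranQ:
    def test_shifted_snp_dominates_and_leave_one_out_restores(self, rng):
        J = 6
        bx = rng.uniform(0.05, 0.2, J)
        theta = 0.4
        sy = np.full(J, 0.01)
        by = theta * bx
        by[2] += 10 * sy[2]  # one outlying instrument
        beta = ivw(bx, by, sy).beta
        q_full, df, p = cochran_q(bx, by, sy, beta)
        w = bx**2 / sy**2
        contrib = w * (by / bx - beta) ** 2
        assert np.argmax(contrib) == 2
        assert contrib[2] / q_full > 0.5
        keep = np.arange(J) != 2
        beta2 = ivw(bx[keep], by[keep], sy[keep]).beta
        q_loo, _, p_loo = cochran_q(bx[keep], by[keep], sy[keep], beta2)
        assert q_loo < 0.05 * q_full
        assert p_loo > 0.99

    def test_single_instrument_reports_missing(self):
        q, df, p = cochran_q([0.1], [0.05], [0.01], 0.5)
        assert np.isnan(q) and df == 0


def _inst(snp, ea, oa, eaf, beta, se=0.01, n=100_000):
    return {"snp": snp, "effect_allele": ea, "other_allele": oa,
            "eaf": eaf, "beta": beta, "se": se, "n": n}


class TestHarmonize:
    def test_identical_alleles_pass_through(self):
        exp = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.05)])
        al = harmonize(exp, out)
        assert al.loc[0, "beta_y"] == 0.05
        assert al.attrs["harmonization"]["n_flipped"] == 0

    def test_swapped_alleles_flip_sign(self):
        exp = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([_inst("rs1", "G", "A", 0.7, 0.05)])
        al = harmonize(exp, out)
        assert al.loc[0, "beta_y"] == -0.05
        assert al.attrs["harmonization"]["n_flipped"] == 1

    def test_strand_flip_same_orientation(self):
        exp = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([_inst("rs1", "T", "C", 0.3, 0.05)])
        al = harmonize(exp, out)
        assert al.loc[0, "beta_y"] == 0.05

    def test_palindromic_aligned_by_frequency(self):
        exp = pd.DataFrame([_inst("rs1", "A", "T", 0.10, 0.1)])
        out = pd.DataFrame([_inst("rs1", "A", "T", 0.91, 0.05)])
        al = harmonize(exp, out)
        assert len(al) == 1
        assert al.loc[0, "beta_y"] == -0.05  # frequency mismatch => flip

    def test_palindromic_ambiguous_dropped(self):
        exp = pd.DataFrame([_inst("rs1", "A", "T", 0.50, 0.1)])
        out = pd.DataFrame([_inst("rs1", "A", "T", 0.50, 0.05)])
        al = harmonize(exp, out)
        assert len(al) == 0
        assert al.attrs["harmonization"]["n_dropped"] == 1

    def test_mismatched_pair_dropped(self):
        exp = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([_inst("rs1", "A", "C", 0.3, 0.05)])
        al = harmonize(exp, out)
        assert len(al) == 0

    def test_allele_recoding_invariance_of_ivw(self):
        exp = pd.DataFrame(
            [
                _inst("rs1", "A", "G", 0.3, 0.10),
                _inst("rs2", "C", "T", 0.2, 0.08),
                _inst("rs3", "G", "A", 0.4, 0.12),
            ]
        )
        out = pd.DataFrame(
            [
                _inst("rs1", "A", "G", 0.3, 0.03),
                _inst("rs2", "C", "T", 0.2, 0.02),
                _inst("rs3", "G", "A", 0.4, 0.04),
            ]
        )
        al = harmonize(exp, out)
        base = ivw(al["beta_x"], al["beta_y"], al["se_y"]).beta
        # recode every exposure SNP to the other allele
        flipped = exp.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            exp["other_allele"],
            exp["effect_allele"],
        )
        flipped["beta"] = -exp["beta"]
        flipped["eaf"] = 1 - exp["eaf"]
        al2 = harmonize(flipped, out)
        assert ivw(al2["beta_x"], al2["beta_y"], al2["se_y"]).beta == pytest.approx(
            base, abs=1e-12
        )


class TestValidateInstruments:
    def test_duplicates_rejected(self):
        tab = pd.DataFrame([_inst("rs1", "A", "G", 0.3, 0.1)] * 2)
        with pytest.raises(ValueError, match="duplicated"):
            validate_instruments(tab)

    def test_bad_rows_dropped(self):
        tab = pd.DataFrame(
            [
                _inst("rs1", "A", "G", 0.3, 0.1),
                _inst("rs2", "AT", "G", 0.3, 0.1),
                _inst("rs3", "A", "G", 0.3, 0.1, se=0.0),
            ]
        )
        ok = validate_instruments(tab)
        assert ok["snp"].tolist() == ["rs1"]


class TestPerSnpEstimation:
    def test_recovers_known_effect_on_log_crp(self):
        cfg = dataclasses.replace(SimulationConfig(), n_participants=100_000, seed=19)
        cohort, truth = generate_cohort(cfg)
        tab = estimate_snp_associations(cohort, "log_crp")
        for snp, b_true in zip(truth.snp_ids, truth.beta_logcrp):
            row = tab.set_index("snp").loc[snp]
            assert row["beta"] == pytest.approx(b_true, abs=3.5 * row["se"])

    def test_permuted_dosages_are_null(self, default_cohort, rng):
        cohort, truth = default_cohort
        shuffled = cohort.copy()
        for snp in truth.snp_ids:
            shuffled[snp] = rng.permutation(shuffled[snp].to_numpy())
        tab = estimate_snp_associations(shuffled, "log_crp")
        assert np.all(np.abs(tab["beta"]) < 4 * tab["se"])

    def test_constant_ipw_weights_match_plain(self, default_cohort):
        cohort, _ = default_cohort
        plain = estimate_snp_associations(cohort, "dep_score")
        w = np.full(len(cohort), 2.0)
        weighted = estimate_snp_associations(cohort, "dep_score", ipw_weights=w)
        assert np.allclose(plain["beta"], weighted["beta"], atol=1e-8)

    def test_monomorphic_snp_dropped(self, default_cohort):
        cohort, _ = default_cohort
        c = cohort.copy()
        c["g_CRP_1"] = 0
        tab = estimate_snp_associations(c, "log_crp")
        assert "g_CRP_1" not in set(tab["snp"])

    def test_poisson_matches_statsmodels(self, default_cohort):
        cohort, _ = default_cohort
        tab = estimate_snp_associations(cohort, "dep_score", snp_columns=["g_IL6R_1"])
        X = sm.add_constant(
            np.column_stack(
                [
                    cohort["g_IL6R_1"],
                    cohort["age"],
                    (cohort["sex"] == "female").astype(float),
                ]
            )
        )
        ref = sm.GLM(cohort["dep_score"], X, family=sm.families.Poisson()).fit(
            cov_type="HC0"
        )
        c = tab.attrs["ceiling_attenuation"]
        assert 0.85 < c <= 1.0
        assert tab.loc[0, "beta"] * c == pytest.approx(ref.params.iloc[1], rel=1e-6)
        assert tab.loc[0, "se"] * c == pytest.approx(ref.bse.iloc[1], rel=1e-4)

    def test_ceiling_correction_vanishes_without_ceiling_mass(self, rng):
        from inflamr._ceiling import estimate_ceiling_correction

        scores = rng.poisson(2.0, 5000)  # nowhere near the PHQ-9 maximum
        assert estimate_ceiling_correction(scores, 27) == 1.0

    def test_ceiling_attenuation_matches_brute_force_simulation(self, rng):
        """The quadrature attenuation factor equals a direct Monte-Carlo
        estimate of d log E[min(S, cap)] under the same NB-lognormal law."""
        from inflamr._ceiling import ceiling_attenuation_factor

        a, sigma, r, cap = 0.45, 1.0, 25.0, 27
        c = ceiling_attenuation_factor(a, sigma, r, cap)
        z = rng.normal(size=2_000_000)
        dt = 0.05
        vals = []
        for t in (-dt, dt):
            mu = np.exp(a + t + sigma * z)
            s = np.minimum(rng.negative_binomial(r, r / (r + mu)), cap)
            vals.append(np.log(s.mean()))
        c_mc = (vals[1] - vals[0]) / (2 * dt)
        assert c == pytest.approx(c_mc, abs=0.02)
        assert c < 0.99  # real attenuation at this calibration

    def test_stratified_estimation_drops_sex_covariate(self, default_cohort):
        cohort, _ = default_cohort
        women = estimate_snp_associations(cohort, "log_crp", stratum="women")
        assert (women["n"] == (cohort["sex"] == "female").sum()).all()


class TestRunMR:
    def test_one_and_two_sample_agree(self):
        cfg = dataclasses.replace(
            SimulationConfig(), n_participants=60_000, theta_il6_dep=0.3,
            theta_crp_dep=0.0, seed=23,
        )
        cohort, truth = generate_cohort(cfg)
        one = run_mr("one_sample", "il6", "dep_score", cohort=cohort)
        two = run_mr(
            "two_sample", "il6", "dep_score", cohort=cohort,
            instruments=truth.instrument_table("il6r"),
        )
        assert one.beta == pytest.approx(two.beta, abs=2.5 * one.se)
        assert one.n_snps == two.n_snps == 3

    def test_unknown_design_rejected(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValueError):
            run_mr("three_sample", "crp", "dep_score", cohort=cohort)

    def test_sex_stratified_runs(self, default_cohort):
        cohort, _ = default_cohort
        res = run_mr("one_sample", "crp", "dep_dx", cohort=cohort, stratum="women")
        assert res.stratum == "women"
        assert np.isfinite(res.beta)
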