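"""Risk-equivalent dose, organ-equivalent dose and excess absolute risk."""

import numpy as np
import pytest

from rtrisk.cohort import Patient
from rtrisk.dvh import DVH, mean_dose
from rtrisk.scr import (
    OrganRiskParams, accumulated_ear, cohort_scr, ear, fraction_dose,
    load_organ_params, load_synthetic_organ_params, oed, red_full,
)


def params(alpha=0.05, R=0.5, beta_ear=8.0, gamma_e=0.002, gamma_a=4.0,
           alpha_beta=3.0, organ="organ"):
    return OrganRiskParams(organ=organ, alpha=alpha, R=R, beta_ear=beta_ear,
                           gamma_e=gamma_e, gamma_a=gamma_a,
                           alpha_beta=alpha_beta)


def uniform_dvh(dose, organ="o"):
    eps = 1e-9
    return DVH(organ, "differential", [0.0, dose - eps, dose + eps], [0.0, 100.0])


class TestFractionDose:
    @pytest.mark.parametrize("D,n,expect", [(51.0, 30, 1.7), (63.0, 30, 2.1), (0.0, 30, 0.0)])
    def test_prescription_levels(self, D, n, expect):
        assert fraction_dose(D, n) == pytest.approx(expect)

    def test_invalid_fraction_count(self):
        with pytest.raises(ValueError):
            fraction_dose(10.0, 0)


class TestRED:
    def test_zero_dose_is_zero(self):
        for R in (0.0, 0.3, 0.7, 1.0):
            assert red_full(0.0, 0.0, params(R=R)) == 0.0

    def test_unit_slope_at_origin(self):
        for R in (0.0, 0.2, 0.5, 0.9, 1.0):
            p = params(R=R)
            D = 1e-6
            assert red_full(D, D / 30, p) / D == pytest.approx(1.0, abs=1e-4)

    def test_plateau_limit_closed_form(self):
        # alpha' = 0.1, D = 20 -> (1/0.1)(1 - exp(-2)) = 8.6466
        p = params(alpha=0.1, R=1.0 - 1e-9, alpha_beta=3.0)
        val = red_full(20.0, 0.0, p)  # d = 0 keeps alpha' = alpha
        assert val == pytest.approx(10.0 * (1 - np.exp(-2.0)), abs=1e-4)
        assert val == pytest.approx(8.6466, abs=1e-4)

    def test_bell_limit_closed_form(self):
        p = params(alpha=0.1, R=0.0)
        assert red_full(20.0, 0.0, p) == pytest.approx(20.0 * np.exp(-2.0), rel=1e-9)

    @pytest.mark.parametrize("edge", [1e-6, 1.0 - 1e-6])
    def test_continuity_at_branch_switch(self, edge):
        inner = params(R=edge + (1e-8 if edge < 0.5 else -1e-8))
        outer = params(R=edge - (1e-8 if edge < 0.5 else -1e-8))
        for D in (2.0, 15.0, 40.0):
            assert red_full(D, D / 30, inner) == pytest.approx(
                red_full(D, D / 30, outer), abs=1e-5
            )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            red_full(-1.0, 0.0, params())


class TestOED:
    def test_uniform_dose_equals_red(self):
        p = params()
        d = uniform_dvh(30.0)
        expect = red_full(30.0, 1.0, p)
        assert oed(d, p, n_fractions=30) == pytest.approx(expect, rel=1e-6)

    def test_two_bin_hand_average(self):
        p = params()
        d = DVH("o", "differential", [0.0, 10.0, 30.0], [50.0, 50.0])
        r1 = red_full(5.0, 5.0 / 30, p)
        r2 = red_full(20.0, 20.0 / 30, p)
        assert oed(d, p, 30) == pytest.approx(0.5 * r1 + 0.5 * r2, rel=1e-12)

    def test_linear_response_limit_gives_mean_dose(self, rng):
        from conftest import random_dvh

        p = params(alpha=1e-7, R=0.5)
        for _ in range(5):
            d = random_dvh(rng)
            assert oed(d, p, 30) == pytest.approx(mean_dose(d), rel=1e-3)

    def test_low_dose_dominance_monotonicity(self):
        # in the low-dose regime (alpha' * Dmax < 1) moving volume to a
        # higher bin must not decrease OED
        p = params(alpha=0.02, R=0.5)
        rng = np.random.default_rng(3)
        for _ in range(20):
            edges = np.array([0.0, 5.0, 10.0, 15.0, 20.0])
            v = rng.dirichlet(np.ones(4)) * 100.0
            d1 = DVH("o", "differential", edges, v)
            v2 = v.copy()
            j = int(rng.integers(0, 3))
            shift = v2[j] * 0.5
            v2[j] -= shift
            v2[j + 1] += shift
            d2 = DVH("o", "differential", edges, v2)
            assert oed(d2, p, 30) >= oed(d1, p, 30) - 1e-12


class TestEAR:
    def test_reference_ages_modifier_is_one(self):
        p = params(beta_ear=7.7)
        assert ear(10.0, p, age_x=30.0, age_a=70.0) == pytest.approx(77.0)

    def test_zero_oed_zero_risk(self):
        assert ear(0.0, params(), 45.0, 70.0) == 0.0

    def test_zero_gammas_age_independent(self):
        p = params(gamma_e=0.0, gamma_a=0.0)
        assert ear(5.0, p, 30.0, 70.0) == pytest.approx(ear(5.0, p, 55.0, 60.0))

    def test_linear_in_oed_and_beta(self):
        p1, p2 = params(beta_ear=4.0), params(beta_ear=8.0)
        assert ear(6.0, p1, 45.0) * 2 == pytest.approx(ear(6.0, p2, 45.0))
        assert ear(3.0, p1, 45.0) * 2 == pytest.approx(ear(6.0, p1, 45.0))

    def test_invalid_ages(self):
        with pytest.raises(ValueError):
            ear(1.0, params(), -1.0, 70.0)
        with pytest.raises(ValueError):
            ear(1.0, params(), 70.0, 60.0)

    def test_accumulated_ear_sums_yearly_terms(self):
        p = params()
        total = accumulated_ear(2.0, p, age_x=67.2)
        by_hand = sum(ear(2.0, p, 67.2, a) for a in (68.0, 69.0, 70.0))
        assert total == pytest.approx(by_hand)


def mini_cohort(ages, modalities, dvh_doses):
    out = []
    for i, (a, m, dose) in enumerate(zip(ages, modalities, dvh_doses)):
        out.append(Patient(
            id=f"p{i}", age=a, ajcc=1, t_stage=1, n_stage=0, scf=False,
            chemo=False, modality=m, rp_grade=0,
            dvhs={"lung": uniform_dvh(dose, "lung")},
        ))
    return out


class TestCohortSCR:
    PARAMS = {"lung": params(organ="lung")}

    def test_age_cutoff_filter(self):
        cohort = mini_cohort([60, 66, 70], ["IMRT", "VMAT", "IMRT"], [10, 10, 10])
        res, _ = cohort_scr(cohort, self.PARAMS, age_cutoff=65.0)
        assert res["id"].nunique() == 1

    def test_identical_arms_null_pvalues(self):
        cohort = mini_cohort([50] * 8, ["IMRT"] * 4 + ["VMAT"] * 4,
                             [5, 10, 15, 20] * 2)
        _, comp = cohort_scr(cohort, self.PARAMS)
        assert comp.loc["lung", "oed_p"] == pytest.approx(1.0)
        assert comp.loc["lung", "ear_p"] == pytest.approx(1.0)

    def test_dominated_dvhs_give_lower_oed(self):
        rng = np.random.default_rng(9)
        imrt_doses = rng.uniform(8, 14, 15)
        vmat_doses = imrt_doses - 4.0  # stochastically dominated
        cohort = mini_cohort(
            [55] * 30, ["IMRT"] * 15 + ["VMAT"] * 15,
            np.r_[imrt_doses, vmat_doses],
        )
        _, comp = cohort_scr(cohort, self.PARAMS)
        assert comp.loc["lung", "oed_mean_VMAT"] < comp.loc["lung", "oed_mean_IMRT"]

    def test_missing_organ_params_skipped_with_warning(self):
        cohort = mini_cohort([50, 50], ["IMRT", "VMAT"], [10, 12])
        with pytest.warns(UserWarning, match="no risk parameters"):
            with pytest.raises(ValueError):
                cohort_scr(cohort, {"stomach": params(organ="stomach")})

    def test_all_excluded_rejected(self):
        cohort = mini_cohort([70, 72], ["IMRT", "VMAT"], [10, 12])
        with pytest.raises(ValueError, match="age cutoff"):
            cohort_scr(cohort, self.PARAMS)


def test_synthetic_param_template_loads():
    p = load_synthetic_organ_params()
    assert set(p) == {
        "ipsilateral_lung", "contralateral_lung", "contralateral_breast",
        "spinal_cord", "liver", "stomach",
    }
    for organ in p.values():
        assert organ.alpha > 0 and 0 <= organ.R <= 1


def test_param_loading_from_mapping():
    p = load_organ_params({"liver": {"alpha": 0.1, "R": 0.4, "beta_ear": 2.0,
                                     "gamma_e": 0.0, "gamma_a": 1.0}})
    assert p["liver"].alpha_beta == 3.0
    with pytest.raises(ValueError):
        load_organ_params({"liver": {"alpha": -1, "R": 0.4, "beta_ear": 2.0,
                                     "gamma_e": 0.0, "gamma_a": 1.0}})
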