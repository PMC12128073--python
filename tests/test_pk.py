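"""Closed-form infusion kinetics against numerical integration and identities."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vancopk import (CovariateRecord, DoseEvent, Regimen, StructuralParams,
                     conc, crcl_boer, crcl_schwartz, creatinine_clearance,
                     steady_state_conc)
from conftest import random_params


def ode_conc(params, regimen, t_eval):
    """Independent oracle: adaptive ODE integration of the infusion model."""
    two = params.n_compartments == 2
    k10 = params.CL / params.V1
    if two:
        k12, k21 = params.Q / params.V1, params.Q / params.V2

    def rate(t):
        return sum(ev.rate for ev in regimen.dose_events
                   if ev.start_time < t <= ev.end_time)

    def rhs(t, y):
        if two:
            return [rate(t) - (k10 + k12) * y[0] + k21 * y[1],
                    k12 * y[0] - k21 * y[1]]
        return [rate(t) - k10 * y[0]]

    t_end = max(t_eval) + 1e-9
    # Break integration at infusion switch points for accuracy.
    switches = sorted({ev.start_time for ev in regimen.dose_events}
                      | {ev.end_time for ev in regimen.dose_events}
                      | set(np.atleast_1d(t_eval)) | {0.0, t_end})
    switches = [s for s in switches if 0.0 <= s <= t_end]
    y = np.zeros(2 if two else 1)
    out = {}
    for a, b in zip(switches, switches[1:]):
        sol = solve_ivp(rhs, (a, b), y, rtol=1e-10, atol=1e-12,
                        dense_output=True)
        y = sol.y[:, -1]
        out[b] = y[0] / params.V1
    out[0.0] = 0.0
    return np.array([out[min(out, key=lambda s: abs(s - t))]
                     for t in np.atleast_1d(t_eval)])


class TestSingleDoseConc:
    def test_zero_before_and_at_first_dose(self, params_1cmt):
        reg = Regimen.repeated(100.0, 12.0, 1.0, 1)
        assert conc(params_1cmt, reg, 0.0) == 0.0

    def test_one_compartment_end_of_infusion_value(self):
        # (R0/CL)(1 - e^{-k t}) with R0=100 mg/h, k=0.5/h at t=1 h
        params = StructuralParams(CL=5.0, V1=10.0)
        reg = Regimen.repeated(100.0, 12.0, 1.0, 1)
        expected = (100.0 / 5.0) * (1 - np.exp(-0.5))
        assert conc(params, reg, 1.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.869, abs=5e-4)

    @pytest.mark.parametrize("two_cmt", [False, True])
    def test_matches_ode_integration(self, two_cmt):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = random_params(rng, two_cmt)
            tau = rng.uniform(4.0, 24.0)
            t_inf = rng.uniform(0.25, min(3.0, tau / 2))
            reg = Regimen.repeated(rng.uniform(5, 500), tau, t_inf, 3)
            t = rng.uniform(0.0, 3 * tau, size=4)
            np.testing.assert_allclose(conc(params, reg, t),
                                       ode_conc(params, reg, t),
                                       rtol=1e-6, atol=1e-10)

    def test_two_compartment_reduces_to_one_as_q_vanishes(self):
        reg = Regimen.repeated(120.0, 8.0, 1.0, 2)
        p1 = StructuralParams(CL=3.0, V1=12.0)
        p2 = StructuralParams(CL=3.0, V1=12.0, Q=1e-9, V2=5.0)
        t = np.linspace(0.1, 15.9, 40)
        np.testing.assert_allclose(conc(p2, reg, t), conc(p1, reg, t),
                                   rtol=1e-6)

    def test_linear_in_dose(self, params_2cmt):
        reg1 = Regimen.repeated(100.0, 8.0, 1.0, 4)
        reg2 = Regimen.repeated(200.0, 8.0, 1.0, 4)
        t = np.linspace(0.0, 30.0, 50)
        np.testing.assert_allclose(2 * conc(params_2cmt, reg1, t),
                                   conc(params_2cmt, reg2, t), rtol=1e-12)

    def test_continuous_at_infusion_end(self, params_1cmt):
        reg = Regimen.repeated(100.0, 8.0, 1.0, 1)
        eps = 1e-9
        assert conc(params_1cmt, reg, 1.0 - eps) == pytest.approx(
            conc(params_1cmt, reg, 1.0 + eps), rel=1e-6)

    def test_negative_time_rejected(self, params_1cmt, regimen_q8):
        with pytest.raises(ValueError):
            conc(params_1cmt, Regimen.repeated(30, 8, 1, 1), -1.0)


class TestSteadyState:
    @pytest.mark.parametrize("two_cmt", [False, True])
    def test_matches_explicit_50_dose_superposition(self, two_cmt):
        from vancopk.pk import _disposition
        rng = np.random.default_rng(7)
        for _ in range(5):
            params = random_params(rng, two_cmt)
            # tau long enough that 50 doses reach accumulation within 1e-5
            lam_min = float(np.min(_disposition(params)[0]))
            tau = max(4.0, 12.0 / (49 * lam_min))
            t_inf = 1.0
            dose = 100.0
            reg = Regimen.repeated(dose, tau, t_inf, 50)
            t_in = rng.uniform(0, tau, size=3)
            ss = steady_state_conc(params, dose, tau, t_inf, t_in)
            brute = conc(params, reg, 49 * tau + t_in)
            np.testing.assert_allclose(ss, brute, rtol=1e-4)

    def test_geometric_series_identity_one_compartment(self, params_1cmt):
        dose, tau, t_inf = 100.0, 8.0, 1.0
        k = params_1cmt.k
        t = 6.0  # post-infusion
        single = conc(params_1cmt, Regimen.repeated(dose, tau, t_inf, 1), t)
        assert steady_state_conc(params_1cmt, dose, tau, t_inf, t) == \
            pytest.approx(single / (1 - np.exp(-k * tau)), rel=1e-12)

    def test_accumulation_exceeds_first_dose(self, params_2cmt):
        dose, tau, t_inf = 100.0, 8.0, 1.0
        reg1 = Regimen.repeated(dose, tau, t_inf, 1)
        for t in (0.5, 2.0, 7.5):
            assert steady_state_conc(params_2cmt, dose, tau, t_inf, t) > \
                conc(params_2cmt, reg1, t)

    def test_tau_not_exceeding_infusion_rejected(self, params_1cmt):
        with pytest.raises(ValueError, match="tau"):
            steady_state_conc(params_1cmt, 100.0, 1.0, 1.0, 0.5)


class TestRenalFunction:
    def test_schwartz_constructed_identity(self):
        # height 100 cm and SCr exactly 0.413 mg/dL gives 100 mL/min/1.73m2
        assert crcl_schwartz(100.0, 0.413 * 88.4) == pytest.approx(100.0)

    def test_schwartz_inverse_proportional_to_creatinine(self):
        assert crcl_schwartz(120.0, 40.0) == pytest.approx(
            2 * crcl_schwartz(120.0, 80.0))

    def test_schwartz_hand_computed(self):
        assert crcl_schwartz(140.0, 19.0) == pytest.approx(269.0, rel=5e-3)

    def test_schwartz_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            crcl_schwartz(0.0, 30.0)
        with pytest.raises(ValueError):
            crcl_schwartz(100.0, -1.0)

    def test_infant_formula_positive_over_neonatal_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            cov = CovariateRecord(
                weight=rng.uniform(0.7, 4.2), postnatal_age=rng.uniform(3, 40),
                gestational_age=rng.uniform(25.4, 41.0),
                height=rng.uniform(32, 55),
                serum_creatinine=rng.uniform(15, 81))
            assert crcl_boer(cov) > 0

    def test_infant_formula_decreasing_in_creatinine(self):
        lo = CovariateRecord(weight=3.0, postnatal_age=20, gestational_age=38,
                             height=50, serum_creatinine=20.0)
        hi = CovariateRecord(weight=3.0, postnatal_age=20, gestational_age=38,
                             height=50, serum_creatinine=60.0)
        assert crcl_boer(lo) > crcl_boer(hi)

    def test_dispatch_boundary_uses_schwartz_at_365_days(self):
        cov = CovariateRecord(weight=9.0, postnatal_age=365.0, height=74.0,
                              serum_creatinine=20.0)
        assert creatinine_clearance(cov) == pytest.approx(
            crcl_schwartz(74.0, 20.0))
        cov_infant = CovariateRecord(weight=9.0, postnatal_age=364.0,
                                     height=74.0, serum_creatinine=20.0)
        assert creatinine_clearance(cov_infant) == pytest.approx(
            crcl_boer(cov_infant))

    def test_pluggable_infant_formula(self):
        cov = CovariateRecord(weight=4.0, postnatal_age=100.0, height=60.0,
                              serum_creatinine=25.0)
        assert crcl_boer(cov, formula=lambda c: 42.0) == 42.0


class TestDomainTypes:
    def test_pma_derived_from_components(self):
        cov = CovariateRecord(weight=2.0, postnatal_age=14.0,
                              gestational_age=30.0, serum_creatinine=30.0)
        assert cov.postmenstrual_age == pytest.approx(32.0)

    def test_inconsistent_pma_rejected(self):
        with pytest.raises(ValueError, match="postmenstrual"):
            CovariateRecord(weight=2.0, postnatal_age=14.0,
                            gestational_age=30.0, postmenstrual_age=35.0,
                            serum_creatinine=30.0)

    def test_cohort_label_threshold(self):
        a = CovariateRecord(weight=3.0, postnatal_age=49.9,
                            serum_creatinine=30.0)
        b = CovariateRecord(weight=3.0, postnatal_age=50.0,
                            serum_creatinine=30.0)
        assert a.cohort == "A" and b.cohort == "B"

    def test_overlapping_infusions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Regimen(maintenance_dose=100, tau=8, infusion_duration=1,
                    dose_events=(DoseEvent(100, 0.0, 2.0),
                                 DoseEvent(100, 1.0, 2.0)))

    def test_tau_must_exceed_infusion(self):
        with pytest.raises(ValueError):
            Regimen(maintenance_dose=100, tau=1.0, infusion_duration=2.0)

    def test_daily_dose(self, regimen_q8):
        assert regimen_q8.daily_dose == pytest.approx(90.0)
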