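"""Reaction terms, oxygen switches, aging factor and treatment hooks."""

import numpy as np
import pytest

from woundpde.kinetics import (
    SPECIES,
    KineticsContractError,
    aging_factor_A,
    growth_switch_G,
    hbot_source,
    hypoxia_switch_D,
    quercetin_reduction_check,
    reaction_rhs,
)
from woundpde.parameters import (
    AgingProfile,
    TreatmentSchedule,
    derive_steady_state_parameters,
)


def zero_state():
    return {name: 0.0 for name in SPECIES}


def random_state(params, rng, scale=2.0):
    scales = {
        "M1": params.M1_0, "M2": params.M2_0, "F": params.F0, "Fs": params.Fs0,
        "E": params.E0, "rho": params.rho0, "P": params.K_P, "Ta": params.K_Ta,
        "Tb": params.K_Tb, "I6": params.K_I6, "V": params.K_V, "w": params.w0,
    }
    return {k: s * rng.uniform(0.0, scale) for k, s in scales.items()}


class TestSwitches:
    @pytest.mark.parametrize("w, w0, expected", [(4e-6, 4e-6, 0.5), (0.0, 4e-6, 0.0),
                                                 (1.2e-5, 4e-6, 0.75)])
    def test_growth_switch_values(self, w, w0, expected):
        assert growth_switch_G(w, w0) == pytest.approx(expected)

    def test_growth_switch_monotone(self):
        w = np.linspace(0, 1e-5, 100)
        assert np.all(np.diff(growth_switch_G(w, 4e-6)) > 0)

    @pytest.mark.parametrize("w, expected", [(2e-6, 1.0), (4e-6, 0.0), (2.5e-6, 0.0)])
    def test_hypoxia_switch(self, w, expected):
        assert hypoxia_switch_D(w, 2.5e-6) == expected

    def test_hypoxia_switch_smoothed_brackets_step(self):
        D = hypoxia_switch_D(np.array([0.0, 2.5e-6, 1e-5]), 2.5e-6, width=1e-7)
        assert D[0] > 0.99 and D[1] == pytest.approx(0.5) and D[2] < 0.01

    def test_aging_factor(self):
        assert aging_factor_A(0.0, 0.7, 50.0) == 0.7
        assert aging_factor_A(50.0, 0.7, 50.0) == pytest.approx(0.35)
        t = np.linspace(0, 100, 50)
        assert np.all(np.diff(aging_factor_A(t, 1.0, 50.0)) < 0)

    def test_aging_factor_mean_matches_reference(self):
        t = np.linspace(0.0, 30.0, 200001)
        mean = np.trapezoid(aging_factor_A(t, 0.5, 50.0), t) / 30.0
        assert mean == pytest.approx(0.45035, abs=1e-5)


class TestHbotSource:
    def test_inside_window(self):
        s = TreatmentSchedule.hbot(1.2e-6)
        assert hbot_source(0.54, s) == pytest.approx(1.2e-6)  # ~12:58

    def test_outside_window(self):
        s = TreatmentSchedule.hbot(1.2e-6)
        assert hbot_source(0.2, s) == 0.0
        assert hbot_source(3.0 + 14.0 / 24.0, s) == 0.0  # window end excluded

    def test_disabled(self):
        s = TreatmentSchedule(gamma_w=1.2e-6, hbot_enabled=False)
        assert hbot_source(0.54, s) == 0.0

    def test_daily_periodicity(self):
        s = TreatmentSchedule.hbot(1.2e-6)
        t = np.linspace(0, 1, 241, endpoint=False)
        assert np.array_equal(hbot_source(t, s), hbot_source(t + 5.0, s))


class TestReactionRhs:
    def test_zero_state_constant_sources_only(self, params):
        rates = reaction_rhs(zero_state(), 3.7, AgingProfile(0.5, 0.5),
                             TreatmentSchedule.none(), params, R_t=0.8)
        assert rates["M1"] == pytest.approx(params.A_M1)
        assert rates["E"] == pytest.approx(params.lam_E / (1.0 + params.B2))
        assert rates["P"] == pytest.approx(params.lam_P * 0.8)
        for name in ("M2", "F", "Fs", "rho", "Ta", "Tb", "I6", "V", "w"):
            assert rates[name] == 0.0, name

    def test_tnf_alpha_steady_state_by_construction(self, params):
        lam = derive_steady_state_parameters(params)["lam_M1Ta"].value
        p = params.replace(lam_M1Ta=lam)
        state = zero_state()
        state.update(M1=p.M1_0, Ta=p.K_Ta)
        rates = reaction_rhs(state, 0.0, AgingProfile(0, 0), TreatmentSchedule.none(),
                             p, R_t=p.R0)
        assert abs(rates["Ta"]) <= 1e-12 * p.mu_Ta * p.K_Ta

    def test_quercetin_couplings(self, params):
        rng = np.random.default_rng(11)
        state = random_state(params, rng)
        state["w"] = 2.0 * params.w0  # well oxygenated: no hypoxic deaths
        aging = AgingProfile(0.4, 0.6)
        r0 = reaction_rhs(state, 1.0, aging, TreatmentSchedule.none(), params, 1.0)
        r1 = reaction_rhs(state, 1.0, aging, TreatmentSchedule.quercetin(1.0), params, 1.0)
        # F proliferation term scaled by exactly 1 + lam_FQ = 1.2
        prolif0 = r0["F"] + (params.lam_FFs * (1 - aging.eta) + params.mu_F) * state["F"]
        prolif1 = r1["F"] + (params.lam_FFs * (1 - aging.eta) + params.mu_F) * state["F"]
        assert prolif1 == pytest.approx(1.2 * prolif0, rel=1e-12)
        # senescent-fibroblast loss increased by exactly mu_FsQ * Q * Fs
        assert r0["Fs"] - r1["Fs"] == pytest.approx(params.mu_FsQ * 1.0 * state["Fs"], rel=1e-12)
        # ECM production scaled by 1 + mu_rhoQ * Q
        prod0 = r0["rho"] + params.mu_rho * state["rho"]
        prod1 = r1["rho"] + params.mu_rho * state["rho"]
        assert prod1 == pytest.approx((1.0 + params.mu_rhoQ) * prod0, rel=1e-12)

    def test_negative_input_rejected(self, params):
        state = zero_state()
        state["F"] = -1e-6
        with pytest.raises(KineticsContractError, match="F"):
            reaction_rhs(state, 0.0, AgingProfile(0, 0), TreatmentSchedule.none(),
                         params, R_t=1.0)

    def test_positivity_structure(self, params):
        # with any species at zero its net rate is non-negative, so the
        # continuous system preserves non-negativity
        rng = np.random.default_rng(5)
        aging = AgingProfile(0.3, 0.8)
        schedule = TreatmentSchedule.hbot_plus_quercetin()
        for _ in range(50):
            base = random_state(params, rng)
            t = rng.uniform(0, 30)
            for name in SPECIES:
                state = dict(base)
                state[name] = 0.0
                rates = reaction_rhs(state, t, aging, schedule, params, R_t=0.9)
                assert rates[name] >= 0.0, name

    def test_logistic_brackets(self, params):
        rng = np.random.default_rng(9)
        state = random_state(params, rng)
        # ECM production reverses at carrying capacity
        state["rho"] = params.rho_m * 1.01
        rates = reaction_rhs(state, 0.0, AgingProfile(0, 0), TreatmentSchedule.none(),
                             params, 1.0)
        assert rates["rho"] < 0
        # fibroblast proliferation contributes nothing above F_m
        state = random_state(params, rng)
        state["F"] = params.F_m
        r = reaction_rhs(state, 0.0, AgingProfile(1.0, 0.0), TreatmentSchedule.none(),
                         params, 1.0)
        state["w"] = 2 * params.w0  # ensure no hypoxic death difference
        assert r["F"] <= 0.0

    def test_time_enters_only_through_A_and_h(self, params):
        rng = np.random.default_rng(13)
        state = random_state(params, rng)
        schedule = TreatmentSchedule.hbot(1.2e-6)
        # equal time-of-day, different days: only A(t) differs; neutralize it
        aging0 = AgingProfile(0.5, 0.0)
        r1 = reaction_rhs(state, 0.3, aging0, schedule, params, 1.0)
        r2 = reaction_rhs(state, 7.3, aging0, schedule, params, 1.0)
        for name in SPECIES:
            assert r1[name] == pytest.approx(r2[name], rel=1e-14), name

    def test_hbot_monotone_in_oxygen_rate(self, params):
        rng = np.random.default_rng(17)
        on = TreatmentSchedule.hbot(1.2e-6)
        off = TreatmentSchedule.none()
        aging = AgingProfile(0.5, 0.5)
        for _ in range(20):
            state = random_state(params, rng)
            t = rng.uniform(0, 3)
            dw_on = reaction_rhs(state, t, aging, on, params, 1.0)["w"]
            dw_off = reaction_rhs(state, t, aging, off, params, 1.0)["w"]
            assert dw_on >= dw_off
            if not (12.0 / 24.0 <= t % 1.0 < 14.0 / 24.0):
                assert dw_on == dw_off

    def test_optional_oxygen_decay(self, params):
        state = zero_state()
        state["w"] = params.w0
        r_off = reaction_rhs(state, 0.0, AgingProfile(0, 0), TreatmentSchedule.none(),
                             params, 1.0)
        p_on = params.replace(mu_w_enabled=True)
        r_on = reaction_rhs(state, 0.0, AgingProfile(0, 0), TreatmentSchedule.none(),
                            p_on, 1.0)
        assert r_off["w"] - r_on["w"] == pytest.approx(params.mu_w * params.w0)


class TestQuercetinReduction:
    def test_zero_dose_reduces_to_untreated(self, params):
        assert quercetin_reduction_check(params, Q=0.0)

    def test_null_couplings_reduce_to_untreated(self, params):
        p = params.replace(lam_FQ=0.0, mu_rhoQ=0.0, mu_FsQ=0.0)
        assert quercetin_reduction_check(p, Q=1.0)

    def test_active_drug_differs(self, params):
        assert not quercetin_reduction_check(params, Q=1.0)
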