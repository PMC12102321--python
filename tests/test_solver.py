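"""Moving-boundary integration: initialization, transport, boundaries, runs."""

import numpy as np
import pytest

from woundpde.kinetics import SPECIES
from woundpde.parameters import AgingProfile, TreatmentSchedule
from woundpde.solver import (
    DIFFUSING,
    SolverProfile,
    _advective_tendency,
    advance,
    apply_boundary_conditions,
    boundary_residuals,
    initialize,
    run_simulation,
)


@pytest.fixture(scope="module")
def small_profile():
    return SolverProfile(n=60, dt_max=1e-2)


class TestInitialize:
    def test_edge_values(self, params, small_profile):
        st = initialize(params, AgingProfile(0.3, 0.7), small_profile)
        for name in SPECIES:
            if name in ("rho", "P"):
                continue
            assert st.fields[name][0] == 0.0, name
        assert st.fields["P"][0] == pytest.approx(
            params.beta_P * params.R0 * (params.B - params.R0))
        assert np.all(st.fields["rho"] == params.rho0)
        assert np.all(st.v == 0.0)

    def test_boundary_values_at_B(self, params, small_profile):
        st = initialize(params, AgingProfile(0.0, 0.0), small_profile)
        bv = params.boundary_values()
        for name in DIFFUSING:
            assert st.fields[name][-1] == pytest.approx(bv[name]), name

    def test_full_eta_removes_senescent_fibroblasts(self, params, small_profile):
        st = initialize(params, AgingProfile(1.0, 0.5), small_profile)
        assert np.all(st.fields["Fs"][:-1] == 0.0)

    def test_senescent_burden_scales_with_age(self, params, small_profile):
        old = initialize(params, AgingProfile(0.0, 0.0), small_profile)
        young = initialize(params, AgingProfile(0.9, 1.0), small_profile)
        assert np.all(young.fields["Fs"][1:-1] <= old.fields["Fs"][1:-1])


class TestBoundaryConditions:
    def test_uniform_pdgf_flux_residual(self, params, small_profile):
        st = initialize(params, AgingProfile(0, 0), small_profile)
        st.fields["P"][:] = params.K_P
        res = boundary_residuals(st, params)
        assert res["P"] == pytest.approx(params.beta_P * st.grid.R)

    def test_flat_attractants_reduce_cells_to_neumann(self, params, small_profile):
        st = initialize(params, AgingProfile(0, 0), small_profile)
        for name in SPECIES:
            st.fields[name][:] = 1e-3
        res = boundary_residuals(st, params)
        for name in ("M1", "F", "E"):
            assert res[name] == 0.0

    def test_hbot_elevates_boundary_oxygen_in_window(self, params, small_profile):
        st = initialize(params, AgingProfile(0, 0), small_profile)
        sched = TreatmentSchedule.hbot(1.2e-6)
        st.t = 13.0 / 24.0  # 13:00, inside the window
        apply_boundary_conditions(st, params, sched, AgingProfile(0, 0), small_profile)
        assert st.fields["w"][-1] == pytest.approx(
            params.w0 + 1.2e-6 * (1.0 / 24.0))
        st.t = 10.0 / 24.0
        apply_boundary_conditions(st, params, sched, AgingProfile(0, 0), small_profile)
        assert st.fields["w"][-1] == params.w0

    def test_pinning_throughout_a_run(self, params, small_profile):
        res = run_simulation(params, AgingProfile(0.5, 0.5), TreatmentSchedule.none(),
                             horizon=2.0, snapshot_times=[1.0, 2.0],
                             profile=small_profile)
        bv = params.boundary_values()
        for st in res.snapshots.values():
            for name in DIFFUSING:
                assert st.fields[name][-1] == pytest.approx(bv[name], rel=1e-12), name


class TestTransport:
    def test_uniform_fields_without_kinetics_are_stationary(self, zero_kinetics_params,
                                                            small_profile):
        p = zero_kinetics_params
        st = initialize(p, AgingProfile(0, 0), small_profile)
        bv = p.boundary_values()
        for name in SPECIES:
            st.fields[name][:] = bv.get(name, p.rho0)
        before = {k: v.copy() for k, v in st.fields.items()}
        for _ in range(5):
            st, dt = advance(st, 1e-2, p, AgingProfile(0, 0),
                             TreatmentSchedule.none(), small_profile)
        assert st.grid.R == p.R0  # no pressure, no motion
        for name in SPECIES:
            scale = max(bv.get(name, p.rho0), 1e-30)
            assert np.max(np.abs(st.fields[name] - before[name])) <= 1e-12 * scale, name

    def test_advection_matches_characteristics_oracle(self):
        # rho_t + (1/r)(r v rho)_r = 0 with constant v < 0 on a frozen grid;
        # exact solution r rho(r, t) = (r - v t) rho0(r - v t)
        n = 512
        r = np.linspace(1.0, 1.5, n + 1)
        h = r[1] - r[0]
        v = np.full_like(r, -0.5)
        width = 0.06
        rho0 = lambda s: 1.0 + np.exp(-((s - 1.22) / width) ** 2)
        rho = rho0(r)
        t, t_end = 0.0, 0.04
        dt = 0.5 * h / 0.5
        while t < t_end - 1e-12:
            step = min(dt, t_end - t)
            rho = rho + step * _advective_tendency(rho, v, r, h)
            t += step
        exact = (r - v[0] * t_end) * rho0(r - v[0] * t_end) / r
        l1_err = np.sum(np.abs(rho - exact)) / np.sum(np.abs(exact))
        assert l1_err <= 0.01

    def test_null_doses_equal_no_drug(self, params, small_profile):
        aging = AgingProfile(0.4, 0.6)
        armed = TreatmentSchedule(Q=0.0, gamma_w=0.0, hbot_enabled=True, q_enabled=True)
        r1 = run_simulation(params, aging, armed, horizon=2.0, profile=small_profile)
        r2 = run_simulation(params, aging, TreatmentSchedule.none(), horizon=2.0,
                            profile=small_profile)
        np.testing.assert_array_equal(np.interp([1.0, 2.0], r1.t, r1.R),
                                      np.interp([1.0, 2.0], r2.t, r2.R))


class TestRunSimulation:
    def test_determinism(self, params, small_profile):
        a = run_simulation(params, AgingProfile(0.2, 0.2), TreatmentSchedule.none(),
                           horizon=1.0, profile=small_profile)
        b = run_simulation(params, AgingProfile(0.2, 0.2), TreatmentSchedule.none(),
                           horizon=1.0, profile=small_profile)
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.t, b.t)

    def test_pwc_consistent_with_radius(self, params, small_profile):
        res = run_simulation(params, AgingProfile(0, 0), TreatmentSchedule.none(),
                             horizon=3.0, profile=small_profile)
        expected = 100.0 * (res.R0 - res.R) / res.R0
        if res.status == "closed":
            expected[-1] = 100.0
        np.testing.assert_allclose(res.pwc, expected, rtol=1e-12)

    def test_daily_recording(self, params, small_profile):
        res = run_simulation(params, AgingProfile(0.5, 0.5), TreatmentSchedule.none(),
                             horizon=3.0, profile=small_profile)
        for d in (1.0, 2.0, 3.0):
            assert np.any(np.isclose(res.t, d))

    def test_closure_declared_at_threshold(self, params, small_profile):
        res = run_simulation(params, AgingProfile(0, 0), TreatmentSchedule.none(),
                             horizon=30.0, profile=small_profile)
        if res.status == "closed":
            assert res.R[-1] <= small_profile.r_min + 1e-12
            assert res.pwc[-1] == 100.0

    def test_fields_stay_nonnegative_and_finite(self, params, small_profile):
        res = run_simulation(params, AgingProfile(0.92, 1.0),
                             TreatmentSchedule.hbot_plus_quercetin(),
                             horizon=2.0, snapshot_times=[0.5, 1.0, 2.0],
                             profile=small_profile)
        for st in res.snapshots.values():
            for name in SPECIES:
                assert np.all(st.fields[name] >= 0.0), name
                assert np.all(np.isfinite(st.fields[name])), name
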