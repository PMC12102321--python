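import numpy as np
import pytest

from woundpde import AgingProfile, ModelParameters, TreatmentSchedule
from woundpde.experiments import TABLE2_PATIENTS, make_schedule
from woundpde.solver import SolverProfile, run_simulation


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def headline_profile() -> SolverProfile:
    """Moderate resolution used for the multi-run scenario grids."""
    return SolverProfile(n=120, dt_max=1e-2)


@pytest.fixture(scope="session")
def table2_results(params, headline_profile):
    """One simulation per (patient, arm) of the day-30 roster, shared by tests."""
    out = {}
    for label, eta, a0 in TABLE2_PATIENTS:
        for arm in ("none", "Q", "HBOT", "HBOT+Q"):
            res = run_simulation(params, AgingProfile(eta, a0), make_schedule(arm),
                                 horizon=30.0, profile=headline_profile)
            out[(label, arm)] = res
    return out


@pytest.fixture(scope="session")
def zero_kinetics_params(params) -> ModelParameters:
    """All sources, sinks and mechanics switched off (transport-only model)."""
    import dataclasses

    zeroed = {}
    for f in dataclasses.fields(params):
        if f.name.startswith(("lam_", "mu_")) and f.name != "mu_w_enabled":
            zeroed[f.name] = 0.0
    zeroed.update(A_M1=0.0, c_w=0.0, gamma=0.0, beta_P=0.0, chi_P=0.0, chi_V=0.0)
    return params.replace(**zeroed)
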