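"""Local kinetics of the wound network: reaction terms, switches and drugs.

The twelve interacting species are the inflammatory and anti-inflammatory
macrophages (M1, M2), fibroblasts and senescent fibroblasts (F, Fs),
endothelial cells (E), extracellular matrix (rho), the cytokines PDGF (P),
TNF-alpha (Ta), TGF-beta (Tb), IL-6 (I6) and VEGF (V), and oxygen (w).
This module evaluates the non-transport right-hand sides pointwise; the
solver adds diffusion, advection and chemotaxis.

Diabetes enters through the blockades B1 (damping constant M1 -> M2
polarization) and B2 (damping endothelial maturation).  Aging enters through
(1 - eta) scaling of the fibroblast senescence conversion and through the
decaying VEGF production factor A(t) = A0 / (1 + t^2 / T_w^2).  Treatment
enters as a constant quercetin level Q (enhanced fibroblast proliferation
and ECM production, extra clearance of senescent fibroblasts) and a pulsed
hyperbaric-oxygen source gamma_w active in a daily window.
"""

from __future__ import annotations

import numpy as np

from .parameters import AgingProfile, ModelParameters, TreatmentSchedule

__all__ = [
    "SPECIES",
    "growth_switch_G",
    "hypoxia_switch_D",
    "aging_factor_A",
    "hbot_source",
    "hbot_boundary_oxygen",
    "effective_Q",
    "reaction_rhs",
    "quercetin_reduction_check",
]

#: canonical species ordering used by the solver state arrays
SPECIES = ("M1", "M2", "F", "Fs", "E", "rho", "P", "Ta", "Tb", "I6", "V", "w")

_NEG_TOL = 1e-10


class KineticsContractError(ValueError):
    """A species value violates the non-negativity contract."""


def growth_switch_G(w, w0: float):
    """Oxygen-dependent growth factor G(w) = w / (w0 + w) in [0, 1)."""
    if w0 <= 0:
        raise ValueError(f"w0 must be positive, got {w0!r}")
    w = np.asarray(w, dtype=float)
    out = w / (w0 + w)
    return float(out) if out.ndim == 0 else out


def hypoxia_switch_D(w, w_i: float, width: float = 0.0):
    """Hypoxic-death switch D(w) = H(w_i - w).

    Sharp Heaviside by default with the convention H(0) = 0 (no hypoxic
    death exactly at threshold).  A positive ``width`` replaces the step by
    a logistic of that concentration scale, for stiff-integrator
    friendliness.
    """
    w = np.asarray(w, dtype=float)
    if width > 0:
        out = 1.0 / (1.0 + np.exp(np.clip((w - w_i) / width, -500, 500)))
    else:
        out = np.where(w < w_i, 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def aging_factor_A(t, A0: float, T_w: float):
    """VEGF-production aging factor A(t) = A0 / (1 + t^2 / T_w^2)."""
    t = np.asarray(t, dtype=float)
    out = A0 / (1.0 + (t / T_w) ** 2)
    return float(out) if out.ndim == 0 else out


def in_hbot_window(t, schedule: TreatmentSchedule):
    """True when the time of day of ``t`` (days) lies in the daily HBOT window."""
    start, end = schedule.hbot_window
    tod = np.asarray(t, dtype=float) % 1.0
    out = (tod >= start / 24.0) & (tod < end / 24.0)
    return bool(out) if out.ndim == 0 else out


def hbot_source(t, schedule: TreatmentSchedule):
    """Pulsed HBOT oxygen source gamma_w * h(t) in g/cm^3/d."""
    if not schedule.hbot_enabled:
        out = np.zeros_like(np.asarray(t, dtype=float))
        return float(out) if out.ndim == 0 else out
    out = np.where(in_hbot_window(t, schedule), schedule.gamma_w, 0.0)
    return float(out) if out.ndim == 0 else out


def hbot_boundary_oxygen(t: float, schedule: TreatmentSchedule, w0: float,
                         accrue_from_day_start: bool = False) -> float:
    """Oxygen Dirichlet value at r = B: w0, elevated during HBOT windows.

    During the window the boundary value is raised by the accrued dose
    integral of gamma_w.  By default the accrual resets at each day's window
    start; ``accrue_from_day_start`` instead accrues from the start of the
    simulation (the alternative literal reading).
    """
    if not schedule.hbot_enabled or not in_hbot_window(t, schedule):
        return w0
    start = schedule.hbot_window[0] / 24.0
    if accrue_from_day_start:
        # accrued over all windows since t = 0
        day = np.floor(t)
        window_len = (schedule.hbot_window[1] - schedule.hbot_window[0]) / 24.0
        accrued = day * window_len + ((t % 1.0) - start)
    else:
        accrued = (t % 1.0) - start
    return w0 + schedule.gamma_w * max(accrued, 0.0)


def effective_Q(schedule: TreatmentSchedule) -> float:
    """Quercetin level actually applied (zero when the arm is disabled)."""
    return schedule.Q if schedule.q_enabled else 0.0


def _check_nonnegative(state) -> None:
    for name in SPECIES:
        x = np.asarray(state[name], dtype=float)
        if np.any(x < -_NEG_TOL) or not np.all(np.isfinite(x)):
            raise KineticsContractError(
                f"species {name} violates non-negativity contract (min {np.min(x):.3e})"
            )


def reaction_rhs(state, t: float, aging: AgingProfile, schedule: TreatmentSchedule,
                 params: ModelParameters, R_t: float, *, check: bool = True,
                 hypoxia_width: float = 0.0) -> dict:
    """Non-transport rates dX/dt (g/cm^3/d) for all twelve species.

    ``state`` maps species names to scalars or arrays of a common shape.
    ``R_t`` is the current wound radius, which sources PDGF in proportion to
    the damaged-platelet pool at the wound edge.
    """
    if check:
        _check_nonnegative(state)
    p = params
    M1, M2, F, Fs, E = (np.asarray(state[k], dtype=float) for k in ("M1", "M2", "F", "Fs", "E"))
    rho, P, Ta, Tb, I6, V, w = (
        np.asarray(state[k], dtype=float) for k in ("rho", "P", "Ta", "Tb", "I6", "V", "w")
    )
    if not (0.0 < R_t <= p.B):
        raise ValueError(f"R_t must lie in (0, B], got {R_t}")

    Q = effective_Q(schedule)
    G = growth_switch_G(w, p.w0)
    D = hypoxia_switch_D(w, p.w_i, width=hypoxia_width)
    A_t = aging_factor_A(t, aging.A0, p.T_w)

    fP = P / (p.K_P + P)
    fTa = Ta / (p.K_Ta + Ta)
    fTb = Tb / (p.K_Tb + Tb)
    fI6 = I6 / (p.K_I6 + I6)
    fV = V / (p.K_V + V)

    rates = {}
    rates["rho"] = (
        p.lam_rho * F * (1.0 + p.lam_rho_Tb * fTb) * (1.0 - rho / p.rho_m) * (1.0 + p.mu_rhoQ * Q)
        - p.mu_rho * rho
    )
    pol_M1M2 = p.lam_M1M2 / (1.0 + p.B1)
    rates["M1"] = (
        p.A_M1
        + p.lam_M1P * p.M1_0 * fP
        - p.lam_M1M2Tb * M1 * fTb
        + p.lam_M2M1Ta * M2 * fTa
        - pol_M1M2 * M1
        + p.lam_M2M1I6 * M2 * fI6
        - p.mu_M1 * M1
    )
    rates["M2"] = (
        pol_M1M2 * M1
        + p.lam_M1M2Tb * G * M1 * fTb
        - p.lam_M2M1Ta * M2 * fTa
        - p.lam_M2M1I6 * M2 * fI6
        - p.mu_M2 * M2
        - p.mu_M2w * D * M2
    )
    rates["F"] = (
        p.lam_F * G * (1.0 + p.lam_FQ * Q) * F * (1.0 - F / p.F_m)
        - p.lam_FFs * (1.0 - aging.eta) * F
        - p.mu_F * F
        - p.mu_Fw * D * F
    )
    rates["Fs"] = p.lam_FFs * (1.0 - aging.eta) * F - p.mu_Fs * Fs - p.mu_FsQ * Q * Fs
    rates["E"] = p.lam_E / (1.0 + p.B2) * (1.0 + p.lam_EV * fV) - p.mu_E * E
    rates["P"] = (
        p.lam_P * R_t + p.lam_FP * F - (p.mu_PF * F + p.mu_PM * M1) * fP - p.mu_P * P
    )
    rates["Ta"] = p.lam_M1Ta * M1 - p.mu_Ta * Ta
    rates["Tb"] = p.lam_FTb * F + p.lam_M2Tb * M2 - p.mu_Tb * Tb
    rates["I6"] = p.lam_FsI6 * Fs - p.mu_I6 * I6
    rates["V"] = (
        (p.lam_FV * F + p.lam_FsV * Fs) * A_t + p.lam_M2V * M2 - p.mu_EV * E * fV - p.mu_V * V
    )
    rates["w"] = p.lam_Ew * E - p.c_w * (F + M2) * w + hbot_source(t, schedule)
    if p.mu_w_enabled:
        rates["w"] = rates["w"] - p.mu_w * w
    return rates


def quercetin_reduction_check(params: ModelParameters, Q: float,
                              aging: AgingProfile | None = None,
                              n_states: int = 100, seed: int = 0,
                              rtol: float = 1e-12) -> bool:
    """True iff the drugged kinetics coincide with the untreated kinetics.

    Probes ``n_states`` random positive states and compares the reaction
    rates under a quercetin schedule of dose ``Q`` against the no-drug
    schedule, term by term.  By construction this holds exactly at Q = 0 or
    when all drug couplings vanish.
    """
    aging = aging or AgingProfile(0.5, 0.5)
    rng = np.random.default_rng(seed)
    scales = {
        "M1": params.M1_0, "M2": params.M2_0, "F": params.F0, "Fs": params.Fs0,
        "E": params.E0, "rho": params.rho0, "P": params.K_P, "Ta": params.K_Ta,
        "Tb": params.K_Tb, "I6": params.K_I6, "V": params.K_V, "w": params.w0,
    }
    with_q = TreatmentSchedule(Q=Q, q_enabled=True)
    no_q = TreatmentSchedule.none()
    for _ in range(n_states):
        state = {k: s * rng.uniform(0.0, 2.0) for k, s in scales.items()}
        t = rng.uniform(0.0, 30.0)
        r_q = reaction_rhs(state, t, aging, with_q, params, R_t=params.R0)
        r_0 = reaction_rhs(state, t, aging, no_q, params, R_t=params.R0)
        for name in SPECIES:
            a, b = r_q[name], r_0[name]
            if abs(a - b) > rtol * max(abs(a), abs(b), 1e-30):
                return False
    return True
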