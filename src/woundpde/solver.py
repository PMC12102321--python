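"""Moving-boundary integration of the wound-healing PDE system.

The annulus [R(t), B] is mapped onto the fixed computational interval
xi in [0, 1] by the front-fixing change of variables

    xi = (r - R(t)) / (B - R(t)),      r_j = R + xi_j (B - R),

so the wound edge sits at xi = 0 and the healthy boundary at xi = 1 for all
times.  In the mapped frame every field acquires the standard mesh-motion
advection term (1 - xi) * dR/dt * dX/dr in addition to its physical
transport.  Cell species (M1, M2, F, Fs, E) carry diffusion, advection with
the tissue velocity v and (M1, F toward PDGF; E toward VEGF) chemotaxis;
cytokines and oxygen carry diffusion only; the ECM density rho is advected
without diffusion and needs no boundary data at the wound edge (outgoing
characteristic).

Time stepping is implicit-explicit: diffusion and the stiff linear loss
terms are backward-Euler (tridiagonal solves per species), advection,
chemotaxis and the remaining kinetics are explicit first-order upwind /
forward Euler, with adaptive step control (CFL plus positivity retries) and
forced step boundaries at the edges of HBOT windows.  The free boundary
moves by dR/dt = v(R(t), t); the wound is declared closed when R falls to
R_min, where the coordinate map degenerates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.linalg import solve_banded

from . import kinetics, mechanics
from .kinetics import SPECIES, effective_Q
from .parameters import AgingProfile, ModelParameters, TreatmentSchedule

__all__ = [
    "RadialGrid",
    "SimulationState",
    "SimulationResult",
    "SolverProfile",
    "initialize",
    "apply_boundary_conditions",
    "boundary_residuals",
    "advance",
    "run_simulation",
]

CELLS = ("M1", "M2", "F", "Fs", "E")
DIFFUSING = ("M1", "M2", "F", "Fs", "E", "P", "Ta", "Tb", "I6", "V", "w")
CHEMOTAXIS = {"M1": ("chi_P", "P"), "F": ("chi_P", "P"), "E": ("chi_V", "V")}
#: species with a homogeneous Neumann condition at the wound edge
NEUMANN_AT_EDGE = ("M2", "Fs", "I6", "Ta", "Tb", "V", "w")


class IntegrationError(RuntimeError):
    """Time integration failed; carries a diagnostic snapshot."""

    def __init__(self, message: str, state: "SimulationState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class SolverProfile:
    """Numerical controls for the moving-boundary integration."""

    n: int = 200                 # number of grid intervals on [R, B]
    dt_max: float = 1e-2         # baseline maximum step (d)
    dt_window: float = 1e-3      # maximum step inside HBOT windows (d)
    cfl: float = 0.4             # advective Courant limit
    r_min: float = 1e-2          # closure radius (cm); PWC = 100 at or below
    hypoxia_width: float = 0.0   # optional smoothing of the hypoxia switch (g/cm^3)
    hbot_accrue_from_start: bool = False  # boundary-oxygen accrual convention
    fs_boundary_scaled: bool = False      # scale the Fs Dirichlet value by (1 - eta)
    max_retries: int = 20
    record_interval: float = 1.0  # R/PWC sampling cadence (d)

    def replace(self, **kw) -> "SolverProfile":
        return dataclasses.replace(self, **kw)

    #: a cheaper profile adequate for dense parameter sweeps / ranking
    @staticmethod
    def reduced(n: int = 60, dt_max: float = 2e-2) -> "SolverProfile":
        return SolverProfile(n=n, dt_max=dt_max, dt_window=2e-3)


@dataclass
class RadialGrid:
    """Uniform front-fixed grid: xi in [0, 1] mapped to [R, B]."""

    n: int
    R: float
    B: float
    xi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.R < self.B):
            raise ValueError(f"require 0 < R < B, got R={self.R}, B={self.B}")
        self.xi = np.linspace(0.0, 1.0, self.n + 1)

    @property
    def r(self) -> np.ndarray:
        return self.R + self.xi * (self.B - self.R)

    @property
    def h(self) -> float:
        return (self.B - self.R) / self.n


@dataclass
class SimulationState:
    """Grid, all species fields, tissue velocity and the current time."""

    grid: RadialGrid
    fields: dict[str, np.ndarray]
    v: np.ndarray
    t: float

    def copy(self) -> "SimulationState":
        g = RadialGrid(self.grid.n, self.grid.R, self.grid.B)
        return SimulationState(g, {k: x.copy() for k, x in self.fields.items()},
                               self.v.copy(), self.t)


@dataclass
class SimulationResult:
    """Trajectories of the wound radius and percent wound closure."""

    t: np.ndarray
    R: np.ndarray
    pwc: np.ndarray
    status: str                      # horizon_reached | closed | failed
    R0: float
    snapshots: dict[float, SimulationState] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def pwc_final(self) -> float:
        return float(self.pwc[-1])

    def pwc_at(self, day: float) -> float:
        """PWC at a given day (linear interpolation; 100 after closure)."""
        if day >= self.t[-1]:
            return float(self.pwc[-1]) if self.status != "failed" else float("nan")
        return float(np.interp(day, self.t, self.pwc))


def _quadratic_profile(xi: np.ndarray, cap: float) -> np.ndarray:
    return cap * xi ** 2


def initialize(params: ModelParameters, aging: AgingProfile,
               profile: SolverProfile | None = None) -> SimulationState:
    """Initial state: healthy values at B falling quadratically to 0 at the edge.

    rho starts uniform at the healthy tissue density rho0; PDGF carries the
    additional wound-edge influx ramp beta_P * R(0) * (B - r); the senescent
    fibroblast profile is scaled by (1 - eta) so biologically younger
    patients start with a lighter senescent burden.
    """
    profile = profile or SolverProfile()
    grid = RadialGrid(profile.n, params.R0, params.B)
    xi, r = grid.xi, grid.r
    bv = params.boundary_values()
    f: dict[str, np.ndarray] = {}
    for name in SPECIES:
        if name == "rho":
            f[name] = np.full(xi.shape, params.rho0)
        elif name == "P":
            f[name] = params.beta_P * params.R0 * (params.B - r) + _quadratic_profile(xi, bv["P"])
        elif name == "Fs":
            f[name] = _quadratic_profile(xi, bv["Fs"]) * (1.0 - aging.eta)
        else:
            f[name] = _quadratic_profile(xi, bv[name])
    state = SimulationState(grid, f, np.zeros_like(xi), 0.0)
    apply_boundary_conditions(state, params, TreatmentSchedule.none(), aging, profile)
    return state


def apply_boundary_conditions(state: SimulationState, params: ModelParameters,
                              schedule: TreatmentSchedule, aging: AgingProfile,
                              profile: SolverProfile | None = None) -> SimulationState:
    """Pin the Dirichlet values at r = B (with HBOT-elevated oxygen).

    The wound-edge (r = R) conditions are flux conditions; they are built
    into the discrete transport operators rather than imposed on values.
    """
    profile = profile or SolverProfile()
    bv = params.boundary_values()
    if profile.fs_boundary_scaled:
        bv["Fs"] = bv["Fs"] * (1.0 - aging.eta)
    bv["w"] = kinetics.hbot_boundary_oxygen(
        state.t, schedule, params.w0, profile.hbot_accrue_from_start
    )
    for name in DIFFUSING:
        state.fields[name][-1] = bv[name]
    return state


def boundary_residuals(state: SimulationState, params: ModelParameters) -> dict[str, float]:
    """Discrete residuals of the wound-edge flux conditions (diagnostics).

    For PDGF the condition is -dP/dr = beta_P * R(t); for the Neumann
    species it is dX/dr = 0; for the chemotactic cells it is the zero
    total-flux balance D X_r - chi X A_r = 0.
    """
    h = state.grid.h
    R = state.grid.R
    out: dict[str, float] = {}
    P = state.fields["P"]
    out["P"] = abs(-(P[1] - P[0]) / h - params.beta_P * R)
    for name in NEUMANN_AT_EDGE:
        X = state.fields[name]
        out[name] = abs((X[1] - X[0]) / h)
    for name, (chi_name, attract) in CHEMOTAXIS.items():
        X = state.fields[name]
        A = state.fields[attract]
        D = getattr(params, f"D_{name}")
        chi = getattr(params, chi_name)
        out[name] = abs(D * (X[1] - X[0]) / h - chi * X[0] * (A[1] - A[0]) / h)
    return out


def _implicit_loss(name: str, state: Mapping[str, np.ndarray], params: ModelParameters,
                   aging: AgingProfile, schedule: TreatmentSchedule,
                   hypoxia_width: float) -> np.ndarray | float:
    """Linear-in-X loss coefficient treated implicitly (lagged where nonlinear)."""
    p = params
    Q = effective_Q(schedule)
    if name == "M1":
        return p.mu_M1
    if name == "M2":
        D = kinetics.hypoxia_switch_D(state["w"], p.w_i, hypoxia_width)
        return p.mu_M2 + p.mu_M2w * D
    if name == "F":
        D = kinetics.hypoxia_switch_D(state["w"], p.w_i, hypoxia_width)
        return p.mu_F + p.mu_Fw * D + p.lam_FFs * (1.0 - aging.eta)
    if name == "Fs":
        return p.mu_Fs + p.mu_FsQ * Q
    if name == "E":
        return p.mu_E
    if name == "P":
        return p.mu_P
    if name == "Ta":
        return p.mu_Ta
    if name == "Tb":
        return p.mu_Tb
    if name == "I6":
        return p.mu_I6
    if name == "V":
        return p.mu_V + p.mu_EV * state["E"] / (p.K_V + state["V"])
    if name == "w":
        c = p.c_w * (state["F"] + state["M2"])
        return c + (p.mu_w if p.mu_w_enabled else 0.0)
    raise KeyError(name)


def _advective_tendency(X: np.ndarray, v: np.ndarray, r: np.ndarray, h: float) -> np.ndarray:
    """-(1/r) d(r v X)/dr with first-order upwind fluxes; node N untouched."""
    r_face = 0.5 * (r[1:] + r[:-1])
    v_face = 0.5 * (v[1:] + v[:-1])
    X_up = np.where(v_face > 0, X[:-1], X[1:])
    flux = r_face * v_face * X_up
    out = np.zeros_like(X)
    out[1:-1] = -(flux[1:] - flux[:-1]) / (r[1:-1] * h)
    # half cell at the wound edge; the flux through the R face uses the
    # (upwind) edge value itself since v(R) < 0 draws from the interior side
    edge_flux = r[0] * v[0] * X[0]
    out[0] = -(flux[0] - edge_flux) / (r[0] * 0.5 * h)
    return out


def _chemotactic_tendency(X: np.ndarray, A: np.ndarray, chi: float, r: np.ndarray,
                          h: float) -> np.ndarray:
    """-(1/r) d(r chi X dA/dr)/dr, upwinded on the chemotactic velocity.

    The flux through the wound-edge face is zero: together with the zero
    diffusive flux there this realizes the zero total-flux condition.
    """
    r_face = 0.5 * (r[1:] + r[:-1])
    u_face = chi * (A[1:] - A[:-1]) / h
    X_up = np.where(u_face > 0, X[:-1], X[1:])
    flux = r_face * u_face * X_up
    out = np.zeros_like(X)
    out[1:-1] = -(flux[1:] - flux[:-1]) / (r[1:-1] * h)
    out[0] = -flux[0] / (r[0] * 0.5 * h)
    return out


def _mesh_tendency(X: np.ndarray, xi: np.ndarray, Rdot: float, h: float) -> np.ndarray:
    """Mesh-motion term (1 - xi) * dR/dt * dX/dr, upwinded; node N untouched."""
    a = (1.0 - xi) * Rdot
    out = np.zeros_like(X)
    if Rdot <= 0:
        # characteristics travel toward larger r in the mapped frame
        out[1:-1] = a[1:-1] * (X[1:-1] - X[:-2]) / h
        out[0] = a[0] * (X[1] - X[0]) / h
    else:
        out[0:-1] = a[0:-1] * (X[1:] - X[0:-1]) / h
    return out


def _diffusion_solve(X_expl: np.ndarray, name: str, D: float, coeff, dirichlet: float,
                     r: np.ndarray, h: float, dt: float) -> np.ndarray:
    """Backward-Euler solve of (I - dt L_diff + dt c) X = X_expl with X_N fixed.

    The wound-edge row is the half-cell finite volume with zero diffusive
    flux through the R face (the PDGF influx enters through the explicit
    part).
    """
    n = r.size - 1
    r_face = 0.5 * (r[1:] + r[:-1])
    main = np.empty(n + 1)
    lower = np.zeros(n)   # sub-diagonal entries a[j, j-1]
    upper = np.zeros(n)   # super-diagonal entries a[j, j+1]
    c = np.broadcast_to(np.asarray(coeff, dtype=float), (n + 1,))

    fac = dt * D / (h * h)
    main[1:-1] = 1.0 + dt * c[1:-1] + fac * (r_face[1:] + r_face[:-1]) / r[1:-1]
    lower[:-1] = -fac * r_face[:-1] / r[1:-1]    # a[j, j-1], j = 1..n-1
    upper[1:] = -fac * r_face[1:] / r[1:-1]      # a[j, j+1], j = 1..n-1
    # half cell at the edge
    main[0] = 1.0 + dt * c[0] + 2.0 * fac * r_face[0] / r[0]
    upper[0] = -2.0 * fac * r_face[0] / r[0]
    # Dirichlet row at B
    main[-1] = 1.0
    lower[-1] = 0.0

    rhs = X_expl.copy()
    rhs[-1] = dirichlet

    ab = np.zeros((3, n + 1))
    ab[0, 1:] = upper
    ab[1, :] = main
    ab[2, :-1] = lower
    return solve_banded((1, 1), ab, rhs)


def advance(state: SimulationState, dt_target: float, params: ModelParameters,
            aging: AgingProfile, schedule: TreatmentSchedule,
            profile: SolverProfile | None = None) -> tuple[SimulationState, float]:
    """One accepted IMEX step; returns the new state and the dt actually taken.

    The step solves the quasi-static velocity problem from the current ECM
    density, moves the free boundary with the edge velocity, transports and
    reacts all species in the front-fixed frame, and re-imposes the
    boundary conditions.  The step is shortened for the advective CFL limit
    and retried at half the step on positivity or finiteness failures.
    """
    profile = profile or SolverProfile()
    if dt_target <= 0:
        raise ValueError(f"dt_target must be positive, got {dt_target}")
    p = params
    grid = state.grid
    r, h, xi = grid.r, grid.h, grid.xi
    fields = state.fields

    vel = mechanics.solve_velocity(fields["rho"], r, p.gamma, p.rho1)
    Rdot = vel.v_edge
    v = vel.v

    # CFL limit from material + mesh + chemotactic speeds
    u_rel = np.abs(v - (1.0 - xi) * Rdot)
    u_chem = 0.0
    for name, (chi_name, attract) in CHEMOTAXIS.items():
        A = fields[attract]
        u_chem = max(u_chem, getattr(p, chi_name) * np.max(np.abs(np.diff(A))) / h)
    u_max = max(np.max(u_rel), u_chem, 1e-12)
    dt = min(dt_target, profile.cfl * h / u_max)

    scales = {**{k: v_ for k, v_ in p.boundary_values().items()}, "rho": p.rho_m}
    rates = kinetics.reaction_rhs(
        {k: np.maximum(f, 0.0) for k, f in fields.items()}, state.t, aging, schedule,
        p, R_t=grid.R, check=False, hypoxia_width=profile.hypoxia_width,
    )

    for attempt in range(profile.max_retries):
        new_fields: dict[str, np.ndarray] = {}
        ok = True
        # --- ECM: advection only, fully explicit ---
        rho = fields["rho"]
        tend = _advective_tendency(rho, v, r, h) + _mesh_tendency(rho, xi, Rdot, h)
        # wound-edge node: relative motion vanishes, the local balance is
        # rho_t = -rho (v_r + v/r) + F_rho with v_r(R) = Psi(rho(R))
        tend[0] = -rho[0] * (vel.dvdr_edge + v[0] / r[0])
        # healthy boundary: v(B) = 0, compression only through v_r(B)
        tend[-1] = -rho[-1] * (v[-1] - v[-2]) / h
        rho_new = rho + dt * (tend + rates["rho"])
        new_fields["rho"] = rho_new

        bv = p.boundary_values()
        if profile.fs_boundary_scaled:
            bv["Fs"] = bv["Fs"] * (1.0 - aging.eta)
        bv["w"] = kinetics.hbot_boundary_oxygen(
            state.t + dt, schedule, p.w0, profile.hbot_accrue_from_start
        )

        for name in DIFFUSING:
            X = fields[name]
            c_imp = _implicit_loss(name, fields, p, aging, schedule, profile.hypoxia_width)
            expl = rates[name] + np.asarray(c_imp) * X  # add back the implicit loss
            expl = expl + _mesh_tendency(X, xi, Rdot, h)
            if name in CELLS:
                expl = expl + _advective_tendency(X, v, r, h)
            if name in CHEMOTAXIS:
                chi_name, attract = CHEMOTAXIS[name]
                expl = expl + _chemotactic_tendency(X, fields[attract], getattr(p, chi_name), r, h)
            D = getattr(p, f"D_{name}")
            expl0_bc = 0.0
            if name == "P":
                # PDGF influx through the wound-edge face: -dP/dr = beta_P R
                expl0_bc = 2.0 * D * p.beta_P * grid.R / h
            rhs = X + dt * expl
            rhs[0] += dt * expl0_bc
            X_new = _diffusion_solve(rhs, name, D, c_imp, bv[name], r, h, dt)
            new_fields[name] = X_new

        # --- positivity / sanity audit ---
        for name, X_new in new_fields.items():
            if not np.all(np.isfinite(X_new)):
                ok = False
                break
            if np.min(X_new) < -1e-6 * scales[name]:
                ok = False
                break
        if ok:
            break
        dt *= 0.5
        if dt < 1e-12:
            raise IntegrationError(
                f"step-size underflow at t = {state.t:.6f} (species {name})", state
            )
    else:
        raise IntegrationError(
            f"no acceptable step after {profile.max_retries} retries at t = {state.t:.6f}",
            state,
        )

    for name, X_new in new_fields.items():
        np.maximum(X_new, 0.0, out=X_new)

    R_new = grid.R + dt * Rdot
    R_new = min(max(R_new, 0.5 * profile.r_min), p.B - 1e-9)
    new_grid = RadialGrid(grid.n, R_new, grid.B)
    new_state = SimulationState(new_grid, new_fields, v, state.t + dt)
    apply_boundary_conditions(new_state, p, schedule, aging, profile)
    return new_state, dt


def _window_edges(schedule: TreatmentSchedule, horizon: float) -> np.ndarray:
    if not schedule.hbot_active:
        return np.empty(0)
    start, end = schedule.hbot_window
    days = np.arange(0.0, np.ceil(horizon) + 1.0)
    edges = np.concatenate([days + start / 24.0, days + end / 24.0])
    return np.sort(edges[(edges > 0) & (edges < horizon)])


def run_simulation(params: ModelParameters, aging: AgingProfile,
                   schedule: TreatmentSchedule, horizon: float = 30.0,
                   snapshot_times: Iterable[float] = (),
                   profile: SolverProfile | None = None) -> SimulationResult:
    """Integrate from the initial wound to ``horizon`` days or closure.

    Deterministic for a given configuration.  Records R(t) and PWC(t) at
    least daily and at HBOT window edges; optional full-field snapshots at
    the requested times.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    profile = profile or SolverProfile()
    p = params
    state = initialize(p, aging, profile)
    R0 = p.R0

    snapshot_times = sorted(set(float(s) for s in snapshot_times))
    record_times = np.arange(0.0, horizon + 1e-12, profile.record_interval)
    events = np.unique(np.concatenate([
        record_times, _window_edges(schedule, horizon), np.asarray(snapshot_times), [horizon],
    ]))
    events = events[(events > 0) & (events <= horizon + 1e-12)]

    ts = [0.0]
    Rs = [R0]
    steps = 0
    status = "horizon_reached"
    snapshots: dict[float, SimulationState] = {}
    if snapshot_times and snapshot_times[0] == 0.0:
        snapshots[0.0] = state.copy()

    try:
        for t_event in events:
            while state.t < t_event - 1e-12:
                in_window = schedule.hbot_active and kinetics.in_hbot_window(state.t, schedule)
                dt_cap = profile.dt_window if in_window else profile.dt_max
                dt_target = min(dt_cap, t_event - state.t)
                state, _ = advance(state, dt_target, p, aging, schedule, profile)
                steps += 1
                if state.grid.R <= profile.r_min:
                    status = "closed"
                    break
            ts.append(state.t)
            Rs.append(state.grid.R)
            if any(abs(t_event - s) < 1e-9 for s in snapshot_times):
                snapshots[t_event] = state.copy()
            if status == "closed":
                break
    except IntegrationError as exc:
        status = "failed"
        snapshots[state.t] = exc.state.copy() if exc.state is not None else state.copy()

    t_arr = np.asarray(ts)
    R_arr = np.asarray(Rs)
    pwc = 100.0 * (R0 - R_arr) / R0
    if status == "closed":
        pwc[-1] = 100.0
    return SimulationResult(
        t=t_arr, R=R_arr, pwc=pwc, status=status, R0=R0, snapshots=snapshots,
        diagnostics={"steps": steps, "n": profile.n, "dt_max": profile.dt_max},
    )
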