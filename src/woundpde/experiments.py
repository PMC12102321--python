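"""Study designs: treatment-arm tables, (eta, A0) plane sweeps, closure regions.

The four treatment arms are no drug, quercetin alone (Q), hyperbaric oxygen
alone (HBOT) and the combination (HBOT+Q).  A "patient" is a biological age
pair (eta, A0); rosters of named patients are evaluated at a fixed day
(typically 30 or 45) by the percent wound closure

    PWC(t) = 100 * (R(0) - R(t)) / R(0).

Plane sweeps evaluate PWC(day) on a dense (eta, A0) grid per arm; the
equi-PWC region extraction compares the HBOT and HBOT+Q grids at a closure
level and returns the band of ages treatable only by the combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .parameters import AgingProfile, ModelParameters, TreatmentSchedule
from .solver import SolverProfile, run_simulation

__all__ = [
    "ARMS",
    "PatientRoster",
    "SweepGrid",
    "pwc",
    "make_schedule",
    "run_arm_table",
    "sweep_age_plane",
    "extract_equi_pwc_region",
    "TABLE2_PATIENTS",
    "TABLE3_PATIENTS",
]

ARMS = ("none", "Q", "HBOT", "HBOT+Q")

#: reference quercetin dose (g/d) and HBOT oxygen source (g/cm^3/d)
DEFAULT_Q = 1.0
DEFAULT_GAMMA_W = 1.2e-6

#: named patients evaluated at day 30, ordered oldest to youngest
TABLE2_PATIENTS = [
    ("1", 0.15, 0.56),
    ("2", 0.3, 0.67),
    ("3", 0.6, 0.78),
    ("4", 0.7, 0.89),
    ("5", 0.92, 1.0),
]

#: older patients evaluated at day 45, ordered oldest to youngest
TABLE3_PATIENTS = [
    ("6", 0.0, 0.0),
    ("7", 0.001, 0.11),
    ("8", 0.003, 0.22),
    ("9", 0.004, 0.33),
    ("10", 0.03, 0.44),
]


def pwc(R0: float, Rt: float) -> float:
    """Percent wound closure 100 * (R0 - Rt) / R0."""
    if R0 <= 0:
        raise ValueError(f"initial radius must be positive, got {R0}")
    if Rt < 0:
        raise ValueError(f"current radius must be non-negative, got {Rt}")
    return 100.0 * (R0 - Rt) / R0


@dataclass(frozen=True)
class PatientRoster:
    """Ordered list of labelled (eta, A0) patients and an evaluation day."""

    patients: tuple[tuple[str, float, float], ...]
    day: float = 30.0

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.patients]
        if len(set(labels)) != len(labels):
            raise ValueError("patient labels must be unique")
        for label, eta, A0 in self.patients:
            AgingProfile(eta, A0)  # validates the [0, 1] ranges

    @staticmethod
    def table2() -> "PatientRoster":
        return PatientRoster(tuple(TABLE2_PATIENTS), day=30.0)

    @staticmethod
    def table3() -> "PatientRoster":
        return PatientRoster(tuple(TABLE3_PATIENTS), day=45.0)


def make_schedule(arm: str, Q: float = DEFAULT_Q, gamma_w: float = DEFAULT_GAMMA_W) -> TreatmentSchedule:
    """Treatment schedule for a named arm."""
    if arm == "none":
        return TreatmentSchedule.none()
    if arm == "Q":
        return TreatmentSchedule.quercetin(Q)
    if arm == "HBOT":
        return TreatmentSchedule.hbot(gamma_w)
    if arm == "HBOT+Q":
        return TreatmentSchedule.hbot_plus_quercetin(Q, gamma_w)
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def run_arm_table(roster: PatientRoster, arms: tuple[str, ...] = ARMS,
                  params: ModelParameters | None = None,
                  Q: float = DEFAULT_Q, gamma_w: float = DEFAULT_GAMMA_W,
                  profile: SolverProfile | None = None,
                  decimals: int | None = 2) -> pd.DataFrame:
    """PWC(day) for every (patient, arm): one simulation per cell.

    Cells where the wound closed before the evaluation day report exactly
    100; failed simulations report NaN.  The result is a DataFrame with one
    row per arm and one column per patient label.
    """
    params = params or ModelParameters()
    table: dict[str, list[float]] = {label: [] for label, *_ in roster.patients}
    for arm in arms:
        schedule = make_schedule(arm, Q, gamma_w)
        for label, eta, A0 in roster.patients:
            res = run_simulation(params, AgingProfile(eta, A0), schedule,
                                 horizon=roster.day, profile=profile)
            val = np.nan if res.status == "failed" else res.pwc_at(roster.day)
            if decimals is not None and np.isfinite(val):
                val = round(val, decimals)
            table[label].append(val)
    df = pd.DataFrame(table, index=list(arms))
    df.index.name = "arm"
    return df


@dataclass
class SweepGrid:
    """PWC(day) on a rectangular (eta, A0) grid for one treatment arm."""

    eta: np.ndarray
    a0: np.ndarray
    pwc: np.ndarray       # shape (len(eta), len(a0))
    arm: str
    day: float

    def __post_init__(self) -> None:
        if self.pwc.shape != (self.eta.size, self.a0.size):
            raise ValueError("PWC matrix shape must match the axis lengths")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pwc, index=pd.Index(self.eta, name="eta"),
                            columns=pd.Index(self.a0, name="A0"))


def sweep_age_plane(eta_range: tuple[float, float], a0_range: tuple[float, float],
                    resolution: int, arm: str, day: float = 30.0,
                    params: ModelParameters | None = None,
                    profile: SolverProfile | None = None,
                    Q: float = DEFAULT_Q, gamma_w: float = DEFAULT_GAMMA_W) -> SweepGrid:
    """Dense PWC(day) matrix over the biological-age plane for one arm.

    Per-node failures propagate as NaN; the sweep is deterministic.
    """
    if resolution < 2 and not (eta_range[0] == eta_range[1] and a0_range[0] == a0_range[1]):
        raise ValueError("resolution must be >= 2 per axis")
    params = params or ModelParameters()
    schedule = make_schedule(arm, Q, gamma_w)
    n = max(resolution, 1)
    eta_vals = np.linspace(*eta_range, n) if eta_range[0] != eta_range[1] else np.array([eta_range[0]])
    a0_vals = np.linspace(*a0_range, n) if a0_range[0] != a0_range[1] else np.array([a0_range[0]])
    out = np.full((eta_vals.size, a0_vals.size), np.nan)
    for i, eta in enumerate(eta_vals):
        for j, a0 in enumerate(a0_vals):
            res = run_simulation(params, AgingProfile(eta, a0), schedule,
                                 horizon=day, profile=profile)
            if res.status != "failed":
                out[i, j] = res.pwc_at(day)
    return SweepGrid(eta=eta_vals, a0=a0_vals, pwc=out, arm=arm, day=day)


def _contours(grid: SweepGrid, level: float) -> list[np.ndarray]:
    """Marching-squares polylines of PWC = level, in (eta, A0) coordinates."""
    lines = measure.find_contours(grid.pwc, level)
    out = []
    for line in lines:
        eta = np.interp(line[:, 0], np.arange(grid.eta.size), grid.eta)
        a0 = np.interp(line[:, 1], np.arange(grid.a0.size), grid.a0)
        out.append(np.column_stack([eta, a0]))
    return out


def extract_equi_pwc_region(grid_hbot: SweepGrid, grid_qhbot: SweepGrid,
                            level: float = 100.0, closure_tol: float = 1e-6) -> dict:
    """Ages treatable by HBOT+Q but not by HBOT alone at the given PWC level.

    Returns the boolean membership mask, its (eta, A0) cell centers, and the
    two marching-squares contour polylines PWC = level on each grid.  The
    region is {(eta, A0) : PWC_QHBOT >= level > PWC_HBOT}; for level = 100
    a tolerance absorbs the discrete closure threshold.
    """
    if not (np.array_equal(grid_hbot.eta, grid_qhbot.eta)
            and np.array_equal(grid_hbot.a0, grid_qhbot.a0)):
        raise ValueError("the two sweep grids must share axes")
    if not (0.0 < level <= 100.0):
        raise ValueError(f"level must lie in (0, 100], got {level}")
    eff = level - closure_tol if level == 100.0 else level
    mask = (grid_qhbot.pwc >= eff) & (grid_hbot.pwc < eff)
    finite = np.isfinite(grid_hbot.pwc) & np.isfinite(grid_qhbot.pwc)
    mask &= finite
    lo = min(np.nanmin(grid_hbot.pwc), np.nanmin(grid_qhbot.pwc))
    hi = max(np.nanmax(grid_hbot.pwc), np.nanmax(grid_qhbot.pwc))
    warning = None
    if not (lo <= eff <= hi):
        warning = f"level {level} outside the sampled PWC range [{lo:.2f}, {hi:.2f}]"
    ee, aa = np.meshgrid(grid_hbot.eta, grid_hbot.a0, indexing="ij")
    return {
        "mask": mask,
        "points": np.column_stack([ee[mask], aa[mask]]),
        "contour_hbot": _contours(grid_hbot, eff),
        "contour_qhbot": _contours(grid_qhbot, eff),
        "level": level,
        "warning": warning,
    }
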