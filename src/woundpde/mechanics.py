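"""Tissue mechanics: ECM pressure and the quasi-static radial velocity.

The partially healed annulus R(t) <= r <= B is modeled as a single-phase
upper convected Maxwell fluid moving with a scalar radial velocity v(r, t).
On the slow timescale of healing the momentum balance is quasi-static,

    (1/r) d/dr ( r dv/dr ) - v / r^2 = dPsi/dr,

with v(B) = 0 at the healthy-tissue boundary and dv/dr = Psi at the wound
edge r = R(t).  Psi(rho) is the internal isotropic pressure generated by the
ECM once its density exceeds the threshold rho_1.

The radial operator equals d/dr[(1/r) d(rv)/dr], so the ODE integrates
exactly once to (1/r) d(rv)/dr = Psi + C.  Together with the two boundary
conditions this yields a closed quadrature representation

    r v(r) = u_R [1 + (r^2 - R^2) / (2 R^2)] + int_R^r s Psi(s) ds,
    u_R = R v(R) = -2 R^2 I / (R^2 + B^2),   I = int_R^B s Psi(s) ds,

which the solver evaluates with cumulative trapezoidal quadrature (second
order in the grid spacing; exact whenever s*Psi(s) is piecewise linear, in
particular for constant Psi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VelocityField", "pressure_psi", "solve_velocity", "boundary_speed"]


class VelocitySolveError(RuntimeError):
    """The velocity problem is degenerate (bad grid or geometry)."""


@dataclass(frozen=True)
class VelocityField:
    """Radial tissue velocity on the current grid of the annulus [R, B]."""

    r: np.ndarray          # radii, strictly increasing, r[0] = R, r[-1] = B (cm)
    v: np.ndarray          # velocity (cm/d); v[-1] = 0 exactly
    v_edge: float          # v(R), the wound-edge speed dR/dt
    dvdr_edge: float       # dv/dr at r = R (equals Psi(rho(R)) by construction)


def pressure_psi(rho, gamma: float, rho1: float):
    """ECM pressure Psi(rho): zero below the threshold, linear above.

    Psi = 0 for rho <= rho1 and gamma * (rho/rho1 - 1) for rho > rho1;
    continuous (with a kink) at rho = rho1.  Accepts scalars or arrays.
    """
    rho = np.asarray(rho, dtype=float)
    if rho1 <= 0:
        raise ValueError(f"rho1 must be positive, got {rho1!r}")
    psi = gamma * (rho / rho1 - 1.0)
    out = np.where(rho > rho1, psi, 0.0)
    return float(out) if out.ndim == 0 else out


def solve_velocity(rho: np.ndarray, r: np.ndarray, gamma: float, rho1: float,
                   psi: np.ndarray | None = None) -> VelocityField:
    """Solve the quasi-static velocity BVP on the annulus grid ``r``.

    Parameters
    ----------
    rho : ECM density at each node of ``r`` (ignored when ``psi`` is given).
    r : strictly increasing radii with r[0] = R(t) > 0 and r[-1] = B.
    psi : optionally a precomputed pressure profile.  With ``len(r)`` values
        it is nodal and integrated by trapezoid; with ``len(r) - 1`` values
        it is piecewise constant per interval and integrated exactly.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise VelocitySolveError("grid must contain at least two nodes")
    if r[0] <= 0:
        raise VelocitySolveError(f"wound radius must be positive, got R = {r[0]}")
    if np.any(np.diff(r) <= 0):
        raise VelocitySolveError("grid radii must be strictly increasing")
    if psi is None:
        psi = pressure_psi(np.asarray(rho, dtype=float), gamma, rho1)
    psi = np.asarray(psi, dtype=float)
    R, B = r[0], r[-1]
    if psi.shape == (r.size - 1,):
        # piecewise-constant pressure per interval: integrate s*Psi exactly
        seg = psi * 0.5 * (r[1:] ** 2 - r[:-1] ** 2)
        psi_edge = psi[0]
    elif psi.shape == r.shape:
        s_psi = r * psi
        seg = 0.5 * (s_psi[1:] + s_psi[:-1]) * np.diff(r)
        psi_edge = psi[0]
    else:
        raise VelocitySolveError("psi/rho and r must have matching shapes")
    # cumulative integral of s*Psi from R to each node
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    I = cum[-1]
    u_R = -2.0 * R * R * I / (R * R + B * B)
    u = u_R * (1.0 + (r * r - R * R) / (2.0 * R * R)) + cum
    v = u / r
    v[-1] = 0.0  # exact Dirichlet node (analytically zero already)
    v_edge = u_R / R
    # from the first integral: dv/dr = Psi + C - v/r with C = v(R)/R
    dvdr_edge = psi_edge + v_edge / R - v[0] / R
    if not np.all(np.isfinite(v)):
        raise VelocitySolveError("non-finite velocity solution")
    return VelocityField(r=r, v=v, v_edge=float(v_edge), dvdr_edge=float(dvdr_edge))


def boundary_speed(field: VelocityField) -> float:
    """Wound-edge speed dR/dt = v(R(t), t); negative values close the wound."""
    return field.v_edge
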