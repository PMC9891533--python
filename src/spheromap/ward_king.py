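"""Simplified Ward--King multiphase spheroid model.

A moving-boundary PDE system for the living-cell fraction n(r, t), the
cellular-material fraction p(r, t) = 1 - n (no voids), and a nutrient
concentration c(r, t) in diffusive equilibrium.  Cells proliferate at a
Hill-type nutrient-dependent rate k_m(c) and die at a rate k_d(c) that
rises as nutrient falls; the nutrient is consumed at rate alpha * k_m(c).
Material diffuses with diffusivity Dp, enters through the spheroid surface
at flux rate Qp from a medium with material fraction p0, and the boundary
R(t) moves with the local material velocity.

With no voids the velocity field satisfies div(v) = -Dp * laplacian(n), so
v = -Dp dn/dr, and the cell fraction obeys

    dn/dt + v dn/dr = n Dp laplacian(n) + (k_m(c) - k_d(c)) n.

Numerics: Landau transformation rho = r / R(t) maps the domain to [0, 1];
second-order central differences in rho; the quasi-steady nutrient
two-point boundary value problem is re-solved by a damped Newton iteration
at every right-hand-side evaluation (warm-started from the previous
solve); time stepping uses a stiff adaptive integrator.  The coordinate
singularity at rho = 0 is handled by the spherical symmetry limit
(laplacian -> 3 d2/dr2).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .growth_models import CrowdingCurve, TimeGrid, Trajectory, as_time_grid

__all__ = [
    "WKParams",
    "WKState",
    "wk_growth_rate",
    "wk_death_rate",
    "solve_ward_king",
    "wk_empirical_crowding",
]


@dataclasses.dataclass(frozen=True)
class WKParams:
    """Ward--King parameters.

    lam, delta : maximum per-volume growth / death rates (d^-1)
    c1, c2     : half-maximum nutrient levels for growth and death
    alpha      : nutrient consumption coefficient (um^-2 d; multiplies
                 k_m(c) in the quasi-steady nutrient equation posed in
                 dimensional radius)
    Dp         : cellular-material diffusivity (um^2 d^-1)
    Qp         : boundary material-inflow rate (um d^-1)
    p0         : material fraction in the surrounding medium
    m1, m2     : Hill exponents, fixed at 10 to emulate threshold switches
    n0         : initial (uniform) cell fraction
    """

    lam: float
    delta: float
    c1: float
    c2: float
    alpha: float
    Dp: float
    Qp: float
    p0: float
    m1: float = 10.0
    m2: float = 10.0
    n0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lam", "delta", "alpha", "Dp", "Qp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        for name in ("c1", "c2"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("p0", "n0"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclasses.dataclass(frozen=True)
class WKState:
    """Profile snapshot on the normalised radial grid rho = r / R(t)."""

    rho: np.ndarray
    n: np.ndarray
    c: np.ndarray
    v: np.ndarray
    R: float
    t: float

    @property
    def p(self) -> np.ndarray:
        """Material fraction from the no-void constraint."""
        return 1.0 - self.n


def wk_growth_rate(c, p: WKParams):
    """Hill growth rate k_m(c) = lam c^m1 / (c1^m1 + c^m1)."""
    c = np.asarray(c, dtype=float)
    out = p.lam * c**p.m1 / (p.c1**p.m1 + c**p.m1)
    return out if out.ndim else float(out)


def wk_death_rate(c, p: WKParams):
    """Hill death rate k_d(c) = delta (1 - c^m2 / (c2^m2 + c^m2))."""
    c = np.asarray(c, dtype=float)
    out = p.delta * (1.0 - c**p.m2 / (p.c2**p.m2 + c**p.m2))
    return out if out.ndim else float(out)


def _growth_rate_deriv(c: np.ndarray, p: WKParams) -> np.ndarray:
    cm = c**p.m1
    denom = (p.c1**p.m1 + cm) ** 2
    with np.errstate(invalid="ignore"):
        d = p.lam * p.m1 * c ** (p.m1 - 1.0) * p.c1**p.m1 / denom
    return np.where(np.isfinite(d), d, 0.0)


def _solve_nutrient(
    u: np.ndarray, R: float, p: WKParams, rho: np.ndarray, c_init: np.ndarray
) -> np.ndarray:
    """Quasi-steady nutrient profile from laplacian(c) = alpha k_m(c) n.

    Discretised on the rho grid and solved by damped Newton iteration with
    a tridiagonal Jacobian; boundary conditions c'(0) = 0, c(1) = 1.
    """
    m = rho.size
    h = rho[1] - rho[0]
    scale = p.alpha * R * R
    if scale == 0.0:
        return np.ones(m)
    c = np.clip(c_init.copy(), 0.0, 1.0)
    c[-1] = 1.0

    def residual(cv: np.ndarray) -> np.ndarray:
        f = np.empty(m)
        f[0] = 6.0 * (cv[1] - cv[0]) / h**2 - scale * wk_growth_rate(cv[0], p) * u[0]
        lap = (cv[2:] - 2.0 * cv[1:-1] + cv[:-2]) / h**2 + (
            cv[2:] - cv[:-2]
        ) / (h * rho[1:-1])
        f[1:-1] = lap - scale * np.asarray(wk_growth_rate(cv[1:-1], p)) * u[1:-1]
        f[-1] = cv[-1] - 1.0
        return f

    for _ in range(60):
        f = residual(c)
        norm = np.max(np.abs(f))
        if norm < 1e-10 * max(1.0, scale):
            break
        km_d = _growth_rate_deriv(c, p)
        diag = np.empty(m)
        diag[0] = -6.0 / h**2 - scale * km_d[0] * u[0]
        diag[1:-1] = -2.0 / h**2 - scale * km_d[1:-1] * u[1:-1]
        diag[-1] = 1.0
        lower = np.zeros(m)
        upper = np.zeros(m)
        upper[1] = 6.0 / h**2  # J[0, 1]
        upper[2:] = 1.0 / h**2 + 1.0 / (h * rho[1:-1])  # J[i, i+1]
        lower[:-2] = 1.0 / h**2 - 1.0 / (h * rho[1:-1])  # J[i, i-1]
        lower[-2] = 0.0  # boundary row
        ab = np.vstack([upper, diag, lower])
        step = solve_banded((1, 1), ab, -f)
        # damped update with projection into [0, 1]
        lam_damp = 1.0
        for _ in range(8):
            trial = np.clip(c + lam_damp * step, 0.0, 1.0)
            trial[-1] = 1.0
            if np.max(np.abs(residual(trial))) < norm or lam_damp < 1e-3:
                break
            lam_damp *= 0.5
        c = trial
    else:
        raise RuntimeError(
            f"nutrient BVP failed to converge (R={R:.3g}, residual={norm:.3g})"
        )
    return c


class _WKDiscretisation:
    """Mutable helper carrying the grid and a warm-start nutrient cache."""

    def __init__(self, p: WKParams, n_rho: int):
        self.p = p
        self.rho = np.linspace(0.0, 1.0, n_rho)
        self.h = self.rho[1] - self.rho[0]
        self.c_cache = np.ones(n_rho)

    def nutrient(self, u: np.ndarray, R: float) -> np.ndarray:
        c = _solve_nutrient(u, R, self.p, self.rho, self.c_cache)
        self.c_cache = c
        return c

    def velocity(self, u: np.ndarray, R: float) -> np.ndarray:
        """v(rho) = -(Dp / R) du/drho, with the Robin boundary slope."""
        p = self.p
        h = self.h
        du = np.empty_like(u)
        du[0] = 0.0
        du[1:-1] = (u[2:] - u[:-2]) / (2.0 * h)
        du[-1] = R * p.Qp / p.Dp * (1.0 - p.p0 - u[-1]) if p.Dp > 0 else 0.0
        return -(p.Dp / R) * du

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        rho, h = self.rho, self.h
        u = y[:-1]
        R = y[-1]
        if R <= 0 or not np.all(np.isfinite(u)):
            raise RuntimeError(f"Ward-King state became invalid at t={t:.4g}")
        c = self.nutrient(u, R)
        v = self.velocity(u, R)
        dRdt = -p.Qp * (1.0 - p.p0 - u[-1])

        # first derivative of u in rho (central; symmetric at 0, Robin at 1)
        u_r = np.empty_like(u)
        u_r[0] = 0.0
        u_r[1:-1] = (u[2:] - u[:-2]) / (2.0 * h)
        g = R * p.Qp / p.Dp * (1.0 - p.p0 - u[-1]) if p.Dp > 0 else 0.0
        u_r[-1] = g
        # laplacian of u in rho with ghost node at rho = 1 + h
        lap = np.empty_like(u)
        lap[0] = 6.0 * (u[1] - u[0]) / h**2
        lap[1:-1] = (u[2:] - 2.0 * u[1:-1] + u[:-2]) / h**2 + (
            u[2:] - u[:-2]
        ) / (h * rho[1:-1])
        ghost = u[-2] + 2.0 * h * g
        lap[-1] = (ghost - 2.0 * u[-1] + u[-2]) / h**2 + 2.0 * g
        adv = (rho * dRdt - v) / R
        du = adv * u_r + u * (p.Dp / R**2) * lap + (
            np.asarray(wk_growth_rate(c, p)) - np.asarray(wk_death_rate(c, p))
        ) * u
        return np.append(du, dRdt)


def solve_ward_king(
    p: WKParams,
    R0: float = 10.0,
    grid=None,
    n_rho: int = 101,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> tuple[Trajectory, list[WKState]]:
    """Integrate the Ward--King system; return R(t) and profile snapshots.

    The state snapshots (one per output time) carry the cell fraction,
    nutrient, and velocity profiles on the normalised grid.
    """
    if n_rho < 20:
        raise ValueError("n_rho must be at least 20")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    tg = as_time_grid(grid)
    disc = _WKDiscretisation(p, n_rho)
    y0 = np.append(np.full(n_rho, float(p.n0)), float(R0))
    t = tg.times
    t0 = t[0]
    sol = solve_ivp(
        disc.rhs,
        (t0, t[-1]) if t[-1] > t0 else (t0, t0 + 1e-9),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"Ward-King integration failed: {sol.message}; "
            f"last state R={sol.y[-1, -1] if sol.y.size else 'n/a'}"
        )
    states: list[WKState] = []
    for k, tk in enumerate(t):
        u = sol.y[:-1, k]
        R = float(sol.y[-1, k])
        c = disc.nutrient(u, R)
        v = disc.velocity(u, R)
        states.append(WKState(rho=disc.rho.copy(), n=u.copy(), c=c, v=v, R=R, t=float(tk)))
    radius = sol.y[-1, :].copy()
    traj = Trajectory(tg, radius)
    return traj, states


def wk_empirical_crowding(traj: Trajectory, lam: float) -> CrowdingCurve:
    """Empirical crowding function f(R) = 3/(lam R) dR/dt.

    dR/dt is estimated by centred finite differences of the trajectory
    (one-sided at the ends); applicable to any model's output, including
    PDE models with no closed-form crowding function.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    t = traj.times.times
    r = traj.radius
    if t.size < 3:
        raise ValueError("need at least 3 trajectory points to differentiate")
    drdt = np.gradient(r, t)
    f = 3.0 * drdt / (lam * r)
    return CrowdingCurve(r.copy(), f)
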