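"""Radial growth laws for avascular tumour spheroids.

The models form a hierarchy ordered by mechanistic detail: the logistic,
bounded-Gompertz and Richards models are phenomenological sigmoids in the
spheroid radius R(t); the radial-death model adds an explicit necrotic core
of fixed rim thickness; the Greenspan model resolves nutrient-limited
growth arrest and necrosis through implicitly defined inner radii.  All
models are written in the generalised-logistic form

    dR/dt = (lam / 3) * R * f(R),

where ``lam`` (units d^-1) is the maximum *volumetric* growth rate (the
factor 1/3 converts volume growth to radial growth) and ``f`` is the model's
crowding function, with f -> 0 as growth saturates.

Closed forms are used wherever they exist (logistic, bounded Gompertz,
Richards, and the pure-exponential early phases of the radial-death and
Greenspan models); the remaining dynamics are integrated with an adaptive
Runge--Kutta scheme at tight tolerances.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "TimeGrid",
    "Trajectory",
    "LogisticParams",
    "GompertzParams",
    "RichardsParams",
    "RadialDeathParams",
    "GreenspanParams",
    "CrowdingCurve",
    "solve_logistic",
    "solve_bounded_gompertz",
    "solve_richards",
    "solve_radial_death",
    "greenspan_inner_radii",
    "solve_greenspan",
    "crowding_function",
    "DEFAULT_R0",
]

#: Initial spheroid radius in micrometres, treated as known and directly
#: measurable; kept well below the limiting size so the simple models stay
#: identifiable.  Overridable in every solver.
DEFAULT_R0 = 10.0

_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-10


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{name} must be non-negative and finite, got {value!r}")


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times in days, starting at t >= 0."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a non-empty 1-d array")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        if t[0] < 0:
            raise ValueError("times must start at t >= 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


def as_time_grid(grid) -> TimeGrid:
    """Coerce an array-like of times to a :class:`TimeGrid`."""
    if isinstance(grid, TimeGrid):
        return grid
    return TimeGrid(np.asarray(grid, dtype=float))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Model-predicted spheroid radius at the observation times.

    ``inner_radius`` and ``necrotic_radius`` (Greenspan's R_i and R_n) are
    populated only by models that resolve the inner spheroid structure.
    """

    times: TimeGrid
    radius: np.ndarray
    inner_radius: Optional[np.ndarray] = None
    necrotic_radius: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radius, dtype=float)
        if r.shape != self.times.times.shape:
            raise ValueError("radius length must match times")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError("radius must be positive and finite")
        object.__setattr__(self, "radius", r)
        for name in ("inner_radius", "necrotic_radius"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != r.shape:
                    raise ValueError(f"{name} length must match times")
                object.__setattr__(self, name, v)
        ri, rn = self.inner_radius, self.necrotic_radius
        if ri is not None and rn is not None:
            if np.any(rn < -1e-9) or np.any(rn > ri + 1e-9) or np.any(ri > r + 1e-9):
                raise ValueError("inner radii must satisfy 0 <= R_n <= R_i <= R")


@dataclasses.dataclass(frozen=True)
class CrowdingCurve:
    """Sampled crowding function f(R) = 3/(lam R) dR/dt."""

    radius: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radius, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if r.shape != f.shape:
            raise ValueError("radius and f must have equal length")
        object.__setattr__(self, "radius", r)
        object.__setattr__(self, "f", f)


@dataclasses.dataclass(frozen=True)
class LogisticParams:
    """lam: volumetric growth rate (d^-1); Rmax: maximum radius (um)."""

    lam: float
    Rmax: float

    def __post_init__(self) -> None:
        _check_nonnegative(lam=self.lam)
        _check_positive(Rmax=self.Rmax)


@dataclasses.dataclass(frozen=True)
class GompertzParams:
    """Bounded-Gompertz parameters: lam (d^-1) and Rmax (um)."""

    lam: float
    Rmax: float

    def __post_init__(self) -> None:
        _check_nonnegative(lam=self.lam)
        _check_positive(Rmax=self.Rmax)


@dataclasses.dataclass(frozen=True)
class RichardsParams:
    """lam (d^-1), Rmax (um) and dimensionless shape beta > 0.

    beta = 1 recovers the logistic model; beta -> 0+ the standard Gompertz.
    """

    lam: float
    Rmax: float
    beta: float

    def __post_init__(self) -> None:
        _check_nonnegative(lam=self.lam)
        _check_positive(Rmax=self.Rmax, beta=self.beta)


@dataclasses.dataclass(frozen=True)
class RadialDeathParams:
    """lam (d^-1), necrotic loss rate zeta (d^-1), viable rim Rd (um)."""

    lam: float
    zeta: float
    Rd: float

    def __post_init__(self) -> None:
        _check_nonnegative(lam=self.lam, zeta=self.zeta)
        _check_positive(Rd=self.Rd)


@dataclasses.dataclass(frozen=True)
class GreenspanParams:
    """Composite Greenspan parameters.

    Q in (0, 1) is the relative nutrient-threshold composite, Rd (um) the
    spheroid radius at necrosis onset, gamma = zeta/lam the dimensionless
    necrotic loss ratio, and lam (d^-1) the volumetric growth rate.
    """

    Q: float
    Rd: float
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.Q) or not (0 < self.Q < 1):
            raise ValueError(f"Q must lie in (0, 1), got {self.Q!r}")
        _check_positive(Rd=self.Rd)
        _check_nonnegative(gamma=self.gamma, lam=self.lam)


def _validate_solver_inputs(R0: float, grid) -> TimeGrid:
    _check_positive(R0=R0)
    return as_time_grid(grid)


def solve_logistic(p: LogisticParams, R0: float = DEFAULT_R0, grid=None) -> Trajectory:
    """Logistic radial growth dR/dt = (lam/3) R (1 - R/Rmax), closed form."""
    tg = _validate_solver_inputs(R0, grid)
    t = tg.times
    if p.lam == 0.0:
        radius = np.full_like(t, R0)
    else:
        radius = p.Rmax / (1.0 + (p.Rmax / R0 - 1.0) * np.exp(-p.lam * t / 3.0))
    return Trajectory(tg, radius)


def solve_bounded_gompertz(p: GompertzParams, R0: float = DEFAULT_R0, grid=None) -> Trajectory:
    """Bounded Gompertz: dR/dt = (lam/3) R min(log(Rmax/R), 1).

    Growth is exactly exponential while R < Rmax/e, after which the
    standard Gompertz law applies.  Both regimes have closed forms joined
    continuously (in value and slope) at the switch radius.
    """
    tg = _validate_solver_inputs(R0, grid)
    t = tg.times
    if p.lam == 0.0:
        return Trajectory(tg, np.full_like(t, R0))
    r_switch = p.Rmax / math.e
    if R0 < r_switch:
        t_switch = (3.0 / p.lam) * math.log(r_switch / R0)
        r_at_switch = r_switch
    else:
        t_switch = 0.0
        r_at_switch = R0
    radius = np.empty_like(t)
    early = t <= t_switch
    radius[early] = R0 * np.exp(p.lam * t[early] / 3.0)
    late = ~early
    # Gompertz closed form from (t_switch, r_at_switch)
    radius[late] = p.Rmax * np.exp(
        math.log(r_at_switch / p.Rmax) * np.exp(-p.lam * (t[late] - t_switch) / 3.0)
    )
    return Trajectory(tg, radius)


def solve_richards(p: RichardsParams, R0: float = DEFAULT_R0, grid=None) -> Trajectory:
    """Richards growth dR/dt = (lam/3) R (1 - (R/Rmax)^beta), closed form.

    The substitution u = (R/Rmax)^beta turns the equation into a logistic
    ODE for u with rate beta*lam/3; the solution is evaluated in log space
    so it remains accurate as beta -> 0+.
    """
    tg = _validate_solver_inputs(R0, grid)
    t = tg.times
    if p.lam == 0.0:
        return Trajectory(tg, np.full_like(t, R0))
    log_u0 = p.beta * math.log(R0 / p.Rmax)
    u0 = math.exp(log_u0)
    decay = np.exp(-p.beta * p.lam * t / 3.0)
    log_u = log_u0 - np.log(u0 + (1.0 - u0) * decay)
    radius = p.Rmax * np.exp(log_u / p.beta)
    return Trajectory(tg, radius)


def _radial_death_rhs(R: float, p: RadialDeathParams) -> float:
    # volume balance dV/dt = lam*V1 - zeta*N with N the necrotic-core volume
    core = max(0.0, R - p.Rd)
    frac = (core / R) ** 3
    return (p.lam / 3.0) * R * (1.0 - frac) - (p.zeta / 3.0) * R * frac


def solve_radial_death(p: RadialDeathParams, R0: float = DEFAULT_R0, grid=None) -> Trajectory:
    """Radial-death model: exponential growth up to a viable rim of
    thickness Rd, beyond which the necrotic core loses mass at rate zeta.

    The reduction of the two-compartment volume balance to a single radius
    ODE gives dR/dt = (lam/3) R [1 - (1 + zeta/lam) (max(0, R - Rd)/R)^3].
    The pre-necrosis segment (R <= Rd) is evaluated by the exact exponential
    closed form; the remainder is integrated numerically.
    """
    tg = _validate_solver_inputs(R0, grid)
    t = tg.times
    radius = np.empty_like(t)
    if p.lam == 0.0 and R0 <= p.Rd:
        return Trajectory(tg, np.full_like(t, R0))
    if R0 <= p.Rd and p.lam > 0:
        t_cross = (3.0 / p.lam) * math.log(p.Rd / R0)
    else:
        t_cross = 0.0
    early = t <= t_cross
    radius[early] = R0 * np.exp(p.lam * t[early] / 3.0)
    late_t = t[~early]
    if late_t.size:
        r_start = p.Rd if t_cross > 0 else R0
        sol = solve_ivp(
            lambda _t, y: [_radial_death_rhs(y[0], p)],
            (t_cross, late_t[-1]),
            [r_start],
            t_eval=late_t,
            method="RK45",
            rtol=_ODE_RTOL,
            atol=_ODE_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"radial-death integration failed: {sol.message}")
        radius[~early] = sol.y[0]
    return Trajectory(tg, radius)


def greenspan_inner_radii(R: float, p: GreenspanParams) -> tuple[float, float, int]:
    """Inhibited and necrotic radii (R_i, R_n) of the Greenspan model at
    outer radius R, together with the growth phase (1, 2 or 3).

    Phase 1 (R < Q Rd): nutrient everywhere sufficient, R_i = R_n = 0.
    Phase 2 (Q Rd <= R < Rd): an arrested core, R_i = sqrt(R^2 - Q^2 Rd^2).
    Phase 3 (R >= Rd): a necrotic core; R_n is the root of the cubic

        0 = R^3 - Rd^2 R - 3 R R_n^2 + 2 R_n^3           on (0, R),

    (the quasi-steady nutrient profile with consumption confined to the
    viable shell and no flux into the core) and R_i the root of

        0 = Q^2 Rd^2 R R_i + R R_i^3 + 2 R R_n^3 - R^3 R_i - 2 R_i R_n^3

    on (R_n, R).  Both roots are bracketed and unique; they are solved with
    a guaranteed-convergence bracketing method to 1e-12 relative tolerance.
    """
    _check_positive(R=R)
    q_rd = p.Q * p.Rd
    if R < q_rd:
        return 0.0, 0.0, 1
    if R < p.Rd:
        ri = math.sqrt(max(R * R - q_rd * q_rd, 0.0))
        return ri, 0.0, 2

    def cubic(rn: float) -> float:
        return R**3 - p.Rd**2 * R - 3.0 * R * rn * rn + 2.0 * rn**3

    # cubic is strictly decreasing in R_n with cubic(0) >= 0 > cubic(R);
    # exactly at R = Rd the root sits on the bracket edge R_n = 0
    if R * R - p.Rd * p.Rd <= 1e-14 * R * R:
        rn = 0.0
    else:
        try:
            rn = brentq(cubic, 0.0, R, xtol=1e-12 * R, rtol=1e-15)
        except ValueError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"no bracketed necrotic-radius root for R={R}, Rd={p.Rd}: {exc}"
            ) from exc

    if rn <= 1e-9 * R:
        # exactly at necrosis onset the quartic degenerates to the phase-2 form
        ri = math.sqrt(max(R * R - q_rd * q_rd, 0.0))
        return ri, 0.0, 3

    def quartic(ri: float) -> float:
        return (
            q_rd * q_rd * R * ri
            + R * ri**3
            + 2.0 * R * rn**3
            - R**3 * ri
            - 2.0 * ri * rn**3
        )

    try:
        ri = brentq(quartic, rn, R, xtol=1e-12 * R, rtol=1e-15)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"no bracketed inhibited-radius root for R={R}, Rd={p.Rd}, Rn={rn}: {exc}"
        ) from exc
    rn = min(max(rn, 0.0), ri)
    return ri, rn, 3


def _greenspan_rhs(R: float, p: GreenspanParams) -> float:
    ri, rn, _ = greenspan_inner_radii(R, p)
    return (p.lam / 3.0) * R * (1.0 - (ri / R) ** 3 - p.gamma * (rn / R) ** 3)


def solve_greenspan(p: GreenspanParams, R0: float = DEFAULT_R0, grid=None) -> Trajectory:
    """Greenspan nutrient-limited growth.

    Integrates dR/dt = (lam/3) R (1 - R_i^3/R^3 - gamma R_n^3/R^3) with the
    inner radii recomputed from the algebraic constraints at every
    evaluation.  The pure-exponential first phase (R < Q Rd) is evaluated in
    closed form; the right-hand side is continuous across both phase
    boundaries, so the remaining dynamics are handled by the adaptive
    stepper at tight tolerances.

    Returns the outer radius together with R_i(t) and R_n(t).
    """
    tg = _validate_solver_inputs(R0, grid)
    t = tg.times
    radius = np.empty_like(t)
    q_rd = p.Q * p.Rd
    if p.lam == 0.0:
        radius[:] = R0
    else:
        if R0 < q_rd:
            t_cross = (3.0 / p.lam) * math.log(q_rd / R0)
            r_start = q_rd
        else:
            t_cross = 0.0
            r_start = R0
        early = t <= t_cross
        radius[early] = R0 * np.exp(p.lam * t[early] / 3.0)
        late_t = t[~early]
        if late_t.size:
            sol = solve_ivp(
                lambda _t, y: [_greenspan_rhs(y[0], p)],
                (t_cross, late_t[-1]),
                [r_start],
                t_eval=late_t,
                method="RK45",
                rtol=_ODE_RTOL,
                atol=_ODE_ATOL,
            )
            if not sol.success:
                raise RuntimeError(f"Greenspan integration failed: {sol.message}")
            radius[~early] = sol.y[0]
    inner = np.empty_like(radius)
    necro = np.empty_like(radius)
    for k, r in enumerate(radius):
        inner[k], necro[k], _ = greenspan_inner_radii(r, p)
    return Trajectory(tg, radius, inner_radius=inner, necrotic_radius=necro)


def crowding_function(model_id: str, params, radii) -> CrowdingCurve:
    """Evaluate the crowding function f(R) = 3/(lam R) dR/dt of a model.

    ``params`` is the model's parameter dataclass.  The Ward--King model has
    no closed-form crowding function; use
    :func:`spheromap.ward_king.wk_empirical_crowding` instead.
    """
    r = np.asarray(radii, dtype=float)
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("radii must be positive and finite")
    if model_id == "logistic":
        f = 1.0 - r / params.Rmax
    elif model_id == "gompertz":
        f = np.minimum(np.log(params.Rmax / r), 1.0)
    elif model_id == "richards":
        f = 1.0 - (r / params.Rmax) ** params.beta
    elif model_id == "radial_death":
        if params.lam <= 0:
            raise ValueError("radial-death crowding function requires lam > 0")
        core = np.maximum(0.0, r - params.Rd)
        f = 1.0 - (1.0 + params.zeta / params.lam) * (core / r) ** 3
    elif model_id == "greenspan":
        f = np.empty_like(r)
        for k, rk in enumerate(r):
            ri, rn, _ = greenspan_inner_radii(rk, params)
            f[k] = 1.0 - (ri / rk) ** 3 - params.gamma * (rn / rk) ** 3
    else:
        raise ValueError(f"unknown or unsupported model_id {model_id!r}")
    return CrowdingCurve(r, f)
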