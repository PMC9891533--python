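"""Least-squares maps between model parameter spaces, and their geometry.

The map from a (possibly non-identifiable) source model i at parameters
p_i to an identifiable surrogate model j is defined in the least-squares
sense,

    f_ij(p_i) = argmin_{p_j} || m_i(p_i) - m_j(p_j) ||,

i.e. the surrogate parameters a least-squares fit would recover from
noise-free source output.  Goodness of correspondence is the usual R^2
against the source-prediction mean.  The geometry of f_ij carries the
identifiability structure:

* the Jacobian J_ij = df_ij/dp_i, whose rows are normal to the manifolds
  of constant surrogate features in source-parameter space;
* the dimensionless relative sensitivity matrix
  S^(k1,k2) = (p_i^(k2) / p_j^(k1)) J^(k1,k2), read as the % change of
  surrogate parameter k1 per % change of source parameter k2;
* constant-feature level sets traced through parameter-space slices;
* steering moves that use sensitivity rows (optionally orthogonalised
  against the other rows) to change one surrogate feature while holding
  the others approximately fixed.

Because f_ij is defined through an inner optimisation, every evaluation
used in finite differences is warm-started from the anchor's fitted
surrogate parameters, and derivative columns are Richardson-extrapolated
with step-size adaptation until two levels agree; this keeps optimiser
noise out of the Jacobian.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .growth_models import DEFAULT_R0, as_time_grid, solve_greenspan, GreenspanParams
from .inference import _nm_minimise
from .information_geometry import FIMResult
from .registry import get_model, predict

__all__ = [
    "MapResult",
    "MapJacobian",
    "SensitivityMatrix",
    "ManifoldSurface",
    "OrthogonalityReport",
    "fit_map",
    "map_jacobian",
    "sensitivity_matrix",
    "feature_manifold",
    "tangent_normal_check",
    "orthogonality_report",
    "steer",
]

logger = logging.getLogger(__name__)

#: default observation design for evaluating between-model maps
DEFAULT_MAP_GRID = np.arange(0.0, 22.0)


@dataclasses.dataclass(frozen=True)
class MapResult:
    source_model: str
    source_params: np.ndarray
    target_model: str
    target_params: np.ndarray
    r_squared: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")


@dataclasses.dataclass(frozen=True)
class MapJacobian:
    """k_j x k_i matrix; rows are target-parameter gradients w.r.t. source."""

    matrix: np.ndarray
    target_names: tuple[str, ...]
    source_names: tuple[str, ...]
    anchor: MapResult

    def row(self, target_param: str) -> np.ndarray:
        return self.matrix[self.target_names.index(target_param)]


@dataclasses.dataclass(frozen=True)
class SensitivityMatrix:
    """Dimensionless k_j x k_i relative sensitivities (% per %)."""

    matrix: np.ndarray
    target_names: tuple[str, ...]
    source_names: tuple[str, ...]

    def row(self, target_param: str) -> np.ndarray:
        return self.matrix[self.target_names.index(target_param)]


@dataclasses.dataclass(frozen=True)
class ManifoldSurface:
    feature_name: str
    level: float
    slice_spec: dict
    points: np.ndarray  # n_points x k_i source-parameter coordinates
    source_names: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class OrthogonalityReport:
    """Eigenvalues (relative to largest, ascending) and the dot products of
    each eigenvector with the unit vectors along the map-Jacobian rows."""

    relative_eigenvalues: np.ndarray
    dots: np.ndarray  # shape (k, n_rows)
    row_names: tuple[str, ...]


def fit_map(
    source_model: str,
    p_i,
    target_model: str,
    grid=None,
    init=None,
    R0: float = DEFAULT_R0,
    maxfev: int = 10_000,
) -> MapResult:
    """Least-squares surrogate parameters f_ij(p_i) and the map R^2."""
    src_spec = get_model(source_model)
    tgt_spec = get_model(target_model)
    p_i = np.asarray(p_i, dtype=float)
    tg = as_time_grid(grid if grid is not None else DEFAULT_MAP_GRID)
    m_src = predict(source_model, p_i, R0, tg)

    bounds = np.asarray(tgt_spec.bounds, dtype=float)
    zb = np.log(bounds)

    def objective(z: np.ndarray) -> float:
        try:
            m_tgt = predict(target_model, np.exp(z), R0, tg)
        except (RuntimeError, FloatingPointError, OverflowError, ValueError):
            return np.inf
        r = m_src - m_tgt
        return float(r @ r)

    starts = [tgt_spec.default_params]
    if init is not None:
        starts.insert(0, np.asarray(init, dtype=float))
    if source_model == target_model:
        starts.insert(0, p_i)
    best = None
    for s in starts:
        s = np.clip(s, bounds[:, 0], bounds[:, 1])
        res = _nm_minimise(objective, np.log(s), zb, maxfev=maxfev)
        if res is not None and np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"map optimisation failed for {source_model}->{target_model}")
    p_j = np.exp(best.x)
    ss_res = best.fun
    centred = m_src - m_src.mean()
    ss_tot = float(centred @ centred)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return MapResult(
        source_model=source_model,
        source_params=p_i,
        target_model=target_model,
        target_params=p_j,
        r_squared=min(r2, 1.0),
        residual_norm=math.sqrt(max(ss_res, 0.0)),
    )


def _map_eval(
    source_model: str,
    p: np.ndarray,
    target_model: str,
    tg,
    warm: np.ndarray,
    R0: float,
) -> np.ndarray:
    return fit_map(source_model, p, target_model, tg, init=warm, R0=R0).target_params


def map_jacobian(
    source_model: str,
    p_i,
    target_model: str,
    grid=None,
    fd_step: float = 1e-3,
    R0: float = DEFAULT_R0,
    agreement_tol: float = 1e-3,
    max_shrink: int = 3,
    anchor: Optional[MapResult] = None,
) -> MapJacobian:
    """Finite-difference Jacobian J_ij = df_ij/dp_i of the model map.

    Each column uses central differences at steps h and h/2 combined by
    Richardson extrapolation; if the two levels disagree beyond
    ``agreement_tol`` (relative, guarded at small magnitudes) the step is
    shrunk and the column recomputed.  All inner map evaluations are
    warm-started from the anchor's fitted target parameters.
    """
    src_spec = get_model(source_model)
    tgt_spec = get_model(target_model)
    p_i = np.asarray(p_i, dtype=float)
    tg = as_time_grid(grid if grid is not None else DEFAULT_MAP_GRID)
    if anchor is None:
        anchor = fit_map(source_model, p_i, target_model, tg, R0=R0)
    warm = anchor.target_params
    scale = np.maximum(np.abs(warm), 1e-12)

    cols = []
    for j in range(src_spec.k):
        h0 = fd_step * (abs(p_i[j]) if p_i[j] != 0 else 1.0)

        def central(step: float) -> np.ndarray:
            pp, pm = p_i.copy(), p_i.copy()
            pp[j] += step
            pm[j] -= step
            fp = _map_eval(source_model, pp, target_model, tg, warm, R0)
            fm = _map_eval(source_model, pm, target_model, tg, warm, R0)
            return (fp - fm) / (2.0 * step)

        best_col, best_disagreement = None, math.inf
        h = h0
        for _ in range(max_shrink + 1):
            d_h = central(h)
            d_h2 = central(h / 2.0)
            extrap = (4.0 * d_h2 - d_h) / 3.0
            # per-entry relative disagreement of the two Richardson levels.
            # The floor is set in the column's natural units (target scale
            # per source unit): entries whose relative sensitivity is below
            # 1e-2 %-per-% are indistinguishable from zero and must not
            # block acceptance with noise-to-noise ratios.
            floor = 1e-2 * scale / max(abs(p_i[j]), 1e-300)
            ref = np.maximum(np.abs(extrap), floor)
            disagreement = float(np.max(np.abs(d_h2 - d_h) / ref))
            if disagreement < best_disagreement:
                best_col, best_disagreement = extrap, disagreement
            if disagreement <= agreement_tol:
                break
            h /= 4.0
        if best_col is None or best_disagreement > max(0.05, 10.0 * agreement_tol):
            raise RuntimeError(
                f"map-Jacobian column for {src_spec.param_names[j]} failed to "
                f"stabilise (best disagreement {best_disagreement:.3g})"
            )
        if best_disagreement > agreement_tol:
            logger.warning(
                "map-Jacobian column %s accepted at disagreement %.3g",
                src_spec.param_names[j],
                best_disagreement,
            )
        cols.append(best_col)
    J = np.column_stack(cols)
    return MapJacobian(
        matrix=J,
        target_names=tgt_spec.param_names,
        source_names=src_spec.param_names,
        anchor=anchor,
    )


def sensitivity_matrix(
    J: MapJacobian,
    p_i=None,
    p_j=None,
    convention: str = "target_per_source",
) -> SensitivityMatrix:
    """Relative sensitivity matrix of the model map.

    With the default convention, entry (k1, k2) is
    (p_i^(k2) / p_j^(k1)) * J^(k1,k2): the relative (%-per-%) change of
    target parameter k1 per relative change of source parameter k2.  The
    ``"source_per_target"`` convention applies the reciprocal scaling.
    """
    p_i = np.asarray(p_i if p_i is not None else J.anchor.source_params, dtype=float)
    p_j = np.asarray(p_j if p_j is not None else J.anchor.target_params, dtype=float)
    if np.any(p_i == 0) or np.any(p_j == 0):
        raise ValueError("relative sensitivities require nonzero parameters")
    if convention == "target_per_source":
        S = (1.0 / p_j)[:, None] * J.matrix * p_i[None, :]
    elif convention == "source_per_target":
        S = p_j[:, None] * J.matrix / p_i[None, :]
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return SensitivityMatrix(S, J.target_names, J.source_names)


def _feature_value(
    source_model: str,
    p: np.ndarray,
    target_model: str,
    feature_name: str,
    tg,
    warm,
    R0: float,
) -> float:
    """A surrogate feature (target parameter) or, optionally, the final-time
    necrotic core radius of the Greenspan model."""
    if feature_name == "necrotic_radius_final":
        if source_model != "greenspan":
            raise ValueError("necrotic_radius_final is only defined for greenspan")
        traj = solve_greenspan(GreenspanParams(*p), R0, tg)
        return float(traj.necrotic_radius[-1])
    tgt_spec = get_model(target_model)
    idx = tgt_spec.param_names.index(feature_name)
    return float(_map_eval(source_model, p, target_model, tg, warm, R0)[idx])


def feature_manifold(
    source_model: str,
    p_anchor,
    target_model: str,
    feature_name: str,
    slice_spec: dict,
    resolution: int = 5,
    grid=None,
    R0: float = DEFAULT_R0,
    rel_tol: float = 5e-3,
) -> ManifoldSurface:
    """Trace the level set of a surrogate feature through a parameter slice.

    ``slice_spec`` maps two source-parameter names to (lo, hi) ranges that
    are swept on a ``resolution`` x ``resolution`` grid, and names a third
    parameter (``slice_spec["solve"]`` with its own (lo, hi) bracket) that
    is root-found per gridline so the mapped feature equals its anchor
    value.  All other source parameters are pinned at the anchor.

    Gridlines with no bracketed root are omitted with a log entry.
    """
    src_spec = get_model(source_model)
    p_anchor = np.asarray(p_anchor, dtype=float)
    tg = as_time_grid(grid if grid is not None else DEFAULT_MAP_GRID)
    anchor_fit = fit_map(source_model, p_anchor, target_model, tg, R0=R0)
    warm = anchor_fit.target_params
    level = _feature_value(
        source_model, p_anchor, target_model, feature_name, tg, warm, R0
    )

    sweep = [(name, rng) for name, rng in slice_spec.items() if name != "solve"]
    if len(sweep) != 2 or "solve" not in slice_spec:
        raise ValueError(
            "slice_spec needs two swept parameters plus a 'solve' entry "
            "of the form {'solve': (name, (lo, hi))}"
        )
    solve_name, solve_bracket = slice_spec["solve"]
    sweep_idx = [src_spec.param_names.index(name) for name, _ in sweep]
    solve_idx = src_spec.param_names.index(solve_name)

    axes = [np.linspace(lo, hi, resolution) for _, (lo, hi) in sweep]
    points = []
    for a in axes[0]:
        for b in axes[1]:
            base = p_anchor.copy()
            base[sweep_idx[0]] = a
            base[sweep_idx[1]] = b

            def residual(x: float) -> float:
                q = base.copy()
                q[solve_idx] = x
                return (
                    _feature_value(
                        source_model, q, target_model, feature_name, tg, warm, R0
                    )
                    - level
                )

            lo, hi = solve_bracket
            samples = np.linspace(lo, hi, 7)
            vals = []
            for x in samples:
                try:
                    vals.append(residual(x))
                except (RuntimeError, ValueError):
                    vals.append(math.nan)
            root = None
            for s0, s1, v0, v1 in zip(samples[:-1], samples[1:], vals[:-1], vals[1:]):
                if np.isfinite(v0) and np.isfinite(v1) and v0 * v1 <= 0:
                    root = brentq(residual, s0, s1, xtol=1e-10 * max(abs(hi), 1.0))
                    break
            if root is None:
                logger.info(
                    "no bracketed root on gridline %s=%.4g, %s=%.4g",
                    sweep[0][0], a, sweep[1][0], b,
                )
                continue
            q = base.copy()
            q[solve_idx] = root
            achieved = _feature_value(
                source_model, q, target_model, feature_name, tg, warm, R0
            )
            if abs(achieved - level) > rel_tol * max(abs(level), 1e-12):
                logger.info("discarding off-level point (drift %.3g)", achieved - level)
                continue
            points.append(q)
    return ManifoldSurface(
        feature_name=feature_name,
        level=level,
        slice_spec=slice_spec,
        points=np.asarray(points).reshape(-1, src_spec.k),
        source_names=src_spec.param_names,
    )


def tangent_normal_check(
    J: MapJacobian, fim_result: FIMResult, slice_params: Sequence[str]
) -> dict:
    """Check that the sloppy direction lies along the intersection of the
    constant-feature tangent planes in a 3-parameter slice.

    The first two Jacobian rows are restricted to the slice; their cross
    product spans the intersection of the two tangent planes.  It is
    compared (by |cosine|) against the sloppiest eigenvector of the FIM
    restricted to the same slice.
    """
    if len(slice_params) != 3:
        raise ValueError("cross product requires a 3-parameter slice")
    idx = [J.source_names.index(name) for name in slice_params]
    u1 = J.matrix[0, idx]
    u2 = J.matrix[1, idx]
    if np.linalg.norm(np.cross(u1, u2)) < 1e-14 * np.linalg.norm(u1) * np.linalg.norm(u2):
        raise ValueError("map-Jacobian rows are parallel in this slice")
    cross = np.cross(u1, u2)
    cross /= np.linalg.norm(cross)
    fidx = [list(fim_result.param_names).index(name) for name in slice_params]
    sub = fim_result.fim[np.ix_(fidx, fidx)]
    evals, evecs = np.linalg.eigh(0.5 * (sub + sub.T))
    v1 = evecs[:, 0] / np.linalg.norm(evecs[:, 0])
    cosine = abs(float(cross @ v1))
    return dict(
        cross_product=cross,
        sloppy_eigenvector=v1,
        abs_cosine=cosine,
        slice_params=tuple(slice_params),
    )


def orthogonality_report(fim_result: FIMResult, J: MapJacobian) -> OrthogonalityReport:
    """Dot products of every FIM eigenvector with the unit vectors along the
    map-Jacobian rows, ordered by ascending eigenvalue."""
    if fim_result.eigenvectors.shape[0] != J.matrix.shape[1]:
        raise ValueError("FIM and map-Jacobian dimensions disagree")
    order = np.argsort(fim_result.eigenvalues)  # ascending
    evals = fim_result.eigenvalues[order]
    evecs = fim_result.eigenvectors[:, order]
    rel = evals / fim_result.eigenvalues.max()
    rows = J.matrix / np.linalg.norm(J.matrix, axis=1, keepdims=True)
    dots = evecs.T @ rows.T  # (k, n_rows)
    return OrthogonalityReport(
        relative_eigenvalues=rel,
        dots=dots,
        row_names=J.target_names,
    )


def steer(
    p_i,
    S: SensitivityMatrix,
    target_row,
    rel_change: float,
    orthogonalize: bool = False,
) -> np.ndarray:
    """Multiplicative parameter move achieving a predicted relative change
    in one surrogate feature.

    The move direction is the chosen sensitivity row (optionally its
    component orthogonal to the remaining rows), scaled so the linearised
    prediction of the targeted feature's relative change equals
    ``rel_change``; parameters update as p_k <- p_k (1 + d_k).
    """
    p_i = np.asarray(p_i, dtype=float)
    if isinstance(target_row, str):
        row_idx = S.target_names.index(target_row)
    else:
        row_idx = int(target_row)
    s_t = S.matrix[row_idx].astype(float)
    if np.linalg.norm(s_t) == 0:
        raise ValueError("target sensitivity row is zero")
    d = s_t.copy()
    if orthogonalize:
        for k in range(S.matrix.shape[0]):
            if k == row_idx:
                continue
            s_o = S.matrix[k]
            n_o = np.linalg.norm(s_o)
            if n_o == 0:
                continue
            cosang = abs(float(s_t @ s_o) / (np.linalg.norm(s_t) * n_o))
            if cosang > 1.0 - 1e-10:
                raise ValueError("sensitivity rows are parallel; cannot orthogonalise")
            d = d - (d @ s_o) / (n_o**2) * s_o
        if np.linalg.norm(d) < 1e-14 * np.linalg.norm(s_t):
            raise ValueError("orthogonalised direction vanished")
    predicted = float(s_t @ d)
    if predicted == 0:
        raise ValueError("direction produces no predicted change in the target feature")
    d = d * (rel_change / predicted)
    return p_i * (1.0 + d)
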