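"""Sensitivity Jacobian, Fisher information, sloppiness, and sloppy paths.

For additive Gaussian noise of known sigma the observed Fisher information
matrix of a model with prediction vector m(p) is

    F(p) = J(p)^T J(p) / sigma^2,

where J is the n x k sensitivity Jacobian dm/dp.  (Dividing by sigma^2 is
the standard Gaussian-noise scaling; the normalised spectrum, eigenvector
directions and rank that the sloppiness analysis rests on are invariant to
it.)  Eigenvectors of small eigenvalues are "sloppy" directions: parameter
moves the data cannot resolve.  The sloppy path follows the sloppiest
eigenvector field v1(p) through parameter space,

    dp/ds = v1(p),  p(0) = p_start,

integrated with a fixed-step RK4 scheme in rescaled coordinates (p divided
by p_start) since the arclength parameterisation is arbitrary.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .growth_models import DEFAULT_R0, as_time_grid
from .registry import get_model, predict
from .synthetic_data import Dataset

__all__ = [
    "SensitivityJacobian",
    "FIMResult",
    "SloppyPath",
    "model_jacobian",
    "fim",
    "spectrum_report",
    "sloppy_path",
]


@dataclasses.dataclass(frozen=True)
class SensitivityJacobian:
    """n x k matrix of dR(t_m)/dp_j (um per parameter unit)."""

    matrix: np.ndarray
    param_names: tuple[str, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.param_names):
            raise ValueError("matrix must be n x k with k = len(param_names)")
        if not np.all(np.isfinite(m)):
            raise ValueError("Jacobian entries must be finite")
        object.__setattr__(self, "matrix", m)


@dataclasses.dataclass(frozen=True)
class FIMResult:
    fim: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns matching eigenvalues
    condition_number: float
    normalised_spectrum: np.ndarray
    param_names: tuple[str, ...] = ()


@dataclasses.dataclass(frozen=True)
class SloppyPath:
    arclength: np.ndarray
    points: np.ndarray  # (n_steps + 1) x k parameter vectors
    loglik_along: np.ndarray
    param_names: tuple[str, ...] = ()


def model_jacobian(
    model_id: str,
    p,
    grid,
    R0: float = DEFAULT_R0,
    rel_step: float = 1e-4,
    richardson: bool = False,
) -> SensitivityJacobian:
    """Central finite-difference sensitivity Jacobian of the radius.

    The step for parameter j is ``rel_step * |p_j|`` (falling back to
    ``rel_step`` for zero parameters).  With ``richardson=True`` a second
    evaluation at half the step is combined by Richardson extrapolation,
    cancelling the leading O(h^2) error.
    """
    spec = get_model(model_id)
    p = np.asarray(p, dtype=float)
    tg = as_time_grid(grid)

    def fd(step_scale: float) -> np.ndarray:
        cols = []
        for j in range(spec.k):
            h = step_scale * (abs(p[j]) if p[j] != 0 else 1.0)
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            mp = predict(model_id, pp, R0, tg)
            mm = predict(model_id, pm, R0, tg)
            cols.append((mp - mm) / (2.0 * h))
        return np.column_stack(cols)

    J = fd(rel_step)
    if richardson:
        J_half = fd(rel_step / 2.0)
        J = (4.0 * J_half - J) / 3.0
    return SensitivityJacobian(J, spec.param_names, tg.times)


def _canonical_sign(V: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the first nonzero component is positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-14)[0]
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def fim(J: SensitivityJacobian, sigma: float) -> FIMResult:
    """Fisher information F = J^T J / sigma^2 with ordered eigensystem."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    A = J.matrix
    F = A.T @ A / sigma**2
    F = 0.5 * (F + F.T)
    evals, evecs = np.linalg.eigh(F)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _canonical_sign(evecs[:, order])
    lam_max = evals[0]
    if lam_max <= 0:
        raise ValueError("FIM has non-positive leading eigenvalue")
    cond = lam_max / evals[-1] if evals[-1] > 0 else math.inf
    return FIMResult(
        fim=F,
        eigenvalues=evals,
        eigenvectors=evecs,
        condition_number=float(cond),
        normalised_spectrum=evals / lam_max,
        param_names=J.param_names,
    )


def sloppy_count(fim_result: FIMResult, gap_decades: float = 3.0) -> int:
    """Number of eigenvalues below the largest spectral gap, provided that
    gap spans at least ``gap_decades`` decades; 0 if no such gap exists."""
    lam = np.maximum(fim_result.eigenvalues, np.finfo(float).tiny)
    logs = np.log10(lam)
    gaps = logs[:-1] - logs[1:]  # descending order
    if gaps.size == 0 or np.max(gaps) < gap_decades:
        return 0
    split = int(np.argmax(gaps))
    return lam.size - split - 1


def spectrum_report(
    models_and_params: Sequence[tuple[str, Sequence[float]]],
    grid,
    sigma: float,
    R0: float = DEFAULT_R0,
    gap_decades: float = 3.0,
    rel_step: float = 1e-4,
) -> pd.DataFrame:
    """Normalised FIM spectra for several models on a common design.

    Returns one row per eigenvalue with the model id, the eigenvalue
    scaled so the spectral radius is unity, its log10, and the per-model
    count of sloppy eigenvalues (those separated from the informative
    cluster by at least ``gap_decades`` decades).
    """
    rows = []
    for model_id, p in models_and_params:
        J = model_jacobian(model_id, p, grid, R0=R0, rel_step=rel_step)
        res = fim(J, sigma)
        n_sloppy = sloppy_count(res, gap_decades)
        for rank, lam in enumerate(res.normalised_spectrum):
            rows.append(
                dict(
                    model=model_id,
                    rank=rank,
                    normalised_eigenvalue=float(lam),
                    log10_normalised=float(np.log10(max(lam, np.finfo(float).tiny))),
                    n_sloppy=n_sloppy,
                )
            )
    return pd.DataFrame(rows)


def _sloppiest_direction(
    model_id: str, q: np.ndarray, p_ref: np.ndarray, grid, sigma: float, R0: float,
    rel_step: float,
) -> np.ndarray:
    """Unit eigenvector of the smallest FIM eigenvalue in scaled coordinates
    q = p / p_ref (chain rule: J_q = J_p diag(p_ref))."""
    p = q * p_ref
    J = model_jacobian(model_id, p, grid, R0=R0, rel_step=rel_step)
    A = J.matrix * p_ref[np.newaxis, :]
    F = A.T @ A / sigma**2
    evals, evecs = np.linalg.eigh(0.5 * (F + F.T))
    v = evecs[:, 0]
    return v / np.linalg.norm(v)


def sloppy_path(
    model_id: str,
    p_start,
    sigma: float,
    grid,
    span: float,
    step: float = 1e-2,
    data: Optional[Dataset] = None,
    R0: float = DEFAULT_R0,
    rel_step: float = 1e-4,
) -> SloppyPath:
    """Integrate dp/ds = v1(p) along the sloppiest FIM eigendirection.

    Integration uses fixed-step RK4 in coordinates scaled by ``p_start``.
    The eigenvector sign is kept continuous (positive dot product with the
    previous direction); if the direction field turns abruptly within one
    step (an eigenvalue crossing), the step is halved and retried.  The
    log-likelihood along the path is evaluated against ``data`` or, by
    default, against the noise-free trajectory generated at ``p_start``.
    """
    spec = get_model(model_id)
    p_start = np.asarray(p_start, dtype=float)
    tg = as_time_grid(grid)
    if data is None:
        y = predict(model_id, p_start, R0, tg)
        data = Dataset(tg, y, sigma)
    from .inference import log_likelihood  # local import avoids a cycle

    n_steps = max(1, int(round(abs(span) / step)))
    ds = math.copysign(abs(span) / n_steps, span if span != 0 else 1.0)

    q = np.ones(spec.k)
    prev_dir = _sloppiest_direction(model_id, q, p_start, tg, sigma, R0, rel_step)

    def direction(qv: np.ndarray, ref: np.ndarray) -> np.ndarray:
        v = _sloppiest_direction(model_id, qv, p_start, tg, sigma, R0, rel_step)
        return -v if float(v @ ref) < 0 else v

    arclength = [0.0]
    points = [p_start.copy()]
    lls = [log_likelihood(data, model_id, p_start, R0)]
    s = 0.0
    for _ in range(n_steps):
        h = ds
        for _attempt in range(5):
            k1 = direction(q, prev_dir)
            k2 = direction(q + 0.5 * h * k1, k1)
            k3 = direction(q + 0.5 * h * k2, k2)
            k4 = direction(q + h * k3, k3)
            new_dir = (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if float(k4 @ k1) >= 0.8:  # smooth enough within the step
                break
            h *= 0.5
        q = q + h * new_dir
        prev_dir = k1
        s += h
        p = q * p_start
        arclength.append(s)
        points.append(p)
        lls.append(log_likelihood(data, model_id, p, R0))
    return SloppyPath(
        arclength=np.asarray(arclength),
        points=np.asarray(points),
        loglik_along=np.asarray(lls),
        param_names=spec.param_names,
    )
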