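"""Seeded generation of noisy synthetic spheroid-radius datasets.

Observations follow the additive Gaussian measurement model

    y_k = R(t_k; p) + eps_k,    eps_k ~ N(0, sigma^2) i.i.d.,

with sigma treated as known.  Noise can push small radii negative; values
are kept as generated, since clipping would bias the noise model and the
Gaussian likelihood handles them correctly.

Named scenarios fix the study conditions used throughout the analysis:

``main``
    Greenspan generator [Q, Rd, gamma, lam] = [0.8, 150, 1, 1], R0 = 10 um,
    daily observations t = 0, 1, ..., 21 d, sigma = 20 um.
``noise_sweep``
    As ``main`` with sigma in {5, 10, 20, 40} um and 100 replicates each.
``early_time``
    22 equally spaced observations on 0 <= t <= 5 d with sigma = 2 um.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .growth_models import TimeGrid, as_time_grid
from .registry import get_model, predict

__all__ = ["ScenarioConfig", "Dataset", "generate_dataset", "scenario", "SCENARIO_NAMES"]


@dataclasses.dataclass(frozen=True)
class Dataset:
    """Observed radii y (um) at the grid times, with known noise sigma."""

    times: TimeGrid
    y: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.shape != self.times.times.shape:
            raise ValueError("y length must match times")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.times)


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    generator_model: str
    generator_params: np.ndarray
    R0: float
    grid: TimeGrid
    sigma: float
    replicates: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        get_model(self.generator_model)  # validates the id
        object.__setattr__(
            self, "generator_params", np.asarray(self.generator_params, dtype=float)
        )
        object.__setattr__(self, "grid", as_time_grid(self.grid))
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # sub-seed derived deterministically from (seed, replicate)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


def generate_dataset(cfg: ScenarioConfig, replicate: int = 0) -> Dataset:
    """One noisy dataset for the given replicate index.

    Identical (cfg, replicate) pairs produce bit-identical data; distinct
    replicate indices produce independent noise vectors.
    """
    m = predict(cfg.generator_model, cfg.generator_params, cfg.R0, cfg.grid)
    rng = _replicate_rng(cfg.seed, replicate)
    noise = rng.normal(0.0, cfg.sigma, size=m.shape) if cfg.sigma > 0 else 0.0
    y = m + noise
    # a noise-free "dataset" still needs sigma > 0 for the likelihood
    # machinery; a unit nominal sigma leaves least-squares fits unchanged
    sigma = cfg.sigma if cfg.sigma > 0 else 1.0
    return Dataset(cfg.grid, y, sigma)


def generate_replicates(cfg: ScenarioConfig) -> list[Dataset]:
    """All replicates of a scenario as a list of datasets."""
    return [generate_dataset(cfg, r) for r in range(cfg.replicates)]


#: sigma grid for the noise sweep (um)
NOISE_SWEEP_SIGMAS = (5.0, 10.0, 20.0, 40.0)

SCENARIO_NAMES = ("main", "noise_sweep", "early_time")


def scenario(name: str, seed: int = 1) -> ScenarioConfig:
    """Named study conditions (see module docstring)."""
    base = dict(
        generator_model="greenspan",
        generator_params=np.array([0.8, 150.0, 1.0, 1.0]),
        R0=10.0,
        seed=seed,
    )
    if name == "main":
        return ScenarioConfig(
            grid=TimeGrid(np.arange(0.0, 22.0)), sigma=20.0, replicates=1, **base
        )
    if name == "noise_sweep":
        # one config per sigma is produced by sweep consumers; the base
        # config carries the middle sigma and the replicate count
        return ScenarioConfig(
            grid=TimeGrid(np.arange(0.0, 22.0)), sigma=20.0, replicates=100, **base
        )
    if name == "early_time":
        return ScenarioConfig(
            grid=TimeGrid(np.linspace(0.0, 5.0, 22)), sigma=2.0, replicates=1, **base
        )
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
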