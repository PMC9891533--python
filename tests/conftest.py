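"""Shared fixtures: the reference Greenspan anchor and derived objects.

Expensive objects (maps, Jacobians, datasets) are session-scoped so the
suite computes them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from spheromap.growth_models import GreenspanParams, solve_greenspan
from spheromap.model_map import fit_map, map_jacobian, sensitivity_matrix
from spheromap.synthetic_data import generate_dataset, scenario

#: reference Greenspan parameters [Q, Rd, gamma, lam]
P1 = np.array([0.8, 150.0, 1.0, 1.0])


@pytest.fixture(scope="session")
def grid_daily() -> np.ndarray:
    return np.arange(0.0, 22.0)


@pytest.fixture(scope="session")
def p1() -> np.ndarray:
    return P1.copy()


@pytest.fixture(scope="session")
def greenspan_traj(grid_daily):
    return solve_greenspan(GreenspanParams(*P1), 10.0, grid_daily)


@pytest.fixture(scope="session")
def main_dataset():
    return generate_dataset(scenario("main", seed=1))


@pytest.fixture(scope="session")
def map_to_logistic(p1):
    return fit_map("greenspan", p1, "logistic")


@pytest.fixture(scope="session")
def map_to_gompertz(p1):
    return fit_map("greenspan", p1, "gompertz")


@pytest.fixture(scope="session")
def jac_greenspan_logistic(p1, map_to_logistic):
    return map_jacobian("greenspan", p1, "logistic", anchor=map_to_logistic)


@pytest.fixture(scope="session")
def sens_greenspan_logistic(jac_greenspan_logistic):
    return sensitivity_matrix(jac_greenspan_logistic)
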