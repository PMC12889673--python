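"""Shared fixtures: small grids, toy models, and the default ISN dataset."""

from __future__ import annotations

import numpy as np
import pytest

from spatialssn import (
    InputDrive,
    KernelParams,
    NetworkModel,
    RetinotopicGrid,
    default_fixture,
)
from spatialssn.network import N_PRE, N_REC
from spatialssn.synth import DEFAULT_SIZES, make_input_fields


@pytest.fixture(scope="session")
def grid12() -> RetinotopicGrid:
    return RetinotopicGrid(12, 12, 6.0)


@pytest.fixture(scope="session")
def isn_dataset():
    """Default noiseless ISN fixture: 12x12 grid, 9 sizes, seed 0."""
    return default_fixture(seed=0)


@pytest.fixture(scope="session")
def weak_dataset():
    """Weak-recurrence fixture (stable even without inhibition)."""
    return default_fixture(seed=0, regime="weak")


def make_uncoupled_model(
    grid: RetinotopicGrid,
    bias,
    nonlinearity: str = "rectified_quadratic",
    scale: float = 10.0,
) -> NetworkModel:
    """Model with all kernel amplitudes zero (w ≡ 0)."""
    from spatialssn.network import Nonlinearity

    kern = KernelParams(np.zeros((N_REC, N_PRE)), np.full((N_REC, N_PRE), scale))
    return NetworkModel(
        grid, kern, bias=np.asarray(bias, float),
        nonlinearity=Nonlinearity(nonlinearity),
    )


def zero_drive(grid: RetinotopicGrid, sizes=DEFAULT_SIZES) -> InputDrive:
    return InputDrive(grid, sizes, np.zeros((3, len(sizes), grid.n_nodes)))


@pytest.fixture()
def small_grid() -> RetinotopicGrid:
    return RetinotopicGrid(4, 4, 6.0)


@pytest.fixture(scope="session")
def small_drive():
    grid = RetinotopicGrid(4, 4, 6.0)
    return grid, make_input_fields(grid, DEFAULT_SIZES)
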