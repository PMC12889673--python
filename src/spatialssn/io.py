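"""Serialization of rate fields and network models.

Rate fields travel as long-format CSV (columns ``population, x_deg, y_deg,
stimulus_size_deg, rate``) or, for speed, as an HDF5 bundle with one
``[size, y, x]`` array per population.  Network models are stored as YAML
with nested amplitude/scale tables.  All writers/readers round-trip
exactly (CSV values are written with 17 significant digits).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from spatialssn.grid import RetinotopicGrid
from spatialssn.network import (
    ALL_PRESYN,
    N_PRE,
    N_REC,
    RECURRENT_TYPES,
    SOURCE_TYPES,
    InputDrive,
    KernelParams,
    NetworkModel,
    Nonlinearity,
    RateField,
)

CSV_HEADER = ["population", "x_deg", "y_deg", "stimulus_size_deg", "rate"]

KNOWN_POPULATIONS = set(RECURRENT_TYPES) | set(SOURCE_TYPES)


# ---------------------------------------------------------------------------
# CSV rate tables
# ---------------------------------------------------------------------------

def write_rate_table(path: str | Path, field: RateField) -> None:
    """Write a rate field as long-format CSV (17 significant digits)."""
    grid = field.grid
    rows = []
    for pop in field.populations:
        arr = field.get(pop)  # (S, N)
        for k, s in enumerate(field.sizes):
            rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "x_deg": grid.coords[:, 0],
                        "y_deg": grid.coords[:, 1],
                        "stimulus_size_deg": s,
                        "rate": arr[k],
                    }
                )
            )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def _grid_from_coords(xs: np.ndarray, ys: np.ndarray) -> RetinotopicGrid:
    ux, uy = np.unique(xs), np.unique(ys)
    if len(ux) < 2 or len(uy) < 2:
        raise ValueError("rate table does not span a 2D grid")
    dx = np.diff(ux)
    if not np.allclose(dx, dx[0]) or not np.allclose(np.diff(uy), dx[0]):
        raise ValueError("rate table grid is not regular")
    return RetinotopicGrid(n_x=len(ux), n_y=len(uy), spacing=float(dx[0]))


def read_rate_table(path: str | Path, drive: bool = False) -> RateField:
    """Read a long-format CSV rate table back into a :class:`RateField`.

    Unknown population labels and duplicate (population, x, y, size) keys
    are rejected.  A header-only file yields an empty field on a minimal
    2×2 grid.  With ``drive=True`` an :class:`InputDrive` is returned.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != CSV_HEADER:
        raise ValueError(f"expected header {CSV_HEADER}, got {list(df.columns)}")
    if df.empty:
        grid = RetinotopicGrid(2, 2, 1.0)
        pops = SOURCE_TYPES if drive else RECURRENT_TYPES
        data = np.zeros((len(pops), 0, grid.n_nodes))
        if drive:
            return InputDrive(grid, [], data)
        return RateField(pops, grid, [], data)
    unknown = set(df["population"].unique()) - KNOWN_POPULATIONS
    if unknown:
        raise ValueError(f"unknown population labels: {sorted(unknown)}")
    if df.duplicated(subset=["population", "x_deg", "y_deg", "stimulus_size_deg"]).any():
        raise ValueError("duplicate (population, x, y, size) keys in rate table")
    grid = _grid_from_coords(df["x_deg"].to_numpy(), df["y_deg"].to_numpy())
    sizes = np.unique(df["stimulus_size_deg"].to_numpy())
    present = [p for p in (RECURRENT_TYPES + SOURCE_TYPES) if p in set(df["population"])]
    data = np.zeros((len(present), len(sizes), grid.n_nodes))
    # node index from coordinates
    ix = np.rint(df["x_deg"].to_numpy() / grid.spacing + (grid.n_x - 1) / 2).astype(int)
    iy = np.rint(df["y_deg"].to_numpy() / grid.spacing + (grid.n_y - 1) / 2).astype(int)
    node = iy * grid.n_x + ix
    pop_idx = df["population"].map({p: i for i, p in enumerate(present)}).to_numpy()
    size_idx = np.searchsorted(sizes, df["stimulus_size_deg"].to_numpy())
    data[pop_idx, size_idx, node] = df["rate"].to_numpy()
    if drive:
        if tuple(present) != SOURCE_TYPES:
            raise ValueError(f"drive table must contain exactly {SOURCE_TYPES}")
        return InputDrive(grid, sizes, data)
    return RateField(present, grid, sizes, data)


# ---------------------------------------------------------------------------
# HDF5 bundles
# ---------------------------------------------------------------------------

def write_rate_bundle(path: str | Path, field: RateField) -> None:
    """Write a rate field as an HDF5 bundle: one [size, y, x] array per population."""
    grid = field.grid
    with h5py.File(path, "w") as f:
        f.attrs["spacing"] = grid.spacing
        f.attrs["n_x"] = grid.n_x
        f.attrs["n_y"] = grid.n_y
        f.create_dataset("stimulus_sizes", data=field.sizes)
        for pop in field.populations:
            arr = field.get(pop).reshape(len(field.sizes), grid.n_y, grid.n_x)
            f.create_dataset(f"rates/{pop}", data=arr)


def read_rate_bundle(path: str | Path, drive: bool = False) -> RateField:
    """Read an HDF5 rate bundle written by :func:`write_rate_bundle`."""
    with h5py.File(path, "r") as f:
        grid = RetinotopicGrid(int(f.attrs["n_x"]), int(f.attrs["n_y"]), float(f.attrs["spacing"]))
        sizes = f["stimulus_sizes"][()]
        pops = [p for p in (RECURRENT_TYPES + SOURCE_TYPES) if p in f["rates"]]
        data = np.stack(
            [f[f"rates/{p}"][()].reshape(len(sizes), -1) for p in pops]
        )
    if drive:
        return InputDrive(grid, sizes, data)
    return RateField(pops, grid, sizes, data)


# ---------------------------------------------------------------------------
# Model YAML
# ---------------------------------------------------------------------------

def _table_to_dict(table: np.ndarray) -> dict:
    return {
        post: {pre: float(table[a, b]) for b, pre in enumerate(ALL_PRESYN)}
        for a, post in enumerate(RECURRENT_TYPES)
    }


def model_to_dict(model: NetworkModel) -> dict:
    return {
        "grid": {
            "n_x": model.grid.n_x,
            "n_y": model.grid.n_y,
            "spacing": float(model.grid.spacing),
        },
        "amplitudes": _table_to_dict(model.kernels.amplitude),
        "scales": _table_to_dict(model.kernels.scale),
        "biases": {p: float(model.bias[a]) for a, p in enumerate(RECURRENT_TYPES)},
        "taus": {p: float(model.tau[a]) for a, p in enumerate(RECURRENT_TYPES)},
        "nonlinearity": model.nonlinearity.kind,
        "sigma_r": float(model.sigma_r),
        "residual_gain": float(model.residual_gain),
    }


def model_from_dict(d: Mapping) -> NetworkModel:
    grid = RetinotopicGrid(int(d["grid"]["n_x"]), int(d["grid"]["n_y"]), float(d["grid"]["spacing"]))
    kern = KernelParams.from_tables(d["amplitudes"], d["scales"])
    bias = np.array([d["biases"][p] for p in RECURRENT_TYPES], dtype=float)
    tau = np.array([d["taus"][p] for p in RECURRENT_TYPES], dtype=float)
    return NetworkModel(
        grid=grid,
        kernels=kern,
        bias=bias,
        tau=tau,
        nonlinearity=Nonlinearity(d.get("nonlinearity", "rectified_quadratic")),
        sigma_r=float(d.get("sigma_r", 30.0)),
        residual_gain=float(d.get("residual_gain", 0.125)),
    )


def write_model_yaml(path: str | Path, model: NetworkModel) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(model_to_dict(model), f, sort_keys=False)


def read_model_yaml(path: str | Path) -> NetworkModel:
    with open(path) as f:
        return model_from_dict(yaml.safe_load(f))
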