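"""Synthetic ground-truth models and rate-field datasets.

Real experiments of this kind measure cell-type-specific responses to
drifting gratings of 9 sizes (5°–85° in 10° steps) and summarize them as
rate fields over retinotopic space.  The measured feedforward (L4) and
feedback (LM) input fields are not public, so this module generates a
structurally matched stand-in: plateau-with-Gaussian-edge input profiles
whose plateau tracks the stimulus radius, a ground-truth SSN in a chosen
dynamical regime, and noisy observations of its steady states.  Every
downstream stage (fitting, stability, perturbations) can therefore be
exercised and validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

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
    NetworkOperator,
    Nonlinearity,
    RateField,
    residual_field,
    steady_state,
)

#: The 9 stimulus sizes used throughout: 5° to 85° in 10° steps.
DEFAULT_SIZES: np.ndarray = np.arange(5.0, 86.0, 10.0)


# ---------------------------------------------------------------------------
# Input profiles
# ---------------------------------------------------------------------------

@dataclass
class InputProfileSpec:
    """Radially symmetric external-input profile, one per stimulus size.

    ``kind="plateau_gaussian_edge"`` gives a field equal to ``peak`` inside
    the plateau radius with a Gaussian fall-off of width ``edge_scale``
    outside; ``kind="gaussian"`` (or a zero plateau) reduces to a pure
    Gaussian bump.  Plateau radii default to the stimulus radius s/2, the
    footprint of the stimulus itself.
    """

    kind: str = "plateau_gaussian_edge"
    peak: Sequence[float] = ()
    plateau_radius: Sequence[float] = ()
    edge_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("plateau_gaussian_edge", "gaussian"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        self.peak = np.asarray(self.peak, dtype=float)
        self.plateau_radius = np.asarray(self.plateau_radius, dtype=float)
        if np.any(self.peak < 0):
            raise ValueError("peak amplitudes must be non-negative")
        if self.plateau_radius.size and np.any(np.diff(self.plateau_radius) < 0):
            raise ValueError("plateau radii must be nondecreasing in size")

    def field(self, grid: RetinotopicGrid, size_idx: int) -> np.ndarray:
        """(n_nodes,) field for the stimulus with index ``size_idx``."""
        peak = self.peak[size_idx]
        rad = 0.0 if self.kind == "gaussian" else self.plateau_radius[size_idx]
        d = np.maximum(grid.radii - rad, 0.0)
        return peak * np.exp(-d ** 2 / (2.0 * self.edge_scale ** 2))


@dataclass
class NoiseSpec:
    """Observation noise applied to ground-truth steady states."""

    kind: str = "gaussian_additive"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_additive", "gaussian_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class SyntheticDataset:
    """Ground truth model, its drive, and noisy observed rate fields."""

    truth: NetworkModel
    drive: InputDrive
    observed: RateField


# ---------------------------------------------------------------------------
# Ground-truth models
# ---------------------------------------------------------------------------

# Base amplitude table (rows: postsynaptic E, PV, SST, VIP; columns:
# presynaptic E, PV, SST, VIP, L4, LM, R).  Hand-tuned once so that the
# resulting network is inhibition-stabilized with surround-suppressed
# size tuning for E/PV/SST under the default drive; seeds jitter it.
_BASE_AMPLITUDE = np.array(
    [
        # E      PV     SST    VIP    L4     LM     R
        [0.80, -0.25, -0.30, -0.05, 1.20, 0.60, 0.60],   # -> E
        [1.00, -0.30, -0.20, -0.05, 1.00, 0.50, 0.40],   # -> PV
        [0.50, -0.05, -0.00, -0.15, 0.10, 0.50, 0.70],   # -> SST
        [0.40, -0.15, -0.25, -0.00, 0.30, 0.60, 0.40],   # -> VIP
    ]
)

_BASE_BIAS = np.array([-0.10, -0.10, -0.10, -0.05])

# Spatial-scale table in degrees.  SST pools excitation over a wider
# neighbourhood than the other types, the standard source of spatially
# extended surround inhibition; all other projections use 10°.
_BASE_SCALE = np.full((N_REC, N_PRE), 10.0)
_BASE_SCALE[2, 0] = 20.0  # E -> SST


def default_scale_table() -> np.ndarray:
    """Copy of the default 4×7 kernel spatial-scale table (degrees)."""
    return _BASE_SCALE.copy()


def _jittered_params(rng: np.random.Generator, jitter: float):
    amp = _BASE_AMPLITUDE * rng.uniform(1 - jitter, 1 + jitter, _BASE_AMPLITUDE.shape)
    bias = _BASE_BIAS + rng.uniform(-0.05, 0.05, N_REC)
    return amp, bias


def _isn_diagnostics(model: NetworkModel, drive: InputDrive, s: float):
    """(converged, full_leading_re, E_sub_leading_re) at stimulus size s."""
    # local import: stability depends on this module's fixtures otherwise
    from spatialssn.stability import build_linearization, leading_eigenvalue, subnetwork_jacobian

    # candidate models that never settle (limit cycles, runaway) would
    # otherwise burn the full default step budget during retries
    ctx = build_linearization(model, drive, s, max_steps=8000)
    if not ctx.valid:
        return False, np.nan, np.nan
    lam_full = leading_eigenvalue(ctx.jacobian())
    lam_e = leading_eigenvalue(subnetwork_jacobian(ctx, ("PV", "SST", "VIP")))
    return True, lam_full.real, lam_e.real


def make_ground_truth_model(
    seed: int,
    grid: RetinotopicGrid,
    scales: np.ndarray | None = None,
    regime: str = "isn",
    drive: InputDrive | None = None,
    check_size: float = 55.0,
    jitter: float = 0.10,
    max_attempts: int = 12,
) -> NetworkModel:
    """Seeded ground-truth SSN in a requested dynamical regime.

    ``regime="isn"`` returns a model that, at the steady state for a
    ``check_size`` stimulus, has an unstable E subnetwork (leading Jacobian
    eigenvalue with positive real part) while the full network is stable —
    i.e. an inhibition-stabilized network.  ``regime="weak"`` scales all
    recurrent amplitudes by 0.01, giving a network that is stable even
    without inhibition.  Amplitude signs always respect the excitatory /
    inhibitory constraint.  The generator retries with rescaled amplitudes
    until the regime's eigenvalue conditions hold.

    Raises
    ------
    RuntimeError
        If no model satisfying the regime is found in ``max_attempts``.
    """
    if regime not in ("isn", "weak"):
        raise ValueError(f"unknown regime {regime!r}")
    if scales is None:
        scales = _BASE_SCALE
    rng = np.random.default_rng(seed)
    amp, bias = _jittered_params(rng, jitter)
    if regime == "weak":
        amp = amp.copy()
        amp[:, :N_REC] *= 0.01
        return NetworkModel(grid, KernelParams(amp, np.asarray(scales, float)), bias)

    sizes = DEFAULT_SIZES
    if drive is None:
        drive = make_input_fields(grid, sizes)
    rec_scale = 1.0
    for _ in range(max_attempts):
        a = amp.copy()
        a[:, :N_REC] *= rec_scale
        model = NetworkModel(grid, KernelParams(a, np.asarray(scales, float)), bias)
        ok, full_re, e_re = _isn_diagnostics(model, drive, check_size)
        if ok and full_re < 0 and e_re > 0:
            # require convergence at every size, not just the probe
            _, conv = steady_state(model, drive, max_steps=8000)
            if conv.all():
                return model
        if not ok or full_re >= 0:
            rec_scale *= 0.85  # too strong: back off recurrence
        else:
            rec_scale *= 1.15  # E subnetwork stable: strengthen recurrence
    raise RuntimeError(
        f"no ISN-regime model found for seed {seed} in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Input fields
# ---------------------------------------------------------------------------

def default_l4_spec(sizes: Sequence[float] = DEFAULT_SIZES) -> InputProfileSpec:
    """Feedforward drive: grows with size then mildly surround-suppressed."""
    sizes = np.asarray(sizes, float)
    peak = 1.1 * (sizes / 25.0) / (1.0 + (sizes / 25.0) ** 2) * 2.0
    return InputProfileSpec(
        kind="plateau_gaussian_edge",
        peak=peak,
        plateau_radius=sizes / 2.0,
        edge_scale=8.0,
    )


def default_lm_spec(sizes: Sequence[float] = DEFAULT_SIZES) -> InputProfileSpec:
    """Feedback drive: saturating growth with stimulus size."""
    sizes = np.asarray(sizes, float)
    peak = 0.9 * sizes / (sizes + 30.0)
    return InputProfileSpec(
        kind="plateau_gaussian_edge",
        peak=peak,
        plateau_radius=sizes / 2.0,
        edge_scale=12.0,
    )


def make_input_fields(
    grid: RetinotopicGrid,
    sizes: Sequence[float] = DEFAULT_SIZES,
    spec_l4: InputProfileSpec | None = None,
    spec_lm: InputProfileSpec | None = None,
    sigma_r: float = 30.0,
    residual_gain: float = 0.125,
) -> InputDrive:
    """Assemble the external drive (L4, LM, R fields) for all sizes.

    L4 and LM come from the given profile specs (defaults:
    :func:`default_l4_spec` / :func:`default_lm_spec`); the residual field
    R is the model's √s-scaled Gaussian bump.
    """
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes < 0):
        raise ValueError("stimulus sizes must be non-negative")
    # stimuli larger than the grid footprint are allowed: the drive then
    # saturates to its plateau value over the whole modelled patch
    if spec_l4 is None:
        spec_l4 = default_l4_spec(sizes)
    if spec_lm is None:
        spec_lm = default_lm_spec(sizes)
    S = len(sizes)
    data = np.zeros((len(SOURCE_TYPES), S, grid.n_nodes))
    for k in range(S):
        data[0, k] = spec_l4.field(grid, k)
        data[1, k] = spec_lm.field(grid, k)
        data[2, k] = residual_field(grid, sizes[k], sigma_r, residual_gain)
    return InputDrive(grid, sizes, data)


def radial_profile_to_field(
    profile: Sequence[tuple[float, float]], grid: RetinotopicGrid
) -> np.ndarray:
    """2D field from a 1D (distance, rate) profile by linear interpolation.

    Mirrors how experimental rate fields are tabulated: rate as a function
    of distance between a neuron's receptive-field centre and the stimulus
    centre.  Beyond the last tabulated distance the last value is held.
    """
    if len(profile) == 0:
        raise ValueError("profile must contain at least one (distance, rate) pair")
    d = np.asarray([p[0] for p in profile], dtype=float)
    v = np.asarray([p[1] for p in profile], dtype=float)
    if np.any(d < 0) or np.any(np.diff(d) < 0):
        raise ValueError("profile distances must be nonnegative and sorted")
    return np.interp(grid.radii, d, v)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(
    truth: NetworkModel,
    drive: InputDrive,
    noise: NoiseSpec | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticDataset:
    """Noisy observations of a ground-truth model's steady states.

    ``observed = clip(steady_state + noise, 0)``; additive noise sd is
    interpreted per population as ``sd × peak rate`` of that population,
    multiplicative noise scales each rate by ``1 + N(0, sd)``.  If
    ``out_dir`` is given, the observed rates and drive are written in the
    rate-table CSV format and the truth model as YAML.
    """
    if noise is None:
        noise = NoiseSpec()
    ss, conv = steady_state(truth, drive)
    if not conv.all():
        bad = drive.sizes[~conv]
        raise RuntimeError(f"ground-truth steady state did not converge at sizes {bad}")
    rng = np.random.default_rng(noise.seed)
    data = ss.data.copy()
    if noise.sd > 0:
        if noise.kind == "gaussian_additive":
            peak = data.max(axis=(1, 2), keepdims=True)
            data = data + rng.normal(0.0, noise.sd, data.shape) * peak
        else:
            data = data * (1.0 + rng.normal(0.0, noise.sd, data.shape))
        data = np.maximum(data, 0.0)
    observed = RateField(RECURRENT_TYPES, truth.grid, drive.sizes, data)
    ds = SyntheticDataset(truth=truth, drive=drive, observed=observed)
    if out_dir is not None:
        from spatialssn.io import write_model_yaml, write_rate_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_rate_table(out / "observed.csv", observed)
        write_rate_table(out / "drive.csv", drive)
        write_model_yaml(out / "truth.yaml", truth)
    return ds


def default_fixture(
    seed: int = 0,
    noise_sd: float = 0.0,
    regime: str = "isn",
    n: int = 12,
    spacing: float = 6.0,
) -> SyntheticDataset:
    """The shipped default fixture: 12×12 grid, Δ = 6°, sizes 5°–85°.

    Small enough for test suites; noiseless by default so that parameter
    recovery is well-posed.
    """
    grid = RetinotopicGrid(n, n, spacing)
    drive = make_input_fields(grid, DEFAULT_SIZES)
    truth = make_ground_truth_model(seed, grid, regime=regime, drive=drive)
    noise = NoiseSpec(sd=noise_sd, seed=seed + 1)
    return generate_dataset(truth, drive, noise)
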