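"""Core network data model and rate dynamics.

The model is a stabilized supralinear network (SSN): four recurrent cell
types A ∈ {E, PV, SST, VIP} on a 2D retinotopic grid, each unit following

    τ_A dr_A(x;s)/dt = -r_A(x;s) + f( Σ_B Σ_y W_AB(x-y) r_B(y;s) Δ² + T_A )

where B additionally ranges over the external sources L4 (feedforward),
LM (feedback) and R (residual), f is a rectified quadratic (or optionally
rectified linear) input-output function, and the connectivity kernels
W_AB are isotropic 2D Gaussians

    W_AB(x-y) = w_AB / (2π σ_AB²) · exp(-|x-y|² / (2 σ_AB²)).

Amplitudes w_AB are non-negative for excitatory presynaptic types
(E, L4, LM, R) and non-positive for inhibitory ones (PV, SST, VIP).
The residual input is a single Gaussian bump whose peak grows with the
square root of stimulus size:  r_R(x;s) = g·√s·exp(-|x|²/(2σ_R²)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from spatialssn.grid import RetinotopicGrid

#: Recurrent cell types, in the fixed order used for all block layouts.
RECURRENT_TYPES: tuple[str, ...] = ("E", "PV", "SST", "VIP")
#: External input sources, in fixed order.
SOURCE_TYPES: tuple[str, ...] = ("L4", "LM", "R")
#: All presynaptic types (recurrent + sources), in fixed order.
ALL_PRESYN: tuple[str, ...] = RECURRENT_TYPES + SOURCE_TYPES
#: Presynaptic types whose outgoing weights must be >= 0.
EXCITATORY_PRESYN = frozenset({"E", "L4", "LM", "R"})

N_REC = len(RECURRENT_TYPES)
N_PRE = len(ALL_PRESYN)


# ---------------------------------------------------------------------------
# Nonlinearity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nonlinearity:
    """Rectified power-law input-output function.

    ``rectified_quadratic`` maps u ↦ [u]₊² (the SSN's expansive
    nonlinearity); ``rectified_linear`` maps u ↦ [u]₊.  The derivative at
    u ≤ 0 is 0 for both, so silent units decouple from the linearization.
    """

    kind: str = "rectified_quadratic"

    def __post_init__(self) -> None:
        if self.kind not in ("rectified_quadratic", "rectified_linear"):
            raise ValueError(f"unknown nonlinearity kind: {self.kind!r}")

    def f(self, u: np.ndarray) -> np.ndarray:
        up = np.maximum(u, 0.0)
        if self.kind == "rectified_quadratic":
            return up * up
        return up

    def df(self, u: np.ndarray) -> np.ndarray:
        """Elementwise derivative f'(u); 0 at u ≤ 0 by convention."""
        if self.kind == "rectified_quadratic":
            return 2.0 * np.maximum(u, 0.0)
        return (np.asarray(u) > 0.0).astype(float)


def apply_nonlinearity(u: np.ndarray, nl: Nonlinearity) -> np.ndarray:
    """Apply the input-output function elementwise; output is ≥ 0."""
    return nl.f(np.asarray(u, dtype=float))


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def gaussian_kernel_matrix(
    grid: RetinotopicGrid, amplitude: float, scale: float
) -> np.ndarray:
    """Node-by-node coupling matrix of an isotropic 2D Gaussian kernel.

    Entry (i, j) is ``amplitude / (2π scale²) · exp(-|x_i - x_j|²/(2 scale²))``.
    Multiplying by Δ² and summing over j approximates the kernel integral,
    which equals ``amplitude`` for nodes far from the (open, truncated)
    boundary.

    Raises
    ------
    ValueError
        If ``scale`` is not positive (grids with < 2 nodes per axis are
        already rejected by :class:`RetinotopicGrid`).
    """
    if not scale > 0:
        raise ValueError("kernel scale must be positive")
    norm = amplitude / (2.0 * np.pi * scale ** 2)
    return norm * np.exp(-grid.sq_distance_matrix / (2.0 * scale ** 2))


@dataclass
class KernelParams:
    """Gaussian kernel amplitudes and spatial scales.

    ``amplitude[a, b]`` and ``scale[a, b]`` are indexed by postsynaptic
    recurrent type ``a`` (order :data:`RECURRENT_TYPES`) and presynaptic
    type ``b`` (order :data:`ALL_PRESYN`), giving 4×7 tables.  Amplitudes
    carry the sign of the presynaptic type: ≥ 0 for E/L4/LM/R, ≤ 0 for
    PV/SST/VIP.  Scales are in degrees and strictly positive.
    """

    amplitude: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.amplitude.shape != (N_REC, N_PRE) or self.scale.shape != (N_REC, N_PRE):
            raise ValueError(f"kernel tables must have shape ({N_REC}, {N_PRE})")
        self.validate()

    def validate(self) -> None:
        if not np.all(self.scale > 0):
            raise ValueError("all kernel scales must be positive")
        for b, pre in enumerate(ALL_PRESYN):
            col = self.amplitude[:, b]
            if pre in EXCITATORY_PRESYN:
                if np.any(col < 0):
                    raise ValueError(f"amplitudes from {pre} must be non-negative")
            elif np.any(col > 0):
                raise ValueError(f"amplitudes from {pre} must be non-positive")

    @classmethod
    def from_tables(
        cls,
        amplitude: Mapping[str, Mapping[str, float]],
        scale: Mapping[str, Mapping[str, float]] | float,
    ) -> "KernelParams":
        """Build from nested ``{post: {pre: value}}`` dicts (or uniform scale)."""
        amp = np.zeros((N_REC, N_PRE))
        if np.isscalar(scale):
            sig = np.full((N_REC, N_PRE), float(scale))
        else:
            sig = np.zeros((N_REC, N_PRE))
        for a, post in enumerate(RECURRENT_TYPES):
            for b, pre in enumerate(ALL_PRESYN):
                amp[a, b] = amplitude[post][pre]
                if not np.isscalar(scale):
                    sig[a, b] = scale[post][pre]
        return cls(amp, sig)

    def amplitude_of(self, post: str, pre: str) -> float:
        return float(self.amplitude[RECURRENT_TYPES.index(post), ALL_PRESYN.index(pre)])

    def scale_of(self, post: str, pre: str) -> float:
        return float(self.scale[RECURRENT_TYPES.index(post), ALL_PRESYN.index(pre)])


# ---------------------------------------------------------------------------
# Rate fields
# ---------------------------------------------------------------------------

class RateField:
    """Rates indexed by (population, grid node, stimulus size).

    Stored as an array of shape ``(n_populations, n_sizes, n_nodes)`` with
    nodes flattened row-major (see :attr:`RetinotopicGrid.coords`).  Values
    are non-negative; stimulus sizes are strictly increasing, in degrees.
    """

    def __init__(
        self,
        populations: Sequence[str],
        grid: RetinotopicGrid,
        sizes: Sequence[float],
        data: np.ndarray,
    ) -> None:
        self.populations = tuple(populations)
        self.grid = grid
        self.sizes = np.asarray(sizes, dtype=float)
        self.data = np.asarray(data, dtype=float)
        if self.sizes.ndim != 1 or (len(self.sizes) > 1 and not np.all(np.diff(self.sizes) > 0)):
            raise ValueError("stimulus sizes must be strictly increasing")
        expected = (len(self.populations), len(self.sizes), grid.n_nodes)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != expected {expected}")
        if np.any(self.data < 0):
            raise ValueError("rates must be non-negative")

    # -- accessors ---------------------------------------------------------
    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def size_index(self, size: float) -> int:
        idx = np.flatnonzero(np.isclose(self.sizes, size))
        if idx.size == 0:
            raise KeyError(f"stimulus size {size} not in {self.sizes}")
        return int(idx[0])

    def get(self, population: str, size: float | None = None) -> np.ndarray:
        """Rates of one population: (n_sizes, n_nodes), or (n_nodes,) at one size."""
        arr = self.data[self.pop_index(population)]
        if size is None:
            return arr
        return arr[self.size_index(size)]

    def size_tuning(self, population: str, node: int | None = None) -> np.ndarray:
        """Response vs stimulus size of one node (default: the centred unit)."""
        if node is None:
            node = self.grid.center_index
        return self.data[self.pop_index(population), :, node]

    def copy(self) -> "RateField":
        return RateField(self.populations, self.grid, self.sizes, self.data.copy())

    def allclose(self, other: "RateField", **kw) -> bool:
        return (
            self.populations == other.populations
            and np.array_equal(self.sizes, other.sizes)
            and np.allclose(self.data, other.data, **kw)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RateField(populations={self.populations}, "
            f"n_sizes={len(self.sizes)}, n_nodes={self.grid.n_nodes})"
        )


class InputDrive(RateField):
    """External source rate fields r_L4, r_LM, r_R on the model grid."""

    def __init__(self, grid, sizes, data, populations=SOURCE_TYPES):
        if tuple(populations) != SOURCE_TYPES:
            raise ValueError(f"drive populations must be {SOURCE_TYPES}")
        super().__init__(populations, grid, sizes, data)


def residual_field(
    grid: RetinotopicGrid,
    s: float,
    sigma_r: float,
    gain: float = 0.125,
    scaling: str = "sqrt",
) -> np.ndarray:
    """Residual-input field r_R(x;s) = gain·√s·exp(-|x|²/(2 σ_R²)).

    The residual input stands in for unmeasured projections to L2/3; its
    peak amplitude grows with the square root of stimulus size.  With
    ``scaling="linear"`` the amplitude instead grows linearly in s, the
    hypothetical alternative whose much steeper large-vs-small amplitude
    ratio motivates the square-root choice.
    """
    if s < 0:
        raise ValueError("stimulus size must be non-negative")
    if not sigma_r > 0:
        raise ValueError("sigma_r must be positive")
    if scaling == "sqrt":
        amp = gain * np.sqrt(s)
    elif scaling == "linear":
        amp = gain * s
    else:
        raise ValueError(f"unknown residual scaling {scaling!r}")
    return amp * np.exp(-grid.radii ** 2 / (2.0 * sigma_r ** 2))


def residual_drive_fields(model: "NetworkModel", sizes: Sequence[float]) -> np.ndarray:
    """Stack of residual fields, shape (n_sizes, n_nodes)."""
    return np.stack(
        [residual_field(model.grid, s, model.sigma_r, model.residual_gain) for s in sizes]
    )


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """All parameters of the spatial SSN.

    The 32 free parameters inferred from data are the 28 kernel amplitudes
    and the 4 biases; spatial scales, time constants, the nonlinearity and
    the residual profile (σ_R, gain) are fixed.
    """

    grid: RetinotopicGrid
    kernels: KernelParams
    bias: np.ndarray  # (4,) input-current units, per recurrent type
    tau: np.ndarray = field(default_factory=lambda: np.array([0.02, 0.01, 0.01, 0.01]))
    nonlinearity: Nonlinearity = field(default_factory=Nonlinearity)
    sigma_r: float = 30.0
    residual_gain: float = 0.125

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.bias.shape != (N_REC,) or self.tau.shape != (N_REC,):
            raise ValueError(f"bias and tau must have shape ({N_REC},)")
        if not np.all(self.tau > 0):
            raise ValueError("time constants must be positive")
        for name in ("sigma_r", "residual_gain"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not np.all(np.isfinite(self.bias)) or not np.all(np.isfinite(self.kernels.amplitude)):
            raise ValueError("model parameters must be finite")

    def with_params(self, amplitude: np.ndarray, bias: np.ndarray) -> "NetworkModel":
        """Copy of the model with new amplitudes (4×7) and biases (4,)."""
        kern = KernelParams(np.asarray(amplitude, float), self.kernels.scale.copy())
        return replace(self, kernels=kern, bias=np.asarray(bias, float))

    # -- free-parameter vector (28 amplitudes + 4 biases) ------------------
    def free_params(self) -> np.ndarray:
        return np.concatenate([self.kernels.amplitude.ravel(), self.bias])

    def with_free_params(self, theta: np.ndarray) -> "NetworkModel":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (N_REC * N_PRE + N_REC,):
            raise ValueError("expected 32 free parameters")
        amp = theta[: N_REC * N_PRE].reshape(N_REC, N_PRE)
        return self.with_params(amp, theta[N_REC * N_PRE:])


# ---------------------------------------------------------------------------
# Fast evaluation operator
# ---------------------------------------------------------------------------

class NetworkOperator:
    """Precomputed kernels and source currents for repeated evaluation.

    Unit-amplitude kernel matrices depend only on the grid and the (fixed)
    scale table, so they are computed once; the recurrent connectivity and
    the external input are then cheap functions of the amplitudes/biases.
    This is the workhorse behind the steady-state solvers and the fitter.
    """

    def __init__(self, model: NetworkModel, drive: InputDrive | None = None) -> None:
        if drive is not None and drive.grid is not model.grid:
            if (
                drive.grid.n_x != model.grid.n_x
                or drive.grid.n_y != model.grid.n_y
                or drive.grid.spacing != model.grid.spacing
            ):
                raise ValueError("drive grid does not match model grid")
        self.model = model
        self.drive = drive
        self.grid = model.grid
        self.n = self.grid.n_nodes
        self.dv = self.grid.area_element
        # unit kernels per (post, pre) pair; amplitude folded in later
        self._unit_kernels = np.empty((N_REC, N_PRE), dtype=object)
        for a in range(N_REC):
            for b in range(N_PRE):
                self._unit_kernels[a, b] = gaussian_kernel_matrix(
                    self.grid, 1.0, model.kernels.scale[a, b]
                )
        # per-source unit currents: u[a][b][s] = Δ² K̂_ab r_b(s), (S, n)
        self._unit_source_currents = None
        if drive is not None:
            self.sizes = drive.sizes
            S = len(self.sizes)
            usc = np.zeros((N_REC, len(SOURCE_TYPES), S, self.n))
            for a in range(N_REC):
                for j, src in enumerate(SOURCE_TYPES):
                    K = self._unit_kernels[a, N_REC + j]
                    usc[a, j] = self.dv * drive.get(src) @ K.T
                # K symmetric, but keep the (x,y) orientation explicit
            self._unit_source_currents = usc

    # -- assembly ----------------------------------------------------------
    def unit_kernel(self, a: int, b: int) -> np.ndarray:
        return self._unit_kernels[a, b]

    def recurrent_matrix(self, amplitude: np.ndarray) -> np.ndarray:
        """Full (4n × 4n) node-level recurrent connectivity, Δ² included."""
        n = self.n
        W = np.zeros((N_REC * n, N_REC * n))
        for a in range(N_REC):
            for b in range(N_REC):
                w = amplitude[a, b]
                if w != 0.0:
                    W[a * n:(a + 1) * n, b * n:(b + 1) * n] = (
                        w * self.dv
                    ) * self._unit_kernels[a, b]
        return W

    def external_input(self, amplitude: np.ndarray, bias: np.ndarray) -> np.ndarray:
        """External current Σ_src w·(K r_src)Δ² + T, shape (4n, S)."""
        if self._unit_source_currents is None:
            raise ValueError("operator was built without a drive")
        S = len(self.sizes)
        h = np.zeros((N_REC * self.n, S))
        for a in range(N_REC):
            blk = h[a * self.n:(a + 1) * self.n]
            for j in range(len(SOURCE_TYPES)):
                w = amplitude[a, N_REC + j]
                if w != 0.0:
                    blk += w * self._unit_source_currents[a, j].T
            blk += bias[a]
        return h

    def block(self, vec: np.ndarray, a: int) -> np.ndarray:
        """Slice of a stacked (4n, ...) array belonging to recurrent type a."""
        return vec[a * self.n:(a + 1) * self.n]


# ---------------------------------------------------------------------------
# Input assembly and dynamics
# ---------------------------------------------------------------------------

def total_input(
    model: NetworkModel,
    rates: RateField,
    drive: InputDrive,
    s: float,
    operator: NetworkOperator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Per-type total input current and its per-source decomposition.

    Returns ``(total, parts)`` where ``total[A]`` is the (n_nodes,) input
    current to type A at stimulus size ``s`` and ``parts[A][B]`` is the
    contribution of presynaptic type/source B (bias under key ``"bias"``);
    the parts sum to the total.
    """
    if tuple(rates.populations) != RECURRENT_TYPES:
        raise ValueError("rates must cover the four recurrent types")
    for f_ in (rates, drive):
        if (f_.grid.n_x, f_.grid.n_y, f_.grid.spacing) != (
            model.grid.n_x, model.grid.n_y, model.grid.spacing,
        ):
            raise ValueError("rate/drive grid does not match model grid")
    op = operator or NetworkOperator(model)
    dv = model.grid.area_element
    amp = model.kernels.amplitude
    parts: dict[str, dict[str, np.ndarray]] = {}
    total: dict[str, np.ndarray] = {}
    for a, post in enumerate(RECURRENT_TYPES):
        parts[post] = {}
        acc = np.full(model.grid.n_nodes, model.bias[a])
        parts[post]["bias"] = np.full(model.grid.n_nodes, model.bias[a])
        for b, pre in enumerate(ALL_PRESYN):
            r_pre = rates.get(pre, s) if pre in RECURRENT_TYPES else drive.get(pre, s)
            contrib = amp[a, b] * dv * (op.unit_kernel(a, b) @ r_pre)
            parts[post][pre] = contrib
            acc = acc + contrib
        total[post] = acc
    return total, parts


class DivergenceError(RuntimeError):
    """Raised when rates exceed the divergence ceiling during integration."""


#: Any rate above this aborts integration with a divergence signal.
DIVERGENCE_CEILING = 1.0e6


def _euler_solve(
    W: np.ndarray,
    h: np.ndarray,
    tau_nodes: np.ndarray,
    nl: Nonlinearity,
    r0: np.ndarray,
    dt: float,
    max_steps: int,
    tol: float,
    ceiling: float = DIVERGENCE_CEILING,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Explicit-Euler relaxation of τ dr/dt = -r + f(Wr + h).

    All stimulus sizes are integrated simultaneously (columns of ``h``).
    Returns ``(r, converged, diverged)`` with per-column flags; converged
    columns are frozen once their relative residual drops below ``tol``.
    """
    r = r0.copy()
    S = h.shape[1]
    converged = np.zeros(S, dtype=bool)
    diverged = np.zeros(S, dtype=bool)
    step_fac = (dt / tau_nodes)[:, None]
    active = np.ones(S, dtype=bool)
    for _ in range(max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        ra = r[:, idx]
        g = -ra + nl.f(W @ ra + h[:, idx])
        res = np.max(np.abs(g), axis=0) / (np.max(ra, axis=0) + 1e-12)
        newly_conv = res < tol
        bad = np.max(ra, axis=0) > ceiling
        r[:, idx] = ra + step_fac * g
        converged[idx[newly_conv]] = True
        diverged[idx[bad]] = True
        active[idx[newly_conv | bad]] = False
    return r, converged, diverged


def _newton_polish(
    W: np.ndarray,
    h: np.ndarray,
    nl: Nonlinearity,
    r: np.ndarray,
    tol: float,
    max_iter: int = 25,
    max_rel_step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton refinement of fixed points r = f(Wr + h), per column.

    Steps are damped (capped relative to the current rate scale) so the
    polish stays within the basin found by the relaxation phase.  Returns
    the refined rates and a per-column success flag.
    """
    n = W.shape[0]
    S = h.shape[1]
    ok = np.zeros(S, dtype=bool)
    out = r.copy()
    for j in range(S):
        rj = out[:, j].copy()
        scale0 = max(np.max(rj), 1e-9)
        for _ in range(max_iter):
            u = W @ rj + h[:, j]
            g = nl.f(u) - rj
            resid = np.max(np.abs(g)) / (np.max(rj) + 1e-12)
            if resid < tol:
                ok[j] = True
                break
            Fdiag = nl.df(u)
            A = np.eye(n) - Fdiag[:, None] * W
            try:
                delta = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                break
            step_norm = np.max(np.abs(delta))
            cap = max_rel_step * max(np.max(rj), scale0, 1.0)
            if step_norm > cap:
                delta *= cap / step_norm
            rj = np.maximum(rj + delta, 0.0)
            if not np.all(np.isfinite(rj)) or np.max(rj) > DIVERGENCE_CEILING:
                break
        else:
            u = W @ rj + h[:, j]
            resid = np.max(np.abs(nl.f(u) - rj)) / (np.max(rj) + 1e-12)
            ok[j] = resid < tol
        if ok[j]:
            out[:, j] = rj
    return out, ok


def integrate_dynamics(
    model: NetworkModel,
    drive: InputDrive,
    r0: RateField | None = None,
    dt: float | None = None,
    duration: float = 1.0,
    record_every: int = 10,
    extra_input: np.ndarray | None = None,
    operator: NetworkOperator | None = None,
) -> tuple[np.ndarray, RateField, np.ndarray]:
    """Explicit time stepping of the rate dynamics for all stimulus sizes.

    Parameters
    ----------
    r0 : RateField, optional
        Initial rates (default: zeros).
    dt : float, optional
        Time step; default min(τ)/10, must satisfy dt ≤ min(τ)/5.
    duration : float
        Total simulated time in seconds.
    record_every : int
        Sampling stride for the returned trajectory.
    extra_input : ndarray, optional
        Additional current, shape (4·n_nodes, n_sizes) or a callable-free
        constant term (used for perturbation experiments).

    Returns
    -------
    times : (n_samples,) array of sample times.
    final : RateField of the state at the last step.
    trajectory : (n_samples, 4·n_nodes, n_sizes) array.
    """
    if dt is None:
        dt = float(np.min(model.tau)) / 10.0
    if not (dt > 0 and dt <= np.min(model.tau) / 5.0 + 1e-15):
        raise ValueError("dt must be positive and at most min(tau)/5")
    op = operator or NetworkOperator(model, drive)
    W = op.recurrent_matrix(model.kernels.amplitude)
    h = op.external_input(model.kernels.amplitude, model.bias)
    if extra_input is not None:
        h = h + extra_input
    n = op.n
    tau_nodes = np.repeat(model.tau, n)
    if r0 is None:
        r = np.zeros_like(h)
    else:
        r = np.concatenate([r0.get(p) for p in RECURRENT_TYPES], axis=1).T.copy()
    n_steps = max(int(round(duration / dt)), 1)
    step_fac = (dt / tau_nodes)[:, None]
    nl = model.nonlinearity
    times = [0.0]
    traj = [r.copy()]
    for k in range(1, n_steps + 1):
        g = -r + nl.f(W @ r + h)
        r = r + step_fac * g
        if np.max(r) > DIVERGENCE_CEILING:
            raise DivergenceError(f"rates exceeded ceiling at t={k * dt:.4f}s")
        if k % record_every == 0 or k == n_steps:
            times.append(k * dt)
            traj.append(r.copy())
    final = RateField(
        RECURRENT_TYPES,
        model.grid,
        drive.sizes,
        np.maximum(r.T.reshape(len(drive.sizes), N_REC, n).swapaxes(0, 1), 0.0),
    )
    return np.asarray(times), final, np.asarray(traj)


def steady_state(
    model: NetworkModel,
    drive: InputDrive,
    s: float | None = None,
    tol: float = 1e-6,
    max_steps: int = 100_000,
    dt: float | None = None,
    r0: RateField | None = None,
    operator: NetworkOperator | None = None,
    newton_polish: bool = True,
) -> tuple[RateField, np.ndarray]:
    """Steady state of the rate dynamics.

    Relaxes the dynamics by explicit Euler until the relative residual
    ``max|−r + f(input)| / (max r + ε)`` drops below ``tol`` (optionally
    finishing with a damped Newton polish), for every stimulus size in
    ``drive`` or just size ``s``.

    Returns the steady-state :class:`RateField` and a per-size boolean
    convergence flag; divergence or an exhausted step budget is reported
    through the flag, never raised.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    op = operator or NetworkOperator(model, drive)
    sizes = drive.sizes if s is None else np.array([s], dtype=float)
    W = op.recurrent_matrix(model.kernels.amplitude)
    h_all = op.external_input(model.kernels.amplitude, model.bias)
    if s is not None:
        h_all = h_all[:, [drive.size_index(s)]]
    if dt is None:
        dt = float(np.min(model.tau)) / 10.0
    tau_nodes = np.repeat(model.tau, op.n)
    if r0 is None:
        r_init = np.zeros_like(h_all)
    else:
        cols = [r0.size_index(sz) for sz in sizes]
        r_init = np.concatenate(
            [r0.get(p)[cols] for p in RECURRENT_TYPES], axis=1
        ).T.copy()
    # loose Euler phase finds the basin; Newton sharpens to tol
    euler_tol = max(tol, 1e-4) if newton_polish else tol
    r, conv, div = _euler_solve(
        W, h_all, tau_nodes, model.nonlinearity, r_init, dt, max_steps, euler_tol
    )
    if newton_polish:
        cols = np.flatnonzero(conv & ~div)
        if cols.size:
            polished, ok = _newton_polish(
                W, h_all[:, cols], model.nonlinearity, r[:, cols], tol
            )
            r[:, cols] = np.where(ok[None, :], polished, r[:, cols])
            # fall back to a strict Euler run for columns Newton could not fix
            bad = cols[~ok]
            if bad.size:
                r_b, c_b, d_b = _euler_solve(
                    W, h_all[:, bad], tau_nodes, model.nonlinearity,
                    r[:, bad], dt, max_steps, tol,
                )
                r[:, bad] = r_b
                conv[bad] = c_b
                div[bad] |= d_b
    converged = conv & ~div
    n = op.n
    data = np.maximum(r.T.reshape(len(sizes), N_REC, n).swapaxes(0, 1), 0.0)
    field_sizes = sizes
    return RateField(RECURRENT_TYPES, model.grid, field_sizes, data), converged
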