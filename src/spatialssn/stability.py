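"""Jacobian spectra and cell-type-specific stabilization analysis.

At a fixed point the linearized dynamics are governed by the Jacobian

    J = T⁻¹ (−I + F W),

where T is the diagonal matrix of time constants, F the diagonal matrix of
nonlinearity derivatives f'(u) evaluated at the fixed-point input, and W
the node-level connectivity (kernels × Δ²).  Whether an inhibitory cell
type X is required for stabilization is read off the Jacobian of the
subnetwork with all nodes of X removed: a leading eigenvalue with positive
real part means the excluded type is needed to keep the circuit stable.
The four standard subnetworks are the E-only subnetwork (is any inhibition
needed?), and the networks excluding PV, SST, or VIP respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse.linalg

from spatialssn.network import (
    N_REC,
    RECURRENT_TYPES,
    InputDrive,
    NetworkModel,
    NetworkOperator,
    RateField,
    steady_state,
)

#: Subnetwork labels -> excluded populations.
SUBNETWORKS: dict[str, tuple[str, ...]] = {
    "E": ("PV", "SST", "VIP"),
    "E-SST-VIP": ("PV",),
    "E-PV-VIP": ("SST",),
    "E-PV-SST": ("VIP",),
    "full": (),
}

#: Dense eigensolver is used up to this many rows; iterative above.
DENSE_EIG_LIMIT = 2000


@dataclass
class LinearizationContext:
    """Everything needed to linearize the dynamics at a fixed point.

    ``W`` is node-level connectivity with Δ² folded in, ``F`` the diagonal
    gain entries f'(u*), ``tau`` per-node time constants; ``blocks`` maps
    each population to its node indices in the stacked layout.  Contexts
    may also be built directly from matrices (e.g. for low-dimensional
    textbook circuits) via the constructor.
    """

    W: np.ndarray
    F: np.ndarray
    tau: np.ndarray
    blocks: Mapping[str, np.ndarray]
    fixed_point: RateField | None = None
    size: float | None = None
    valid: bool = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        m = self.W.shape[0]
        if self.W.shape != (m, m) or self.F.shape != (m,) or self.tau.shape != (m,):
            raise ValueError("inconsistent matrix/vector dimensions")
        if np.any(self.F < 0):
            raise ValueError("gain entries f'(u) must be non-negative")
        if np.any(self.tau <= 0):
            raise ValueError("time constants must be positive")
        self.blocks = {k: np.asarray(v, dtype=int) for k, v in self.blocks.items()}

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def jacobian(self) -> np.ndarray:
        """J = T⁻¹(−I + F W)."""
        m = self.n_units
        return (-np.eye(m) + self.F[:, None] * self.W) / self.tau[:, None]

    def indices_excluding(self, excluded: Iterable[str]) -> np.ndarray:
        excluded = set(excluded)
        keep = [
            idx
            for pop, idx in self.blocks.items()
            if pop not in excluded
        ]
        return np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)


def build_linearization(
    model: NetworkModel,
    drive: InputDrive,
    s: float,
    operator: NetworkOperator | None = None,
    tol: float = 1e-8,
    max_steps: int = 100_000,
) -> LinearizationContext:
    """Linearization of the SSN at the steady state for stimulus size ``s``.

    If the steady state does not converge the context is returned with
    ``valid=False`` and should not be analysed further.
    """
    op = operator or NetworkOperator(model, drive)
    fp, conv = steady_state(model, drive, s=s, tol=tol, operator=op, max_steps=max_steps)
    n = model.grid.n_nodes
    blocks = {
        pop: np.arange(a * n, (a + 1) * n) for a, pop in enumerate(RECURRENT_TYPES)
    }
    W = op.recurrent_matrix(model.kernels.amplitude)
    h = op.external_input(model.kernels.amplitude, model.bias)[:, drive.size_index(s)]
    r = np.concatenate([fp.get(p, s) for p in RECURRENT_TYPES])
    u = W @ r + h
    F = model.nonlinearity.df(u)
    tau_nodes = np.repeat(model.tau, n)
    return LinearizationContext(
        W=W,
        F=F,
        tau=tau_nodes,
        blocks=blocks,
        fixed_point=fp,
        size=float(s),
        valid=bool(conv[0]),
    )


def subnetwork_jacobian(
    ctx: LinearizationContext, excluded: Iterable[str] = ()
) -> np.ndarray:
    """Jacobian with the rows/columns of the excluded populations removed.

    The E population can never be excluded; excluding nothing returns the
    full Jacobian.
    """
    excluded = tuple(excluded)
    if "E" in excluded:
        raise ValueError("the E population cannot be excluded")
    unknown = set(excluded) - set(ctx.blocks)
    if unknown:
        raise ValueError(f"unknown populations to exclude: {sorted(unknown)}")
    J = ctx.jacobian()
    if not excluded:
        return J
    keep = ctx.indices_excluding(excluded)
    return J[np.ix_(keep, keep)]


def leading_eigenvalue(matrix: np.ndarray) -> complex:
    """Eigenvalue with the largest real part.

    Ties are broken deterministically: among eigenvalues of maximal real
    part the one of smallest |imaginary part| wins, and of a conjugate
    pair the representative with non-negative imaginary part is returned.
    Dense decomposition is used up to ``DENSE_EIG_LIMIT`` rows, an
    iterative largest-real-part solver above.
    """
    matrix = np.asarray(matrix)
    m = matrix.shape[0]
    if matrix.shape != (m, m):
        raise ValueError("matrix must be square")
    if m <= DENSE_EIG_LIMIT:
        vals = np.linalg.eigvals(matrix)
    else:
        vals = scipy.sparse.linalg.eigs(
            matrix, k=min(6, m - 2), which="LR", return_eigenvectors=False
        )
    order = np.lexsort((np.abs(vals.imag), -vals.real))
    lead = vals[order[0]]
    if lead.imag < 0:
        lead = np.conj(lead)
    return complex(lead)


@dataclass
class StabilityReport:
    """Per-size leading eigenvalues of all subnetworks, plus derived flags.

    ``entries`` is a tidy table with columns size, subnetwork, re_lead,
    im_lead, n_unstable; ``flags`` maps each stimulus size to the derived
    booleans (inhibition_stabilized and the per-type *_required flags).
    ``tau`` records the time constants the Jacobians were built with.
    """

    entries: pd.DataFrame
    flags: dict[float, dict[str, bool]]
    tau: np.ndarray

    def leading(self, size: float, subnetwork: str) -> complex:
        sel = self.entries[
            (self.entries["subnetwork"] == subnetwork)
            & np.isclose(self.entries["size"], size)
        ]
        if sel.empty:
            raise KeyError(f"no entry for size {size}, subnetwork {subnetwork!r}")
        row = sel.iloc[0]
        return complex(row["re_lead"], row["im_lead"])

    def flag(self, size: float, name: str) -> bool:
        for sz, fl in self.flags.items():
            if np.isclose(sz, size):
                return fl[name]
        raise KeyError(f"no flags for size {size}")


def classify_stabilization(
    model: NetworkModel,
    drive: InputDrive,
    sizes: Sequence[float] | None = None,
    operator: NetworkOperator | None = None,
) -> StabilityReport:
    """Cell-type-specific stabilization classification across sizes.

    For every stimulus size, evaluates the leading eigenvalue of the full
    Jacobian and of the four subnetworks, and derives:

    - ``inhibition_stabilized``: E subnetwork unstable and full network
      stable (the ISN signature);
    - ``PV_required`` / ``SST_required`` / ``VIP_required``: the network
      without that type is unstable.

    Sizes whose steady state does not converge are reported with NaN
    eigenvalues and no flags.
    """
    if sizes is None:
        sizes = drive.sizes
    op = operator or NetworkOperator(model, drive)
    records = []
    flags: dict[float, dict[str, bool]] = {}
    for s in sizes:
        ctx = build_linearization(model, drive, float(s), operator=op)
        lead: dict[str, complex] = {}
        for name, excl in SUBNETWORKS.items():
            if not ctx.valid:
                records.append(
                    dict(size=float(s), subnetwork=name, re_lead=np.nan,
                         im_lead=np.nan, n_unstable=-1)
                )
                continue
            sub = subnetwork_jacobian(ctx, excl)
            vals = np.linalg.eigvals(sub) if sub.shape[0] <= DENSE_EIG_LIMIT else None
            if vals is not None:
                order = np.lexsort((np.abs(vals.imag), -vals.real))
                lam = vals[order[0]]
                if lam.imag < 0:
                    lam = np.conj(lam)
                n_unstable = int(np.sum(vals.real > 0))
            else:
                lam = leading_eigenvalue(sub)
                n_unstable = -1
            lead[name] = lam
            records.append(
                dict(size=float(s), subnetwork=name, re_lead=float(lam.real),
                     im_lead=float(lam.imag), n_unstable=n_unstable)
            )
        if ctx.valid:
            flags[float(s)] = {
                "inhibition_stabilized": lead["E"].real > 0 and lead["full"].real < 0,
                "PV_required": lead["E-SST-VIP"].real > 0,
                "SST_required": lead["E-PV-VIP"].real > 0,
                "VIP_required": lead["E-PV-SST"].real > 0,
            }
    return StabilityReport(
        entries=pd.DataFrame.from_records(records),
        flags=flags,
        tau=model.tau.copy(),
    )
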