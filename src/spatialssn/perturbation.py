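"""Linear response theory and perturbation experiments.

At a stable fixed point, a small change δh in the input produces a
steady-state rate change δr ≈ R δh with the response matrix

    R = (I − F W)⁻¹ F.

The diagonal block R_XX maps perturbations of cell type X onto activity
changes of the same type.  A perturbation is *paradoxical* when
δr_X · δh_X < 0 — the activity moves against the injected current.

Uniform perturbations γ·1_X probe the mean activity; expanding 1_X in the
eigenbasis of R_XX (R_XX v_i = λ_i v_i, λ ascending by real part) shows
the mean change mixes all modes, so a negative λ₁ can be masked by the
others.  A patterned perturbation γ·v₁ instead isolates the leading mode:
its projection responds as γ λ₁ |v₁|², paradoxical exactly when λ₁ < 0.

The counting diagnostic: the number of eigenvalues of −J₋X with negative
real part (unstable modes of the subnetwork excluding X) has the same
parity as the number of eigenvalues of R_XX with negative real part
(paradoxically responding modes of X), because det(−J₋X) and det(R_XX)
share their sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from spatialssn.network import (
    DIVERGENCE_CEILING,
    RECURRENT_TYPES,
    DivergenceError,
    InputDrive,
    NetworkModel,
    NetworkOperator,
    RateField,
    steady_state,
)
from spatialssn.stability import LinearizationContext, build_linearization

#: Condition-number threshold above which an eigenbasis is flagged defective.
DEFECTIVE_COND = 1e10

#: Composite perturbation target: PV, SST and VIP jointly.
ALL_INHIBITORY = ("PV", "SST", "VIP")


class CriticalityError(RuntimeError):
    """(I − F W) is singular: the network sits at criticality."""


# ---------------------------------------------------------------------------
# Response matrix and eigenbases
# ---------------------------------------------------------------------------

@dataclass
class EigenBasis:
    """Eigen-decomposition of a response block R_XX.

    Eigenvalues are sorted ascending by real part (ties: ascending
    |imaginary part|); eigenvectors have unit Euclidean norm with the
    phase fixed so the largest-magnitude entry is real and positive.
    ``coefficients`` solves 1_X = V c.  ``reliable`` is False when V is
    ill-conditioned (defective to numerical precision).
    """

    values: np.ndarray
    vectors: np.ndarray  # columns
    coefficients: np.ndarray
    condition: float
    reliable: bool


@dataclass
class ResponseContext:
    """Response matrix R with block structure and cached eigenbases."""

    R: np.ndarray
    blocks: Mapping[str, np.ndarray]
    ctx: LinearizationContext
    _bases: dict[str, EigenBasis] = field(default_factory=dict, repr=False)

    def block(self, X: str) -> np.ndarray:
        idx = self.blocks[X]
        return self.R[np.ix_(idx, idx)]

    def eigenbasis(self, X: str) -> EigenBasis:
        if X not in self._bases:
            self._bases[X] = _eigenbasis(self.block(X))
        return self._bases[X]


def _eigenbasis(RXX: np.ndarray) -> EigenBasis:
    vals, vecs = np.linalg.eig(RXX)
    order = np.lexsort((np.abs(vals.imag), vals.real))
    vals = vals[order]
    vecs = vecs[:, order]
    # normalize: unit norm, largest-|entry| real positive
    norms = np.linalg.norm(vecs, axis=0)
    vecs = vecs / norms
    lead_entry = vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])]
    phase = np.where(np.abs(lead_entry) > 0, lead_entry / np.abs(lead_entry), 1.0)
    vecs = vecs / phase
    cond = float(np.linalg.cond(vecs))
    reliable = cond < DEFECTIVE_COND
    ones = np.ones(RXX.shape[0])
    if reliable:
        c = np.linalg.solve(vecs, ones.astype(complex))
    else:
        c, *_ = np.linalg.lstsq(vecs, ones.astype(complex), rcond=None)
    if np.max(np.abs(vals.imag)) == 0.0:
        vals = vals.real
        vecs = vecs.real
        c = c.real
    return EigenBasis(vals, vecs, c, cond, reliable)


def response_matrix(ctx: LinearizationContext) -> ResponseContext:
    """Response matrix R = (I − F W)⁻¹ F at a stable fixed point.

    Raises :class:`CriticalityError` when (I − F W) is singular, i.e. the
    linearization sits exactly at an instability threshold.
    """
    if not ctx.valid:
        raise ValueError("linearization context is invalid (non-converged fixed point)")
    m = ctx.n_units
    A = np.eye(m) - ctx.F[:, None] * ctx.W
    sign, logdet = np.linalg.slogdet(A)
    if sign == 0 or not np.isfinite(logdet):
        raise CriticalityError("I - F W is singular; network at criticality")
    R = np.linalg.solve(A, np.diag(ctx.F))
    return ResponseContext(R=R, blocks=ctx.blocks, ctx=ctx)


# ---------------------------------------------------------------------------
# Analytic predictions
# ---------------------------------------------------------------------------

@dataclass
class UniformPrediction:
    """Analytic response of cell type X to the uniform perturbation γ·1_X.

    ``delta_r`` is the per-node rate change, ``mean`` its average over the
    nodes of X, ``dot_ones`` the dot product with 1_X (= N_X × mean, the
    readout some experiments report).  ``leading_term`` and ``remainder``
    split the mean into the λ₁c₁²⟨v₁²⟩ contribution of the smallest mode
    and everything else; a negative leading term can be masked by a larger
    positive remainder, which is why uniform perturbations may fail to
    look paradoxical even when λ₁ < 0.
    """

    delta_r: np.ndarray
    mean: float
    dot_ones: float
    leading_term: float
    remainder: float
    basis_unreliable: bool


def uniform_prediction(
    rc: ResponseContext, X: str, gamma: float
) -> UniformPrediction:
    """Predicted activity change of type X under the uniform input γ·1_X.

    Computed through the eigenbasis as γ Σ_i c_i λ_i v_i; if the basis is
    numerically defective, falls back to the direct product R_XX (γ·1_X)
    and flags the basis as unreliable.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    basis = rc.eigenbasis(X)
    RXX = rc.block(X)
    n_x = RXX.shape[0]
    if basis.reliable:
        delta = gamma * (basis.vectors * (basis.coefficients * basis.values)).sum(axis=1)
        delta = np.real_if_close(delta, tol=1e6)
        delta = np.asarray(delta.real, dtype=float)
    else:
        delta = RXX @ np.full(n_x, gamma)
    lam1 = basis.values[0]
    c1 = basis.coefficients[0]
    v1 = basis.vectors[:, 0]
    # mean decomposition: (γ/N) λ₁c₁²(v₁·v₁) + remainder
    leading = float(np.real(gamma / n_x * lam1 * c1 ** 2 * np.vdot(v1.conj(), v1)))
    mean = float(delta.mean())
    return UniformPrediction(
        delta_r=delta,
        mean=mean,
        dot_ones=float(delta.sum()),
        leading_term=leading,
        remainder=mean - leading,
        basis_unreliable=not basis.reliable,
    )


@dataclass
class PatternedPrediction:
    """Analytic response of type X to the patterned perturbation γ·v_i."""

    pattern: np.ndarray
    delta_r: np.ndarray
    projection: float
    eigenvalue: complex
    complex_pair: bool


def patterned_prediction(
    rc: ResponseContext, X: str, gamma: float, i: int = 0
) -> PatternedPrediction:
    """Predicted response to a perturbation along eigenvector v_i of R_XX.

    For a real eigenpair the response is γ λ_i v_i and the projection onto
    the pattern is γ λ_i |v_i|² — paradoxical iff λ_i < 0.  If λ_i belongs
    to a complex pair, the physically realizable pattern is the normalized
    real part of v_i; the response is then computed by direct matrix
    action and flagged ``complex_pair``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    basis = rc.eigenbasis(X)
    lam = basis.values[i]
    v = basis.vectors[:, i]
    if np.iscomplexobj(basis.values) and abs(np.imag(lam)) > 1e-12 * max(1.0, abs(lam)):
        pattern = np.real(v)
        nrm = np.linalg.norm(pattern)
        if nrm == 0:
            raise ValueError("real part of the requested eigenvector vanishes")
        pattern = pattern / nrm
        delta = rc.block(X) @ (gamma * pattern)
        delta = np.asarray(np.real(delta), dtype=float)
        return PatternedPrediction(
            pattern=pattern,
            delta_r=delta,
            projection=float(delta @ pattern),
            eigenvalue=complex(lam),
            complex_pair=True,
        )
    pattern = np.asarray(np.real(v), dtype=float)
    delta = gamma * float(np.real(lam)) * pattern
    return PatternedPrediction(
        pattern=pattern,
        delta_r=delta,
        projection=gamma * float(np.real(lam)) * float(pattern @ pattern),
        eigenvalue=complex(lam),
        complex_pair=False,
    )


# ---------------------------------------------------------------------------
# Dynamical simulation
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """An ideal current-injection perturbation of one (or all) inhibitory types.

    ``target`` is a recurrent cell type or the tuple PV+SST+VIP
    (:data:`ALL_INHIBITORY`); ``pattern`` is ``"uniform"``, an eigenvector
    index of R_XX (single-type targets only), or an explicit vector with
    one entry per targeted node.  γ > 0 scales the injected current, which
    switches on at ``onset`` seconds and stays on.
    """

    target: str | tuple[str, ...]
    pattern: object = "uniform"
    gamma: float = 0.001
    onset: float = 1.0
    duration: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if isinstance(self.target, str) and self.target not in RECURRENT_TYPES:
            if self.target == "all_inhibitory":
                self.target = ALL_INHIBITORY
            else:
                raise ValueError(f"unknown target {self.target!r}")

    @property
    def target_types(self) -> tuple[str, ...]:
        return (self.target,) if isinstance(self.target, str) else tuple(self.target)


@dataclass
class PerturbationResult:
    """Simulated and analytic response to a perturbation.

    ``times`` are simulation times (s, perturbation onset included);
    ``readout_mean`` is δ⟨r_X⟩(t) over the targeted nodes and
    ``readout_dot`` the projection δr_X(t)·pattern.  ``analytic_mean`` /
    ``analytic_dot`` are the linear-response predictions for the same
    readouts, and ``paradoxical`` is the sign test δr·δh < 0 on the final
    simulated state.
    """

    spec: PerturbationSpec
    times: np.ndarray
    readout_mean: np.ndarray
    readout_dot: np.ndarray
    analytic_mean: float
    analytic_dot: float
    paradoxical: bool
    final_delta: np.ndarray
    diverged: bool = False


def _pattern_vector(
    spec: PerturbationSpec, rc: ResponseContext | None, idx_per_type: dict[str, np.ndarray]
) -> np.ndarray:
    """Stacked pattern over the targeted nodes (order: spec.target_types)."""
    n_target = sum(len(idx_per_type[t]) for t in spec.target_types)
    if isinstance(spec.pattern, str) and spec.pattern == "uniform":
        return np.ones(n_target)
    if isinstance(spec.pattern, (int, np.integer)):
        if len(spec.target_types) != 1:
            raise ValueError("eigenvector patterns require a single target type")
        if rc is None:
            raise ValueError("eigenvector patterns require a response context")
        # the pattern itself does not depend on the amplitude
        pred = patterned_prediction(rc, spec.target_types[0], 1.0, int(spec.pattern))
        return pred.pattern
    vec = np.asarray(spec.pattern, dtype=float)
    if vec.shape != (n_target,):
        raise ValueError(f"pattern must have {n_target} entries")
    return vec


def simulate_perturbation(
    model: NetworkModel,
    drive: InputDrive,
    s: float,
    spec: PerturbationSpec,
    dt: float | None = None,
    record_every: int = 10,
    settle_tol: float = 1e-6,
    operator: NetworkOperator | None = None,
) -> PerturbationResult:
    """Integrate the dynamics through a perturbation and compare to theory.

    Starting from the steady state at stimulus size ``s``, the current
    γ·pattern is added to the targeted population(s) from ``spec.onset``
    onward.  The run ends at ``onset + duration`` or earlier once the
    readout's relative change per time constant falls below
    ``settle_tol``.  Analytic predictions use the response matrix at the
    unperturbed fixed point.
    """
    op = operator or NetworkOperator(model, drive)
    # a tightly resolved fixed point, so small perturbation responses are
    # not drowned by residual relaxation of the baseline itself
    fp, conv = steady_state(model, drive, s=s, tol=1e-12, operator=op)
    if not conv[0]:
        raise RuntimeError(f"steady state did not converge at size {s}")
    ctx = build_linearization(model, drive, s, operator=op)
    rc = response_matrix(ctx)
    n = model.grid.n_nodes
    idx_per_type = {t: np.arange(n) for t in RECURRENT_TYPES}

    pattern = _pattern_vector(spec, rc, idx_per_type)
    # scatter the pattern into the stacked 4n layout
    delta_h = np.zeros(4 * n)
    offset = 0
    target_idx = []
    for t in spec.target_types:
        a = RECURRENT_TYPES.index(t)
        block = np.arange(a * n, (a + 1) * n)
        delta_h[block] = pattern[offset:offset + n]
        target_idx.append(block)
        offset += n
    target_idx = np.concatenate(target_idx)

    # analytic predictions from the full response matrix
    delta_analytic = rc.R @ (spec.gamma * delta_h)
    analytic_mean = float(delta_analytic[target_idx].mean())
    analytic_dot = float(delta_analytic[target_idx] @ pattern)

    # dynamical simulation from the fixed point
    if dt is None:
        dt = float(np.min(model.tau)) / 10.0
    W = op.recurrent_matrix(model.kernels.amplitude)
    h = op.external_input(model.kernels.amplitude, model.bias)[:, drive.size_index(s)]
    h_pert = h + spec.gamma * delta_h
    r_star = np.concatenate([fp.get(p, s) for p in RECURRENT_TYPES])
    r = r_star.copy()
    tau_nodes = np.repeat(model.tau, n)
    step_fac = dt / tau_nodes
    nl = model.nonlinearity
    n_steps = max(int(round(spec.duration / dt)), 1)
    times = [spec.onset]
    mean_ts = [0.0]
    dot_ts = [0.0]
    diverged = False
    check_stride = max(int(round(np.max(model.tau) / dt)), 1)
    last_check = 0.0
    for k in range(1, n_steps + 1):
        r = r + step_fac * (-r + nl.f(W @ r + h_pert))
        if np.max(r) > DIVERGENCE_CEILING:
            diverged = True
            break
        if k % record_every == 0 or k == n_steps:
            d = r[target_idx] - r_star[target_idx]
            times.append(spec.onset + k * dt)
            mean_ts.append(float(d.mean()))
            dot_ts.append(float(d @ pattern))
        if k % check_stride == 0:
            cur = float((r[target_idx] - r_star[target_idx]) @ pattern)
            if abs(cur - last_check) <= settle_tol * max(abs(cur), 1e-12):
                d = r[target_idx] - r_star[target_idx]
                if times[-1] < spec.onset + k * dt:
                    times.append(spec.onset + k * dt)
                    mean_ts.append(float(d.mean()))
                    dot_ts.append(float(d @ pattern))
                break
            last_check = cur
    final_delta = r[target_idx] - r_star[target_idx]
    paradoxical = bool(final_delta @ (spec.gamma * pattern) < 0)
    return PerturbationResult(
        spec=spec,
        times=np.asarray(times),
        readout_mean=np.asarray(mean_ts),
        readout_dot=np.asarray(dot_ts),
        analytic_mean=analytic_mean,
        analytic_dot=analytic_dot,
        paradoxical=paradoxical,
        final_delta=final_delta,
        diverged=diverged,
    )


# ---------------------------------------------------------------------------
# Mode counting and the parity diagnostic
# ---------------------------------------------------------------------------

def count_paradoxical_modes(rc: ResponseContext, X: str) -> int:
    """Number of eigenvalues of R_XX with negative real part.

    Each such mode responds paradoxically to a perturbation patterned
    along its eigenvector; complex conjugates are counted individually.
    """
    vals = rc.eigenbasis(X).values
    return int(np.sum(np.real(vals) < 0))


def count_unstable_modes(ctx: LinearizationContext, excluded: str) -> int:
    """Number of eigenvalues of −J₋X with negative real part.

    Equivalently, the number of unstable modes of the subnetwork with
    cell type X removed; complex conjugates are counted individually.
    """
    from spatialssn.stability import subnetwork_jacobian

    J_sub = subnetwork_jacobian(ctx, (excluded,))
    vals = np.linalg.eigvals(-J_sub)
    return int(np.sum(np.real(vals) < 0))


@dataclass
class ParityResult:
    """Outcome of the determinant-parity diagnostic for one cell type."""

    X: str
    n_unstable: int
    n_paradoxical: int
    parity_match: bool
    det_sign_match: bool
    holds: bool
    indeterminate: bool


def parity_check_ctx(
    ctx: LinearizationContext,
    X: str,
    rc: ResponseContext | None = None,
    logdet_floor: float = -200.0,
) -> ParityResult:
    """Parity diagnostic from an existing linearization context.

    Checks that (a) the parity of unstable modes of −J₋X equals the parity
    of paradoxical modes of R_XX and (b) sign det(−J₋X) == sign det(R_XX).
    Near-singular determinants (log|det| below ``logdet_floor`` or exactly
    zero) make the result indeterminate.
    """
    from spatialssn.stability import subnetwork_jacobian

    if rc is None:
        rc = response_matrix(ctx)
    n_unst = count_unstable_modes(ctx, X)
    n_par = count_paradoxical_modes(rc, X)
    sign_j, logdet_j = np.linalg.slogdet(-subnetwork_jacobian(ctx, (X,)))
    sign_r, logdet_r = np.linalg.slogdet(rc.block(X))
    indeterminate = (
        sign_j == 0
        or sign_r == 0
        or logdet_j < logdet_floor
        or logdet_r < logdet_floor
    )
    parity_match = (n_unst % 2) == (n_par % 2)
    det_match = sign_j == sign_r
    return ParityResult(
        X=X,
        n_unstable=n_unst,
        n_paradoxical=n_par,
        parity_match=parity_match,
        det_sign_match=det_match,
        holds=parity_match and det_match and not indeterminate,
        indeterminate=bool(indeterminate),
    )


def parity_check(
    model: NetworkModel, drive: InputDrive, s: float, X: str
) -> ParityResult:
    """Parity diagnostic for cell type X at the size-``s`` fixed point."""
    ctx = build_linearization(model, drive, s)
    if not ctx.valid:
        raise RuntimeError(f"steady state did not converge at size {s}")
    return parity_check_ctx(ctx, X)
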