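# Methods

## Model

The package implements a spatially extended stabilized supralinear network
(SSN): rate units of four recurrent cell types (E, PV, SST, VIP) on a
regular 2D retinotopic grid, with dynamics

τ_A dr_A(x;s)/dt = −r_A(x;s) + f( Σ_B Σ_y W_AB(x−y) r_B(y;s) Δ² + T_A ),

f(u) = [u]₊² by default (optionally [u]₊). Presynaptic types B include the
recurrent populations and three external sources: feedforward L4, feedback
LM, and a residual input R = gain·√s·exp(−|x|²/2σ_R²) standing in for
unmeasured projections. Kernels are isotropic Gaussians normalized so the
amplitude w_AB equals the kernel's spatial integral; amplitudes are
non-negative from excitatory types (E, L4, LM, R) and non-positive from
inhibitory ones (PV, SST, VIP). The Δ² factor makes kernel sums
discretized spatial integrals, so amplitudes are resolution-independent.

Assumptions: space and cell type are the only dimensions (no orientation
or feature tuning, no delays, no conductances); boundaries are open
(truncated), since retinotopic space is not periodic; all units of a type
share τ_A, T_A and kernels (translation invariance up to boundaries).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| Δ | grid spacing (deg) | 6 | each unit pools a 6°×6° patch of retinotopy |
| n_x × n_y | grid nodes | 12×12 (tests), 30×30 supported | 12×12 spans ±33°, enough for stimuli up to 85° at desk scale |
| τ_E; τ_PV,SST,VIP | time constants (s) | 0.02; 0.01 | standard E-slower-than-I rate-model convention; stability flags are sign-based and unchanged by per-type positive rescaling, but τ enters J, so reports record the τ used |
| σ_AB | kernel scales (deg) | 10 everywhere; 20 for E→SST in the synthetic truth | no measured table is shipped; scales are config inputs. The wider E→SST pooling is the standard source of spatially extended surround inhibition |
| σ_R, gain | residual profile | 30°, 1/8 | √s amplitude scaling keeps the large/small stimulus ratio at √17 ≈ 4.1 instead of the 17× a linear scaling would give |
| c_A | loss weights | (1,1,1,1) | no dataset-specific reweighting for synthetic data |
| divergence ceiling | rate bound | 10⁶ | supralinear networks may lack stable fixed points; such parameter regions must register as high loss, not crash |

The 32 free parameters of a fit are exactly the 28 kernel amplitudes and
4 biases; σ, τ and the residual profile stay fixed.

## Numerics

**Steady states.** Explicit Euler relaxation (dt = min τ/10, relative
residual max|−r + f(u)|/(max r + ε) < 10⁻⁶, budget 10⁵ steps by default),
followed by a damped Newton polish of r = f(Wr + h); the polish is
accepted only where it reduces the residual, and columns it cannot fix
fall back to strict Euler. All stimulus sizes are relaxed simultaneously
as matrix columns. Divergence (any rate above the ceiling) and budget
exhaustion are reported as flags, never raised from `steady_state`.

**Fitting.** The loss is L = √(Σ_s Σ_A Σ_x c_A (r−r̃)² / Σ_s Σ_A Σ_x
c_A r̃²). The bracket reading with a single global normalizing
denominator was adopted because that denominator is explicitly a
normalization that does not affect the optimum; a per-size-normalized
variant is available behind a config flag. Gradients are exact at the
solved fixed point via implicit differentiation, dr*/dθ = (I−FW)⁻¹F
∂u/∂θ — the limit of backpropagating through the unrolled relaxation —
assembled from one adjoint solve per stimulus size and verified against
central finite differences (relative error < 10⁻³ contract; measured
~10⁻⁹). The optimizer is L-BFGS-B over the sign-constraint box; any
gradient-based constrained local method satisfying the gradient contract
would do. Fixed points are warm-started across objective evaluations
(short Euler + Newton), with a cold start (Euler from zero, dt = min τ/5,
6000 steps) where the warm path fails; the loss of the returned optimum is
always re-evaluated from a cold start so warm-start shortcuts cannot bias
the reported number. Sizes whose steady state diverges or stalls
contribute a fixed penalty of 100× that size's data power to the squared
numerator (→ loss 10 if all sizes fail, against 1 for predicting zero),
keeping line searches finite and steering the search away from unstable
regions.

**Initialization.** Restart inits draw amplitude magnitudes uniformly in
[0, 1] (recurrent ones halved) with the presynaptic sign, and biases
uniformly in [−0.25, 0.25]; draws whose dynamics do not converge are
rejected and resampled (≤ 20 tries). Biases are kept near threshold
deliberately: with f(u) = [u]₊², a strongly negative initial bias silences
a population, whose parameters then sit on an exactly flat patch of the
loss surface (f′ = 0), and multistart recovery becomes unreliable.

**Stability.** J = T⁻¹(−I + FW) with F = diag f′(u*) at the fixed point;
f′(0) is defined as 0 for both nonlinearities, so silent units decouple
from J (they contribute eigenvalues −1/τ and no modes — this affects which
modes exist and is intentional). Subnetwork Jacobians remove all rows and
columns of the excluded types; E is never excluded. Leading eigenvalues
use a dense solver up to 2000 rows and an iterative largest-real-part
solver above, with deterministic tie-breaking (max real part, then
smallest |imag|, conjugate representative with imag ≥ 0). Distributions of
leading eigenvalues across models are reported as raw per-model values.

**Perturbations.** R = (I−FW)⁻¹F at a stable fixed point; eigenvectors of
R_XX are unit-norm with the largest-magnitude entry made real positive,
eigenvalues sorted ascending by real part; coefficients of 1_X solve
Vc = 1 (defectiveness flagged at condition number 10¹⁰, with a direct
matrix-action fallback). If λ₁ belongs to a complex pair, the physically
realizable pattern is the normalized real part of v₁ and the prediction
uses direct matrix action, flagged as such. Simulations start from a
fixed point resolved to 10⁻¹² and inject γ·pattern from t = 1 s, running
2 s or until the readout's relative change per time constant falls below
10⁻⁶. Both the per-neuron mean δ⟨r_X⟩ and the dot product δr_X·1_X
(= N_X × mean) readouts are computed, since experimental reports use
either. The parity diagnostic compares the count of eigenvalues of −J₋X
with negative real part against the count of eigenvalues of R_XX with
negative real part and checks sign det(−J₋X) = sign det(R_XX) via
slogdet; a vanishing determinant marks the result indeterminate.

## Synthetic data

The generator emulates the structure of size-tuning experiments: 9 sizes
(5°–85° in 10° steps), 2D rate fields peaked at the stimulus center, and
noisy observations of a ground-truth model's steady states. L4/LM input
fields use a plateau-with-Gaussian-edge family (plateau radius = stimulus
radius s/2); the L4 peak amplitude rises and then mildly declines with
size while LM saturates, so the feedforward drive roughly tracks stimulus
extent. These profiles are an explicit stand-in for measured input fields,
which are not public; no claim is made that they match the real ones, and
passing recovery tests therefore demonstrates correctness of the inference
machinery on structurally matched data, not fidelity to cortex. Noise is
additive Gaussian per population (sd = fraction of that population's peak
rate), clipped at zero; calcium-imaging noise statistics are deliberately
not emulated.

Ground-truth models jitter a hand-tuned base amplitude table by ±10%
(seeded) and, for the `isn` regime, verify that at the 55° steady state
the E subnetwork is unstable while the full network is stable, retrying
with rescaled recurrent amplitudes until both hold. The base table was
tuned once so that the default fixture is inhibition-stabilized with
PV required across large sizes, SST required at 25°–85°, surround-
suppressed E/PV tuning, and rates of order 1–40; under the ±10% jitter
roughly half the seeds keep SST required, giving the across-model
heterogeneity the analyses probe. The `weak` regime scales recurrent
amplitudes by 0.01, making even the E subnetwork stable.

## Problem sizes

Tests and the acceptance script run on a 12×12 grid (576 recurrent units,
9 sizes); multistart fits use 10 restarts with 200 L-BFGS-B iterations.
These sizes were chosen so the full suite runs on a laptop-class single
core in minutes while keeping all qualitative regimes (ISN, SST
requirement, paradoxical and non-paradoxical uniform responses)
reachable; the machinery itself handles 30×30 grids (3600 units,
dense Jacobians of 14400² entries switch to the iterative eigensolver).

## Known limitations

- Steady-state tracking inside the fitter follows the warm-started branch
  of fixed points; a fold bifurcation between evaluations can make the
  tracked branch differ from the one reached from zero rates (the final
  reported loss is immune, being cold-started).
- The loss surface of the 32-parameter problem is multimodal; recovery of
  a known truth is reliable for the best of ~10 restarts on noiseless
  data but individual restarts often end in poor local minima.
- No uncertainty quantification over parameters; ranking is by point
  loss only.
- The parity and stabilization analyses assume the fixed point is exactly
  stationary; near-critical networks (|det| ≈ 0) are flagged
  indeterminate rather than classified.
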