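"""Core network: kernels, nonlinearities, residual input, dynamics."""

import numpy as np
import pytest

from spatialssn import (
    InputDrive,
    KernelParams,
    NetworkModel,
    Nonlinearity,
    RateField,
    RetinotopicGrid,
    apply_nonlinearity,
    gaussian_kernel_matrix,
    integrate_dynamics,
    residual_field,
    steady_state,
    total_input,
)
from spatialssn.network import N_PRE, N_REC, RECURRENT_TYPES

from conftest import make_uncoupled_model, zero_drive

SIZES = np.arange(5.0, 86.0, 10.0)


# ---------------------------------------------------------------------------
# Gaussian kernels
# ---------------------------------------------------------------------------

class TestGaussianKernel:
    def test_peak_value_is_normalization(self):
        g = RetinotopicGrid(5, 5, 2.0)
        sigma = 7.5
        K = gaussian_kernel_matrix(g, 1.0, sigma)
        assert np.allclose(np.diag(K), 1.0 / (2 * np.pi * sigma**2))

    def test_symmetry(self):
        g = RetinotopicGrid(6, 4, 3.0)
        K = gaussian_kernel_matrix(g, -2.3, 11.0)
        assert np.allclose(K, K.T)

    def test_center_row_sum_approximates_amplitude(self):
        # 30x30 grid at 6 deg spans +-87 deg: the discretized integral of
        # a sigma=12 kernel from the center recovers the amplitude to <1%
        g = RetinotopicGrid(30, 30, 6.0)
        K = gaussian_kernel_matrix(g, 2.0, 12.0)
        row = K[g.center_index].sum() * g.area_element
        assert abs(row - 2.0) / 2.0 < 0.01

    @pytest.mark.parametrize("n,rel_tol", [(10, 0.2), (20, 0.02), (30, 0.01)])
    def test_row_sum_converges_with_extent(self, n, rel_tol):
        g = RetinotopicGrid(n, n, 6.0)
        K = gaussian_kernel_matrix(g, 1.0, 12.0)
        row = K[g.center_index].sum() * g.area_element
        assert abs(row - 1.0) < rel_tol

    def test_nonpositive_scale_rejected(self):
        g = RetinotopicGrid(3, 3, 1.0)
        for s in (0.0, -1.0):
            with pytest.raises(ValueError):
                gaussian_kernel_matrix(g, 1.0, s)


# ---------------------------------------------------------------------------
# Nonlinearity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kind,u,expected",
    [
        ("rectified_quadratic", -1.0, 0.0),
        ("rectified_quadratic", 2.0, 4.0),
        ("rectified_quadratic", 0.0, 0.0),
        ("rectified_linear", 0.5, 0.5),
        ("rectified_linear", -3.0, 0.0),
    ],
)
def test_nonlinearity_values(kind, u, expected):
    assert apply_nonlinearity(np.array(u), Nonlinearity(kind)) == expected


@pytest.mark.parametrize(
    "kind,u,expected",
    [
        ("rectified_quadratic", 3.0, 6.0),
        ("rectified_quadratic", -1.0, 0.0),
        ("rectified_linear", 2.0, 1.0),
        ("rectified_linear", 0.0, 0.0),  # derivative at 0 defined as 0
        ("rectified_linear", -2.0, 0.0),
    ],
)
def test_nonlinearity_derivative(kind, u, expected):
    assert Nonlinearity(kind).df(np.array(u)) == expected


# ---------------------------------------------------------------------------
# Kernel parameter sign constraints
# ---------------------------------------------------------------------------

def test_kernel_sign_constraints_enforced():
    amp = np.zeros((N_REC, N_PRE))
    scale = np.full((N_REC, N_PRE), 10.0)
    KernelParams(amp, scale)  # zeros are fine for both signs
    bad = amp.copy()
    bad[0, 1] = 0.5  # positive weight from PV
    with pytest.raises(ValueError):
        KernelParams(bad, scale)
    bad = amp.copy()
    bad[0, 0] = -0.5  # negative weight from E
    with pytest.raises(ValueError):
        KernelParams(bad, scale)
    with pytest.raises(ValueError):
        KernelParams(amp, np.zeros_like(scale))


# ---------------------------------------------------------------------------
# Residual input
# ---------------------------------------------------------------------------

class TestResidualField:
    def test_peak_is_gain_times_sqrt_size(self):
        g = RetinotopicGrid(5, 5, 2.0)
        f = residual_field(g, 4.0, sigma_r=30.0, gain=0.125)
        assert np.isclose(f[g.center_index], 0.25)

    def test_zero_size_gives_zero_field(self):
        g = RetinotopicGrid(5, 5, 2.0)
        assert np.all(residual_field(g, 0.0, 30.0) == 0.0)

    def test_sqrt_peak_ratio_85_over_5(self):
        g = RetinotopicGrid(5, 5, 2.0)
        hi = residual_field(g, 85.0, 30.0)[g.center_index]
        lo = residual_field(g, 5.0, 30.0)[g.center_index]
        assert np.isclose(hi / lo, np.sqrt(17.0))

    def test_negative_size_rejected(self):
        g = RetinotopicGrid(5, 5, 2.0)
        with pytest.raises(ValueError):
            residual_field(g, -1.0, 30.0)


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

def _uniform_rates(grid, value=0.0, pops=RECURRENT_TYPES):
    data = np.full((len(pops), len(SIZES), grid.n_nodes), float(value))
    return RateField(pops, grid, SIZES, data)


class TestTotalInput:
    def test_all_zero_weights_gives_bias(self):
        g = RetinotopicGrid(6, 6, 6.0)
        m = make_uncoupled_model(g, [2.0, -1.0, 0.5, 0.0])
        total, parts = total_input(m, _uniform_rates(g, 1.0), zero_drive(g, SIZES), 5.0)
        for a, pop in enumerate(RECURRENT_TYPES):
            assert np.allclose(total[pop], m.bias[a])

    def test_uniform_presynaptic_rate_interior_node(self):
        # a single presynaptic source at uniform rate c drives the interior
        # with w*c + T (kernel integral equals the amplitude)
        g = RetinotopicGrid(20, 20, 6.0)
        m = make_uncoupled_model(g, [0.3, 0.0, 0.0, 0.0])
        amp = m.kernels.amplitude.copy()
        amp[0, 0] = 1.7  # E -> E only
        m = m.with_params(amp, m.bias)
        c = 2.5
        total, _ = total_input(m, _uniform_rates(g, c), zero_drive(g, SIZES), 5.0)
        center = g.center_index
        assert abs(total["E"][center] - (1.7 * c + 0.3)) / (1.7 * c) < 0.02

    def test_decomposition_sums_to_total(self):
        g = RetinotopicGrid(5, 5, 6.0)
        rng = np.random.default_rng(3)
        amp = rng.uniform(0, 1, (N_REC, N_PRE))
        amp[:, 1:4] *= -1
        scale = np.full((N_REC, N_PRE), 10.0)
        m = NetworkModel(g, KernelParams(amp, scale), bias=rng.normal(size=4))
        rates = RateField(
            RECURRENT_TYPES, g, SIZES,
            rng.uniform(0, 2, (N_REC, len(SIZES), g.n_nodes)),
        )
        drive = InputDrive(g, SIZES, rng.uniform(0, 1, (3, len(SIZES), g.n_nodes)))
        total, parts = total_input(m, rates, drive, 25.0)
        for pop in RECURRENT_TYPES:
            acc = sum(parts[pop].values())
            assert np.allclose(acc, total[pop])


# ---------------------------------------------------------------------------
# Dynamics and steady states
# ---------------------------------------------------------------------------

class TestDynamics:
    def test_uncoupled_converges_to_squared_bias(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [2.0, 2.0, 2.0, 2.0])
        _, final, _ = integrate_dynamics(m, zero_drive(g, SIZES), duration=0.5)
        assert np.allclose(final.data, 4.0, atol=1e-4)

    def test_negative_bias_converges_to_zero(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [-1.0, -1.0, -1.0, -1.0])
        _, final, _ = integrate_dynamics(m, zero_drive(g, SIZES), duration=0.3)
        assert np.allclose(final.data, 0.0)

    def test_rates_stay_nonnegative_along_trajectory(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [1.0, -0.5, 0.2, -2.0])
        _, _, traj = integrate_dynamics(m, zero_drive(g, SIZES), duration=0.2)
        assert np.all(traj >= 0.0)

    def test_halving_dt_changes_little(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [1.5, 0.5, -0.5, 1.0])
        _, f1, _ = integrate_dynamics(m, zero_drive(g, SIZES), dt=0.002, duration=0.5)
        _, f2, _ = integrate_dynamics(m, zero_drive(g, SIZES), dt=0.001, duration=0.5)
        assert np.max(np.abs(f1.data - f2.data)) < 1e-4

    def test_too_large_dt_rejected(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [1.0] * 4)
        with pytest.raises(ValueError):
            integrate_dynamics(m, zero_drive(g, SIZES), dt=0.01)  # > min(tau)/5


class TestSteadyState:
    def test_uncoupled_closed_form(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [3.0, 3.0, 3.0, 3.0])
        ss, conv = steady_state(m, zero_drive(g, SIZES))
        assert conv.all()
        assert np.allclose(ss.data, 9.0, rtol=1e-6)

    def test_linear_nonlinearity_closed_form(self):
        g = RetinotopicGrid(4, 4, 6.0)
        m = make_uncoupled_model(g, [3.0, 0.5, -1.0, 0.0], nonlinearity="rectified_linear")
        ss, conv = steady_state(m, zero_drive(g, SIZES))
        assert conv.all()
        expected = np.array([3.0, 0.5, 0.0, 0.0])
        for a, pop in enumerate(RECURRENT_TYPES):
            assert np.allclose(ss.get(pop), expected[a], atol=1e-8)

    def test_residual_below_tolerance_by_construction(self, isn_dataset):
        m, drive = isn_dataset.truth, isn_dataset.drive
        tol = 1e-6
        ss, conv = steady_state(m, drive, s=55.0, tol=tol)
        assert conv[0]
        from spatialssn.network import NetworkOperator

        op = NetworkOperator(m, drive)
        W = op.recurrent_matrix(m.kernels.amplitude)
        h = op.external_input(m.kernels.amplitude, m.bias)[:, drive.size_index(55.0)]
        r = np.concatenate([ss.get(p, 55.0) for p in RECURRENT_TYPES])
        resid = np.max(np.abs(-r + m.nonlinearity.f(W @ r + h))) / (r.max() + 1e-12)
        assert resid < tol

    def test_matches_damped_fixed_point_iteration_oracle(self, small_drive):
        # independent oracle: heavily damped Picard iteration on the
        # assembled (W, h) system
        grid, drive = small_drive
        from spatialssn import make_ground_truth_model
        from spatialssn.network import NetworkOperator

        m = make_ground_truth_model(0, grid, regime="weak")
        op = NetworkOperator(m, drive)
        W = op.recurrent_matrix(m.kernels.amplitude)
        h = op.external_input(m.kernels.amplitude, m.bias)[:, drive.size_index(55.0)]
        r = np.zeros(W.shape[0])
        for _ in range(20000):
            r_new = r + 0.05 * (-r + m.nonlinearity.f(W @ r + h))
            if np.max(np.abs(r_new - r)) < 1e-12:
                r = r_new
                break
            r = r_new
        ss, conv = steady_state(m, drive, s=55.0, tol=1e-10)
        assert conv[0]
        got = np.concatenate([ss.get(p, 55.0) for p in RECURRENT_TYPES])
        assert np.max(np.abs(got - r)) < 1e-6

    def test_invariant_to_initial_condition_within_basin(self, isn_dataset):
        m, drive = isn_dataset.truth, isn_dataset.drive
        ss0, conv0 = steady_state(m, drive, s=35.0)
        r0 = ss0.copy()
        r0.data[:] = np.maximum(r0.data * 1.2, 0.01)
        ss1, conv1 = steady_state(m, drive, s=35.0, r0=r0)
        assert conv0[0] and conv1[0]
        assert np.allclose(ss0.data, ss1.data, atol=1e-5, rtol=1e-4)

    def test_translation_equivariance_on_interior(self):
        # shifting the external drive by one node shifts the interior
        # steady-state response by one node (up to boundary effects)
        g = RetinotopicGrid(12, 12, 6.0)
        from spatialssn import make_ground_truth_model
        from spatialssn.synth import make_input_fields

        m = make_ground_truth_model(0, g, regime="weak")
        sizes = np.array([25.0])
        drive = make_input_fields(g, [25.0])
        ss, conv = steady_state(m, drive)
        # shift drive one node in +x
        shifted = drive.data.reshape(3, 1, 12, 12).copy()
        shifted = np.roll(shifted, 1, axis=3)
        drive2 = InputDrive(g, sizes, shifted.reshape(3, 1, -1))
        ss2, conv2 = steady_state(m, drive2)
        assert conv.all() and conv2.all()
        a = ss.data.reshape(4, 12, 12)
        b = ss2.data.reshape(4, 12, 12)
        # compare interior block, away from the open boundary
        interior = np.s_[:, 3:-3, 3:-3]
        # tolerance reflects open-boundary truncation on the small grid
        assert np.allclose(np.roll(a, 1, axis=2)[interior], b[interior], atol=0.05)


def test_rate_field_validation(grid12):
    with pytest.raises(ValueError):
        RateField(RECURRENT_TYPES, grid12, [5.0, 5.0],
                  np.zeros((4, 2, grid12.n_nodes)))
    with pytest.raises(ValueError):
        RateField(RECURRENT_TYPES, grid12, [5.0],
                  -np.ones((4, 1, grid12.n_nodes)))
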