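"""Delay-network construction, discretization, and delay decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from ldntsc import ldn, synth
from ldntsc.exceptions import DataError


def matrices_by_double_loop(d):
    """Independent elementwise evaluation of the closed forms."""
    A = np.empty((d, d))
    B = np.empty(d)
    for i in range(d):
        B[i] = (2 * i + 1) * (-1) ** i
        for j in range(d):
            if i < j:
                A[i, j] = (2 * i + 1) * (-1)
            else:
                A[i, j] = (2 * i + 1) * (-1) ** (i - j + 1)
    return A, B


class TestStateMatrices:
    def test_closed_form_small_orders(self):
        A1, B1 = ldn.make_state_matrices(1)
        assert A1.tolist() == [[-1.0]] and B1.tolist() == [1.0]
        A2, B2 = ldn.make_state_matrices(2)
        assert A2.tolist() == [[-1.0, -1.0], [3.0, -3.0]]
        assert B2.tolist() == [1.0, -3.0]

    @pytest.mark.parametrize("d", range(1, 17))
    def test_matches_double_loop_exactly(self, d):
        A, B = ldn.make_state_matrices(d)
        A_ref, B_ref = matrices_by_double_loop(d)
        assert np.array_equal(A, A_ref)
        assert np.array_equal(B, B_ref)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 32))
    def test_row_magnitude_and_sign_laws(self, d):
        A, B = ldn.make_state_matrices(d)
        i = np.arange(d)
        assert np.array_equal(np.abs(A), np.tile(2 * i[:, None] + 1, (1, d)))
        assert np.array_equal(np.sign(B), (-1.0) ** i)

    @pytest.mark.parametrize("bad", [0, -3, 2.5, "4", True])
    def test_rejects_invalid_order(self, bad):
        with pytest.raises(ValueError):
            ldn.make_state_matrices(bad)


class TestScaling:
    def test_window_scaling(self):
        A, B = ldn.make_state_matrices(3)
        Ac, Bc = ldn.scale_by_window(A, B, 1.0)
        assert np.array_equal(Ac, A) and np.array_equal(Bc, B)
        Ac, Bc = ldn.scale_by_window(A, B, 0.5)
        assert np.array_equal(Ac, 2 * A) and np.array_equal(Bc, 2 * B)
        Ac, Bc = ldn.scale_by_window(*ldn.make_state_matrices(1), 0.1)
        assert Ac.tolist() == [[-10.0]] and Bc.tolist() == [10.0]

    def test_rejects_nonpositive_window(self):
        A, B = ldn.make_state_matrices(2)
        with pytest.raises(ValueError):
            ldn.scale_by_window(A, B, 0.0)


class TestNeuralMapping:
    def test_arithmetic(self):
        Ap, Bp = ldn.neural_mapping(np.array([[-10.0]]), np.array([10.0]), 0.1)
        assert Ap.tolist() == [[0.0]] and Bp.tolist() == [1.0]

    def test_small_tau_limit(self):
        A, B = ldn.make_state_matrices(4)
        Ap, Bp = ldn.neural_mapping(A, B, 1e-14)
        assert np.allclose(Ap, np.eye(4), atol=1e-12)
        assert np.allclose(Bp, 0, atol=1e-12)

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            ldn.neural_mapping(np.ones((2, 3)), np.ones(2), 0.1)

    def test_filtered_form_equivalent_to_zoh(self):
        """Simulating x = h_tau * (A'x + B'u) reproduces the canonical
        dynamics, with error shrinking as dt shrinks."""
        tau, d, theta = 0.1, 4, 0.1
        rng = np.random.default_rng(0)
        base = synth.band_limited_noise(1000, 1e-3, 10, rng)  # 1 s probe
        t_base = np.arange(1000) * 1e-3
        errs = {}
        for dt in (1e-3, 1e-4):
            t = np.arange(int(1.0 / dt)) * dt
            u = np.interp(t, t_base, base)  # same probe on a finer grid
            spec = ldn.make_ldn(d, theta, tau=tau, dt=dt)
            xf = ldn.simulate_filtered(spec.A_prime, spec.B_prime, u, tau, dt)
            xe = ldn.extract_features(u, spec.A_d, spec.B_d, dt=dt).values
            errs[dt] = np.abs(xf - xe).max()
        assert errs[1e-4] < 1e-2
        assert errs[1e-4] < errs[1e-3]


def euler_fine(A_c, B_c, x0, u, dt, refine=1000):
    """Matrix-exponential-free oracle: forward Euler at step dt/refine over
    one ZOH interval (input held constant)."""
    h = dt / refine
    x = x0.copy()
    for _ in range(refine):
        x = x + h * (A_c @ x + B_c * u)
    return x


class TestDiscretization:
    def test_zero_dynamics(self):
        A_d, B_d = ldn.discretize_zoh(np.zeros((3, 3)), np.arange(3.0), 1e-3)
        assert np.allclose(A_d, np.eye(3))
        assert np.allclose(B_d, 1e-3 * np.arange(3.0))

    def test_scalar_closed_form(self):
        A_d, B_d = ldn.discretize_zoh(np.array([[-10.0]]), np.array([10.0]),
                                      0.001)
        assert np.isclose(A_d[0, 0], np.exp(-0.01), rtol=1e-14)

    @pytest.mark.parametrize("d", [2, 5, 12])
    def test_agrees_with_fine_euler(self, d, rng):
        M = rng.standard_normal((d, d))
        A_c = M - (np.abs(np.linalg.eigvals(M).real).max() + 1) * np.eye(d)
        B_c = rng.standard_normal(d)
        A_d, B_d = ldn.discretize_zoh(A_c, B_c, 0.001)
        x0 = rng.standard_normal(d)
        u = 0.7
        ref = euler_fine(A_c, B_c, x0, u, 0.001)
        got = A_d @ x0 + B_d * u
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 1e-6

    def test_impulse_response_follows_matrix_exponential(self):
        spec = ldn.make_ldn(5, 0.2)
        u = np.zeros(101)
        u[0] = 1.0
        X = ldn.extract_features(u, spec.A_d, spec.B_d).values
        for k in (0, 1, 10, 100):
            ref = expm(spec.A_c * k * spec.dt) @ spec.B_d
            assert np.abs(X[k] - ref).max() < 1e-8


class TestExtractFeatures:
    def test_zero_input_zero_trace(self):
        spec = ldn.make_ldn(4, 0.1)
        tr = ldn.extract_features(np.zeros(50), spec.A_d, spec.B_d)
        assert np.array_equal(tr.values, np.zeros((50, 4)))

    def test_first_row_applies_update_at_t0(self):
        spec = ldn.make_ldn(3, 0.1)
        x0 = np.array([0.2, -0.1, 0.3])
        tr = ldn.extract_features(np.array([0.5, 0.0]), spec.A_d, spec.B_d,
                                  x0=x0)
        assert np.allclose(tr.values[0], spec.A_d @ x0 + spec.B_d * 0.5)

    def test_constant_input_steady_state(self):
        # d=1: steady state solves A_c x = -B_c c  ->  x = c
        spec = ldn.make_ldn(1, 0.1)
        c = 0.37
        tr = ldn.extract_features(np.full(3000, c), spec.A_d, spec.B_d)
        assert np.isclose(tr.values[-1, 0], c, atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, a, b):
        spec = ldn.make_ldn(3, 0.05)
        rng = np.random.default_rng(5)
        u1, u2 = rng.standard_normal((2, 80))
        f = lambda u: ldn.extract_features(u, spec.A_d, spec.B_d).values
        assert np.allclose(f(a * u1 + b * u2), a * f(u1) + b * f(u2),
                           atol=1e-9)

    def test_rejects_nonfinite(self):
        spec = ldn.make_ldn(2, 0.1)
        with pytest.raises(DataError):
            ldn.extract_features(np.array([1.0, np.nan]), spec.A_d, spec.B_d)

    def test_csv_roundtrip(self, tmp_path):
        spec = ldn.make_ldn(4, 0.1)
        rng = np.random.default_rng(0)
        tr = ldn.extract_features(rng.standard_normal(30), spec.A_d,
                                  spec.B_d)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "x0,x1,x2,x3"
        back = ldn.FeatureTrace.from_csv(path)
        assert np.array_equal(back.values, tr.values)


class TestDelayDecoder:
    def test_constant_probe_decodes_constant(self):
        spec = ldn.make_ldn(6, 0.1)
        w, err = ldn.fit_delay_decoder(spec, 0.05, np.full(2000, 0.8))
        assert err < 1e-6

    def test_band_limited_probe_accuracy(self):
        spec = ldn.make_ldn(10, 0.1)
        rng = np.random.default_rng(0)
        probe = synth.band_limited_noise(3000, 1e-3, 10, rng)
        _, err = ldn.fit_delay_decoder(spec, 0.05, probe)
        assert err < 0.2

    @pytest.mark.parametrize("phi", [0.0, -0.01, 0.11])
    def test_rejects_delay_outside_window(self, phi):
        spec = ldn.make_ldn(4, 0.1)
        with pytest.raises(ValueError):
            ldn.fit_delay_decoder(spec, phi, np.zeros(1000))
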