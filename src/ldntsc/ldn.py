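"""Legendre Delay Network (LDN): construction, discretization, simulation.

The delay network is the linear time-invariant (LTI) system

    theta * x'(t) = A x(t) + B u(t),        x(t) in R^d,

whose d-dimensional state optimally compresses the trailing ``theta``
seconds of a scalar input u(t): any delayed copy u(t - phi) with
0 < phi <= theta is approximately linearly decodable from x(t).  The
unscaled state matrices have the closed forms (0-based i, j)

    A[i, j] = (2i + 1) * ( -1            if i <  j
                           (-1)^(i-j+1)  if i >= j )
    B[i]    = (2i + 1) * (-1)^i

and the window length enters by scaling both matrices by 1/theta, which
realizes the delay transfer function exp(-theta * s).

Two simulation routes are provided:

* **canonical**: zero-order-hold (ZOH) discretization of (A/theta, B/theta)
  at step ``dt``, giving the exact update x[t] = A_d x[t-1] + B_d u[t];
* **neural**: the mapped pair A' = tau*A + I, B' = tau*B realizes the same
  dynamics through a first-order low-pass synapse of time constant tau,
  x = h_tau * (A' x + B' u).  This is the form the spiking reservoir
  (:mod:`ldntsc.slrc`) implements with neuron populations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .exceptions import DataError

__all__ = [
    "LDNSpec",
    "FeatureTrace",
    "make_state_matrices",
    "scale_by_window",
    "neural_mapping",
    "discretize_zoh",
    "make_ldn",
    "extract_features",
    "simulate_filtered",
    "fit_delay_decoder",
]


def make_state_matrices(d):
    """Closed-form unscaled LDN state matrices of order ``d``.

    Returns ``(A_raw, B_raw)`` with ``A_raw`` of shape (d, d) and ``B_raw``
    of shape (d,).  Every entry of row i has magnitude 2i+1 and
    ``B_raw[i]`` alternates in sign.
    """
    if isinstance(d, bool) or not isinstance(d, (int, np.integer)):
        raise ValueError(f"order d must be a positive integer, got {d!r}")
    if d < 1:
        raise ValueError(f"order d must be >= 1, got {d}")
    i = np.arange(d)[:, None]
    j = np.arange(d)[None, :]
    sign = np.where(i < j, -1.0, (-1.0) ** (i - j + 1))
    A_raw = (2.0 * i + 1.0) * sign
    k = np.arange(d)
    B_raw = (2.0 * k + 1.0) * (-1.0) ** k
    return A_raw, B_raw


def scale_by_window(A_raw, B_raw, theta):
    """Scale the unscaled matrices by 1/theta to set the window length."""
    if not theta > 0:
        raise ValueError(f"window theta must be > 0, got {theta}")
    return np.asarray(A_raw) / theta, np.asarray(B_raw) / theta


def neural_mapping(A_c, B_c, tau):
    """Map continuous matrices to the low-pass synapse form.

    A' = tau*A + I and B' = tau*B: simulating x = h_tau * (A' x + B' u)
    with a first-order filter h_tau reproduces x' = A x + B u.
    """
    A_c = np.asarray(A_c, dtype=float)
    if A_c.ndim != 2 or A_c.shape[0] != A_c.shape[1]:
        raise ValueError(f"A_c must be square, got shape {A_c.shape}")
    if not tau > 0:
        raise ValueError(f"filter constant tau must be > 0, got {tau}")
    return tau * A_c + np.eye(A_c.shape[0]), tau * np.asarray(B_c, dtype=float)


def discretize_zoh(A_c, B_c, dt):
    """Zero-order-hold discretization of x' = A_c x + B_c u at step dt.

    Uses the augmented matrix exponential

        exp([[A_c, B_c], [0, 0]] * dt) = [[A_d, B_d], [0, I]],

    which is exact and does not require A_c to be invertible.
    """
    if not dt > 0:
        raise ValueError(f"step dt must be > 0, got {dt}")
    A_c = np.atleast_2d(np.asarray(A_c, dtype=float))
    B_c = np.asarray(B_c, dtype=float).reshape(-1)
    d = A_c.shape[0]
    M = np.zeros((d + 1, d + 1))
    M[:d, :d] = A_c * dt
    M[:d, d] = B_c * dt
    E = expm(M)
    return E[:d, :d], E[:d, d]


@dataclass
class LDNSpec:
    """A fully constructed delay system at one (d, theta, tau, dt)."""

    d: int
    theta: float
    tau: float | None = None
    dt: float = 0.001
    A_raw: np.ndarray = field(repr=False, default=None)
    B_raw: np.ndarray = field(repr=False, default=None)
    A_c: np.ndarray = field(repr=False, default=None)
    B_c: np.ndarray = field(repr=False, default=None)
    A_prime: np.ndarray = field(repr=False, default=None)
    B_prime: np.ndarray = field(repr=False, default=None)
    A_d: np.ndarray = field(repr=False, default=None)
    B_d: np.ndarray = field(repr=False, default=None)


def make_ldn(d, theta, tau=None, dt=0.001):
    """Build an :class:`LDNSpec` with all derived matrices populated.

    ``A_prime``/``B_prime`` are only computed when ``tau`` is given (the
    reservoir path); the ZOH pair is always computed from the window-scaled
    continuous matrices.
    """
    if not dt > 0 or not theta > 0 or dt > theta:
        raise ValueError(f"require 0 < dt <= theta, got dt={dt}, theta={theta}")
    A_raw, B_raw = make_state_matrices(d)
    A_c, B_c = scale_by_window(A_raw, B_raw, theta)
    A_d, B_d = discretize_zoh(A_c, B_c, dt)
    spec = LDNSpec(d=d, theta=theta, tau=tau, dt=dt, A_raw=A_raw, B_raw=B_raw,
                   A_c=A_c, B_c=B_c, A_d=A_d, B_d=B_d)
    if tau is not None:
        spec.A_prime, spec.B_prime = neural_mapping(A_c, B_c, tau)
    return spec


@dataclass
class FeatureTrace:
    """Temporal features x[t] of one signal: a (T, d) array plus the step."""

    values: np.ndarray
    dt: float

    def to_csv(self, path):
        d = self.values.shape[1]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([f"x{i}" for i in range(d)])
            for row in self.values:
                w.writerow([repr(float(v)) for v in row])

    @classmethod
    def from_csv(cls, path, dt=0.001):
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(values=values, dt=dt)


def extract_features(u, A_d, B_d, x0=None, dt=0.001):
    """Run the discretized LDN over one signal or a batch of signals.

    x[t] = A_d x[t-1] + B_d u[t] with x[-1] = x0 (zeros by default); the
    update is applied at t = 0, so row 0 already reflects u[0].

    Parameters
    ----------
    u : array, shape (T,) or (B, T)
    Returns a :class:`FeatureTrace` for a single signal, or a (B, T, d)
    array for a batch.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise DataError("input signal contains non-finite values")
    single = u.ndim == 1
    U = u[None, :] if single else u
    B_, T = U.shape
    d = len(B_d)
    x = np.zeros((B_, d)) if x0 is None else np.broadcast_to(
        np.asarray(x0, dtype=float), (B_, d)).copy()
    out = np.empty((B_, T, d))
    A_dT = np.asarray(A_d).T
    B_d = np.asarray(B_d)
    for t in range(T):
        x = x @ A_dT + U[:, t, None] * B_d
        out[:, t] = x
    if single:
        return FeatureTrace(values=out[0], dt=dt)
    return out


def simulate_filtered(A_prime, B_prime, u, tau, dt):
    """Simulate the neural form x = h_tau * (A' x + B' u) on a step grid.

    The first-order filter is discretized as y[t] = a y[t-1] + (1-a) v[t]
    with a = exp(-dt/tau); this is the ideal-representation (no neurons)
    version of what the spiking reservoir computes.
    """
    u = np.asarray(u, dtype=float)
    a = np.exp(-dt / tau)
    d = len(B_prime)
    x = np.zeros(d)
    out = np.empty((len(u), d))
    for t in range(len(u)):
        v = A_prime @ x + B_prime * u[t]
        x = a * x + (1.0 - a) * v
        out[t] = x
    return out


def nrmse(estimate, target):
    """Root-mean-square error normalized by the target's RMS deviation.

    For a (numerically) constant target the denominator falls back to the
    target's RMS so that a perfect reconstruction still reports 0.
    """
    estimate = np.asarray(estimate, dtype=float)
    target = np.asarray(target, dtype=float)
    err = np.sqrt(np.mean((estimate - target) ** 2))
    denom = np.std(target)
    if denom < 1e-12:
        denom = max(np.sqrt(np.mean(target**2)), 1e-12)
    return err / denom


def fit_delay_decoder(spec, phi, probe):
    """Least-squares weights decoding u(t - phi) from the LDN state.

    The probe signal is run through the discretized LDN; the first
    ceil(theta/dt) steps are discarded (the window is not yet filled) and
    w solves w^T x[t] ~= u[t - phi/dt] in the least-squares sense.

    Returns ``(weights, nrmse)`` with the NRMSE measured on the same probe.
    """
    if not (0 < phi <= spec.theta):
        raise ValueError(f"delay phi must lie in (0, theta], got {phi}")
    probe = np.asarray(probe, dtype=float)
    k = int(round(phi / spec.dt))
    n0 = int(np.ceil(spec.theta / spec.dt))
    if len(probe) <= max(n0, k) + spec.d:
        raise ValueError("probe too short: need more than theta/dt samples")
    X = extract_features(probe, spec.A_d, spec.B_d, dt=spec.dt).values
    t_idx = np.arange(max(n0, k), len(probe))
    Xf = X[t_idx]
    y = probe[t_idx - k]
    w, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    return w, nrmse(Xf @ w, y)
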