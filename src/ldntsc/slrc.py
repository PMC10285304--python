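"""Spiking Legendre Reservoir Computing (SLRC) model.

A reservoir-computing classifier in which the Legendre delay dynamics are
carried by populations of integrate-and-fire neurons, in the style of the
Neural Engineering Framework (NEF):

* **INP** — the scalar input node, connected to the reservoir with weight
  tau*B (the neural-mapped input matrix);
* **RES** — d ensembles of N_sn neurons, one per state dimension,
  recurrently connected with weight tau*A + I through a first-order
  low-pass synapse of time constant tau;
* **ENS** — a single ensemble of N_sn*d/4 neurons that collects the full
  d-dimensional state through an identity connection;
* **OTP** — class nodes read out from ENS activities by L2-regularized
  least squares (the only learned connection).

Each neuron has a rectified-linear IF tuning curve parameterized on a
normalized input current J: J = 0 at the neuron's intercept, J = 1 at its
preferred input of magnitude ``radius``, and rate = max_rate * max(0, J).
The inter-sample inhibition (a current of magnitude 8 on this normalized
scale, applied for 50 steps) silences the reservoir between independent
samples so no memory of the previous signal leaks into the next.

In ``rate`` mode neurons output their instantaneous rates; in ``spiking``
mode they emit binary spikes that are low-pass filtered with the same tau
before decoding.  NEF weight matrices are kept in factored encoder /
transform / decoder form rather than materialized as dense
neuron-to-neuron matrices; the two are numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from . import ldn
from .data import Dataset
from .exceptions import ConfigurationError, DataError

__all__ = [
    "EnsembleSpec", "SLRCConfig", "SLRCModel",
    "build_ensemble", "compute_decoders", "build_slrc",
    "simulate_slrc", "inhibit", "collect_activities", "fit_readout",
    "classify_slrc",
    "n_neurons", "evaluate",
]


@dataclass
class EnsembleSpec:
    """A population of rectified-linear IF neurons representing a vector."""

    dim: int
    n: int
    fr_min: float
    fr_max: float
    radius: float
    encoders: np.ndarray = field(repr=False)   # (n, dim) unit directions
    gains: np.ndarray = field(repr=False)      # normalized-current slope
    biases: np.ndarray = field(repr=False)     # normalized-current offset
    max_rates: np.ndarray = field(repr=False)  # Hz at the preferred input
    intercepts: np.ndarray = field(repr=False)
    eval_points: np.ndarray = field(repr=False)
    decoders: np.ndarray | None = field(repr=False, default=None)

    def activities(self, x, extra_current=0.0):
        """Firing rates (Hz) at represented value(s) ``x`` of shape
        (..., dim).  ``extra_current`` adds to the normalized current J
        (e.g. -8 for the inter-sample inhibition)."""
        x = np.asarray(x, dtype=float)
        J = (x @ self.encoders.T) * self.gains + self.biases + extra_current
        return self.max_rates * np.maximum(J, 0.0)


def build_ensemble(dim, n, fr_min, fr_max, radius, seed) -> EnsembleSpec:
    """Sample a population: max rates uniform in [fr_min, fr_max],
    intercepts uniform in (-radius, radius), gains/biases solved so each
    neuron is silent at its intercept and fires at its max rate at its
    preferred input of magnitude ``radius``."""
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if not (0 <= fr_min < fr_max):
        raise ConfigurationError(
            f"need 0 <= fr_min < fr_max, got ({fr_min}, {fr_max})")
    if not radius > 0:
        raise ConfigurationError(f"radius must be > 0, got {radius}")
    rng = np.random.default_rng(seed)
    if dim == 1:
        encoders = rng.choice([-1.0, 1.0], size=(n, 1))
        eval_points = np.linspace(-radius, radius, 500)[:, None]
    else:
        encoders = rng.standard_normal((n, dim))
        encoders /= np.linalg.norm(encoders, axis=1, keepdims=True)
        directions = rng.standard_normal((1000, dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = radius * rng.uniform(0, 1, size=(1000, 1)) ** (1.0 / dim)
        eval_points = directions * radii
    max_rates = rng.uniform(fr_min, fr_max, size=n)
    intercepts = rng.uniform(-radius, radius, size=n)
    gains = 1.0 / (radius - intercepts)          # J = 1 at x = radius * e
    biases = -intercepts * gains
    return EnsembleSpec(dim=dim, n=n, fr_min=fr_min, fr_max=fr_max,
                        radius=radius, encoders=encoders, gains=gains,
                        biases=biases, max_rates=max_rates,
                        intercepts=intercepts, eval_points=eval_points)


def compute_decoders(ens: EnsembleSpec, target_fn=None, ridge_lambda=None):
    """L2-regularized least-squares decoders over the evaluation points.

    ``target_fn`` maps (S, dim) points to (S, k) targets; identity by
    default.  The default ridge penalty is 0.1 x the mean maximum rate,
    negligible next to the Hz-scale Gram matrix but enough to tame
    ill-conditioning.
    """
    A = ens.activities(ens.eval_points)
    Y = ens.eval_points if target_fn is None else np.atleast_2d(
        np.asarray(target_fn(ens.eval_points), dtype=float))
    if Y.ndim == 1:
        Y = Y[:, None]
    lam = ridge_lambda if ridge_lambda is not None else 0.1 * float(
        np.mean(ens.max_rates))
    G = A.T @ A + lam * np.eye(ens.n)
    return np.linalg.solve(G, A.T @ Y)


@dataclass(frozen=True)
class SLRCConfig:
    """Defaults follow the best-performing CPU configuration: d = 10,
    theta = 0.12 s, tau = 0.1 s, 200 neurons per reservoir ensemble firing
    between 150 and 350 Hz, reservoir radius 0.5 and collector radius 1."""

    d: int = 10
    theta: float = 0.12
    tau: float = 0.1
    n_sn: int = 200
    fr_min: float = 150.0
    fr_max: float = 350.0
    r_res: float = 0.5
    r_ens: float = 1.0
    inhibit_magnitude: float = 8.0
    inhibit_duration: int = 50
    ridge_lambda: float | None = None
    dt: float = 0.001
    seed: int = 0
    mode: str = "rate"


@dataclass
class SLRCModel:
    config: SLRCConfig
    spec: ldn.LDNSpec = field(repr=False)
    res: list = field(repr=False)        # d 1-D EnsembleSpec
    ens: EnsembleSpec = field(repr=False)
    # recurrent / input transforms on the discrete synapse (see build_slrc)
    W_rec: np.ndarray = field(repr=False, default=None)
    w_in: np.ndarray = field(repr=False, default=None)
    # stacked reservoir arrays for vectorized stepping, all (d, n_sn)
    _enc: np.ndarray = field(repr=False, default=None)
    _gain: np.ndarray = field(repr=False, default=None)
    _bias: np.ndarray = field(repr=False, default=None)
    _maxr: np.ndarray = field(repr=False, default=None)
    _dec: np.ndarray = field(repr=False, default=None)


def n_neurons(model: SLRCModel) -> int:
    """Total spiking neurons: d ensembles of N_sn plus the collector."""
    return sum(e.n for e in model.res) + model.ens.n


def build_slrc(config: SLRCConfig) -> SLRCModel:
    if config.d < 1:
        raise ConfigurationError(f"d must be >= 1, got {config.d}")
    if config.mode not in ("rate", "spiking"):
        raise ConfigurationError(f"unknown mode {config.mode!r}")
    n_ens = (config.n_sn * config.d) // 4
    if n_ens < 1:
        raise ConfigurationError("collector ensemble would be empty")
    spec = ldn.make_ldn(config.d, config.theta, tau=config.tau, dt=config.dt)
    res = [build_ensemble(1, config.n_sn, config.fr_min, config.fr_max,
                          config.r_res, seed=config.seed + i)
           for i in range(config.d)]
    for e in res:
        e.decoders = compute_decoders(e)
    ens = build_ensemble(config.d, n_ens, config.fr_min, config.fr_max,
                         config.r_ens, seed=config.seed + config.d)
    ens.decoders = compute_decoders(ens)
    # The continuous transforms tau*A + I and tau*B are applied in their
    # ZOH-discretized form on the discrete low-pass synapse (the simulator
    # discretizes continuous systems internally with ZOH at dt): with a
    # perfect representation the loop then reproduces the exact discrete
    # delay dynamics x[t] = A_d x[t-1] + B_d u[t].  As dt -> 0 these
    # transforms converge to tau*A + I and tau*B.
    a = np.exp(-config.dt / config.tau)
    W_rec = (spec.A_d - a * np.eye(config.d)) / (1.0 - a)
    w_in = spec.B_d / (1.0 - a)
    model = SLRCModel(config=config, spec=spec, res=res, ens=ens,
                      W_rec=W_rec, w_in=w_in)
    model._enc = np.stack([e.encoders[:, 0] for e in res])
    model._gain = np.stack([e.gains for e in res])
    model._bias = np.stack([e.biases for e in res])
    model._maxr = np.stack([e.max_rates for e in res])
    model._dec = np.stack([e.decoders[:, 0] for e in res])
    return model


class _SLRCState:
    """Synapse filter states (and spiking-mode membrane states)."""

    def __init__(self, model):
        c = model.config
        self.xin = np.zeros(c.d)            # RES represented value
        self.qin = np.zeros(c.d)            # ENS represented value
        if c.mode == "spiking":
            self.v_res = np.zeros((c.d, c.n_sn))
            self.f_res = np.zeros((c.d, c.n_sn))
            self.v_ens = np.zeros(model.ens.n)
            self.f_ens = np.zeros(model.ens.n)


def _res_rates(model, xin, extra):
    J = model._gain * (model._enc * xin[:, None]) + model._bias + extra
    return model._maxr * np.maximum(J, 0.0)


def _step(model, state, u_t, inhibit):
    c = model.config
    a = np.exp(-c.dt / c.tau)
    extra = -c.inhibit_magnitude if inhibit else 0.0
    if c.mode == "rate":
        act_res = _res_rates(model, state.xin, extra)       # (d, n_sn)
        dec = np.einsum("dn,dn->d", model._dec, act_res)
        dec_probe = dec
        act_ens = model.ens.activities(state.qin)
    else:
        # spikes enter the recurrence unfiltered: the synapse low-pass on
        # xin/qin is the one and only filter, exactly as in the rate path
        rate_res = _res_rates(model, state.xin, extra)
        state.v_res += c.dt * rate_res
        sp = (state.v_res >= 1.0).astype(float)
        state.v_res -= sp
        dec = np.einsum("dn,dn->d", model._dec, sp) / c.dt
        state.f_res = a * state.f_res + (1 - a) * sp / c.dt
        dec_probe = np.einsum("dn,dn->d", model._dec, state.f_res)
        rate_ens = model.ens.activities(state.qin)
        state.v_ens += c.dt * rate_ens
        sp_e = (state.v_ens >= 1.0).astype(float)
        state.v_ens -= sp_e
        state.f_ens = a * state.f_ens + (1 - a) * sp_e / c.dt
        act_ens = state.f_ens
    target = model.W_rec @ dec + model.w_in * u_t
    state.xin = a * state.xin + (1 - a) * target
    state.qin = a * state.qin + (1 - a) * dec
    return act_ens, dec_probe


def simulate_slrc(model: SLRCModel, signal, inhibit_before=0, state=None):
    """Run one signal through the reservoir.

    ``inhibit_before`` steps of inhibition (zero input, negative current
    into all reservoir neurons) are applied before the signal.  Returns
    ``(ens_activities, res_decoded, state)``: the (T, N_ens) collector
    activity trace, the (T, d) instantaneously decoded reservoir state,
    and the carry-over state for streaming use.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise DataError("input signal contains non-finite values")
    if state is None:
        state = _SLRCState(model)
    if inhibit_before:
        _, state = inhibit(model, state, steps=inhibit_before)
    T = len(signal)
    acts = np.empty((T, model.ens.n))
    decs = np.empty((T, model.config.d))
    for t in range(T):
        acts[t], decs[t] = _step(model, state, signal[t], inhibit=False)
    return acts, decs, state


def inhibit(model: SLRCModel, state=None, steps=None):
    """Apply the inter-sample inhibition and return its decoded trace.

    Injects the configured negative current into all reservoir neurons for
    ``steps`` steps (the configured duration by default) with zero input.
    Returns ``(res_decoded, state)``; the last row shows the decoded state
    at the end of the inhibition window.
    """
    if state is None:
        state = _SLRCState(model)
    if steps is None:
        steps = model.config.inhibit_duration
    decs = np.empty((steps, model.config.d))
    for t in range(steps):
        _, decs[t] = _step(model, state, 0.0, inhibit=True)
    return decs, state


def collect_activities(model: SLRCModel, dataset: Dataset,
                       inhibit_between=True):
    """One activity summary row per sample: mean collector activity over
    the last ceil(T/4) steps of each sample window.  With
    ``inhibit_between`` the reservoir is inhibited for the configured
    duration before every sample; without it, state simply carries over.
    """
    c = model.config
    n_tail = int(np.ceil(dataset.length / 4))
    state = None
    rows = np.empty((len(dataset), model.ens.n))
    for i, sig in enumerate(dataset.signals):
        pre = c.inhibit_duration if inhibit_between else 0
        acts, _, state = simulate_slrc(model, sig, inhibit_before=pre,
                                       state=state)
        rows[i] = acts[-n_tail:].mean(axis=0)
    return rows


@dataclass
class Readout:
    model: Ridge = field(repr=False)
    n_classes: int

    def scores(self, summaries):
        return self.model.predict(np.atleast_2d(summaries))


def fit_readout(activity_summaries, labels, ridge_lambda=None,
                n_classes=None) -> Readout:
    """Ridge regression from per-sample activity summaries to one-hot
    class targets."""
    A = np.atleast_2d(np.asarray(activity_summaries, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if len(A) != len(labels):
        raise DataError(
            f"{len(A)} summaries but {len(labels)} labels")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    Y = np.eye(n_classes)[labels]
    lam = ridge_lambda if ridge_lambda is not None else 0.1 * float(
        np.mean(np.max(A, axis=0))) if A.size else 1.0
    ridge = Ridge(alpha=max(lam, 1e-12), fit_intercept=True)
    ridge.fit(A, Y)
    return Readout(model=ridge, n_classes=n_classes)


def classify_slrc(readout: Readout, activity_summary):
    """Predicted class from one activity summary.

    Scores are rounded to the nearest integer per class node; the
    prediction is the node with the highest rounded score, raw score
    breaking rounded ties, lowest index breaking exact ties.
    """
    raw = readout.scores(activity_summary)[0]
    rounded = np.rint(raw)
    best = 0
    for c in range(1, len(raw)):
        if (rounded[c], raw[c]) > (rounded[best], raw[best]):
            best = c
    return int(best)


def evaluate(readout: Readout, summaries, labels):
    """Accuracy (%) of the rounded-score classification rule."""
    preds = np.array([classify_slrc(readout, s) for s in
                      np.atleast_2d(summaries)])
    return 100.0 * float(np.mean(preds == np.asarray(labels)))
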