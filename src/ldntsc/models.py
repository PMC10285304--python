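"""The Legendre Spiking Neural Network (LSNN) and its ablation variants.

Architecture (full variant)::

    u(t) --LDN--> x(t) --ENC (2d IF)--> HDN (3d IF) --> OTP (n_classes nodes)

The LDN feature extraction is a static linear preprocessing step: features
for the whole signal are computed first, then the spiking layers are
stepped through time from zero states.  Only the two dense matrices
W_enc_hdn (2d x 3d) and W_hdn_otp (3d x n_classes) are trainable; all
other connections are fixed.  The class score of a sample is the maximum
output-node voltage over time, fed through log-softmax into a negative
log-likelihood loss.

Variants:

* ``full``  — as above; 5d spiking neurons in total.
* ``nhdn``  — no hidden layer: ENC spikes connect directly to the output
  nodes through a single 2d x n_classes matrix (a conventional
  reservoir-computing readout, but trained by gradient descent).
* ``nspk``  — non-spiking counterpart: x(t) feeds a 3d-wide ReLU hidden
  layer and a linear output read per step; the same max-then-softmax loss
  applies.  Being differentiable, this variant doubles as the
  finite-difference anchor for the gradient code.

Because the encoder layer contains no trainable parameters, its spike
trains depend only on the input; they are pre-computed once per dataset
(``encode_dataset``) and reused across epochs.  Gradients are
backpropagated through time by hand, with the surrogate derivative
standing in for the spike nonlinearity and the hard reset excluded from
the gradient path (the standard surrogate-gradient convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ldn
from .exceptions import ConfigurationError, DataError
from .neurons import LayerState, NeuronParams, enc_step, surrogate_grad

__all__ = [
    "LSNNConfig",
    "LSNNModel",
    "build_lsnn",
    "build_lsnn_nhdn",
    "build_lsnn_nspk",
    "forward",
    "classification_loss",
    "encode_dataset",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LSNNConfig:
    """Hyper-parameters of one LSNN instance.

    Defaults follow the ECG-scale setting: d = 10, a 0.12 s rolling window,
    encoder gain rho = 2 with zero bias, tau_cur = 10 ms, tau_vol = 20 ms,
    unit threshold, 1 ms steps.
    """

    d: int = 10
    theta: float = 0.12
    n_classes: int = 2
    rho: float = 2.0
    iota: float = 0.0
    tau_cur: float = 10e-3
    tau_vol: float = 20e-3
    v_thr: float = 1.0
    dt: float = 0.001
    seed: int = 0
    clamp_enc: bool = True

    @property
    def n_enc(self) -> int:
        return 2 * self.d

    @property
    def n_hdn(self) -> int:
        return 3 * self.d

    @property
    def n_spiking(self) -> int:
        """Total spiking neurons in the full variant: 2d + 3d = 5d."""
        return 5 * self.d


@dataclass
class LSNNModel:
    config: LSNNConfig
    variant: str
    spec: ldn.LDNSpec = field(repr=False)
    enc_params: NeuronParams = field(repr=False)
    hdn_params: NeuronParams = field(repr=False)
    otp_params: NeuronParams = field(repr=False)
    weights: dict = field(repr=False)

    @property
    def n_spiking(self) -> int:
        if self.variant == "full":
            return 5 * self.config.d
        if self.variant == "nhdn":
            return 2 * self.config.d
        return 0  # nspk has no spiking neurons

    def copy_weights(self):
        return {k: v.copy() for k, v in self.weights.items()}


def _init_matrix(rng, fan_in, fan_out):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def _make_params(cfg: LSNNConfig):
    enc = NeuronParams(v_thr=cfg.v_thr, rho=cfg.rho, iota=cfg.iota, dt=cfg.dt)
    hdn = NeuronParams(v_thr=cfg.v_thr, tau_cur=cfg.tau_cur, dt=cfg.dt)
    otp = NeuronParams(v_thr=cfg.v_thr, tau_cur=cfg.tau_cur,
                       tau_vol=cfg.tau_vol, dt=cfg.dt)
    return enc, hdn, otp


def _check_config(cfg: LSNNConfig):
    if cfg.d < 1:
        raise ConfigurationError(f"d must be >= 1, got {cfg.d}")
    if cfg.n_classes < 2:
        raise ConfigurationError(
            f"n_classes must be >= 2, got {cfg.n_classes}")


def build_lsnn(config: LSNNConfig) -> LSNNModel:
    """Full LSNN: 2d encoder + 3d hidden spiking neurons, two trained matrices."""
    _check_config(config)
    rng = np.random.default_rng(config.seed)
    spec = ldn.make_ldn(config.d, config.theta, dt=config.dt)
    enc, hdn, otp = _make_params(config)
    weights = {
        "W1": _init_matrix(rng, config.n_enc, config.n_hdn),
        "W2": _init_matrix(rng, config.n_hdn, config.n_classes),
    }
    return LSNNModel(config=config, variant="full", spec=spec,
                     enc_params=enc, hdn_params=hdn, otp_params=otp,
                     weights=weights)


def build_lsnn_nhdn(config: LSNNConfig) -> LSNNModel:
    """Ablation without the hidden layer: ENC spikes feed the output directly."""
    _check_config(config)
    rng = np.random.default_rng(config.seed)
    spec = ldn.make_ldn(config.d, config.theta, dt=config.dt)
    enc, hdn, otp = _make_params(config)
    weights = {"W": _init_matrix(rng, config.n_enc, config.n_classes)}
    return LSNNModel(config=config, variant="nhdn", spec=spec,
                     enc_params=enc, hdn_params=hdn, otp_params=otp,
                     weights=weights)


def build_lsnn_nspk(config: LSNNConfig) -> LSNNModel:
    """Non-spiking counterpart: d-node input, 3d ReLU hidden, linear output."""
    _check_config(config)
    rng = np.random.default_rng(config.seed)
    spec = ldn.make_ldn(config.d, config.theta, dt=config.dt)
    enc, hdn, otp = _make_params(config)
    weights = {
        "W1": _init_matrix(rng, config.d, config.n_hdn),
        "W2": _init_matrix(rng, config.n_hdn, config.n_classes),
    }
    return LSNNModel(config=config, variant="nspk", spec=spec,
                     enc_params=enc, hdn_params=hdn, otp_params=otp,
                     weights=weights)


# ---------------------------------------------------------------------------
# Encoding (static per dataset) and forward simulation
# ---------------------------------------------------------------------------

def _enc_spikes(model: LSNNModel, X):
    """Encoder spike trains for features X of shape (B, T, d) -> (B, T, 2d)."""
    B, T, d = X.shape
    state = LayerState.zeros((B, 2 * d))
    S = np.empty((B, T, 2 * d))
    for t in range(T):
        S[:, t], state = enc_step(X[:, t], model.enc_params, state,
                                  clamp=model.config.clamp_enc)
    return S


def encode_dataset(model: LSNNModel, signals):
    """Static per-dataset preprocessing: LDN features, then (for the spiking
    variants) the encoder spike trains.  Shape (B, T, d) or (B, T, 2d)."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[None, :]
    X = ldn.extract_features(signals, model.spec.A_d, model.spec.B_d,
                             dt=model.config.dt)
    if model.variant == "nspk":
        return X
    return _enc_spikes(model, X)


def _simulate_spiking(model: LSNNModel, Z):
    """Step the trained part of the network over encoded inputs Z.

    Returns (Vo, Sh, Vh_pre): output-voltage trace (B, T, C) and, for the
    full variant, the hidden spikes and pre-reset voltages needed by the
    backward pass (None otherwise).
    """
    B, T, _ = Z.shape
    C = model.config.n_classes
    a_o = model.otp_params.alpha
    b_o = model.otp_params.beta
    Vo = np.empty((B, T, C))
    if model.variant == "nhdn":
        W = model.weights["W"]
        Io = np.zeros((B, C))
        Vo_t = np.zeros((B, C))
        for t in range(T):
            Io = a_o * Io + Z[:, t] @ W
            Vo_t = b_o * Vo_t + Io
            Vo[:, t] = Vo_t
        return Vo, None, None
    W1, W2 = model.weights["W1"], model.weights["W2"]
    H = model.config.n_hdn
    a_h = model.hdn_params.alpha
    thr = model.config.v_thr
    Ih = np.zeros((B, H))
    Vh = np.zeros((B, H))
    Io = np.zeros((B, C))
    Vo_t = np.zeros((B, C))
    Sh = np.empty((B, T, H))
    Vh_pre = np.empty((B, T, H))
    for t in range(T):
        Ih = a_h * Ih + Z[:, t] @ W1
        Vpre = Vh + Ih
        S = (Vpre >= thr).astype(float)
        Vh = Vpre * (1.0 - S)  # hard reset
        Io = a_o * Io + S @ W2
        Vo_t = b_o * Vo_t + Io
        Sh[:, t] = S
        Vh_pre[:, t] = Vpre
        Vo[:, t] = Vo_t
    return Vo, Sh, Vh_pre


def _traces_nspk(model: LSNNModel, X):
    h = np.maximum(X @ model.weights["W1"], 0.0)
    return h @ model.weights["W2"], h


def output_traces(model: LSNNModel, Z):
    """Output-node voltage traces (B, T, C) from encoded inputs."""
    if model.variant == "nspk":
        return _traces_nspk(model, Z)[0]
    return _simulate_spiking(model, Z)[0]


def forward(model: LSNNModel, u):
    """Run one signal end to end.

    Returns ``(V_otp_trace, prediction)``: the (T, n_classes) output-node
    voltage trace and the predicted class (argmax over classes of the
    per-class maximum voltage; ties go to the lowest index).
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1:
        raise DataError("forward expects a single 1-D signal")
    Z = encode_dataset(model, u[None, :])
    V = output_traces(model, Z)
    m = V[0].max(axis=0)
    return V[0], int(np.argmax(m))


def predict(model: LSNNModel, Z, chunk=512):
    """Predicted classes for encoded inputs Z of shape (B, T, .)."""
    preds = []
    for i in range(0, len(Z), chunk):
        V = output_traces(model, Z[i:i + chunk])
        preds.append(np.argmax(V.max(axis=1), axis=1))
    return np.concatenate(preds)


# ---------------------------------------------------------------------------
# Loss and hand-written backward pass
# ---------------------------------------------------------------------------

def _max_scores(V):
    """Per-class maximum voltage and the step it occurs at (first max)."""
    m = V.max(axis=1)
    t_star = V.argmax(axis=1)
    return m, t_star


def _nll_from_scores(m, y):
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= m.shape[1]:
        raise DataError(
            f"labels must lie in [0, {m.shape[1]}), got range "
            f"[{y.min()}, {y.max()}]")
    z = m - m.max(axis=1, keepdims=True)
    logsm = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logsm[np.arange(len(y)), y].mean()
    dm = np.exp(logsm)
    dm[np.arange(len(y)), y] -= 1.0
    dm /= len(y)
    return loss, dm


def classification_loss(V_otp_traces, y_true):
    """Mean NLL of log-softmax over per-class max output voltages."""
    m, _ = _max_scores(np.asarray(V_otp_traces, dtype=float))
    loss, _ = _nll_from_scores(m, y_true)
    return loss


def loss_and_grad(model: LSNNModel, Z, y):
    """Loss and gradients w.r.t. the trainable matrices, via BPTT.

    ``Z`` is the output of :func:`encode_dataset`.  For the spiking
    variants the surrogate derivative 1/(1+|V - V_thr|)^2 replaces the
    spike step in the backward pass and the hard reset carries no
    gradient; the nspk variant is exactly differentiable (away from the
    ReLU/max kinks).
    """
    if model.variant == "nspk":
        return _loss_and_grad_nspk(model, Z, y)
    Vo, Sh, Vh_pre = _simulate_spiking(model, Z)
    m, t_star = _max_scores(Vo)
    loss, dm = _nll_from_scores(m, y)
    B, T, C = Vo.shape
    a_o = model.otp_params.alpha
    b_o = model.otp_params.beta
    if model.variant == "nhdn":
        W = model.weights["W"]
        dW = np.zeros_like(W)
        dVo_carry = np.zeros((B, C))
        dIo_carry = np.zeros((B, C))
        for t in range(T - 1, -1, -1):
            dVo = dm * (t_star == t) + dVo_carry
            dIo = dVo + dIo_carry
            dW += Z[:, t].T @ dIo
            dVo_carry = b_o * dVo
            dIo_carry = a_o * dIo
        return loss, {"W": dW}
    W1, W2 = model.weights["W1"], model.weights["W2"]
    a_h = model.hdn_params.alpha
    thr = model.config.v_thr
    H = model.config.n_hdn
    dW1 = np.zeros_like(W1)
    dW2 = np.zeros_like(W2)
    dVo_carry = np.zeros((B, C))
    dIo_carry = np.zeros((B, C))
    dVh_carry = np.zeros((B, H))
    dIh_carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dVo = dm * (t_star == t) + dVo_carry
        dIo = dVo + dIo_carry
        dW2 += Sh[:, t].T @ dIo
        dSh = dIo @ W2.T
        dVpre = dSh * surrogate_grad(Vh_pre[:, t] - thr) + dVh_carry
        dIh = dVpre + dIh_carry
        dW1 += Z[:, t].T @ dIh
        dVo_carry = b_o * dVo
        dIo_carry = a_o * dIo
        dIh_carry = a_h * dIh
        if t > 0:
            # reset excluded from the gradient: V carries (1 - S) only
            dVh_carry = dVpre * (1.0 - Sh[:, t - 1])
    return loss, {"W1": dW1, "W2": dW2}


def _loss_and_grad_nspk(model: LSNNModel, X, y):
    W1, W2 = model.weights["W1"], model.weights["W2"]
    O, h = _traces_nspk(model, X)
    m, t_star = _max_scores(O)
    loss, dm = _nll_from_scores(m, y)
    B, T, C = O.shape
    dW1 = np.zeros_like(W1)
    dW2 = np.zeros_like(W2)
    rows = np.arange(B)
    for c in range(C):
        ts = t_star[:, c]
        h_sel = h[rows, ts]            # (B, H)
        x_sel = X[rows, ts]            # (B, d)
        dW2[:, c] += h_sel.T @ dm[:, c]
        dh = dm[:, c, None] * W2[None, :, c]
        dz = dh * (h_sel > 0)
        dW1 += x_sel.T @ dz
    return loss, {"W1": dW1, "W2": dW2}


# ---------------------------------------------------------------------------
# Plain-text save / load
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = ("d", "theta", "n_classes", "rho", "iota", "tau_cur",
                  "tau_vol", "v_thr", "dt", "seed", "clamp_enc")


def save_model(model: LSNNModel, directory):
    """Write config as key=value text plus one CSV per weight matrix."""
    import os
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "config.txt"), "w") as fh:
        fh.write(f"variant={model.variant}\n")
        for name in _CONFIG_FIELDS:
            fh.write(f"{name}={getattr(model.config, name)!r}\n")
    for name, W in model.weights.items():
        np.savetxt(os.path.join(directory, f"{name}.csv"), W, delimiter=",")


def load_model(directory) -> LSNNModel:
    import ast
    import os
    kv = {}
    with open(os.path.join(directory, "config.txt")) as fh:
        for line in fh:
            k, _, v = line.strip().partition("=")
            kv[k] = v
    variant = kv.pop("variant")
    cfg = LSNNConfig(**{k: ast.literal_eval(v) for k, v in kv.items()})
    builder = {"full": build_lsnn, "nhdn": build_lsnn_nhdn,
               "nspk": build_lsnn_nspk}[variant]
    model = builder(cfg)
    for name in model.weights:
        W = np.loadtxt(os.path.join(directory, f"{name}.csv"),
                       delimiter=",", ndmin=2)
        model.weights[name] = W
    return model
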