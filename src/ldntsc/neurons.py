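"""Discrete-time integrate-and-fire (IF) neuron dynamics.

Three layer types make up the spiking classifier:

* **ENC** — paired rate encoders.  Neuron 2k carries a positive encoder and
  neuron 2k+1 a negative encoder for feature k:
  I[t] = rho * eps * x_k[t] + iota, V[t] = V[t-1] + I[t];  with iota = 0 and
  the (configurable) lower clamp of V at 0, at most one member of each pair
  spikes on a step.
* **HDN** — hidden IF neurons: I[t] = alpha I[t-1] + W^T S_prev[t],
  V[t] = V[t-1] + I[t]  (no voltage decay, beta = 1).
* **OTP** — output nodes: same current law, V[t] = beta V[t-1] + I[t];
  they never spike and are never reset.

All spiking neurons use a hard reset (V <- 0) in the step they spike, and
spike at V >= V_thr (so exactly at threshold counts).  The membrane
resistance R is fixed at 1.  Decay constants derive from their time
constants as alpha = exp(-dt/tau_cur), beta = exp(-dt/tau_vol); a missing
time constant means no decay (constant 1).

The spike nonlinearity is the Heaviside step; during backpropagation its
undefined derivative is replaced by the surrogate 1/(1+|x|)^2 (the negative
half of the fast sigmoid), evaluated at x = V - V_thr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "LayerState",
    "heaviside_spike",
    "surrogate_grad",
    "enc_step",
    "hdn_step",
    "otp_step",
    "save_spikes_csv",
]


@dataclass(frozen=True)
class NeuronParams:
    """IF parameters shared by all neurons of one layer.

    ``tau_cur``/``tau_vol`` of ``None`` mean no current/voltage decay
    (alpha/beta = 1), as in the ENC layer (no decay at all) and the HDN
    layer (voltage does not decay).
    """

    v_thr: float = 1.0
    rho: float = 1.0
    iota: float = 0.0
    tau_cur: float | None = None
    tau_vol: float | None = None
    dt: float = 0.001
    R: float = field(default=1.0, init=False)  # fixed by convention

    def __post_init__(self):
        if not self.v_thr > 0:
            raise ValueError(f"v_thr must be > 0, got {self.v_thr}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")

    @property
    def alpha(self) -> float:
        return 1.0 if self.tau_cur is None else float(np.exp(-self.dt / self.tau_cur))

    @property
    def beta(self) -> float:
        return 1.0 if self.tau_vol is None else float(np.exp(-self.dt / self.tau_vol))


@dataclass
class LayerState:
    """Per-layer vectors at one time step (arbitrary leading batch dims)."""

    V: np.ndarray
    I: np.ndarray
    S: np.ndarray

    @classmethod
    def zeros(cls, shape):
        return cls(V=np.zeros(shape), I=np.zeros(shape), S=np.zeros(shape))


def heaviside_spike(V, v_thr):
    """Binary spikes: 1 where V >= v_thr (spike exactly at threshold)."""
    return (np.asarray(V) >= v_thr).astype(float)


def surrogate_grad(x):
    """Surrogate spike derivative 1/(1+|x|)^2, x = V - V_thr (backward only)."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.abs(x)) ** 2


def enc_step(x_t, params: NeuronParams, state: LayerState, clamp: bool = True):
    """One step of the paired-encoder layer.

    ``x_t`` has shape (..., d); the layer has 2d neurons interleaved as
    (+feature0, -feature0, +feature1, ...).  Returns (spikes, new state).
    """
    x_t = np.asarray(x_t, dtype=float)
    d = x_t.shape[-1]
    if state.V.shape[-1] != 2 * d:
        raise ValueError(
            f"state has {state.V.shape[-1]} neurons, expected {2 * d}")
    I = np.empty(x_t.shape[:-1] + (2 * d,))
    drive = params.rho * x_t
    I[..., 0::2] = drive + params.iota
    I[..., 1::2] = -drive + params.iota
    V = state.V + I
    if clamp:
        V = np.maximum(V, 0.0)
    S = heaviside_spike(V, params.v_thr)
    V = V * (1.0 - S)  # hard reset
    return S, LayerState(V=V, I=I, S=S)


def hdn_step(S_prev, W, params: NeuronParams, state: LayerState):
    """One step of the hidden IF layer (current decays, voltage does not)."""
    S_prev = np.asarray(S_prev, dtype=float)
    if W.shape[0] != S_prev.shape[-1] or W.shape[1] != state.V.shape[-1]:
        raise ValueError(
            f"weight shape {W.shape} inconsistent with input "
            f"{S_prev.shape[-1]} and layer {state.V.shape[-1]}")
    I = params.alpha * state.I + S_prev @ W
    V = state.V + I
    S = heaviside_spike(V, params.v_thr)
    V = V * (1.0 - S)  # hard reset
    return S, LayerState(V=V, I=I, S=S)


def otp_step(S_prev, W, params: NeuronParams, state: LayerState):
    """One step of the output nodes: leaky voltage, no spikes, no reset."""
    S_prev = np.asarray(S_prev, dtype=float)
    if W.shape[0] != S_prev.shape[-1] or W.shape[1] != state.V.shape[-1]:
        raise ValueError(
            f"weight shape {W.shape} inconsistent with input "
            f"{S_prev.shape[-1]} and layer {state.V.shape[-1]}")
    I = params.alpha * state.I + S_prev @ W
    V = params.beta * state.V + I
    return LayerState(V=V, I=I, S=np.zeros_like(V))


def save_spikes_csv(spikes, path):
    """Write a (T, N) 0/1 spike raster as a dense CSV matrix."""
    np.savetxt(path, np.asarray(spikes, dtype=int), fmt="%d", delimiter=",")
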