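# Methods

This note documents the models implemented in `ldntsc`, the numerical
choices behind them, and what the synthetic benchmarks do and do not
establish.

## The Legendre Delay Network (`ldntsc.ldn`)

The core primitive is the linear time-invariant delay system.  The
unscaled closed-form matrices `A`, `B` (alternating-sign entries of
magnitude `2i+1`) realize the transfer function `exp(−θs)` once the
dynamics run at rate `1/θ`; the window length therefore enters as
`A_c = A/θ`, `B_c = B/θ`, applied *before* both discretization and the
neural mapping.  The closed forms themselves are window-free, so this
placement is a design decision of this package; it is validated
empirically by the delay-reconstruction test (a least-squares decoder of
`u(t − θ/2)` from the simulated state reaches NRMSE well below 0.2, and
the error shrinks with the order `d`).

Discretization uses the exact zero-order-hold form through the augmented
matrix exponential `exp([[A·Δt, B·Δt], [0, 0]])`, which needs no
invertibility assumption and handles singular dynamics (the `A = 0` case
degenerates to `A_d = I`, `B_d = Δt·B`).  The state update convention is
`x[t] = A_d x[t−1] + B_d u[t]` — the current step's input enters the
current state, matching a simulation in which the whole network is
evaluated once per time step.  Initial state is zero unless supplied.

Delay-decoder fitting discards the first `⌈θ/Δt⌉` samples (the window is
not yet filled) and solves an ordinary least-squares problem on the
simulated trace.  A closed-form Legendre-polynomial readout would also
work; regression was chosen because it is self-contained and directly
testable.  NRMSE is RMS error over the standard deviation of the target,
falling back to the target RMS for (numerically) constant targets.

## IF neurons and the LSNN (`ldntsc.neurons`, `ldntsc.models`)

All spiking neurons are non-leaky integrate-and-fire units with binary
spikes, firing at `V ≥ V_thr` (threshold equality spikes) and hard-reset
to zero in the same step.  Membrane resistance is fixed at 1.  The
within-step order is: current, then voltage, then spikes, then reset.

* **ENC** (2d neurons): each feature dimension drives a +/− encoder pair,
  `I = ρ·ε·x + ι` with `ε ∈ {+1, −1}`; voltages accumulate without decay.
  The membrane voltage is clamped below at 0 (configurable,
  `clamp_enc`): without the clamp the inactive pair member accumulates
  unboundedly negative voltage and stays silent for arbitrarily long
  after the feature changes sign; with it, pair exclusivity (at most one
  member spiking per step when `ι = 0`) holds on any input.
* **HDN** (3d neurons): current decays with `α = exp(−Δt/τ_cur)` and
  integrates weighted presynaptic spikes; voltage accumulates without
  decay.
* **OTP** (one node per class): same current law; voltage decays with
  `β = exp(−Δt/τ_vol)`; never spikes and is never reset.

The loss is the negative log-likelihood of `log softmax` applied to the
per-class *maximum* output voltage over all steps (including `t = 0`).
Prediction is the argmax of those maxima, ties broken to the lowest class
index for determinism.

Backpropagation through time is implemented directly in numpy.  The
spike step's undefined derivative is replaced by
`f'(x) = 1/(1+|x|)²` at `x = V_pre − V_thr` (the negative half of the
fast sigmoid); the hard reset is excluded from the gradient path — the
voltage carry across a spike contributes the factor `(1 − S[t])` with
`S` treated as a constant — which is the standard surrogate-gradient
convention.  Because the encoder layer has no trainable parameters, its
spike trains are precomputed once per dataset and reused across epochs;
LDN features are likewise extracted for whole signals up front and are
not normalized.  The differentiable `nspk` variant (ReLU hidden layer on
the raw features, linear per-step outputs, same max-then-softmax loss)
anchors the gradient code against central finite differences at 1e−4
relative tolerance.

Weight initialization (the only free choice the architecture leaves
open) is uniform on `(−1/√fan_in, +1/√fan_in)`, seeded, which keeps
initial spiking activity scale-stable.

Default hyper-parameters (`d = 10`, `θ = 0.12 s`, `ρ = 2`, `ι = 0`,
`τ_cur = 10 ms`, `τ_vol = 20 ms`, `V_thr = 1`, `η = 0.005`) are drawn
from the ECG-scale search grid; `ι = 0` preserves encoder-pair
exclusivity, and the smaller of the grid's learning rates trains stably
across seeds on the synthetic fixture.

## Training protocol (`ldntsc.training`)

Adam (`β₁ = 0.9`, `β₂ = 0.999`, `ε = 1e−8`; only the learning rate is a
named hyper-parameter) on mini-batches taken as contiguous slices of a
permutation redrawn every 20 epochs; the shuffle RNG derives from the
run seed, so runs are bit-reproducible.  Test accuracy is computed on
the entire test set after every epoch, and a run's headline number is
its best epoch.  This best-epoch-on-test selection is the evaluation
protocol this package reproduces; it is optimistic relative to a
held-out validation split and should be read as such.  Grid search is
the exhaustive product of value lists × seeds with fresh initialization
per run (weights never persist between combinations); `Max_acc` is the
maximum over everything, `Mean_acc` the mean ± *sample* standard
deviation (n−1) of per-seed maxima.  Training sample counts must divide
the batch size; UCR splits are trimmed from the tail
(`data.trim_to_batch`), dropping the minimal number of samples.

## The spiking reservoir (`ldntsc.slrc`)

Each of the `d` reservoir ensembles represents one state dimension with
`N_sn` neurons; a collector ensemble of `N_sn·d/4` neurons represents
the full state; the readout is ridge regression from collector
activities to one-hot targets.  Tuning curves are rectified-linear IF:
on a normalized current scale `J` (zero at the neuron's intercept, one
at its preferred input of magnitude `radius`), `rate = max_rate·max(0, J)`
with max rates uniform in `[FR_min, FR_max]` and intercepts uniform in
`(−radius, radius)`.  The inter-sample inhibition (magnitude 8, 50
steps) acts on this normalized scale, which silences the population; at
the end of the window the instantaneously decoded state is zero, while
the synaptic filter trace decays with `exp(−t/τ)` (about 0.6 of its
value over the 50 ms window) and is further washed out by the delay
dynamics once input resumes.

The continuous neural mapping `A' = τA + I`, `B' = τB` is applied in its
ZOH-discretized form on the discrete low-pass synapse
(`W_rec = (A_d − aI)/(1−a)`, `w_in = B_d/(1−a)`, `a = exp(−Δt/τ)`),
which is what the reference neural simulator computes internally; under
a perfect representation the loop then reproduces the exact discrete
delay dynamics, so the remaining tracking error is purely neural
(≈ 0.05–0.09 NRMSE per dimension at `d = 6`, `N_sn = 200`).  Weight
matrices stay in factored encoder/transform/decoder form — numerically
identical to the dense neuron-to-neuron product, and cheaper.  In
spiking mode neurons integrate their instantaneous rate and emit unit
spikes; the synapse low-pass over the spike decode is the *only* filter
in the loop (filtering twice would destabilize the recurrence), and the
probed/readout activities are the same τ-filtered spike trains.

Decoders solve a ridge problem over 500 evaluation points (a grid for
1-D ensembles, ball-uniform samples otherwise) with default penalty
0.1 × mean max rate — negligible against the Hz-scale Gram matrix but
enough to tame conditioning.  The readout regresses one summary row per
sample — mean collector activity over the last `⌈T/4⌉` steps — because a
per-time-step target is neither needed nor better-defined for
whole-sample labels.  Class scores are rounded to the nearest integer;
prediction is the node with the highest rounded score, raw score
breaking rounded ties, lowest index breaking exact ties.

Operating range matters: rectified-linear tuning curves do not saturate,
so decoders extrapolate badly far outside the representational radius
and the recurrent loop can become unstable if the state leaves it.  The
radius should cover the expected state range (the fidelity benchmarks
use `r_RES = 1.5` with probes whose states stay within ≈ 1.3).

## Synthetic data (`ldntsc.synth`)

The generator produces balanced two-class univariate signals shaped like
the ECG benchmark (T = 140 samples at 1 ms): class 0 an upward Gaussian
bump at uniform random latency, class 1 a downward one (amplitude =
`class_gap`, default 1), plus Gaussian noise (`noise_sigma`, default
0.1); a frequency mode provides sinusoid-pair discrimination.  Default
sizes are 200 train / 100 test.  With the default gap the classes are
separable by thresholding the signed extremum, so any functioning
classifier should approach 100% — passing these tests demonstrates that
the architectures, gradients, and readouts work, *not* that they reach
any particular accuracy on real, imbalanced, noisier archives; the
morphology difference here is far cleaner than real inter-patient ECG
variation.  `band_limited_noise` (causal Butterworth low-pass on white
noise with the warm-up discarded, RMS-normalized) is the probe for delay
and fidelity measurements.

## Problem sizes and determinism

The shipped benchmarks are desk-scale by design: 3-second training runs
(200 samples, 50 epochs, three seeds), 3 s probes for delay/fidelity
measurements, 20-system discretization checks.  Full UCR-archive grid
searches (thousands of runs) use the same code paths via `ldntsc grid`.
All randomness — weight init, data generation, shuffling, ensemble
sampling — flows through explicit integer seeds; identical seeds give
bit-identical results on one platform.

## Known limitations

* Univariate signals only; one hidden layer; no early stopping,
  validation splits, or learning-rate schedules (deliberately outside
  scope).
* The best-epoch-on-test accuracy accounting is optimistic (see above).
* The reservoir's rate model has no refractory saturation, so behaviour
  outside the representational radius is unconstrained.
* Neuromorphic-hardware deployment (firing-rate quantization, energy
  profiling) is out of scope; the CPU simulation uses graded rates or
  ideal binary spikes.
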