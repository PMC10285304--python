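# ldntsc — spiking time-series classification with Legendre Delay Networks

`ldntsc` implements two spiking neural architectures for univariate binary
time-series classification (ECG beats, engine noise, wafer sensors,
seismic traces), aimed at the regime where energy-efficient neuromorphic
deployment matters and networks must stay tiny:

* **LSNN** (Legendre Spiking Neural Network) — a Legendre Delay Network
  (LDN) extracts `d`-dimensional temporal features `x(t)` from the scalar
  input; paired ± rate-encoding integrate-and-fire (IF) neurons (`2d`), a
  spiking hidden layer (`3d`), and leaky output nodes (one per class) are
  trained end to end with surrogate-gradient backpropagation through
  time.  The full network uses just `5d` spiking neurons (50 at `d = 10`).
* **SLRC** (Spiking Legendre Reservoir Computing) — the same delay
  dynamics run *inside* populations of spiking neurons in the style of
  the Neural Engineering Framework; the only trained connection is an
  L2-regularized least-squares readout.

## The model in brief

The LDN is the LTI system `θ·x'(t) = A x(t) + B u(t)` with

```
A[i,j] = (2i+1) · ( −1 if i<j, (−1)^(i−j+1) if i≥j )
B[i]   = (2i+1) · (−1)^i        i, j ∈ [0, d−1]
```

whose state compresses the trailing `θ` seconds of `u(t)`: any delay
`u(t−φ)`, `φ ∈ (0, θ]`, is linearly decodable from `x(t)`.  For the LSNN
the system is ZOH-discretized at Δt = 1 ms; for the SLRC it is mapped
onto a first-order synapse of time constant `τ` via `A' = τA + I`,
`B' = τB`.  Spiking layers follow discrete IF dynamics with binary
spikes, hard reset at `V ≥ V_thr`, current decay `α = exp(−Δt/τ_cur)`
and (output nodes only) voltage decay `β = exp(−Δt/τ_vol)`.  Training
substitutes the surrogate `f'(x) = 1/(1+|x|)²` for the spike derivative
and minimizes the negative log-likelihood of `log softmax(max_t V_otp)`.

## Worked example

Generate a synthetic two-class fixture (upward vs downward ECG-like bumps
in noise) and train an LSNN on it:

```bash
ldntsc synth --out fixture --n-train 200 --n-test 100 --seed 42
ldntsc train-lsnn --dataset fixture/train.tsv --test-dataset fixture/test.tsv \
    --d 10 --epochs 50 --seed 6 --out run
```

which prints

```
wrote 200+100 samples of length 140 to fixture
max test accuracy 100.00% (epoch 7)
```

i.e. a 50-neuron spiking network separates the two waveform classes
perfectly within a few epochs; `run/log.txt` holds the per-epoch loss and
test accuracy, `run/summary.csv` the best epoch, and `run/model/` the
trained weights as plain CSV.  The same data trains the reservoir model
via `ldntsc train-slrc`, and `ldntsc grid` reproduces the
grid × seeds protocol with its `Max_acc` (best over all combinations and
seeds) and `Mean_acc` (mean ± std of per-seed maxima) accounting.

The same flow in Python:

```python
from ldntsc import models, synth, training

train, test = synth.generate(synth.SynthSpec(seed=42))
model = models.build_lsnn(models.LSNNConfig(d=10, seed=6))
result = training.train(model, train, test, training.TrainConfig(epochs=50))
print(result.max_acc)   # 100.0
```

To run on the real UCR archives (ECG5000, FordA/B, Wafer, Earthquakes,
from timeseriesclassification.com), point `--dataset` at the downloaded
file, pick `--dialect {tsv,ts,arff}`, and add `--binarize-ecg5000` to
merge the four abnormal ECG beat classes into one.

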