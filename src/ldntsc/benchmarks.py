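"""Published benchmark accuracies on five univariate binary TSC datasets.

Test accuracies (%) as reported in the literature for these UCR-archive
tasks: the liquid-state-machine (LSM) reservoir results that were the
spiking state of the art, and the accuracies achieved by the LSNN model
family this package implements.  They are inputs for resource/accuracy
comparisons, e.g. the relative improvement of the LSNN over the LSM
baselines.
"""

from __future__ import annotations

__all__ = ["LSM_SPIKING_SOTA", "LSNN_MAX_ACC", "LSNN_NHDN_MAX_ACC",
           "relative_improvement"]

#: LSM-based spiking reservoir results (the prior spiking state of the art).
LSM_SPIKING_SOTA = {
    "Wafer": 98.85,
    "FordA": 80.37,
    "FordB": 64.32,
    "Earthquakes": 71.94,
}

#: Best test accuracy of the full LSNN over its hyper-parameter grid and
#: three seeds.
LSNN_MAX_ACC = {
    "ECG5000": 98.49,
    "Wafer": 99.51,
    "FordA": 93.56,
    "FordB": 82.72,
    "Earthquakes": 80.43,
}

#: Same, for the no-hidden-layer ablation.
LSNN_NHDN_MAX_ACC = {
    "ECG5000": 97.73,
    "Wafer": 99.38,
    "FordA": 89.62,
    "FordB": 77.78,
    "Earthquakes": 79.71,
}


def relative_improvement(new, base):
    """Relative accuracy improvement in percent: 100 * (new - base) / base."""
    return 100.0 * (new - base) / base
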