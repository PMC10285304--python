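"""Readers for UCR-archive time-series files and dataset transformations.

Supported dialects:

* ``tsv``  — one sample per line, label in the first column, values after
  (tab or comma separated); the native UCR distribution format.
* ``ts``   — the sktime text dialect: ``@``-prefixed header lines, then
  ``@data`` followed by ``v1,v2,...,vT:label`` lines.
* ``arff`` — through :func:`scipy.io.arff.loadarff`; the class attribute is
  the last column.

Loading preserves file order and the file's original labels.  Downstream
training requires contiguous labels starting at 0: use
:func:`binarize_ecg5000` (healthy-vs-abnormal merge for the five ECG5000
beat classes) or :func:`canonicalize_labels`.

Signals are used exactly as distributed: no normalization of inputs (or of
the LDN features computed from them) is applied anywhere in this package.
One sample value corresponds to one 1 ms simulation step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, DataError, FormatError

__all__ = ["Dataset", "load_ucr", "write_tsv", "binarize_ecg5000",
           "canonicalize_labels", "trim_to_batch"]

#: ECG5000 beat classes in file-label order (1..5); class 1 is the healthy
#: rhythm, all others are abnormal beat morphologies.
ECG5000_CLASSES = {
    1: "N",          # normal
    2: "R-on-T PVC",  # R-on-T premature ventricular contraction
    3: "PVC",        # premature ventricular contraction
    4: "SP",         # supra-ventricular premature beat
    5: "UB",         # unclassified beat
}


@dataclass
class Dataset:
    """An ordered collection of fixed-length labeled univariate signals."""

    signals: np.ndarray                  # (n, T) float
    labels: np.ndarray                   # (n,) int
    class_names: dict = field(default_factory=dict)
    split: str = ""

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.signals) != len(self.labels):
            raise DataError(
                f"{len(self.signals)} signals but {len(self.labels)} labels")

    def __len__(self):
        return len(self.signals)

    @property
    def length(self):
        """Common sample length T."""
        return self.signals.shape[1]

    def subset(self, idx):
        return replace(self, signals=self.signals[idx],
                       labels=self.labels[idx])


_NUM = re.compile(r"[,\t ]+")


def _parse_label(tok):
    try:
        v = float(tok)
    except ValueError as e:
        raise FormatError(f"non-numeric label {tok!r}") from e
    if v != int(v):
        raise FormatError(f"non-integer label {tok!r}")
    return int(v)


def _load_tsv(path, split):
    rows, labels = [], []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            toks = _NUM.split(line)
            if width is None:
                width = len(toks)
            elif len(toks) != width:
                raise FormatError(
                    f"{path}:{lineno}: row has {len(toks)} fields, "
                    f"expected {width}")
            labels.append(_parse_label(toks[0]))
            try:
                rows.append([float(t) for t in toks[1:]])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    if not rows:
        raise FormatError(f"{path}: no data rows")
    names = {l: str(l) for l in sorted(set(labels))}
    return Dataset(signals=np.array(rows), labels=np.array(labels),
                   class_names=names, split=split)


def _load_ts(path, split):
    rows, labels = [], []
    in_data = False
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                if line.lower().startswith("@data"):
                    in_data = True
                continue
            if not in_data:
                raise FormatError(f"{path}:{lineno}: data before @data")
            body, sep, label = line.rpartition(":")
            if not sep:
                raise FormatError(f"{path}:{lineno}: missing ':label'")
            toks = [t for t in body.split(",") if t != ""]
            if width is None:
                width = len(toks)
            elif len(toks) != width:
                raise FormatError(
                    f"{path}:{lineno}: series has {len(toks)} values, "
                    f"expected {width}")
            try:
                rows.append([float(t) for t in toks])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
            labels.append(_parse_label(label))
    if not rows:
        raise FormatError(f"{path}: no data rows")
    names = {l: str(l) for l in sorted(set(labels))}
    return Dataset(signals=np.array(rows), labels=np.array(labels),
                   class_names=names, split=split)


def _load_arff(path, split):
    from scipy.io import arff
    try:
        data, meta = arff.loadarff(path)
    except Exception as e:
        raise FormatError(f"{path}: ARFF parse failure: {e}") from e
    cols = list(meta.names())
    raw_labels = data[cols[-1]]
    labels = [_parse_label(l.decode() if isinstance(l, bytes) else l)
              for l in raw_labels]
    signals = np.stack([np.asarray(data[c], dtype=float)
                        for c in cols[:-1]], axis=1)
    names = {l: str(l) for l in sorted(set(labels))}
    return Dataset(signals=signals, labels=np.array(labels),
                   class_names=names, split=split)


def load_ucr(path, dialect="tsv", split=""):
    """Load a UCR-archive split; sample order follows file order."""
    loaders = {"tsv": _load_tsv, "ts": _load_ts, "arff": _load_arff}
    if dialect not in loaders:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; choose from {sorted(loaders)}")
    return loaders[dialect](str(path), split)


def write_tsv(dataset: Dataset, path):
    """Write label-first tab-separated rows at full float precision."""
    with open(path, "w") as fh:
        for sig, lab in zip(dataset.signals, dataset.labels):
            fh.write("\t".join([str(int(lab))] + [repr(float(v))
                                                  for v in sig]) + "\n")


def binarize_ecg5000(dataset: Dataset) -> Dataset:
    """Merge the four abnormal ECG5000 beat classes into one.

    File label 1 (normal rhythm) maps to 0, labels 2-5 (the abnormal
    morphologies) map to 1.  Already-binary {0, 1} data passes through
    unchanged; any other label set is an error.
    """
    present = set(int(l) for l in dataset.labels)
    if present <= {0, 1}:
        return replace(dataset, class_names={0: "normal", 1: "abnormal"})
    if not present <= set(ECG5000_CLASSES):
        raise DataError(
            f"unexpected labels {sorted(present - set(ECG5000_CLASSES))}; "
            "expected the 5 ECG5000 classes (1-5) or binary {0,1}")
    new = np.where(dataset.labels == 1, 0, 1)
    return replace(dataset, labels=new,
                   class_names={0: "normal", 1: "abnormal"})


def canonicalize_labels(dataset: Dataset) -> Dataset:
    """Remap labels to contiguous integers 0..K-1 (sorted original order)."""
    uniq, new = np.unique(dataset.labels, return_inverse=True)
    names = {i: dataset.class_names.get(int(l), str(l))
             for i, l in enumerate(uniq)}
    return replace(dataset, labels=new, class_names=names)


def trim_to_batch(dataset: Dataset, batch_size: int) -> Dataset:
    """Drop the minimal number of trailing samples so the count divides
    the batch size; order is preserved."""
    if batch_size < 1:
        raise ConfigurationError(f"batch_size must be >= 1, got {batch_size}")
    drop = len(dataset) % batch_size
    if drop == 0:
        return dataset
    return dataset.subset(slice(0, len(dataset) - drop))
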