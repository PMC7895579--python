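"""Interval neutrosophic classification from a pair of rough networks.

Two rough networks with identical architecture are trained on the same
inputs: the *true* network targets one-hot class codewords, the *false*
network their bitwise complements. For a new instance the true network's
scores are per-class true memberships T, the false network's scores are
false memberships F, and the indeterminacy membership is

    I = 1 − |T − F|

so uncertainty is maximal exactly when the two networks disagree least
about a class. Each (T, I, F) triple lies in [0,1]³ with T + I + F ≤ 3,
forming an interval neutrosophic set over the classes.

Hard decisions binarize the memberships per class (bit = 1 iff T > F)
and resolve the codeword: a single set bit names the class; an all-zero
codeword falls back to the class of maximum indeterminacy; multiple set
bits are resolved by the largest margin T − F among them, ties going to
the earliest class in the class order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data_io import (ConfigurationError, LabeledDataset, NormalizationParams,
                      encode_codewords)
from .rough_core import RNNConfig, RNNModel, network_forward, train_rnn

__all__ = [
    "INSRecord",
    "DualModel",
    "fit_dual",
    "indeterminacy",
    "characterize",
    "binarize",
    "resolve",
    "predict",
    "records_to_rows",
]

MODEL_FORMAT = "inrnn-dual-model"
MODEL_VERSION = 1


@dataclass
class INSRecord:
    """Per-class (T, I, F) membership triple for one instance.

    Invariants: every membership lies in [0, 1]; I = 1 − |T − F| by
    construction, so T + I + F ≤ 3 componentwise and in sum.
    """

    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        k = len(self.class_order)
        if not (self.T.shape == self.I.shape == self.F.shape == (k,)):
            raise ConfigurationError("T/I/F must be vectors over the classes")
        for name, v in (("T", self.T), ("I", self.I), ("F", self.F)):
            if np.any((v < 0) | (v > 1)):
                raise ConfigurationError(f"{name} memberships must lie in [0,1]")


@dataclass
class DualModel:
    """True-membership and false-membership networks plus shared context."""

    true_net: RNNModel
    false_net: RNNModel
    class_order: tuple[str, ...]
    normalization: NormalizationParams | None = None

    def __post_init__(self) -> None:
        if self.true_net.n_inputs != self.false_net.n_inputs:
            raise ConfigurationError("dual networks disagree on input width")
        if self.true_net.n_outputs != self.false_net.n_outputs:
            raise ConfigurationError("dual networks disagree on class count")

    def save(self, path) -> None:
        blob = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "class_order": list(self.class_order),
            "true_net": self.true_net.to_dict(),
            "false_net": self.false_net.to_dict(),
            "normalization": self.normalization.dumps()
            if self.normalization is not None else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "DualModel":
        with open(path, encoding="utf-8") as fh:
            blob = json.load(fh)
        if blob.get("format") != MODEL_FORMAT:
            raise ConfigurationError(f"{path} is not an {MODEL_FORMAT} file")
        norm = (NormalizationParams.loads(blob["normalization"])
                if blob.get("normalization") else None)
        return cls(true_net=RNNModel.from_dict(blob["true_net"]),
                   false_net=RNNModel.from_dict(blob["false_net"]),
                   class_order=tuple(blob["class_order"]),
                   normalization=norm)


def fit_dual(train: LabeledDataset, config: RNNConfig,
             normalization: NormalizationParams | None = None) -> DualModel:
    """Train the true/false network pair on one dataset.

    Both networks share architecture and hyperparameters; their weight
    initializations differ through seeds derived from the master seed
    (seed for the true network, seed + 1 for the false one), so a
    DualModel is reproducible from a single integer.

    Features are expected to be normalized already; pass the fitted
    ``normalization`` so the model can renormalize raw inputs later.
    """
    true_targets, false_targets = encode_codewords(train.labels,
                                                   train.class_order)
    true_net = train_rnn(train.features, true_targets,
                         config.with_seed(config.seed))
    false_net = train_rnn(train.features, false_targets,
                          config.with_seed(config.seed + 1))
    return DualModel(true_net=true_net, false_net=false_net,
                     class_order=train.class_order,
                     normalization=normalization)


def indeterminacy(t, f):
    """Indeterminacy membership I = 1 − |T − F|, elementwise.

    High when the true and false networks nearly agree (|T − F| small),
    zero when they are in full opposition.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any((t < 0) | (t > 1)) or np.any((f < 0) | (f > 1)):
        raise ConfigurationError("memberships must lie in [0, 1]")
    return 1.0 - np.abs(t - f)


def characterize(dual: DualModel, features: np.ndarray) -> INSRecord:
    """Compute one instance's INS record from the dual networks."""
    T, _ = network_forward(features, dual.true_net)
    F, _ = network_forward(features, dual.false_net)
    return INSRecord(T=T, I=indeterminacy(T, F), F=F,
                     class_order=dual.class_order)


def binarize(record: INSRecord) -> np.ndarray:
    """Per-class binary codeword: bit_c = 1 iff T_c > F_c (strict)."""
    return (record.T > record.F).astype(int)


def resolve(bits: np.ndarray, record: INSRecord) -> str:
    """Resolve a binary codeword to a single class label.

    Exactly one set bit → that class. All-zero codeword → the class of
    maximum indeterminacy. Multiple set bits → among them, the class with
    the largest margin T − F; ties break to the earliest class in order.
    """
    bits = np.asarray(bits, dtype=int)
    set_bits = np.flatnonzero(bits)
    if set_bits.size == 1:
        return record.class_order[set_bits[0]]
    if set_bits.size == 0:
        return record.class_order[int(np.argmax(record.I))]
    margins = record.T[set_bits] - record.F[set_bits]
    return record.class_order[set_bits[int(np.argmax(margins))]]


def predict(dual: DualModel, features: np.ndarray,
            normalized: bool = True) -> tuple[list[str], list[INSRecord]]:
    """Characterize → binarize → resolve every row of a feature matrix.

    With ``normalized=False`` the model's stored normalization parameters
    are applied first (an error if the model has none).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.size == 0:
        return [], []
    if not normalized:
        if dual.normalization is None:
            raise ConfigurationError(
                "model carries no normalization parameters; pass "
                "pre-normalized features")
        from .data_io import apply_minmax
        features = apply_minmax(features, dual.normalization)
    labels, records = [], []
    for row in features:
        record = characterize(dual, row)
        labels.append(resolve(binarize(record), record))
        records.append(record)
    return labels, records


def records_to_rows(records: list[INSRecord],
                    labels: list[str]) -> "pd.DataFrame":
    """Tabulate predictions: T/I/F per class, codeword bits, resolved class."""
    import pandas as pd
    rows = []
    for record, label in zip(records, labels):
        bits = binarize(record)
        row: dict = {}
        for i, c in enumerate(record.class_order):
            row[f"T_{c}"] = record.T[i]
            row[f"I_{c}"] = record.I[i]
            row[f"F_{c}"] = record.F[i]
        for i, c in enumerate(record.class_order):
            row[f"bit_{c}"] = int(bits[i])
        row["predicted"] = label
        rows.append(row)
    return pd.DataFrame(rows)
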