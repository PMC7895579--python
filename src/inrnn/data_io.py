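"""Loading, normalization, codeword encoding and fold construction.

The canonical input is a CSV export of a cardiotocography-style table:
21 numeric feature columns plus one fetal-state label column (NSP —
normal / suspicious / pathologic). Labels are accepted either as the
integers 1/2/3 or as the strings N/S/P and are normalized internally to
the ordered class list ``("N", "S", "P")``.

Feature normalization is min–max to [0, 1], fitted on a designated row
subset (the training rows of a fold) and applied with clipping elsewhere,
so test rows never leak into the scaling statistics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfigurationError",
    "DataError",
    "LabeledDataset",
    "NormalizationParams",
    "FoldPlan",
    "NSP_CLASSES",
    "load_ctg_csv",
    "fit_minmax",
    "apply_minmax",
    "encode_codewords",
    "complement_codewords",
    "stratified_kfold",
]

#: Canonical fetal-state class order: Normal, Suspicious, Pathologic.
NSP_CLASSES: tuple[str, ...] = ("N", "S", "P")

#: Accepted spellings for each NSP class in a label column.
_LABEL_ALIASES = {
    "N": "N", "S": "S", "P": "P",
    "1": "N", "2": "S", "3": "P",
    "NORMAL": "N", "SUSPICIOUS": "S", "SUSPECT": "S", "PATHOLOGIC": "P",
}


class ConfigurationError(ValueError):
    """A run was configured inconsistently (bad column names, widths, ...)."""


class DataError(ValueError):
    """Input data violates the expected format (bad cell, unknown label, ...)."""


def _canonical_label(raw: object) -> str:
    text = str(raw).strip().upper()
    if text.endswith(".0"):  # pandas may read an integer label column as float
        text = text[:-2]
    try:
        return _LABEL_ALIASES[text]
    except KeyError:
        raise DataError(f"unknown class label {raw!r}; expected one of "
                        f"{sorted(set(_LABEL_ALIASES))}") from None


@dataclass
class LabeledDataset:
    """Feature matrix with per-instance class labels.

    Attributes
    ----------
    features : ndarray of shape (n_instances, n_attributes)
        Real-valued attributes; unitless once normalized to [0, 1].
    labels : ndarray of str, shape (n_instances,)
        Class name per instance, each a member of ``class_order``.
    class_order : tuple of str
        Ordered class names; indexing into codewords follows this order.
    feature_names : tuple of str
        Column names, for round-tripping through CSV.
    """

    features: np.ndarray
    labels: np.ndarray
    class_order: tuple[str, ...] = NSP_CLASSES
    feature_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ConfigurationError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.features):
            raise ConfigurationError("labels and features disagree on length")
        if len(self.features) == 0:
            raise DataError("dataset is empty")
        unknown = set(self.labels) - set(self.class_order)
        if unknown:
            raise DataError(f"labels {sorted(unknown)} not in class order "
                            f"{self.class_order}")
        if not self.feature_names:
            self.feature_names = tuple(
                f"x{j + 1}" for j in range(self.features.shape[1]))

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def label_indices(self) -> np.ndarray:
        """Labels as integer indices into ``class_order``."""
        lookup = {c: i for i, c in enumerate(self.class_order)}
        return np.array([lookup[l] for l in self.labels], dtype=int)

    def subset(self, rows: Sequence[int]) -> "LabeledDataset":
        rows = np.asarray(rows, dtype=int)
        return LabeledDataset(self.features[rows], self.labels[rows],
                              self.class_order, self.feature_names)

    def to_csv(self, path, label_column: str = "NSP") -> None:
        frame = pd.DataFrame(self.features, columns=list(self.feature_names))
        frame[label_column] = self.labels
        frame.to_csv(path, index=False)


@dataclass
class NormalizationParams:
    """Per-attribute min/max observed on the fitting rows.

    Degenerate attributes (min == max) are flagged; they normalize to 0.0.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise ConfigurationError("min/max must be matching 1-D vectors")
        if np.any(self.maximum < self.minimum):
            raise ConfigurationError("per-attribute max must be >= min")

    @property
    def n_attributes(self) -> int:
        return self.minimum.shape[0]

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant attributes."""
        return self.maximum == self.minimum

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("# min-max normalization parameters, one attribute per line\n")
        for lo, hi in zip(self.minimum, self.maximum):
            buf.write(f"{float(lo)!r}\t{float(hi)!r}\n")
        return buf.getvalue()

    @classmethod
    def loads(cls, text: str) -> "NormalizationParams":
        lows, highs = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            lo, hi = line.split("\t")
            lows.append(float(lo))
            highs.append(float(hi))
        return cls(np.array(lows), np.array(highs))

    @classmethod
    def load(cls, path) -> "NormalizationParams":
        with open(path, encoding="utf-8") as fh:
            return cls.loads(fh.read())


@dataclass
class FoldPlan:
    """A k-fold partition of instance indices, stratified by class."""

    k: int
    test_indices: tuple[np.ndarray, ...]
    seed: int

    def train_indices(self, fold: int) -> np.ndarray:
        """All indices not in ``fold``'s test set, in ascending order."""
        n = sum(len(t) for t in self.test_indices)
        mask = np.ones(n, dtype=bool)
        mask[self.test_indices[fold]] = False
        return np.flatnonzero(mask)


def load_ctg_csv(path,
                 feature_columns: Sequence[str] | None = None,
                 label_column: str = "NSP",
                 class_order: tuple[str, ...] = NSP_CLASSES) -> LabeledDataset:
    """Load a labeled dataset from a headered CSV file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row, UTF-8.
    feature_columns : sequence of str, optional
        Names of the numeric attribute columns. Defaults to every column
        except ``label_column``, in file order.
    label_column : str
        Name of the class column (values 1/2/3 or N/S/P).

    Raises
    ------
    ConfigurationError
        If a named column is missing.
    DataError
        If a feature cell does not parse as a number (the offending row
        and column are named) or a label is not a known class.
    """
    frame = pd.read_csv(path, dtype=object)
    if label_column not in frame.columns:
        raise ConfigurationError(f"label column {label_column!r} not in file "
                                 f"(columns: {list(frame.columns)})")
    if feature_columns is None:
        feature_columns = [c for c in frame.columns if c != label_column]
    missing = [c for c in feature_columns if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"feature columns {missing} not in file")

    raw = frame[list(feature_columns)]
    features = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(feature_columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            raise DataError(f"non-numeric value {raw[col].iloc[bad[0]]!r} in "
                            f"column {col!r}, row {int(bad[0])}")
        features[:, j] = parsed.to_numpy(dtype=float)

    labels = np.array([_canonical_label(v) for v in frame[label_column]],
                      dtype=object)
    return LabeledDataset(features, labels, class_order,
                          tuple(feature_columns))


def fit_minmax(features: np.ndarray,
               fitting_rows: Sequence[int] | None = None) -> NormalizationParams:
    """Fit per-attribute min/max on a row subset (default: all rows)."""
    features = np.asarray(features, dtype=float)
    if fitting_rows is not None:
        fitting_rows = np.asarray(fitting_rows, dtype=int)
        if fitting_rows.size == 0:
            raise ConfigurationError("fitting row set is empty")
        features = features[fitting_rows]
    if features.shape[0] == 0:
        raise ConfigurationError("no rows to fit normalization on")
    return NormalizationParams(features.min(axis=0), features.max(axis=0))


def apply_minmax(features: np.ndarray,
                 params: NormalizationParams) -> np.ndarray:
    """Map each value to (x − min)/(max − min), clipped to [0, 1].

    Constant attributes map to 0.0 everywhere.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[None, :]
    if features.shape[1] != params.n_attributes:
        raise ConfigurationError(
            f"feature width {features.shape[1]} does not match normalization "
            f"width {params.n_attributes}")
    span = params.maximum - params.minimum
    safe = np.where(params.degenerate, 1.0, span)
    scaled = (features - params.minimum) / safe
    scaled[:, params.degenerate] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def encode_codewords(labels: Sequence[str],
                     class_order: tuple[str, ...] = NSP_CLASSES
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Encode labels as (one-hot true targets, bitwise-complement false targets).

    The true codeword of class k has a 1 at bit k and 0 elsewhere; the
    false codeword is its bitwise complement (0 at bit k, 1 elsewhere).
    Returns two (n, k) arrays of 0/1 floats.
    """
    lookup = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    true_targets = np.zeros((len(labels), k))
    for row, label in enumerate(labels):
        try:
            true_targets[row, lookup[label]] = 1.0
        except KeyError:
            raise DataError(f"label {label!r} not in class order "
                            f"{class_order}") from None
    return true_targets, 1.0 - true_targets


def complement_codewords(codewords: np.ndarray) -> np.ndarray:
    """Bitwise complement of 0/1 codewords (an involution)."""
    return 1.0 - np.asarray(codewords, dtype=float)


def stratified_kfold(dataset: LabeledDataset, k: int, seed: int) -> FoldPlan:
    """Build a stratified k-fold plan, deterministic for a given seed.

    Per-class counts across folds differ by at most one, so each fold's
    class proportions track the whole dataset's.
    """
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    counts = pd.Series(dataset.labels).value_counts()
    thin = counts[counts < k]
    if len(thin):
        raise DataError(f"classes with fewer than k={k} members: "
                        f"{dict(thin)}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tests = tuple(np.sort(test) for _, test in
                  splitter.split(dataset.features, dataset.label_indices()))
    return FoldPlan(k=k, test_indices=tests, seed=seed)
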