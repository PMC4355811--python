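"""Data containers, delimited-text I/O and train-fitted feature standardization.

Expression data is held as a samples x genes matrix with integer class codes.
User-facing class labels (strings or numbers) are re-coded to consecutive
integers 1..c at load time; binary subproblems are coded -1/+1 internally
because the fusion operators of the GP trees are defined on signed votes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "Standardizer",
    "load_expression_table",
    "save_expression_table",
    "fit_standardizer",
    "apply_standardizer",
]

#: smallest allowed per-feature scale; constant features map to exactly 0
SD_FLOOR = 1e-12


@dataclass
class LabeledDataset:
    """An expression matrix with per-sample class labels.

    Parameters
    ----------
    matrix : ndarray of shape (n_samples, n_features)
        Numeric expression values, no missing entries.
    labels : ndarray of shape (n_samples,)
        Integer class codes ``1..c``.
    sample_ids, feature_ids : list of str
        Row and column identifiers.
    label_mapping : dict
        Original label -> integer code, recorded at load time so that
        predictions can be decoded back to the user's labels.
    """

    matrix: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (samples x features)")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but {self.labels.shape[0]} labels"
            )
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        if len(self.feature_ids) != self.matrix.shape[1]:
            raise ValueError("feature_ids length must match the number of columns")
        if np.isnan(self.matrix).any():
            raise ValueError("matrix contains missing values; imputation is not supported")
        classes, counts = np.unique(self.labels, return_counts=True)
        small = classes[counts < 2]
        if small.size:
            raise ValueError(
                f"class with fewer than 2 samples: {small.tolist()}; "
                "every class needs at least 2 samples for stratified splitting"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".labels.json")


def load_expression_table(
    path: str | Path,
    label_column: str = "label",
    orientation: str = "samples-in-rows",
) -> LabeledDataset:
    """Read a delimited expression table into a :class:`LabeledDataset`.

    Two dialects are accepted. ``samples-in-rows``: one row per sample, the
    first column holds sample identifiers, one column (``label_column``) holds
    the class label and the remaining columns are genes. ``genes-in-rows``:
    the transposed layout common for microarray exports — one row per gene
    with gene identifiers in the first column, a header of sample IDs, and an
    extra row whose identifier equals ``label_column`` carrying the labels.

    Class labels are re-coded to consecutive integers ``1..c`` (sorted order
    of the original labels) and the mapping is retained on the dataset.
    Delimiter (comma or tab) is sniffed automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "genes-in-rows":
        frame = frame.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    if label_column not in frame.columns:
        raise ValueError(
            f"label column {label_column!r} not found; columns start with "
            f"{list(frame.columns[:5])!r}"
        )
    raw_labels = frame[label_column]
    values = frame.drop(columns=[label_column])
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~values.isna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        row = bad[col].idxmax()
        raise ValueError(f"non-numeric cell at sample {row!r}, feature {col!r}")
    if numeric.isna().any().any():
        raise ValueError("table contains missing values; imputation is not supported")
    uniques = sorted(raw_labels.unique(), key=str)
    mapping = {lab: i + 1 for i, lab in enumerate(uniques)}
    labels = raw_labels.map(mapping).to_numpy(dtype=int)
    return LabeledDataset(
        matrix=numeric.to_numpy(dtype=float),
        labels=labels,
        sample_ids=[str(s) for s in frame.index],
        feature_ids=[str(c) for c in numeric.columns],
        label_mapping={str(k): v for k, v in mapping.items()},
    )


def save_expression_table(
    dataset: LabeledDataset,
    path: str | Path,
    label_column: str = "label",
    sep: str = ",",
) -> Path:
    """Write a dataset in the samples-in-rows dialect plus a JSON label sidecar.

    Returns the table path. The sidecar (``<path>.labels.json``) records the
    original-label -> code mapping for prediction-time decoding.
    """
    path = Path(path)
    inverse = {v: k for k, v in dataset.label_mapping.items()}
    shown = [inverse.get(int(code), int(code)) for code in dataset.labels]
    frame = pd.DataFrame(
        dataset.matrix, index=dataset.sample_ids, columns=dataset.feature_ids
    )
    frame.insert(0, label_column, shown)
    frame.to_csv(path, sep=sep, index_label="sample_id")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(dataset.label_mapping, fh, indent=2)
    return path


@dataclass
class Standardizer:
    """Per-feature affine map ``x -> (x - mean) / sd`` fitted on training data.

    Population (``ddof=0``) standard deviations are used; scales below
    ``SD_FLOOR`` are floored so a constant feature maps to exactly 0 with no
    division-by-zero. The same fitted object must be applied to held-out data
    — refitting on test data would leak its statistics.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    def __post_init__(self) -> None:
        self.mean_ = np.asarray(self.mean_, dtype=float)
        self.scale_ = np.asarray(self.scale_, dtype=float)
        if self.mean_.shape != self.scale_.shape:
            raise ValueError("mean_ and scale_ must have identical shapes")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"feature-count mismatch: fitted on {self.mean_.shape[0]}, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_


def fit_standardizer(train: LabeledDataset | np.ndarray) -> Standardizer:
    """Fit per-feature mean and floored population sd on training samples."""
    X = train.matrix if isinstance(train, LabeledDataset) else np.asarray(train, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardizer needs a 2-d matrix with at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    return Standardizer(mean_=mean, scale_=np.maximum(sd, SD_FLOOR))


def apply_standardizer(s: Standardizer, data: LabeledDataset) -> LabeledDataset:
    """Return a copy of ``data`` with the matrix standardized; labels/ids kept."""
    return LabeledDataset(
        matrix=s.transform(data.matrix),
        labels=data.labels.copy(),
        sample_ids=list(data.sample_ids),
        feature_ids=list(data.feature_ids),
        label_mapping=dict(data.label_mapping),
    )
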