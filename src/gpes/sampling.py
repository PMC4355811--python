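"""Balanced undersampling and the stratified three-fold phase split.

Microarray training sets are small and often imbalanced (e.g. 134 vs 15
samples). Every base tree is trained on a balanced subsample: all minority
samples plus an equal-sized draw without replacement from the majority class.
The training partition itself is split into three stratified folds feeding the
five training phases: one fold pair trains and validates the candidate trees
and the GP fitness (train1/val1), a different fold pair scores and selects the
final committee (train2/val2), so no phase selects on data it trained on and
the two validation folds are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["FoldAssignment", "balanced_subsample", "stratified_kfold", "assign_phase_folds"]


@dataclass
class FoldAssignment:
    """Per-sample fold index plus the fold->phase role map.

    ``phase_fold_map`` names the validation fold for each phase block; the
    corresponding training set is the complement. Defaults: fold 2 validates
    phases 1-3 (candidate filtering and GP fitness), fold 1 validates phases
    4-5 (individual selection and forward search), so val1 and val2 are
    disjoint.
    """

    fold: np.ndarray
    n_folds: int = 3
    phase_fold_map: dict = field(default_factory=lambda: {"val1": 2, "val2": 1})

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold, dtype=int)
        if self.fold.min() < 0 or self.fold.max() >= self.n_folds:
            raise ValueError("fold indices out of range")
        if self.phase_fold_map["val1"] == self.phase_fold_map["val2"]:
            raise ValueError("val1 and val2 must be different folds")

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold == fold)


def balanced_subsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample drawn without replacement.

    With class counts N1 and N2 and Ns = min(N1, N2), returns 2*Ns unique
    indices: every sample of the smaller class plus Ns majority samples drawn
    uniformly without replacement. Already-balanced input returns all indices.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"balanced subsampling needs exactly 2 classes, got {classes.size}")
    per_class = [np.flatnonzero(y == c) for c in classes]
    ns = min(idx.size for idx in per_class)
    chosen = [
        idx if idx.size == ns else rng.choice(idx, size=ns, replace=False)
        for idx in per_class
    ]
    return np.sort(np.concatenate(chosen))


def stratified_kfold(
    y: np.ndarray, k: int = 3, rng: np.random.Generator | None = None
) -> FoldAssignment:
    """Randomly split samples into ``k`` class-stratified folds.

    Within every fold the class proportions match the full set up to integer
    rounding; per-class fold sizes differ by at most one.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts < k].tolist()
        raise ValueError(f"classes {small} have fewer than {k} samples; cannot stratify")
    rng = np.random.default_rng() if rng is None else rng
    seed = int(rng.integers(2**31 - 1))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(y.size, dtype=int)
    for i, (_, val_idx) in enumerate(splitter.split(np.zeros((y.size, 1)), y)):
        fold[val_idx] = i
    return FoldAssignment(fold=fold, n_folds=k)


def assign_phase_folds(fa: FoldAssignment) -> dict[str, np.ndarray]:
    """Map folds to the phase train/validation roles.

    Returns ``train1``/``val1`` (candidate-tree training and the validation
    set used for candidate filtering and GP fitness) and ``train2``/``val2``
    (terminal refitting and the validation set for individual filtering and
    forward search). Guarantees val1 and val2 are disjoint and each phase's
    train/validation pair partitions the samples.
    """
    v1, v2 = fa.phase_fold_map["val1"], fa.phase_fold_map["val2"]
    all_idx = np.arange(fa.fold.size)
    val1 = fa.indices(v1)
    val2 = fa.indices(v2)
    return {
        "train1": np.setdiff1d(all_idx, val1),
        "val1": val1,
        "train2": np.setdiff1d(all_idx, val2),
        "val2": val2,
    }
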