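"""Candidate feature pool built from four complementary selectors.

Each selector ranks genes for a binary problem and contributes its top-k
(default 50); the deduplicated union forms the candidate pool from which
random subspaces are later drawn. With four selectors the pool size lies in
[k, 4k] — [50, 200] at the defaults — so even a 20 000-gene matrix is reduced
to a tractable working set while hedging against any single selector's bias:
the F-test is a univariate location test, RELIEF is local and interaction
aware, random-forest importance captures split utility, and SVM-RFE is an
embedded multivariate method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, f_classif
from sklearn.svm import SVC

__all__ = ["FeaturePool", "run_selector", "relief_weights", "build_feature_pool"]

SELECTORS = ("f_test", "relief", "random_forest", "svm_rfe")


@dataclass
class FeaturePool:
    """Deduplicated union of per-selector top-k gene indices.

    ``indices`` preserves first-seen order over the selectors (f_test, relief,
    random_forest, svm_rfe); ``provenance`` maps each index to the selectors
    that chose it.
    """

    indices: np.ndarray
    per_method: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("pool indices must be unique")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_dict(self) -> dict:
        return {
            "indices": self.indices.tolist(),
            "per_method": {m: v.tolist() for m, v in self.per_method.items()},
            "provenance": {int(k): v for k, v in self.provenance.items()},
        }


def _rank_by_score(scores: np.ndarray, k: int) -> np.ndarray:
    """Top-k indices by score descending, ties broken by smaller index."""
    scores = np.where(np.isnan(scores), -np.inf, scores)
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


def relief_weights(X: np.ndarray, y: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Kernel-weighted RELIEF relevance weights for a binary problem.

    For every sample, same-class ("hit") and other-class ("miss") neighbours
    contribute their per-feature absolute differences, weighted by the
    exponential distance kernel ``exp(-d / sigma)`` and normalised within the
    hit and miss groups; a feature scores high when it separates misses but
    not hits. ``sigma`` is the kernel width: small values approach classic
    nearest-hit/nearest-miss Relief, large values average over many
    neighbours.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("relief requires exactly two classes")
    n = X.shape[0]
    dist = cdist(X, X)
    w = np.zeros(X.shape[1])
    for i in range(n):
        same = (y == y[i]) & (np.arange(n) != i)
        diff = y != y[i]
        for mask, sign in ((same, -1.0), (diff, +1.0)):
            if not mask.any():
                continue
            kern = np.exp(-dist[i, mask] / sigma)
            total = kern.sum()
            if total <= 0:  # all neighbours infinitely far on this kernel
                kern = np.ones_like(kern)
                total = kern.size
            contrib = kern @ np.abs(X[mask] - X[i])
            w += sign * contrib / total
    return w / n


def run_selector(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    *,
    relief_sigma: float = 2.0,
    rfe_step: int = 2,
    rf_n_trees: int = 10,
    svm_c: float = 1.0,
    random_state: int | None = None,
) -> np.ndarray:
    """Rank features for a binary problem and return the top ``k`` indices.

    Methods: ``f_test`` (one-way ANOVA F statistic), ``relief``
    (kernel-weighted nearest-neighbour relevance, width ``relief_sigma``),
    ``random_forest`` (impurity importances summed over ``rf_n_trees`` trees),
    ``svm_rfe`` (recursive elimination of ``rfe_step`` features per iteration
    around a linear SVM with ``C=svm_c``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the feature count {X.shape[1]}")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; selection is undefined")

    if method == "f_test":
        scores, _ = f_classif(X, y)
        return _rank_by_score(scores, k)
    if method == "relief":
        return _rank_by_score(relief_weights(X, y, sigma=relief_sigma), k)
    if method == "random_forest":
        forest = RandomForestClassifier(
            n_estimators=rf_n_trees, random_state=random_state
        ).fit(X, y)
        return _rank_by_score(forest.feature_importances_, k)
    if method == "svm_rfe":
        rfe = RFE(
            SVC(kernel="linear", C=svm_c),
            n_features_to_select=k,
            step=rfe_step,
        ).fit(X, y)
        selected = np.flatnonzero(rfe.support_)
        # order survivors by the final linear model's coefficient magnitude
        final = SVC(kernel="linear", C=svm_c).fit(X[:, selected], y)
        weight = np.abs(np.asarray(final.coef_).ravel())
        return selected[_rank_by_score(weight, selected.size)]
    raise ValueError(f"unknown selector {method!r}; choose one of {SELECTORS}")


def build_feature_pool(
    X: np.ndarray,
    y: np.ndarray,
    k_per_method: int = 50,
    *,
    relief_sigma: float = 2.0,
    rfe_step: int = 2,
    rf_n_trees: int = 10,
    svm_c: float = 1.0,
    random_state: int | None = None,
) -> FeaturePool:
    """Union the four selectors' top-k lists into a deduplicated pool.

    First-seen order is preserved, so the pool's order is deterministic given
    the random-forest seed. If the matrix has fewer than ``k_per_method``
    features, every feature enters the pool.
    """
    k = min(k_per_method, X.shape[1])
    per_method: dict[str, np.ndarray] = {}
    provenance: dict[int, list[str]] = {}
    pool: list[int] = []
    for method in SELECTORS:
        top = run_selector(
            method,
            X,
            y,
            k,
            relief_sigma=relief_sigma,
            rfe_step=rfe_step,
            rf_n_trees=rf_n_trees,
            svm_c=svm_c,
            random_state=random_state,
        )
        per_method[method] = top
        for idx in top.tolist():
            if idx not in provenance:
                pool.append(idx)
                provenance[idx] = []
            provenance[idx].append(method)
    return FeaturePool(
        indices=np.array(pool, dtype=int),
        per_method=per_method,
        provenance=provenance,
    )
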