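"""Random-subspace decision-tree candidates and the above-average filter.

300 candidate trees (by default) are each grown on a fresh balanced subsample
of the phase-1 training fold and a fresh random subspace of the candidate
feature pool. Subspace sizes follow a Gaussian with mean 5 and sd 3 (rounded,
clipped to [1, pool size]), so a typical tree sees only ~5 genes — small, fast
and highly diverse. Candidates whose validation accuracy does not exceed the
candidate mean are discarded; the survivors form the GP terminal set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import FeaturePool
from .sampling import balanced_subsample

__all__ = [
    "BaseClassifierRecord",
    "draw_feature_subset",
    "train_candidate_tree",
    "generate_candidates",
    "filter_above_average",
]


@dataclass
class BaseClassifierRecord:
    """One trained base tree with its subspace, subsample and cached votes."""

    tree: DecisionTreeClassifier
    feature_indices: np.ndarray
    sample_indices: np.ndarray
    votes: np.ndarray  # hard -1/+1 votes on the validation fold
    accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard -1/+1 votes on standardized full-width data."""
        return self.tree.predict(X[:, self.feature_indices]).astype(int)


def draw_feature_subset(
    pool: FeaturePool | np.ndarray,
    rng: np.random.Generator,
    nf_mean: float = 5.0,
    nf_sd: float = 3.0,
) -> np.ndarray:
    """Draw one random subspace from the pool.

    The subspace size is a single Gaussian(nf_mean, nf_sd) variate rounded
    half-away-from-zero and clipped to [1, pool size]; that many distinct pool
    indices are then drawn uniformly without replacement. Clipping at 1 biases
    the realised mean slightly above ``nf_mean``.
    """
    indices = pool.indices if isinstance(pool, FeaturePool) else np.asarray(pool, int)
    if indices.size == 0:
        raise ValueError("feature pool is empty")
    raw = rng.normal(nf_mean, nf_sd)
    size = int(np.floor(abs(raw) + 0.5)) * (1 if raw >= 0 else -1)
    size = int(np.clip(size, 1, indices.size))
    return rng.choice(indices, size=size, replace=False)


def train_candidate_tree(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    pool: FeaturePool | np.ndarray,
    rng: np.random.Generator,
    nf_mean: float = 5.0,
    nf_sd: float = 3.0,
    tree_params: dict | None = None,
) -> BaseClassifierRecord:
    """Fit one candidate: fresh subspace, fresh balanced subsample, one tree.

    The tree (library defaults: Gini impurity, no depth cap) is fit on the
    balanced subsample restricted to the subspace; its hard votes and accuracy
    on the validation fold are cached for reuse by the GP fitness evaluation.
    """
    subset = draw_feature_subset(pool, rng, nf_mean=nf_mean, nf_sd=nf_sd)
    sample_idx = balanced_subsample(y_train, rng)
    tree = DecisionTreeClassifier(
        random_state=int(rng.integers(2**31 - 1)), **(tree_params or {})
    )
    tree.fit(X_train[np.ix_(sample_idx, subset)], y_train[sample_idx])
    votes = tree.predict(X_val[:, subset]).astype(int)
    return BaseClassifierRecord(
        tree=tree,
        feature_indices=subset,
        sample_indices=sample_idx,
        votes=votes,
        accuracy=float(np.mean(votes == y_val)),
    )


def generate_candidates(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    pool: FeaturePool | np.ndarray,
    n: int = 300,
    rng: np.random.Generator | None = None,
    nf_mean: float = 5.0,
    nf_sd: float = 3.0,
    tree_params: dict | None = None,
) -> list[BaseClassifierRecord]:
    """Generate ``n`` independently seeded candidate trees."""
    if n < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng() if rng is None else rng
    return [
        train_candidate_tree(
            X_train, y_train, X_val, y_val, pool, rng,
            nf_mean=nf_mean, nf_sd=nf_sd, tree_params=tree_params,
        )
        for _ in range(n)
    ]


def filter_above_average(records: list[BaseClassifierRecord]) -> list[BaseClassifierRecord]:
    """Keep candidates whose accuracy strictly exceeds the candidate mean.

    If every accuracy is identical the strict rule would empty the pool, so
    all records are kept in that degenerate case.
    """
    if not records:
        raise ValueError("no candidate records to filter")
    accs = np.array([r.accuracy for r in records])
    # tolerance so an accuracy exactly at the mean never passes through
    # floating-point rounding of the mean itself
    survivors = [r for r, a in zip(records, accs) if a > accs.mean() + 1e-9]
    return survivors if survivors else list(records)
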