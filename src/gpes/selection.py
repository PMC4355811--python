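"""Final-committee selection by forward search on majority-voting error.

The last GP generation is first filtered to above-average individuals, then a
greedy forward search builds the committee: start from the single best
individual, and at every step add the unordered pair of remaining candidates
whose inclusion gives the lowest committee majority-voting error (MVE) on the
selection-phase validation fold. Pairwise additions keep the committee size
odd so majority votes never tie. A step is taken even when the MVE is merely
unchanged — deliberately trading a little bias for variance reduction on tiny
validation sets — and the search stops only when the best available pair
strictly worsens the MVE or the candidates are exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .gp import GPIndividual

__all__ = [
    "EnsembleCommittee",
    "majority_vote",
    "mve",
    "filter_above_average_individuals",
    "forward_search",
    "predict_committee",
    "operator_frequencies",
]


@dataclass
class EnsembleCommittee:
    """Ordered committee members plus the MVE trace of the forward search."""

    members: list[GPIndividual]
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) % 2 == 0:
            raise ValueError("committee size must be odd")

    def __len__(self) -> int:
        return len(self.members)


def majority_vote(predictions: np.ndarray) -> np.ndarray:
    """Majority of -1/+1 member votes; rows are members, columns samples."""
    predictions = np.atleast_2d(np.asarray(predictions))
    if predictions.shape[0] % 2 == 0:
        raise ValueError("majority voting requires an odd number of members")
    return np.where(predictions.sum(axis=0) < 0, -1, 1)


def mve(predictions: np.ndarray, y: np.ndarray) -> float:
    """Majority-voting error: misclassified fraction of the validation fold."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty validation set")
    return float(np.mean(majority_vote(predictions) != y))


def filter_above_average_individuals(
    population: list[GPIndividual], accuracies: np.ndarray
) -> tuple[list[GPIndividual], np.ndarray]:
    """Keep individuals whose accuracy strictly exceeds the population mean.

    Same rule as the candidate-tree filter: strict comparison, with the whole
    population retained when all accuracies are identical.
    """
    if not population:
        raise ValueError("empty population")
    accuracies = np.asarray(accuracies, dtype=float)
    keep = accuracies > accuracies.mean() + 1e-9  # guard rounding of the mean
    if not keep.any():
        keep = np.ones_like(keep, dtype=bool)
    kept = [ind for ind, k in zip(population, keep) if k]
    return kept, accuracies[keep]


def forward_search(
    candidates: list[GPIndividual],
    candidate_predictions: np.ndarray,
    y_val: np.ndarray,
    accuracies: np.ndarray | None = None,
) -> tuple[EnsembleCommittee, list[int]]:
    """Greedy pairwise forward search minimising committee MVE.

    ``candidate_predictions`` is the (n_candidates, n_val) matrix of cached
    -1/+1 predictions on the selection validation fold. The committee starts
    with the highest-accuracy candidate; every step evaluates the committee
    MVE for all unordered pairs of remaining candidates and adds the best
    pair. Ties on MVE prefer the pair with the higher summed individual
    accuracy, then the lexicographically smallest index pair. Only a strictly
    worse best-pair MVE (or exhaustion) terminates the search.

    Returns the committee and the selected candidate indices in order.
    """
    if not candidates:
        raise ValueError("forward search needs at least one candidate")
    preds = np.atleast_2d(np.asarray(candidate_predictions))
    if accuracies is None:
        accuracies = np.array([np.mean(p == y_val) for p in preds])
    accuracies = np.asarray(accuracies, dtype=float)

    order = sorted(range(len(candidates)), key=lambda i: (-accuracies[i], i))
    selected = [order[0]]
    remaining = set(range(len(candidates))) - set(selected)
    current = mve(preds[selected], y_val)
    trace = [current]

    while len(remaining) >= 2:
        best_pair, best_mve, best_key = None, None, None
        for i, j in combinations(sorted(remaining), 2):
            trial = mve(preds[selected + [i, j]], y_val)
            key = (trial, -(accuracies[i] + accuracies[j]), (i, j))
            if best_key is None or key < best_key:
                best_pair, best_mve, best_key = (i, j), trial, key
        if best_mve > current + 1e-12:  # strictly worse: stop
            break
        selected.extend(best_pair)
        remaining.difference_update(best_pair)
        current = best_mve
        trace.append(current)

    committee = EnsembleCommittee(
        members=[candidates[i] for i in selected], trace=trace
    )
    return committee, selected


def predict_committee(member_predictions: np.ndarray) -> np.ndarray:
    """Majority vote over committee members' -1/+1 prediction rows."""
    return majority_vote(member_predictions)


def operator_frequencies(committee: EnsembleCommittee) -> dict[str, float]:
    """Share of Min/Average/Max nodes over all members' operator nodes."""
    ops: list[str] = []
    for member in committee.members:
        ops.extend(member.root.operators())
    total = len(ops)
    return {name: ops.count(name) / total for name in ("Min", "Average", "Max")}
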