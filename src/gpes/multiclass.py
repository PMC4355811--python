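"""One-vs-one / one-vs-rest decomposition and vote decoding.

The fusion operators are defined on signed binary votes, so a c-class problem
is decomposed into binary subproblems — c(c-1)/2 for one-vs-one (OVO) or c
for one-vs-rest (OVR) — each trained as an independent binary ensemble (own
feature pool, candidate trees, GP run and committee). Hard subproblem outputs
are decoded back to class labels:

* OVO: each subproblem's +1/-1 is a vote for its positive/negative class;
  the class with most votes wins, ties to the smallest class id.
* OVR: the unique +1-voting class wins; with several (or no) +1 votes, the
  committee vote margin (signed sum of member votes) breaks the tie among the
  +1 voters (or among all classes), again falling back to the smallest id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinarySubproblem", "decompose", "decode_ovo", "decode_ovr", "decode"]


@dataclass
class BinarySubproblem:
    """One binary piece of a decomposed multiclass problem.

    ``positive``/``negative`` are class codes; for OVR the negative side is
    the pooled rest, recorded as ``None``. ``sample_indices`` select the
    training samples involved; ``y`` holds their -1/+1 coding.
    """

    scheme: str
    positive: int
    negative: int | None
    sample_indices: np.ndarray
    y: np.ndarray


def decompose(y: np.ndarray, scheme: str) -> list[BinarySubproblem]:
    """Split a c-class label vector into binary subproblems (c >= 3)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 3:
        raise ValueError("decomposition needs at least 3 classes; use the binary path")
    subproblems: list[BinarySubproblem] = []
    if scheme == "ovo":
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                idx = np.flatnonzero((y == a) | (y == b))
                coded = np.where(y[idx] == a, 1, -1)
                subproblems.append(
                    BinarySubproblem("ovo", int(a), int(b), idx, coded)
                )
    elif scheme == "ovr":
        for a in classes:
            idx = np.arange(y.size)
            coded = np.where(y == a, 1, -1)
            subproblems.append(BinarySubproblem("ovr", int(a), None, idx, coded))
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose 'ovo' or 'ovr'")
    return subproblems


def decode_ovo(
    votes: np.ndarray, pairs: list[tuple[int, int]], classes: np.ndarray
) -> np.ndarray:
    """Tally pairwise -1/+1 votes into class labels.

    ``votes`` is (n_samples, n_subproblems) aligned with ``pairs`` of
    (positive, negative) class codes. Ties go to the smallest class id.
    """
    votes = np.atleast_2d(np.asarray(votes))
    classes = np.asarray(classes)
    tally = np.zeros((votes.shape[0], classes.size), dtype=int)
    pos = {c: i for i, c in enumerate(classes.tolist())}
    for j, (a, b) in enumerate(pairs):
        up = votes[:, j] > 0
        tally[up, pos[a]] += 1
        tally[~up, pos[b]] += 1
    # argmax returns the first (smallest-id) maximum, which is the tie rule
    return classes[np.argmax(tally, axis=1)]


def decode_ovr(
    votes: np.ndarray, margins: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Decode one-vs-rest -1/+1 votes, breaking conflicts by vote margin.

    ``votes``/``margins`` are (n_samples, c), one column per class in
    ``classes`` order; ``margins`` is the committee's signed vote sum. A
    unique +1 wins outright; otherwise the largest margin among +1 voters
    (or among all classes when none voted +1) wins, ties to smallest id.
    """
    votes = np.atleast_2d(np.asarray(votes))
    margins = np.atleast_2d(np.asarray(margins, dtype=float))
    classes = np.asarray(classes)
    out = np.empty(votes.shape[0], dtype=classes.dtype)
    for i in range(votes.shape[0]):
        up = np.flatnonzero(votes[i] > 0)
        pool = up if up.size else np.arange(classes.size)
        if up.size == 1:
            out[i] = classes[up[0]]
            continue
        best = pool[np.argmax(margins[i, pool])]  # argmax ties -> smallest id
        out[i] = classes[best]
    return out


def decode(
    votes: np.ndarray,
    scheme: str,
    classes: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    margins: np.ndarray | None = None,
) -> np.ndarray:
    """Dispatch to the OVO or OVR decoder."""
    if scheme == "ovo":
        if pairs is None:
            raise ValueError("OVO decoding needs the (positive, negative) pair list")
        return decode_ovo(votes, pairs, classes)
    if scheme == "ovr":
        if margins is None:
            margins = np.asarray(votes, dtype=float)
        return decode_ovr(votes, margins, classes)
    raise ValueError(f"unknown scheme {scheme!r}")
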