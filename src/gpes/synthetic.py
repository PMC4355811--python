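"""Synthetic expression data with controlled class structure.

Emulates the microarray regime the method targets: thousands of Gaussian
noise genes, tens of samples per class, a small informative subset whose
class means are shifted, and optional severe imbalance (e.g. 134 vs 15).
Real platform artifacts (batch effects, probe saturation, heavy tails,
gene-gene correlation) are deliberately not modelled — the generator's job is
to give every pipeline stage a signal it provably can or cannot recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = ["SyntheticSpec", "make_dataset", "make_vote_matrix"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    ``shift`` is the class-mean displacement of informative genes in units of
    the noise standard deviation; 0 gives a label-free null dataset,
    values >= 4 give an essentially separable one. Defaults mirror the target
    regime: two classes of 30 samples, 2000 genes of which 20 carry signal at
    a moderate shift of 2 noise-sd.
    """

    n_per_class: tuple[int, ...] = (30, 30)
    n_features: int = 2000
    n_informative: int = 20
    shift: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.shift < 0 or self.noise_sd <= 0:
            raise ValueError("shift must be >= 0 and noise_sd > 0")
        if len(self.n_per_class) < 2 or min(self.n_per_class) < 2:
            raise ValueError("need >= 2 classes with >= 2 samples each")


def _class_patterns(c: int, m: int) -> np.ndarray:
    """Distinct +/-1 mean-sign patterns, one row per class.

    Binary problems get the canonical opposite patterns. With more classes
    the informative genes are split into c near-equal blocks and class k is
    +1 on its own block and -1 elsewhere, so every class pair differs on two
    blocks. Patterns depend only on (c, m): datasets drawn with different
    seeds share one class-conditional distribution, so one seed can serve as
    training data and another as a held-out set.
    """
    if c == 2:
        return np.vstack([np.ones(m), -np.ones(m)])
    if m < c:
        raise ValueError(f"need at least {c} informative genes for {c} classes")
    blocks = np.array_split(np.arange(m), c)
    patterns = -np.ones((c, m))
    for k, block in enumerate(blocks):
        patterns[k, block] = 1.0
    return patterns


def make_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labelled expression matrix under ``spec``.

    Every gene is N(0, noise_sd^2) noise; the first ``n_informative`` genes
    additionally receive ``+/- shift/2 * noise_sd`` per class according to a
    distinct sign pattern per class, so the between-class mean separation on
    an informative gene is ``shift`` noise-sd (binary case). Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    c = len(spec.n_per_class)
    n = int(sum(spec.n_per_class))
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    labels = np.repeat(np.arange(1, c + 1), spec.n_per_class)
    patterns = _class_patterns(c, spec.n_informative)
    half = 0.5 * spec.shift * spec.noise_sd
    for k in range(c):
        rows = labels == k + 1
        X[np.ix_(rows, np.arange(spec.n_informative))] += half * patterns[k]
    perm = rng.permutation(n)
    return LabeledDataset(
        matrix=X[perm],
        labels=labels[perm],
        sample_ids=[f"S{i + 1}" for i in range(n)],
        feature_ids=[f"G{j + 1}" for j in range(spec.n_features)],
        label_mapping={str(k + 1): k + 1 for k in range(c)},
    )


def make_vote_matrix(
    n_classifiers: int,
    n_samples: int,
    error_rates: float | np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent -1/+1 classifier votes with known per-classifier error.

    Ground-truth labels are a balanced -1/+1 vector; classifier i's votes are
    the truth with each entry flipped independently with probability
    ``error_rates[i]``. Used to exercise fusion and committee selection
    without training any trees. Returns ``(votes, truth)`` with votes shaped
    (n_classifiers, n_samples).
    """
    rates = np.broadcast_to(np.asarray(error_rates, dtype=float), (n_classifiers,))
    if rates.min() < 0 or rates.max() > 1:
        raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = np.where(np.arange(n_samples) % 2 == 0, 1, -1)
    truth = rng.permutation(truth)
    flips = rng.random((n_classifiers, n_samples)) < rates[:, None]
    votes = np.where(flips, -truth, truth)
    return votes, truth
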