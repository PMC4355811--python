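"""Scikit-learn style classifier running the five-phase ensemble training.

Training proceeds in five phases on a 3-fold stratified split of the training
data. Phase 1 grows random-subspace decision-tree candidates on balanced
subsamples of the first training fold pair (train1); Phase 2 keeps the
candidates with above-average accuracy on val1 as the GP terminal set;
Phase 3 evolves ternary fusion trees with val1 accuracy as fitness; Phase 4
refits the terminal trees on the second fold pair (train2), rescores the
final generation on val2 and keeps the above-average individuals; Phase 5
selects the final committee by pairwise forward search minimising the
majority-voting error on val2. Multiclass problems are decomposed one-vs-one
or one-vs-rest into independent binary runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .base_pool import (
    BaseClassifierRecord,
    filter_above_average,
    generate_candidates,
)
from .data import Standardizer, fit_standardizer
from .feature_selection import FeaturePool, build_feature_pool
from .gp import GPConfig, evolve, predict_individual
from .multiclass import decode_ovo, decode_ovr, decompose
from .sampling import assign_phase_folds, balanced_subsample, stratified_kfold
from .selection import (
    EnsembleCommittee,
    filter_above_average_individuals,
    forward_search,
    operator_frequencies,
)

__all__ = ["GPESClassifier", "BinaryEnsembleModel"]


@dataclass
class BinaryEnsembleModel:
    """Everything needed to apply one trained binary ensemble.

    ``terminals`` are the phase-4 versions of the surviving base trees (the
    ones the committee's fusion trees reference); ``phase_curves`` records
    the mean validation accuracy at the end of each training phase.
    """

    standardizer: Standardizer
    pool: FeaturePool
    terminals: list[BaseClassifierRecord]
    committee: EnsembleCommittee
    phase_curves: dict[str, float]
    gp_history: list[dict] = field(default_factory=list)
    positive: int | None = None
    negative: int | None = None

    def vote_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_terminals) hard votes on raw (unstandardized) data."""
        Xs = self.standardizer.transform(X)
        return np.column_stack([t.predict(Xs) for t in self.terminals])

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        votes = self.vote_matrix(X)
        return np.vstack(
            [predict_individual(m, votes) for m in self.committee.members]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """-1/+1 committee majority vote."""
        preds = self.member_predictions(X)
        return np.where(preds.sum(axis=0) < 0, -1, 1)

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Signed sum of member votes; magnitude is the committee agreement."""
        return self.member_predictions(X).sum(axis=0).astype(float)


class GPESClassifier(ClassifierMixin, BaseEstimator):
    """Genetic-programming ensemble of random-subspace decision trees.

    Parameters
    ----------
    k_per_method : int, default 50
        Genes kept by each of the four feature selectors; the deduplicated
        union forms the candidate pool (size in [k, 4k]).
    n_candidates : int, default 300
        Random-subspace candidate trees grown in Phase 1.
    nf_mean, nf_sd : float, defaults 5 and 3
        Gaussian law of the per-tree subspace size (rounded, clipped to
        [1, pool size]).
    population_size, n_generations, crossover_rate, mutation_rate :
        GP evolution parameters; defaults 80, 200, 0.8 and 0.4.
    tournament_size, n_elite : int
        Selection pressure and elitism of the generational loop.
    n_folds : int, default 3
        Stratified folds of the phase split; every class needs at least
        ``n_folds`` samples (per subproblem for multiclass input).
    fitness_cv : {None, "10fold"}
        None scores GP fitness on the held-out val1 fold; "10fold" averages
        accuracy over a stratified split of train1+val1 instead.
    phase4_mode : {"refit", "rescore"}
        Whether Phase 4 refits the terminal trees on train2 (default) or
        merely rescores the phase-1 trees on val2.
    scheme : {"auto", "ovo", "ovr"}
        Multiclass decomposition; "auto" selects one-vs-one.
    relief_sigma, rfe_step, rf_n_trees, svm_c :
        Feature-selector hyperparameters (RELIEF kernel width 2, RFE step 2,
        10 importance trees, linear-SVM C=1).
    tree_params : dict or None
        Extra keyword arguments for the base ``DecisionTreeClassifier``.
    random_state : int or None
        Seed for every source of randomness; fits are bit-reproducible.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    models_ : list of BinaryEnsembleModel
        One per binary subproblem (a single entry for binary input).
    scheme_ : str
        "binary", "ovo" or "ovr".
    history_ : list of dict
        Phase curves and GP fitness traces per subproblem.
    """

    def __init__(
        self,
        k_per_method: int = 50,
        n_candidates: int = 300,
        nf_mean: float = 5.0,
        nf_sd: float = 3.0,
        population_size: int = 80,
        n_generations: int = 200,
        crossover_rate: float = 0.8,
        mutation_rate: float = 0.4,
        tournament_size: int = 2,
        n_elite: int = 1,
        n_folds: int = 3,
        fitness_cv: str | None = None,
        phase4_mode: str = "refit",
        scheme: str = "auto",
        relief_sigma: float = 2.0,
        rfe_step: int = 2,
        rf_n_trees: int = 10,
        svm_c: float = 1.0,
        tree_params: dict | None = None,
        random_state: int | None = None,
    ):
        self.k_per_method = k_per_method
        self.n_candidates = n_candidates
        self.nf_mean = nf_mean
        self.nf_sd = nf_sd
        self.population_size = population_size
        self.n_generations = n_generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.tournament_size = tournament_size
        self.n_elite = n_elite
        self.n_folds = n_folds
        self.fitness_cv = fitness_cv
        self.phase4_mode = phase4_mode
        self.scheme = scheme
        self.relief_sigma = relief_sigma
        self.rfe_step = rfe_step
        self.rf_n_trees = rf_n_trees
        self.svm_c = svm_c
        self.tree_params = tree_params
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _gp_config(self) -> GPConfig:
        return GPConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            tournament_size=self.tournament_size,
            n_elite=self.n_elite,
        )

    def _fit_binary(
        self, X: np.ndarray, y_pm: np.ndarray, rng: np.random.Generator
    ) -> BinaryEnsembleModel:
        """Run the five phases on one -1/+1 subproblem."""
        standardizer = fit_standardizer(X)
        Xs = standardizer.transform(X)
        folds = stratified_kfold(y_pm, k=self.n_folds, rng=rng)
        roles = assign_phase_folds(folds)
        tr1, v1 = roles["train1"], roles["val1"]
        tr2, v2 = roles["train2"], roles["val2"]

        pool = build_feature_pool(
            Xs[tr1],
            y_pm[tr1],
            k_per_method=self.k_per_method,
            relief_sigma=self.relief_sigma,
            rfe_step=self.rfe_step,
            rf_n_trees=self.rf_n_trees,
            svm_c=self.svm_c,
            random_state=int(rng.integers(2**31 - 1)),
        )

        # Phase 1: random-subspace candidates on balanced subsamples of train1
        candidates = generate_candidates(
            Xs[tr1], y_pm[tr1], Xs[v1], y_pm[v1], pool,
            n=self.n_candidates, rng=rng,
            nf_mean=self.nf_mean, nf_sd=self.nf_sd, tree_params=self.tree_params,
        )
        phase1 = float(np.mean([c.accuracy for c in candidates]))

        # Phase 2: above-average candidates become the GP terminal set
        survivors = filter_above_average(candidates)
        phase2 = float(np.mean([s.accuracy for s in survivors]))

        # Phase 3: evolve fusion trees, fitness = val1 accuracy (cached votes)
        if self.fitness_cv == "10fold":
            eval_idx = np.sort(np.concatenate([tr1, v1]))
            fit_votes = np.column_stack(
                [s.tree.predict(Xs[np.ix_(eval_idx, s.feature_indices)]) for s in survivors]
            ).astype(int)
            fit_y = y_pm[eval_idx]
            n_splits = min(10, int(np.bincount((fit_y > 0).astype(int)).min()))
            splitter = StratifiedKFold(
                n_splits=n_splits, shuffle=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            groups = [te for _, te in splitter.split(fit_votes, fit_y)]
        else:
            fit_votes = np.column_stack([s.votes for s in survivors])
            fit_y = y_pm[v1]
            groups = None
        gp_history: list[dict] = []
        population = evolve(
            self._gp_config(), len(survivors), fit_votes, fit_y, rng,
            fitness_groups=groups, history=gp_history,
        )
        phase3 = float(np.mean([ind.fitness for ind in population]))

        # Phase 4: refit terminals on train2, rescore the population on val2
        terminals = self._phase4_terminals(survivors, Xs, y_pm, tr2, rng)
        val2_votes = np.column_stack(
            [t.tree.predict(Xs[np.ix_(v2, t.feature_indices)]) for t in terminals]
        ).astype(int)
        accs = np.array(
            [np.mean(predict_individual(ind, val2_votes) == y_pm[v2]) for ind in population]
        )
        kept, kept_accs = filter_above_average_individuals(population, accs)
        phase4 = float(np.mean(kept_accs))

        # Phase 5: forward search on val2 majority-voting error
        kept_preds = np.vstack(
            [predict_individual(ind, val2_votes) for ind in kept]
        )
        committee, _ = forward_search(kept, kept_preds, y_pm[v2], accuracies=kept_accs)
        phase5 = 1.0 - committee.trace[-1]

        return BinaryEnsembleModel(
            standardizer=standardizer,
            pool=pool,
            terminals=terminals,
            committee=committee,
            phase_curves={
                "phase1": phase1, "phase2": phase2, "phase3": phase3,
                "phase4": phase4, "phase5": phase5,
            },
            gp_history=gp_history,
        )

    def _phase4_terminals(
        self,
        survivors: list[BaseClassifierRecord],
        Xs: np.ndarray,
        y_pm: np.ndarray,
        tr2: np.ndarray,
        rng: np.random.Generator,
    ) -> list[BaseClassifierRecord]:
        """Refit each surviving tree on train2 (or keep the phase-1 fit)."""
        if self.phase4_mode == "rescore":
            return survivors
        if self.phase4_mode != "refit":
            raise ValueError(f"unknown phase4_mode {self.phase4_mode!r}")
        refit: list[BaseClassifierRecord] = []
        for rec in survivors:
            sub = tr2[balanced_subsample(y_pm[tr2], rng)]
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(2**31 - 1)), **(self.tree_params or {})
            )
            tree.fit(Xs[np.ix_(sub, rec.feature_indices)], y_pm[sub])
            refit.append(
                BaseClassifierRecord(
                    tree=tree,
                    feature_indices=rec.feature_indices,
                    sample_indices=sub,
                    votes=rec.votes,
                    accuracy=rec.accuracy,
                )
            )
        return refit

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "GPESClassifier":
        """Train the ensemble; multiclass input is decomposed per ``scheme``."""
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        codes = np.searchsorted(self.classes_, y) + 1  # 1..c

        self.models_: list[BinaryEnsembleModel] = []
        self.history_: list[dict] = []
        if self.classes_.size == 2:
            self.scheme_ = "binary"
            y_pm = np.where(codes == 2, 1, -1)
            model = self._fit_binary(X, y_pm, rng)
            model.positive, model.negative = 2, 1
            self.models_.append(model)
        else:
            self.scheme_ = "ovo" if self.scheme == "auto" else self.scheme
            for sub in decompose(codes, self.scheme_):
                sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
                model = self._fit_binary(X[sub.sample_indices], sub.y, sub_rng)
                model.positive = sub.positive
                model.negative = sub.negative
                self.models_.append(model)
        for model in self.models_:
            self.history_.append(
                {
                    "positive": model.positive,
                    "negative": model.negative,
                    "phase_curves": model.phase_curves,
                    "committee_size": len(model.committee),
                    "mve_trace": model.committee.trace,
                }
            )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fit with {self.n_features_in_}"
            )
        if self.scheme_ == "binary":
            pm = self.models_[0].predict(X)
            return self.classes_[np.where(pm > 0, 1, 0)]
        code_range = np.arange(1, self.classes_.size + 1)
        votes = np.column_stack([m.predict(X) for m in self.models_])
        if self.scheme_ == "ovo":
            pairs = [(m.positive, m.negative) for m in self.models_]
            codes = decode_ovo(votes, pairs, code_range)
        else:
            margins = np.column_stack([m.margin(X) for m in self.models_])
            codes = decode_ovr(votes, margins, code_range)
        return self.classes_[codes - 1]

    # ------------------------------------------------------------------
    def operator_frequencies(self) -> dict[str, float]:
        """Pooled share of Min/Average/Max nodes over all committee members."""
        check_is_fitted(self, "models_")
        totals = {"Min": 0.0, "Average": 0.0, "Max": 0.0}
        count = 0
        for model in self.models_:
            freq = operator_frequencies(model.committee)
            n_ops = sum(len(m.root.operators()) for m in model.committee.members)
            for k in totals:
                totals[k] += freq[k] * n_ops
            count += n_ops
        return {k: v / count for k, v in totals.items()}
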