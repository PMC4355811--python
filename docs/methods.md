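# Methods

## Problem setting

Expression classification in the microarray / bulk-transcriptomics regime is
an extreme small-n, large-p problem: thousands to tens of thousands of genes,
tens of samples per class, frequent class imbalance, and no affordable
independent validation set. Single models overfit; the bias–variance
trade-off is dominated by variance. This package attacks the variance side
with an ensemble whose diversity is injected at three levels — samples
(balanced undersampling), features (random subspaces over a selector-union
pool) and combiner structure (evolved fusion trees) — and whose every
selection step is validated on folds disjoint from the data that trained the
objects being selected.

## Model

Base classifiers are CART decision trees emitting hard votes, coded −1/+1
for a binary problem. A *fusion tree* is a ternary syntax tree whose leaves
reference base trees and whose internal nodes apply one of three operators to
their three children's votes:

- `Min(v1, v2, v3)` = −1 if any child votes −1 (a veto in favour of the
  negative class);
- `Max(v1, v2, v3)` = +1 if any child votes +1 (the mirror veto);
- `Average(v1, v2, v3)` = sign of v1+v2+v3, i.e. an unweighted majority of
  three — votes are deliberately unweighted because training-set accuracies
  are too noisy at these sample sizes to serve as weights.

Tree depth is capped at 3 with the root counted as depth 1, the root is
always an operator, and every operator has exactly three children, so an
individual fuses 3–9 leaf slots through at most two operator levels. Each
fusion tree is therefore itself a small ensemble classifier; evolving a
population of them searches over *combiner structures*, not over decision
rules, which keeps evaluation cheap (leaf votes are cached) and the search
space small.

## Training phases

The training partition is split once into three stratified folds. With folds
A/B/C the default role map is train1 = A∪B, val1 = C (phases 1–3) and
train2 = A∪C, val2 = B (phases 4–5); val1 ∩ val2 = ∅, the map is a
configuration knob, and any map satisfying the disjointness contract is
valid.

1. **Candidate generation.** 300 trees by default. Each draws a subspace of
   the feature pool of Gaussian(5, 3) size (rounded half-away-from-zero,
   clipped to [1, pool size] — the distribution is specified, the
   discretisation is our choice) and a fresh balanced subsample of train1,
   and is fit with library-default CART settings (Gini, no depth cap).
2. **Candidate filtering.** Keep trees whose val1 accuracy strictly exceeds
   the candidate mean (with an all-equal fallback to keep everything, and a
   1e−9 guard so values exactly at the mean are not admitted through
   floating-point rounding of the mean).
3. **Evolution.** Population 80, 200 generations, crossover 0.8 per selected
   pair, mutation 0.4 per offspring, ramped half-and-half initialisation
   over depths {2, 3}, fitness = val1 accuracy from cached leaf votes.
   The selection scheme is not pinned down by the method description;
   we use size-2 tournament selection with single elitism — a robust default
   for a population of 80 that makes the best fitness non-decreasing.
   Mutation granularity is likewise our reading: with probability 0.4 one
   uniformly chosen node is changed (terminal redirected, or operator
   switched to a different operator). Crossover repairs depth violations by
   re-drawing the crossover points up to 10 times, then falls back to parent
   copies.
4. **Individual filtering.** The final generation is re-scored on val2 after
   the leaf trees are refit on balanced subsamples of train2 ("retraining"
   is read as refitting the terminals; a rescore-only mode is provided), and
   the strict above-average filter is applied again.
5. **Forward search.** The committee starts with the best individual; each
   step adds the unordered *pair* of remaining candidates minimising the
   committee majority-voting error (MVE) on val2. Pair additions keep the
   committee odd, so majority votes never tie. Steps with unchanged MVE are
   accepted — on validation folds this small, refusing MVE-neutral additions
   would freeze committees at sizes 1–3 and forfeit variance reduction — and
   the search stops only on a strictly worse best pair or exhaustion. MVE
   ties between pairs prefer the higher summed individual accuracy, then the
   lexicographically smallest index pair.

## Feature pool

Four selectors each rank genes for the binary problem and contribute their
top 50: one-way ANOVA F-test, RELIEF, random-forest impurity importance
(10 trees), and SVM-RFE (linear kernel, C = 1, removing 2 features per
iteration). The deduplicated union (first-seen order, ties in a ranking
broken by score descending then index ascending) gives a pool of 50–200
genes. F-test, random forest and RFE use scikit-learn; RELIEF is implemented
in-package as a kernel-weighted nearest-hit/nearest-miss scheme
(`exp(−d/σ)` with σ = 2, normalised within hit and miss groups) since no
installed library provides it. The pool is built once per binary subproblem
from the phase-1 training folds.

## Sampling

Balanced subsampling: with class sizes N1, N2 and Ns = min(N1, N2), every
tree's training set is all Ns minority samples plus Ns majority samples
drawn without replacement — with 134 vs 15 this is 15 + 15. Each candidate
tree draws its own subsample ("bagging-style" per-tree resampling rather
than one shared draw). Replacement-free draws are used because with tens of
samples bootstrap duplicates would erase most of the achievable diversity.

## Multiclass

c-class problems are decomposed one-vs-one (c(c−1)/2 subproblems, default)
or one-vs-rest (c subproblems), each trained as a fully independent binary
run (own standardizer, pool, candidates, evolution, committee). Decoding is
our design (any deterministic monotone rule is admissible): OVO tallies
pairwise wins with ties to the smallest class id; OVR takes a unique +1
vote, otherwise the largest committee vote margin among the +1 voters (or
among all classes when none vote +1), ties again to the smallest id. OVR
with many classes inherits the known weakness that balancing against a tiny
class starves the rest-side training set; this is reported, not patched.

## Standardization and metrics

Features are standardized to zero mean, unit variance with statistics fitted
on the training partition only and reapplied to held-out data; population
(ddof = 0) convention, scale floored at 1e−12 so constant features map to 0.

Binary performance is reported as accuracy and the two-point AUC
½(TP/(TP+FN) + TN/(TN+FP)) — balanced accuracy, the right form for hard
votes. Multiclass reports micro-averaged precision/recall/F-score (β = 1)
and the average per-class accuracy AAc. Note an algebraic consequence of
these definitions: for single-label predictions every error is exactly one
false positive plus one false negative, so micro precision = micro recall =
accuracy, and AAc = 1 − 2E/(c·n) — a monotone transform of the error count
E. Zero denominators raise rather than silently returning 0.

## Synthetic data

The generator emulates the target regime: Gaussian noise genes, a small
informative subset whose class means are shifted by ±shift/2·σ (binary:
opposite signs; multiclass: block patterns, class k elevated on its own
block of informative genes). Patterns depend only on the class count and
informative-gene count, never on the seed, so datasets drawn with different
seeds share one class-conditional distribution and can serve as train and
held-out pairs. A companion utility fabricates −1/+1 vote matrices with
known per-classifier error rates for testing fusion and committee selection
without training trees. Not modelled: batch effects, heavy tails, gene–gene
correlation, probe-level artifacts — passing tests demonstrate correct
mechanics and recovery of planted signal, not performance on real
microarrays.

## Default operating points used by tests and the acceptance script

Unit tests run the pipeline at reduced sizes (tens of candidates, population
~12, a few generations) on 200–500-gene fixtures. The end-to-end checks and
`scripts/acceptance.py` use two classes of 30 samples, 1000 genes, 10
informative at shift 5 (a fixture a default CART tree classifies at ≥0.9
held-out accuracy), with 100 candidates, population 30 and 30 generations
over 10 seeded repeats — large enough for stable phase curves and committee
statistics, small enough to run on one CPU in well under a minute per
repeat. On a fully separable fixture the phase-3 population can saturate at
validation accuracy 1.0, in which case the phase-3 → phase-4 improvement
degenerates to equality; the checks require strict increase below that
ceiling.

## Known limitations

- Fitness evaluation reuses cached leaf votes on val1, so the optional
  "10fold" fitness mode (averaging fold-wise accuracy over a stratified
  split of train1 ∪ val1) scores leaves partly on their own training
  samples; it exists to mirror an alternative fitness protocol, and the
  fold-based default avoids the leak.
- The forward search is O(steps · pairs · |val2|); fine for populations ≤ a
  few hundred, not intended for thousands of candidates.
- Committees store full tree objects; model bundles are joblib pickles, not
  a portable text format.
- OVO trains c(c−1)/2 full pipelines; cost grows quadratically in the class
  count.
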