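# gpes — genetic-programming ensemble classification of expression data

`gpes` classifies high-dimensional, small-sample expression matrices
(microarray or bulk RNA profiles: thousands of genes, tens of samples per
class, often imbalanced) with an ensemble whose *combiner* is learned by
genetic programming. It is aimed at analysts who want a variance-hardened
classifier for cohort-scale expression studies, with a scikit-learn
estimator API and a small CLI.

## The method

Base classifiers are CART decision trees voting −1/+1, each trained on a
balanced subsample (all `Ns = min(N1, N2)` minority samples plus `Ns`
majority samples drawn without replacement) and a random subspace of
Gaussian(5, 3) size drawn from a candidate pool — the deduplicated union of
the top-50 genes of four selectors (ANOVA F-test, RELIEF, random-forest
importance, SVM-RFE), giving 50–200 candidate genes.

The combiner is a population of ternary *fusion trees*: leaves reference
base trees, internal nodes apply `Min` (−1 if any child votes −1), `Max`
(+1 if any child votes +1) or `Average` (majority of three) to hard votes.
Depth is capped at 3, so each individual fuses 3–9 leaf slots. Genetic
programming (population 80, 200 generations, crossover 0.8, mutation 0.4,
ramped half-and-half initialisation) evolves them against validation
accuracy. Training runs in five phases on a 3-fold stratified split: grow
300 candidates → keep the above-average ones → evolve → re-score the last
generation on a second fold pair and filter again → greedy forward search
that repeatedly adds the *pair* of individuals minimising the committee's
majority-voting error (MVE), stopping only when the best pair strictly
worsens it. The final committee classifies by unweighted majority vote.
Multiclass problems are decomposed one-vs-one or one-vs-rest into
independent binary runs.

Reported measures: accuracy and the two-point AUC
`½(TP/(TP+FN) + TN/(TN+FP))` for binary problems; micro-averaged
precision/recall/F-score and average per-class accuracy (AAc) for
multiclass. See `docs/methods.md` for the full model description, defaults
and design choices.

## Worked example

```python
import numpy as np
from gpes import GPESClassifier, SyntheticSpec, make_dataset

train = make_dataset(SyntheticSpec(n_per_class=(30, 30), n_features=1000,
                                   n_informative=10, shift=5.0, seed=1))
test = make_dataset(SyntheticSpec(n_per_class=(30, 30), n_features=1000,
                                  n_informative=10, shift=5.0, seed=2))

clf = GPESClassifier(n_candidates=100, population_size=30,
                     n_generations=30, random_state=0)
clf.fit(train.matrix, train.labels)

print("held-out accuracy:", np.mean(clf.predict(test.matrix) == test.labels))
print("phase curves:", clf.history_[0]["phase_curves"])
print("committee size:", clf.history_[0]["committee_size"])
print("operator shares:", clf.operator_frequencies())
```

Output of this exact script:

```
held-out accuracy: 1.0
phase curves: {'phase1': 0.677, 'phase2': 0.9851351351351352, 'phase3': 0.9933333333333334, 'phase4': 1.0, 'phase5': 1.0}
committee size: 29
operator shares: {'Min': 0.3488372093023256, 'Average': 0.4186046511627907, 'Max': 0.23255813953488372}
```

Reading: candidate trees averaged 0.68 validation accuracy (phase 1); the
above-average filter lifted the surviving pool to 0.985 (phase 2), evolution
pushed the population mean to 0.993 (phase 3), the second filter reached the
ceiling (phase 4), and the forward search grew a 29-member committee (it
keeps adding pairs while the MVE does not worsen). The committee classifies
the held-out draw perfectly; all three fusion operators appear in its trees,
with `Average` the most common.

The same pipeline is available from the shell:

```bash
gpes simulate --n-per-class 30,30 --n-features 1000 --shift 5 --out train.csv
gpes train --data train.csv --seed 0 --out run/
gpes predict --model run/model_rep0.joblib --data test.csv --out preds.csv
gpes evaluate --predictions preds.csv --truth test.csv
```

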