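# isescreen

Descriptor-range filter models for ligand-based virtual screening, learned
by **iterative stochastic elimination (ISE)**.

## The problem

Given a set of known bioactive small molecules (for example approved
anticancer drugs) and a much larger background set assumed inactive (for
example a natural-product catalog), ligand-based screening asks: which
molecules in a new library most resemble the actives?  `isescreen` answers
this with an interpretable model: an ensemble of **filters**, each a
conjunction of closed numeric ranges over a handful of 1D/2D
physicochemical descriptors,

```
filter f:  low_1 ≤ d_1 ≤ high_1  AND  …  AND  low_k ≤ d_k ≤ high_k
```

A molecule inside every range of a filter is predicted active by that
filter.  Filters are scored by the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
```

on a labeled training set.  The model's F filters (default 29) are
aggregated per molecule into the **molecular bioactivity index (MBI)** —
the (optionally MCC-weighted) count of filters the molecule passes — which
ranks a screening library from most to least drug-like-active.

## The optimizer

The space of candidate filters (k-descriptor subsets × per-descriptor
intervals over quantile cut-points of the active class) is far too large to
enumerate.  ISE shrinks it iteratively: sample a population of M random
filters, score each by training MCC, mark the top and bottom 5%, and
eliminate every cut-point value that appears as an interval endpoint much
more often (ratio > r) among the worst filters than among the best —
never touching the best filter found so far.  When few enough combinations
remain, they are scored exhaustively and the top-F unique filters by
(MCC, TP%, name order) become the model.  The run is bit-reproducible from
`(data, config, seed)`.

## Worked example

The synthetic generator plants known discriminative ranges so recovery is
checkable against a closed-form optimum:

```python
from isescreen import (ISEClassifier, PlantedSpec, generate_planted,
                       theoretical_best_auc, roc_auc, descriptor_redundancy)

table, labels, truth = generate_planted(PlantedSpec(seed=0))
clf = ISEClassifier(random_state=0).fit(table, labels)

held, held_labels, _ = generate_planted(PlantedSpec(seed=1000))
auc, _ = roc_auc(clf.decision_function(held), held_labels)
print(f"held-out AUC          {auc:.3f}")
print(f"Bayes-score AUC bound {theoretical_best_auc(PlantedSpec()):.3f}")
best = clf.filters_[0]
print(f"best filter (train MCC {best.stats.mcc:.3f}): {best.render()}")
report = descriptor_redundancy(clf.model_, pool_size=10)
print(report.to_frame().head(4).to_string(index=False))
```

prints

```
held-out AUC          0.853
Bayes-score AUC bound 0.881
best filter (train MCC 0.580): inf_0 (0.305847–0.692569); inf_1 (0.306207–0.697269); noise_1 (0.019226–0.979127); noise_2 (0.00441477–0.930653)
descriptor  count  fold_over_random
     inf_0     29               2.5
     inf_1     29               2.5
   noise_1     25               2.2
   noise_2     23               2.0
```

The generator planted the ranges [0.3, 0.7] on `inf_0` and `inf_1` (with
10% of actives off-range); the learned best filter brackets them to within
~0.007, the held-out ranking reaches 97% of the best AUC any score could
attain under the generative model, and the redundancy report shows both
informative descriptors in all 29 filters while noise descriptors appear
only as throwaway wide ranges.

## Command line

```bash
ise-screen train    --actives a.smi --inactives b.smi --seed 1 --out model.json
ise-screen screen   --model model.json --library lib.smi --out scores.tsv
ise-screen evaluate --model model.json --actives a.smi --inactives b.smi \
                    --mix 100 --out report/
ise-screen descriptors --list
ise-screen synth    --seed 1 --out-table t.tsv --out-labels l.tsv --out-truth truth.yaml
ise-screen redundancy --model model.json --pool-size 186 --out red.tsv
```

Every command writes a JSON manifest (parameters, seed, descriptor-registry
version, input checksums) so any output can be reproduced.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, through the package at run time, the published-table quantity
this environment can reproduce: the fold-over-random redundancy of a
descriptor occurring in 15 of a model's 29 four-descriptor filters with a
training pool of 186 descriptors.

## Layout

```
src/isescreen/
  chemio.py       SMILES/SDF parsing, stratified splits, model & score I/O
  descriptors.py  open descriptor registry, Lipinski/Oprea rules, diversity
  rangefilter.py  filters, confusion counts, MCC
  ise_engine.py   the ISE optimizer
  indexer.py      MBI scoring, threshold sweep, ROC/AUC, enrichment, redundancy
  synthetic.py    planted-signal generator + closed-form Bayes AUC
  estimator.py    scikit-learn ISEClassifier facade
  cli.py          the ise-screen command
docs/methods.md   model, assumptions, numerical choices, limitations
```
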