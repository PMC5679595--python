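# Methods

## Model

A **range filter** is a conjunction of closed intervals over k distinct
molecular descriptors (default k = 4).  A molecule passes the filter iff
every descriptor value lies inside its interval; a missing or
not-computable value (NaN) fails the filter — the conservative choice for
screening, logged once per descriptor.  Closed bounds make zero-width
intervals meaningful (a degenerate candidate set {c} still forms [c, c]).

A **model** is an ordered list of F unique filters (default F = 29),
"unique" meaning distinct (descriptor set, interval bounds) tuples.  The
**molecular bioactivity index** of a molecule is

    MBI = Σ_i  pass_i · w_i,

with unit weights by default or w_i = max(MCC_i, 0) under `weighting="mcc"`.
The MBI formula is this package's documented interpretation of a
filter-ensemble index: a weighted pass count, consistent with index
thresholds of ~4 on a 29-filter model being meaningful.  It is a design
choice, not an established constant of the literature.

Filters are scored by the Matthews correlation coefficient.  Degenerate
confusion matrices (any zero marginal) score 0 by convention, which keeps
the optimizer total; MCC is antisymmetric under prediction negation, and
these two facts are property-tested.

## The ISE optimizer

Search space: all k-subsets of the descriptor pool × all intervals
formable from per-descriptor candidate cut-points.  Candidates are the
active-class minimum and maximum plus `n_cutpoints` evenly spaced interior
quantiles of the **active** distribution (filters must bracket the
actives; the inactive distribution only enters through scoring).  An
interval is a pair of distinct alive values low < high; a descriptor
reduced to one value forms only [c, c].

Loop (all knobs in `ISEConfig`):

1. Sample M = 10,000 filters uniformly (descriptor subset, then interval
   per descriptor); score each by training MCC.
2. Mark the top b·M as BEST and bottom w·M as WORST (b = w = 0.05).
3. For each alive cut-point value, let c_w and c_b be the number of WORST
   and BEST filters using it as an interval endpoint.  Eliminate values
   with c_w / max(c_b, 1) > r (r = 2.0), except values used by the best
   filter found so far (elitism), and never below two alive values per
   descriptor.
4. Repeat until the remaining combination count (computed exactly via an
   elementary-symmetric-polynomial recurrence) falls to the exhaustive
   threshold E = 200,000, nothing is eliminated, or 50 iterations.
5. Score every remaining combination exactly and return the top-F unique
   filters ordered by (MCC desc, TP% desc, lexicographic descriptor/bounds).

Numerical choices:

* **Exhaustive completion factor.**  The loop can stop (stall or iteration
  cap) slightly above E.  Exact enumeration is still cheap within a bounded
  factor, so the exhaustive phase runs whenever the remaining count is
  ≤ 10·E; only a genuine runaway (> 10·E) falls back to returning the
  best sampled filters, with a warning and `trace.fallback = True`.
* **Grid resolution.**  `n_cutpoints = 49` places cut-points at 2% active
  quantile steps.  Measurement on planted data showed resolution — not
  search — is the binding constraint on recovering range boundaries: at 5%
  steps even brute-force enumeration of the grid cannot place an endpoint
  closer than ~2% of active mass to a distribution edge, which measurably
  truncates recovered ranges.
* **Elitism scope.**  Protecting the endpoints of the single best filter is
  the implemented rule.  Protecting the top-F filters was tried and
  rejected: it freezes roughly half the values and stalls elimination.
* **Tie-breaks.**  Population ordering is (MCC desc, sample index); final
  ranking is (MCC desc, TP% desc, canonical key), a total order, so
  (data, config, seed) determines the output bit-exactly.  Scoring uses
  packed-bitset AND/popcount per class, which is exact integer arithmetic.

Filters carry training-set statistics; held-out statistics are attached
afterward by the training pipeline (`ise-screen train` writes them next to
the model).  Scoring during optimization sees only the training split.

## Descriptors

The registry provides open, documented analogues of a commercial engine's
descriptor vocabulary (see `descriptors.py` for per-name definitions:
Crippen-logP-weighted Burden/graph-distance eigenvalues for BCUT/GCUT,
Gasteiger-charge-binned Labute surface areas for the partial-charge
surface descriptors, an ESOL solubility estimate, element-composition
entropy, etc.).  **No numerical agreement with any proprietary engine is
claimed or tested**; the pipeline is descriptor-engine-agnostic and each
definition is deterministic per canonical SMILES and registry version
(`open-1.0`, stamped on every table and model).  `Nmol` has no open
analogue and is registered as permanently not-computable; filters that
reference it simply never pass, and models loaded with descriptors unknown
to the registry flag those filters unusable rather than failing.

Drug-likeness: "obeys the rule of five" is interpreted strictly as zero
violations of {MW > 500, logP > 5, donors > 5, acceptors > 10} (violation
thresholds strict, so a value exactly at a limit does not violate);
`lip_druglike` uses the common ≤ 1-violation reading.  The lead-likeness
rule set is fixed to six closed-bound conditions {MW ≤ 450, −3.5 ≤ logP
≤ 4.5, donors ≤ 5, acceptors ≤ 8, rotatable bonds ≤ 10, rings ≤ 4}; the
literature has several variants, so the choice is declared and
configurable via `DruglikenessRuleSet` rather than hidden.

Diversity uses 2048-bit radius-2 Morgan fingerprints by default and exact
set-arithmetic Tanimoto similarity (|A∩B|/|A∪B|), cross-checked in tests
against RDKit's own implementation.  Because "N molecules with similarity
below a cutoff" is ambiguous between per-molecule nearest-neighbour counts
and pair counts, the report exposes both (`n_molecules_below`,
`n_pairs_below`) and claims no single number.

## Evaluation

* **Threshold sweep**: TP%, FP% and MCC of `score ≥ t` for t = 0, every
  distinct score, and one point above the maximum; TP% and FP% are
  non-increasing in t by construction.
* **ROC/AUC**: AUC is the Mann–Whitney pair statistic
  P(s_act > s_inact) + ½·P(tie), computed from midranks; the emitted ROC
  polyline integrates to the same value by the trapezoid rule (asserted to
  1e−12 in tests, and cross-checked against scikit-learn).
* **Enrichment**: a pool with one active per `mix_ratio` inactives is
  built by seeded downsampling of the over-represented class; ranking ties
  are broken pessimistically (an inactive outranks an active at equal
  score), so reported capture percentages are conservative.
* **Redundancy**: per-descriptor occurrence counts over the model's
  filters; fold-over-random = count / (F·k/D) for a training pool of D
  descriptors, rounded half away from zero to one decimal (this rounding,
  not banker's, reproduces published tables).  D is not derivable from a
  model file and must be supplied; 186 is the reference value consistent
  with the published fold entries under F·k = 116.

## Synthetic stated world

`PlantedSpec` defaults describe the screening setting the package targets:
500 actives vs 2,500 inactives; 2 informative descriptors among 8 noise;
planted ranges [0.3, 0.7] on a unit uniform background (per-descriptor
inactive overlap 0.4 — published filters likewise combine individually
wide per-descriptor ranges into a jointly specific conjunction); actives
respect each planted range with probability 0.9.  With a uniform
background the Bayes-optimal score is the planted-range pass count, whose
AUC has a closed form (`theoretical_best_auc`, exact Poisson-binomial
win-plus-half-tie), giving the recovery tests an analytic yardstick.

What the generator does **not** emulate: descriptor correlation,
heavy-tailed property distributions, activity cliffs, or structured label
noise.  A green recovery test therefore establishes that the optimizer
finds planted axis-aligned signal at realistic class imbalance — not that
it reproduces any particular chemistry.

Recovery acceptance is inherently tight in this world: an ensemble of
top-MCC filters concentrates on the full planted box, so its MBI is nearly
binary, and the AUC of the best binary classifier here is ~97% of the
Bayes AUC.  The 95%-of-Bayes bar thus requires near-exact edge recovery;
with the defaults above it is met on 8 of 10 seeds (the stated threshold),
with the misses caused by elimination stalling on a still-large space and
falling back to sampled filters.

## Known limitations

* The 617-drug anticancer reference set is not redistributable and is not
  bundled, so the two dataset-profile checks fail until a user supplies
  `data/s1_anticancer_drugs.smi`.
* Descriptor values are open analogues: models trained with another
  engine's descriptors are not interchangeable with this registry, and
  published per-filter statistics cannot be reproduced numerically.
* One k per model; no disjunctive or weighted-range filters; no 3D
  descriptors or conformers; standardization beyond SMILES parsing is a
  pass-through hook.
* Duplicate structures across the active/inactive sets are warned about,
  never removed.
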