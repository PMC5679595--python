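"""Iterative stochastic elimination (ISE) over descriptor-range space.

The optimizer searches for conjunctive range filters (k descriptor
intervals, default 4) that separate active from inactive molecules, scored
by training-set MCC.  The search space is the set of all k-subsets of
descriptors crossed with all intervals formable from per-descriptor
candidate cut-points (active-class quantiles).  Each iteration:

1. sample a population of M random filters and score them;
2. mark the top b*M as BEST and bottom w*M as WORST;
3. for every alive cut-point value, compare how often it appears as an
   interval endpoint in WORST versus BEST filters, and eliminate values
   whose worst/best frequency ratio exceeds the threshold r — except values
   used by the best filter found so far (elitism);
4. repeat until the remaining combination count drops below the exhaustive
   threshold E, then score every remaining combination exactly.

The returned model is the top-F filters by (MCC, TP%, lexicographic
descriptor order), deduplicated on (descriptor set, bounds).  Every step is
driven by a single seed; (data, config, seed) determines the output
bit-exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .rangefilter import (
    DescriptorInterval,
    FilterStats,
    RangeFilter,
    coerce_labels,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ISEConfig",
    "ISETrace",
    "DiscretizedSpace",
    "discretize",
    "sample_filter",
    "ise_optimize",
]

_POP8 = np.array([bin(i).count("1") for i in range(256)], dtype=np.int64)


@dataclass(frozen=True)
class ISEConfig:
    """Knobs of the ISE optimizer.

    Parameters
    ----------
    k : intervals per filter.
    population : filters sampled and scored per iteration (M).
    best_fraction, worst_fraction : population quantiles labeled BEST/WORST.
    elimination_ratio : worst/best endpoint-frequency ratio above which a
        cut-point value is eliminated (r).
    exhaustive_threshold : remaining-combination count at which the search
        switches to exact enumeration (E).
    max_iterations : hard cap on elimination rounds.
    n_filters : filters kept in the final model (F).
    n_cutpoints : interior active-class quantiles per descriptor (the
        candidate values additionally include the active min and max);
        the default 49 places cut-points at 2% quantile steps, so an
        interval endpoint can track a boundary of the active
        distribution to within about 1% of the active probability mass.
    seed : master seed; all randomness flows from it.
    """

    k: int = 4
    population: int = 10_000
    best_fraction: float = 0.05
    worst_fraction: float = 0.05
    elimination_ratio: float = 2.0
    exhaustive_threshold: int = 200_000
    max_iterations: int = 50
    n_filters: int = 29
    n_cutpoints: int = 49
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not (0 < self.best_fraction < 0.5 and 0 < self.worst_fraction < 0.5):
            raise ValueError("best/worst fractions must be in (0, 0.5)")


@dataclass
class ISETrace:
    """Per-iteration observability of the elimination loop."""

    iterations: list[dict] = field(default_factory=list)
    exhaustive_count: int = 0
    fallback: bool = False

    def record(self, **row) -> None:
        self.iterations.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.iterations)


@dataclass
class DiscretizedSpace:
    """Per-descriptor candidate cut-points with alive flags.

    An interval is formable from two distinct alive values ``low < high``;
    a descriptor left with a single alive value only forms the degenerate
    zero-width interval ``[c, c]``.
    """

    names: tuple[str, ...]
    values: dict[str, np.ndarray]
    alive: dict[str, np.ndarray]

    def __post_init__(self):
        self._iv_cache: dict[str, list[tuple[int, int]]] = {}

    def alive_values(self, name: str) -> np.ndarray:
        return self.values[name][self.alive[name]]

    def eliminate(self, name: str, value_index: int) -> None:
        self.alive[name][value_index] = False
        self._iv_cache.pop(name, None)

    def n_intervals(self, name: str) -> int:
        v = int(self.alive[name].sum())
        if v == 0:
            return 0
        return v * (v - 1) // 2 if v >= 2 else 1

    def eligible_names(self) -> list[str]:
        return [n for n in self.names if self.n_intervals(n) > 0]

    def combination_count(self, k: int) -> int:
        """Exact count of formable k-descriptor filters (symmetric-poly DP)."""
        counts = [self.n_intervals(n) for n in self.eligible_names()]
        coeffs = [1] + [0] * k
        for c in counts:
            for j in range(min(k, len(coeffs) - 1), 0, -1):
                coeffs[j] += coeffs[j - 1] * c
        return coeffs[k]

    def intervals_for(self, name: str) -> list[tuple[int, int]]:
        """Formable intervals as index pairs into the full value array."""
        cached = self._iv_cache.get(name)
        if cached is not None:
            return cached
        idx = np.flatnonzero(self.alive[name])
        if len(idx) == 1:
            out = [(int(idx[0]), int(idx[0]))]
        else:
            out = [
                (int(idx[a]), int(idx[b]))
                for a in range(len(idx))
                for b in range(a + 1, len(idx))
            ]
        self._iv_cache[name] = out
        return out


def discretize(
    table: pd.DataFrame, labels: Sequence, n_cutpoints: int = 7
) -> DiscretizedSpace:
    """Build candidate cut-points from active-class quantiles.

    Per descriptor the candidates are the active-class minimum and maximum
    plus ``n_cutpoints`` evenly spaced interior quantiles, duplicates
    collapsed.  A constant column degenerates to a single candidate and is
    warned about.
    """
    if n_cutpoints < 0:
        raise ValueError("n_cutpoints must be >= 0")
    y = coerce_labels(labels)
    if not y.any():
        raise ValueError("no active-class rows to discretize on")
    values: dict[str, np.ndarray] = {}
    alive: dict[str, np.ndarray] = {}
    qs = np.linspace(0.0, 1.0, n_cutpoints + 2)
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)[y]
        col = col[np.isfinite(col)]
        if len(col) == 0:
            logger.warning("descriptor %r has no finite active values; dropped", name)
            continue
        cand = np.unique(np.quantile(col, qs, method="nearest"))
        if len(cand) == 1:
            logger.warning("descriptor %r is constant on actives (%g)", name, cand[0])
        values[name] = cand
        alive[name] = np.ones(len(cand), dtype=bool)
    return DiscretizedSpace(names=tuple(values), values=values, alive=alive)


def _sample_indices(
    space: DiscretizedSpace, k: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Sample one filter as (descriptor, low index, high index) triples."""
    eligible = space.eligible_names()
    if len(eligible) < k:
        raise ValueError(
            f"only {len(eligible)} descriptors can form intervals; k={k}"
        )
    picked = rng.choice(len(eligible), size=k, replace=False)
    out = []
    for di in sorted(picked.tolist()):
        name = eligible[di]
        ivs = space.intervals_for(name)
        lo, hi = ivs[int(rng.integers(len(ivs)))]
        out.append((name, lo, hi))
    return out


def sample_filter(
    space: DiscretizedSpace, k: int, rng: np.random.Generator
) -> RangeFilter:
    """Draw one random filter: k distinct descriptors, uniform intervals."""
    triples = _sample_indices(space, k, rng)
    return RangeFilter(
        intervals=tuple(
            DescriptorInterval(name, float(space.values[name][lo]),
                               float(space.values[name][hi]))
            for name, lo, hi in triples
        )
    )


# --------------------------------------------------------------------------
# packed-bitset scoring

class _Scorer:
    """Pre-packed per-interval pass bitsets for fast MCC evaluation.

    For each descriptor and each candidate interval the rows passing the
    interval are packed into uint8 bitsets, separately for the active and
    inactive classes; a filter's confusion counts are then popcounts of
    bitwise ANDs.
    """

    def __init__(self, table: pd.DataFrame, labels: Sequence, space: DiscretizedSpace):
        y = coerce_labels(labels)
        self.n_act = int(y.sum())
        self.n_inact = int((~y).sum())
        if self.n_act == 0 or self.n_inact == 0:
            raise ValueError("both classes are required for scoring")
        self._bits_a: dict[tuple[str, int, int], np.ndarray] = {}
        self._bits_i: dict[tuple[str, int, int], np.ndarray] = {}
        self._cols_a = {}
        self._cols_i = {}
        for name in space.names:
            col = table[name].to_numpy(dtype=float)
            self._cols_a[name] = col[y]
            self._cols_i[name] = col[~y]
        self._values = space.values

    def _bitset(self, cache, cols, key):
        if key not in cache:
            name, lo, hi = key
            vals = self._values[name]
            col = cols[name]
            with np.errstate(invalid="ignore"):
                mask = (col >= vals[lo]) & (col <= vals[hi])
            cache[key] = np.packbits(mask)
        return cache[key]

    def counts(self, triples: Sequence[tuple[str, int, int]]) -> tuple[int, int]:
        """(tp, fp) of the conjunction of the given intervals."""
        acc_a = self._bitset(self._bits_a, self._cols_a, triples[0])
        acc_i = self._bitset(self._bits_i, self._cols_i, triples[0])
        for t in triples[1:]:
            acc_a = acc_a & self._bitset(self._bits_a, self._cols_a, t)
            acc_i = acc_i & self._bitset(self._bits_i, self._cols_i, t)
        return int(_POP8[acc_a].sum()), int(_POP8[acc_i].sum())

    def interval_stack(self, name: str, pairs: list[tuple[int, int]]):
        a = np.stack([self._bitset(self._bits_a, self._cols_a, (name, lo, hi))
                      for lo, hi in pairs])
        i = np.stack([self._bitset(self._bits_i, self._cols_i, (name, lo, hi))
                      for lo, hi in pairs])
        return a, i

    def mcc_from(self, tp, fp):
        return _mcc_arrays(np.asarray(tp), np.asarray(fp), self.n_act, self.n_inact)


def _mcc_arrays(tp, fp, n_act, n_inact):
    tp = tp.astype(float)
    fp = fp.astype(float)
    fn = n_act - tp
    tn = n_inact - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
    return out


def _filter_sort_key(entry):
    """Total deterministic order: MCC desc, TP% desc, then canonical key."""
    mcc_v, tp_pct, key = entry[0], entry[1], entry[2]
    return (-mcc_v, -tp_pct, key)


def _to_range_filter(space, triples, stats) -> RangeFilter:
    return RangeFilter(
        intervals=tuple(
            DescriptorInterval(name, float(space.values[name][lo]),
                               float(space.values[name][hi]))
            for name, lo, hi in triples
        ),
        stats=stats,
    )


def ise_optimize(
    table: pd.DataFrame,
    labels: Sequence,
    config: ISEConfig = ISEConfig(),
) -> tuple[list[RangeFilter], ISETrace]:
    """Run the full ISE loop and return the top-F filters plus a trace.

    Filters carry their training-set :class:`FilterStats`.  Raises when the
    discretized space cannot form a single k-descriptor filter.  If the
    space can no longer shrink while still exceeding the exhaustive
    threshold, the best sampled filters are returned instead (with a
    warning and ``trace.fallback = True``).
    """
    y = coerce_labels(labels)
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    space = discretize(table, y, config.n_cutpoints)
    if len(space.eligible_names()) < config.k:
        raise ValueError(
            "degenerate space: fewer formable descriptors than k"
        )
    rng = np.random.default_rng(config.seed)
    scorer = _Scorer(table, y, space)
    trace = ISETrace()

    best_entry = None        # (mcc, tp_pct, key, triples, stats)
    sampled_pool: dict[tuple, tuple] = {}
    m = config.population
    n_best = max(1, int(math.ceil(config.best_fraction * m)))
    n_worst = max(1, int(math.ceil(config.worst_fraction * m)))
    n_keep = max(n_best, 4 * config.n_filters)

    def entry_from(triples):
        tp, fp = scorer.counts(triples)
        stats = FilterStats(tp=tp, fp=fp, fn=scorer.n_act - tp,
                            tn=scorer.n_inact - fp)
        key = tuple(sorted(
            (name, float(space.values[name][lo]), float(space.values[name][hi]))
            for name, lo, hi in triples
        ))
        return (stats.mcc, stats.tp_pct, key, tuple(triples), stats)

    for iteration in range(config.max_iterations):
        remaining = space.combination_count(config.k)
        if remaining <= config.exhaustive_threshold:
            break
        eligible = space.eligible_names()
        if len(eligible) < config.k:
            raise ValueError("space degenerated below k formable descriptors")
        ivs = {name: space.intervals_for(name) for name in eligible}
        n_iv = np.array([len(ivs[name]) for name in eligible])

        # vectorized population draw: k-subsets of descriptors, then a
        # uniform formable interval per chosen descriptor
        subs = rng.permuted(
            np.tile(np.arange(len(eligible)), (m, 1)), axis=1
        )[:, : config.k]
        subs.sort(axis=1)
        iv_idx = (rng.random((m, config.k)) * n_iv[subs]).astype(np.int64)

        tp = np.empty(m, dtype=np.int64)
        fp = np.empty(m, dtype=np.int64)
        triples_of = []
        for i in range(m):
            triples = tuple(
                (eligible[int(d)], *ivs[eligible[int(d)]][int(j)])
                for d, j in zip(subs[i], iv_idx[i])
            )
            triples_of.append(triples)
            tp[i], fp[i] = scorer.counts(triples)
        mccs = _mcc_arrays(tp, fp, scorer.n_act, scorer.n_inact)
        order = np.lexsort((np.arange(m), -mccs))
        best_idx = order[:n_best]
        worst_idx = order[-n_worst:]
        for i in order[:n_keep].tolist():
            e = entry_from(triples_of[i])
            sampled_pool.setdefault(e[2], e)
        iter_best = entry_from(triples_of[int(order[0])])
        if best_entry is None or iter_best[0] > best_entry[0]:
            best_entry = iter_best

        # endpoint frequencies in WORST vs BEST populations
        cw: dict[tuple[str, int], int] = {}
        cb: dict[tuple[str, int], int] = {}
        for idx_set, counter in ((worst_idx, cw), (best_idx, cb)):
            for i in idx_set.tolist():
                for name, lo, hi in triples_of[i]:
                    counter[(name, lo)] = counter.get((name, lo), 0) + 1
                    if hi != lo:
                        counter[(name, hi)] = counter.get((name, hi), 0) + 1

        # elitism: never eliminate a cut-point used by the best filter so far
        protected = {
            (name, idx)
            for name, lo, hi in best_entry[3]
            for idx in (lo, hi)
        }
        n_eliminated = 0
        for name in space.names:
            alive_idx = np.flatnonzero(space.alive[name])
            if len(alive_idx) <= 2:
                continue
            scored = []
            for vi in alive_idx:
                keyv = (name, int(vi))
                ratio = cw.get(keyv, 0) / max(cb.get(keyv, 0), 1)
                if ratio > config.elimination_ratio and keyv not in protected:
                    scored.append((ratio, int(vi)))
            # never shrink a descriptor below two alive values
            scored.sort(reverse=True)
            allowed = len(alive_idx) - 2
            for ratio, vi in scored[:allowed]:
                space.eliminate(name, vi)
                n_eliminated += 1

        trace.record(
            iteration=iteration,
            best_mcc=float(best_entry[0]),
            population_best_mcc=float(mccs.max()),
            population_median_mcc=float(np.median(mccs)),
            n_eliminated=n_eliminated,
            remaining=space.combination_count(config.k),
        )
        if n_eliminated == 0:
            break

    remaining = space.combination_count(config.k)
    # the loop may stop (nothing left to eliminate / iteration cap) slightly
    # above the threshold; exact enumeration is still feasible within a
    # bounded factor of E, so only a true runaway falls back.
    if remaining <= 10 * config.exhaustive_threshold:
        if remaining > config.exhaustive_threshold:
            logger.warning(
                "elimination stopped at %d combinations (threshold %d); "
                "completing exhaustively anyway", remaining,
                config.exhaustive_threshold,
            )
        final_entries = _exhaustive(space, scorer, config)
        trace.exhaustive_count = remaining
        # elitism: the best sampled filter survives elimination, so the
        # exhaustive pass rescored it; merging is a safety net only.
        if best_entry is not None:
            final_entries.append(best_entry)
    else:
        logger.warning(
            "elimination stalled with %d combinations remaining (> %d); "
            "returning the best sampled filters",
            remaining, config.exhaustive_threshold,
        )
        trace.fallback = True
        final_entries = list(sampled_pool.values())

    dedup: dict[tuple, tuple] = {}
    for e in sorted(final_entries, key=_filter_sort_key):
        dedup.setdefault(e[2], e)
    top = list(dedup.values())[: config.n_filters]
    filters = [_to_range_filter(space, e[3], e[4]) for e in top]
    return filters, trace


def _exhaustive(space: DiscretizedSpace, scorer: _Scorer, config: ISEConfig):
    """Score every remaining k-combination exactly; keep the local top per
    descriptor subset and return the merged candidate entries."""
    names = space.eligible_names()
    keep = 2 * config.n_filters
    out = []
    stacks = {}
    pairs = {}
    for name in names:
        pairs[name] = space.intervals_for(name)
        stacks[name] = scorer.interval_stack(name, pairs[name])
    for subset in itertools.combinations(names, config.k):
        acc_a, acc_i = stacks[subset[0]]
        sizes = [len(pairs[subset[0]])]
        for name in subset[1:]:
            a, i = stacks[name]
            acc_a = (acc_a[:, None, :] & a[None, :, :]).reshape(-1, acc_a.shape[1])
            acc_i = (acc_i[:, None, :] & i[None, :, :]).reshape(-1, acc_i.shape[1])
            sizes.append(len(pairs[name]))
        tp = _POP8[acc_a].sum(axis=1)
        fp = _POP8[acc_i].sum(axis=1)
        mccs = scorer.mcc_from(tp, fp)
        n_local = min(keep, len(mccs))
        top_local = np.argpartition(-mccs, n_local - 1)[:n_local]
        for flat in top_local.tolist():
            idxs = np.unravel_index(flat, sizes)
            triples = tuple(
                (name, *pairs[name][int(ii)]) for name, ii in zip(subset, idxs)
            )
            tp_v, fp_v = int(tp[flat]), int(fp[flat])
            stats = FilterStats(tp=tp_v, fp=fp_v, fn=scorer.n_act - tp_v,
                                tn=scorer.n_inact - fp_v)
            key = tuple(sorted(
                (name, float(space.values[name][lo]), float(space.values[name][hi]))
                for name, lo, hi in triples
            ))
            out.append((stats.mcc, stats.tp_pct, key, triples, stats))
    return out
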