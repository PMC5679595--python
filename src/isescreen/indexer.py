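"""Multi-filter bioactivity indexing and model evaluation.

The molecular bioactivity index (MBI) of a molecule is its weighted
filter-pass count over a model's F range filters — with unit weights it is
simply how many filters the molecule satisfies (0..F).  Libraries are
ranked by MBI; models are evaluated by threshold sweep (TP%/FP%/MCC versus
MBI cutoff), ROC/AUC, enrichment of actives in the top-ranked fraction of
an active:inactive pool, and the redundancy of descriptors across the
model's filters relative to uniform random descriptor choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rangefilter import (
    FilterStats,
    RangeFilter,
    apply_filter,
    apply_filter_table,
    coerce_labels,
    mcc as _mcc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterModel",
    "ScreenReport",
    "RedundancyReport",
    "mbi",
    "mbi_scores",
    "threshold_sweep",
    "roc_auc",
    "enrichment",
    "descriptor_redundancy",
    "fold_over_random",
    "screen",
]


@dataclass(frozen=True)
class FilterModel:
    """An ordered list of unique range filters with an MBI weighting scheme."""

    filters: tuple[RangeFilter, ...]
    weighting: str = "unit"
    registry_version: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "filters", tuple(self.filters))
        if len(self.filters) < 1:
            raise ValueError("a model needs at least one filter")
        if self.weighting not in ("unit", "mcc"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        keys = [f.key() for f in self.filters]
        if len(set(keys)) != len(keys):
            raise ValueError("model filters must be unique (descriptor set, bounds)")

    @property
    def n_filters(self) -> int:
        return len(self.filters)

    @property
    def descriptors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for f in self.filters:
            for name in f.descriptors:
                seen.setdefault(name, None)
        return tuple(seen)

    def weights(self) -> np.ndarray:
        if self.weighting == "unit":
            return np.ones(len(self.filters))
        w = np.empty(len(self.filters))
        for i, f in enumerate(self.filters):
            if f.stats is None:
                raise ValueError("mcc weighting needs FilterStats on every filter")
            w[i] = max(f.stats.mcc, 0.0)
        return w


def mbi(row: Mapping[str, float], model: FilterModel) -> float:
    """Bioactivity index of one molecule: weighted count of passed filters."""
    w = model.weights()
    return float(sum(
        w[i] for i, f in enumerate(model.filters)
        if f.usable and apply_filter(f, row)
    ))


def mbi_scores(table: pd.DataFrame, model: FilterModel) -> np.ndarray:
    """Vectorized MBI over a descriptor table (rows follow table order)."""
    w = model.weights()
    scores = np.zeros(len(table))
    for i, f in enumerate(model.filters):
        if not f.usable:
            continue
        scores += w[i] * apply_filter_table(f, table)
    return scores


def screen(table: pd.DataFrame, model: FilterModel,
           names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Score and rank a library: columns id, name, mbi, rank (1 = best;
    ties share the minimum rank)."""
    scores = mbi_scores(table, model)
    ranks = rankdata(-scores, method="min").astype(int)
    out = pd.DataFrame({
        "id": table.index.astype(str),
        "name": list(names) if names is not None else [""] * len(table),
        "mbi": scores,
        "rank": ranks,
    })
    return out.sort_values(["rank", "id"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# evaluation

def threshold_sweep(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """TP%, FP% and MCC of the classifier ``score >= t`` for every relevant
    threshold t (0, each distinct score, and one point above the maximum)."""
    s = np.asarray(scores, dtype=float)
    y = coerce_labels(labels)
    if y.all() or not y.any():
        raise ValueError("both classes required")
    n_act = int(y.sum())
    n_inact = len(y) - n_act
    thresholds = np.unique(s)
    lo = min(0.0, float(thresholds[0]))
    ts = np.unique(np.concatenate([[lo], thresholds, [thresholds[-1] + 1.0]]))
    rows = []
    for t in ts:
        pred = s >= t
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        rows.append({
            "threshold": float(t),
            "tp_pct": 100.0 * tp / n_act,
            "fp_pct": 100.0 * fp / n_inact,
            "mcc": _mcc((tp, fp, n_inact - fp, n_act - tp)),
        })
    return pd.DataFrame(rows)


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney pair statistic plus the ROC polyline.

    AUC = P(score_active > score_inactive) + 0.5 P(tie), computed from
    midranks; the returned curve (columns fpr, tpr, threshold) integrates
    to the same value by the trapezoid rule.
    """
    s = np.asarray(scores, dtype=float)
    y = coerce_labels(labels)
    if y.all() or not y.any():
        raise ValueError("both classes required")
    n_act = int(y.sum())
    n_inact = len(y) - n_act
    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n_act * (n_act + 1) / 2.0
    auc = float(u / (n_act * n_inact))

    thresholds = np.unique(s)[::-1]
    pts = [{"fpr": 0.0, "tpr": 0.0, "threshold": math.inf}]
    for t in thresholds:
        pred = s >= t
        pts.append({
            "fpr": float(np.sum(pred & ~y)) / n_inact,
            "tpr": float(np.sum(pred & y)) / n_act,
            "threshold": float(t),
        })
    curve = pd.DataFrame(pts)
    return auc, curve


def enrichment(
    scores: Sequence[float],
    labels: Sequence,
    top_fraction: float = 0.01,
    mix_ratio: int = 100,
    seed: int = 0,
) -> float:
    """Percent of actives captured in the top fraction of a 1:mix pool.

    A pool with one active per ``mix_ratio`` inactives is constructed by
    seeded subsampling of whichever class is over-represented.  Molecules
    are ranked by score descending with pessimistic ties (an inactive
    outranks an active at equal score); the return value is
    ``100 * actives-in-top / actives-in-pool`` where the top holds
    ``ceil(top_fraction * pool)`` molecules.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    if mix_ratio < 1:
        raise ValueError("mix_ratio must be >= 1")
    s = np.asarray(scores, dtype=float)
    y = coerce_labels(labels)
    act_idx = np.flatnonzero(y)
    inact_idx = np.flatnonzero(~y)
    if len(act_idx) == 0 or len(inact_idx) == 0:
        raise ValueError("both classes required")
    rng = np.random.default_rng(seed)
    # realize the 1:mix ratio by downsampling the over-represented class
    if len(inact_idx) >= mix_ratio * len(act_idx):
        n_act = len(act_idx)
        n_inact = mix_ratio * n_act
        if n_inact < len(inact_idx):
            inact_idx = rng.choice(inact_idx, size=n_inact, replace=False)
    else:
        n_act = len(inact_idx) // mix_ratio
        if n_act < 1:
            raise ValueError(
                f"inactive pool too small to realize a 1:{mix_ratio} mix"
            )
        act_idx = rng.choice(act_idx, size=n_act, replace=False)
    pool = np.concatenate([act_idx, inact_idx])
    pool_y = np.concatenate([
        np.ones(len(act_idx), dtype=bool),
        np.zeros(len(inact_idx), dtype=bool),
    ])
    pool_s = s[pool]
    # sort by score desc; at equal score inactives first (pessimistic)
    order = np.lexsort((pool_y, -pool_s))
    n_top = int(math.ceil(top_fraction * len(pool)))
    captured = int(pool_y[order[:n_top]].sum())
    return 100.0 * captured / len(act_idx)


# --------------------------------------------------------------------------
# descriptor redundancy

def _round_half_away(x: float, ndigits: int = 1) -> float:
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def fold_over_random(count: int, n_filters: int, k: int, pool_size: int) -> float:
    """How many times more often a descriptor occurs than uniform random
    choice predicts: count / (F*k/D), rounded half away from zero to one
    decimal."""
    if pool_size < 1 or n_filters < 1 or k < 1:
        raise ValueError("n_filters, k and pool_size must be positive")
    expected = n_filters * k / pool_size
    return _round_half_away(count / expected, 1)


@dataclass(frozen=True)
class RedundancyReport:
    """Descriptor occurrence counts across a model's filters."""

    counts: dict[str, int]
    pool_size: int
    n_slots: int             # total descriptor slots = sum of filter sizes

    def fold(self, name: str) -> float:
        c = self.counts.get(name, 0)
        return _round_half_away(c / (self.n_slots / self.pool_size), 1)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            self.counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(
            [
                {"descriptor": n, "count": c, "fold_over_random": self.fold(n)}
                for n, c in rows
            ]
        )


def descriptor_redundancy(model: FilterModel, pool_size: int) -> RedundancyReport:
    """Occurrence count of every descriptor over the model's filters and its
    fold over the uniform-random expectation F*k/D."""
    distinct = len(model.descriptors)
    if pool_size < distinct:
        raise ValueError(
            f"pool size {pool_size} smaller than the {distinct} distinct "
            "descriptors in the model"
        )
    counts: dict[str, int] = {}
    n_slots = 0
    for f in model.filters:
        for name in f.descriptors:
            counts[name] = counts.get(name, 0) + 1
            n_slots += 1
    return RedundancyReport(counts=counts, pool_size=pool_size, n_slots=n_slots)
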