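"""Conjunctive descriptor-range filters and their confusion statistics.

A filter is a conjunction of closed numeric intervals over a small set of
molecular descriptors.  A molecule whose descriptor values fall inside every
interval is predicted active; a single value outside any interval (or a
not-computable cell, encoded as NaN) predicts inactive.  Filters are scored
with the Matthews correlation coefficient (MCC) together with the true
positive and true negative percentages of the labeled set they were
evaluated on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorInterval",
    "RangeFilter",
    "FilterStats",
    "apply_filter",
    "apply_filter_table",
    "confusion_counts",
    "mcc",
]


@dataclass(frozen=True)
class DescriptorInterval:
    """A closed interval ``[low, high]`` over one named descriptor."""

    descriptor: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"interval bounds must be finite: {self}")
        if self.low > self.high:
            raise ValueError(f"interval low > high: {self}")

    def contains(self, value: float) -> bool:
        """Closed-bound membership; NaN (not-computable) is outside."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        return self.low <= value <= self.high

    def render(self) -> str:
        return f"{self.descriptor} ({self.low:g}–{self.high:g})"


@dataclass(frozen=True)
class FilterStats:
    """Confusion counts of a filter on a labeled set, plus derived scores.

    ``tp_pct`` is sensitivity (percent of actives recovered) and ``tn_pct``
    is specificity (percent of inactives rejected).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def mcc(self) -> float:
        return mcc(self)

    @property
    def tp_pct(self) -> float:
        n_act = self.tp + self.fn
        return 100.0 * self.tp / n_act if n_act else float("nan")

    @property
    def tn_pct(self) -> float:
        n_inact = self.tn + self.fp
        return 100.0 * self.tn / n_inact if n_inact else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "mcc": self.mcc,
            "tp_pct": self.tp_pct,
            "tn_pct": self.tn_pct,
        }


@dataclass(frozen=True)
class RangeFilter:
    """A conjunction of intervals over distinct descriptors."""

    intervals: tuple[DescriptorInterval, ...]
    stats: Optional[FilterStats] = None
    usable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        names = [iv.descriptor for iv in self.intervals]
        if len(names) == 0:
            raise ValueError("a filter needs at least one interval")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate descriptor in filter: {names}")

    @property
    def descriptors(self) -> tuple[str, ...]:
        return tuple(iv.descriptor for iv in self.intervals)

    def key(self) -> tuple:
        """Canonical identity: descriptor set with bounds, order-free."""
        return tuple(
            sorted((iv.descriptor, iv.low, iv.high) for iv in self.intervals)
        )

    def with_stats(self, stats: FilterStats) -> "RangeFilter":
        return replace(self, stats=stats)

    def render(self) -> str:
        return "; ".join(iv.render() for iv in self.intervals)


def apply_filter(f: RangeFilter, row: Mapping[str, float]) -> bool:
    """Predict a single molecule: True iff every interval contains its value.

    A descriptor missing from ``row`` or flagged not-computable (NaN) fails
    the filter — the conservative choice for screening.
    """
    for iv in f.intervals:
        if iv.descriptor not in row:
            _warn_missing_once(iv.descriptor)
            return False
        if not iv.contains(row[iv.descriptor]):
            return False
    return True


_missing_warned: set[str] = set()


def _warn_missing_once(name: str) -> None:
    if name not in _missing_warned:
        _missing_warned.add(name)
        logger.warning("descriptor %r absent from row; treated as outside range", name)


def apply_filter_table(f: RangeFilter, table: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`apply_filter` over a molecules x descriptors table."""
    mask = np.ones(len(table), dtype=bool)
    for iv in f.intervals:
        if iv.descriptor not in table.columns:
            _warn_missing_once(iv.descriptor)
            return np.zeros(len(table), dtype=bool)
        col = table[iv.descriptor].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mask &= (col >= iv.low) & (col <= iv.high)
    return mask


def confusion_counts(
    f: RangeFilter, table: pd.DataFrame, labels: Sequence
) -> FilterStats:
    """Confusion matrix of a filter against binary labels aligned to rows.

    Labels may be booleans, 0/1 integers, or the strings
    ``"active"`` / ``"inactive"``.
    """
    y = coerce_labels(labels)
    if len(y) != len(table):
        raise ValueError("labels must align with table rows")
    if y.all() or not y.any():
        raise ValueError("both label classes must be present")
    pred = apply_filter_table(f, table)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return FilterStats(tp=tp, fp=fp, tn=tn, fn=fn)


def coerce_labels(labels: Sequence) -> np.ndarray:
    """Normalize a label vector to a boolean array (True = active)."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    out = np.empty(len(arr), dtype=bool)
    for i, v in enumerate(arr):
        s = str(v).lower()
        if s in ("active", "1", "true"):
            out[i] = True
        elif s in ("inactive", "0", "false"):
            out[i] = False
        else:
            raise ValueError(f"unrecognized label {v!r}")
    return out


def mcc(counts: FilterStats | tuple) -> float:
    """Matthews correlation coefficient from confusion counts.

    Returns 0.0 by convention when any marginal of the confusion matrix is
    empty (all-positive or all-negative predictions, or a missing class),
    which keeps the optimizer total.
    """
    if isinstance(counts, FilterStats):
        tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    else:
        tp, fp, tn, fn = counts
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)
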