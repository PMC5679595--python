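"""Scikit-learn estimator facade over the ISE optimizer.

``ISEClassifier`` is a binary classifier: ``fit`` learns an F-filter range
model from a descriptor table, ``decision_function`` returns the molecular
bioactivity index (weighted filter-pass count), and ``predict`` thresholds
it.  It follows the scikit-learn contract (``get_params``/``set_params``,
trailing-underscore fitted attributes, ``classes_``), so it composes with
pipelines, ``clone`` and model selection; pair it with
:class:`~isescreen.descriptors.DescriptorCalculator` to go straight from
SMILES to predictions.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .ise_engine import ISEConfig, ise_optimize
from .indexer import FilterModel, mbi_scores
from .rangefilter import coerce_labels

__all__ = ["ISEClassifier"]


class ISEClassifier(ClassifierMixin, BaseEstimator):
    """Learn descriptor-range filters by iterative stochastic elimination.

    Parameters mirror :class:`~isescreen.ise_engine.ISEConfig`; see its
    docstring for semantics.  ``weighting`` selects unit or
    positive-MCC filter weights for the bioactivity index;
    ``decision_threshold`` is the MBI at or above which ``predict``
    returns the positive class.

    Attributes
    ----------
    filters_ : list of learned RangeFilter (training stats attached)
    model_ : FilterModel wrapping the filters
    trace_ : ISETrace of the elimination loop
    classes_ : ndarray [negative, positive]
    feature_names_in_ : descriptor names seen during fit
    """

    def __init__(
        self,
        k: int = 4,
        population: int = 10_000,
        best_fraction: float = 0.05,
        worst_fraction: float = 0.05,
        elimination_ratio: float = 2.0,
        exhaustive_threshold: int = 200_000,
        max_iterations: int = 50,
        n_filters: int = 29,
        n_cutpoints: int = 49,
        weighting: str = "unit",
        decision_threshold: float = 1.0,
        random_state: int = 0,
    ):
        self.k = k
        self.population = population
        self.best_fraction = best_fraction
        self.worst_fraction = worst_fraction
        self.elimination_ratio = elimination_ratio
        self.exhaustive_threshold = exhaustive_threshold
        self.max_iterations = max_iterations
        self.n_filters = n_filters
        self.n_cutpoints = n_cutpoints
        self.weighting = weighting
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if hasattr(self, "feature_names_in_"):
            cols = list(self.feature_names_in_)
        else:
            cols = [f"x{i}" for i in range(arr.shape[1])]
        return pd.DataFrame(arr, columns=cols)

    def _config(self) -> ISEConfig:
        return ISEConfig(
            k=self.k,
            population=self.population,
            best_fraction=self.best_fraction,
            worst_fraction=self.worst_fraction,
            elimination_ratio=self.elimination_ratio,
            exhaustive_threshold=self.exhaustive_threshold,
            max_iterations=self.max_iterations,
            n_filters=self.n_filters,
            n_cutpoints=self.n_cutpoints,
            seed=self.random_state,
        )

    def fit(self, X, y) -> "ISEClassifier":
        table = self._as_frame(X)
        y_bool = coerce_labels(y)
        if len(y_bool) != len(table):
            raise ValueError("X and y length mismatch")
        if y_bool.all() or not y_bool.any():
            raise ValueError("y must contain both classes")
        self.feature_names_in_ = np.asarray(table.columns, dtype=object)
        self.n_features_in_ = table.shape[1]
        config = self._config()
        filters, trace = ise_optimize(table, y_bool, config)
        self.filters_ = filters
        self.trace_ = trace
        from dataclasses import asdict

        from .descriptors import REGISTRY_VERSION

        self.model_ = FilterModel(
            filters=tuple(filters),
            weighting=self.weighting,
            registry_version=REGISTRY_VERSION,
            provenance={"seed": self.random_state, "config": asdict(config)},
        )
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Molecular bioactivity index of each row."""
        check_is_fitted(self, "model_")
        table = self._as_frame(X)
        return mbi_scores(table, self.model_)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[(scores >= self.decision_threshold).astype(int)]

    def score_table(self, X) -> pd.DataFrame:
        """Ranked screening report (id, mbi, rank) for a library."""
        from .indexer import screen

        check_is_fitted(self, "model_")
        return screen(self._as_frame(X), self.model_)
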