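"""Iterative random-forest imputation of missing covariates (missForest-style).

The algorithm initialises missing cells at training-column medians, then
cycles over incomplete variables in order of increasing missingness,
regressing each on all other predictors with a random forest and
re-predicting its missing cells.  Iteration stops when the normalised
squared change of the imputed continuous values first *increases* relative
to the previous iteration (the previous iteration's values are kept), or at
``max_iter``.

Unlike refit-on-the-fly implementations, the fitted forests of every
accepted iteration are stored so that *new* rows (validation/test) can be
imputed by replaying the same forests in the same visit order — no
information from held-out rows ever enters the fit, and the outcome label is
never consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

__all__ = ["MissForestImputer"]


@dataclass
class _IterationForests:
    """Forests fitted during one sweep, keyed by target variable."""

    forests: dict = field(default_factory=dict)


class MissForestImputer(BaseEstimator, TransformerMixin):
    """missForest-style imputer for continuous covariates.

    Parameters
    ----------
    n_estimators : int
        Trees per forest (default 100).
    max_iter : int
        Maximum number of sweeps over the incomplete variables (default 10).
    random_state : int or None
        Seed for the forests; fixed seed gives deterministic imputations.

    Attributes
    ----------
    columns_ : list of str
        Training schema (order matters for replay).
    visit_order_ : list of str
        Incomplete variables in increasing-missingness order.
    medians_ : pandas.Series
        Training-column medians used for initialisation.
    iterations_ : list of _IterationForests
        Stored forests per accepted sweep; ``n_iter_ = len(iterations_)``.
    convergence_trace_ : list of float
        Normalised squared change per sweep (including the rejected one).
    train_bounds_ : dict
        Per-variable (min, max) of observed training values.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 10,
                 random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        return X

    def _new_forest(self, k: int) -> RandomForestRegressor:
        seed = None
        if self.random_state is not None:
            seed = (int(self.random_state) + 7919 * k) % (2**31 - 1)
        return RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        )

    # -- fit --------------------------------------------------------------

    def fit(self, X, y=None) -> "MissForestImputer":
        """Fit forests on training rows; ``y`` is accepted but never used."""
        X = self._as_frame(X)
        self.columns_ = list(X.columns)
        vals = X.to_numpy(dtype=float)
        mask = np.isnan(vals)

        self.medians_ = X.median(skipna=True)
        if self.medians_.isna().any():
            bad = self.medians_.index[self.medians_.isna()].tolist()
            raise ValueError(
                f"variable(s) {bad} have zero observed values and cannot be imputed"
            )
        n_missing = mask.sum(axis=0)
        order = np.argsort(n_missing, kind="stable")
        self.visit_order_ = [
            self.columns_[j] for j in order if n_missing[j] > 0
        ]
        self.train_bounds_ = {
            c: (float(np.nanmin(vals[:, j])), float(np.nanmax(vals[:, j])))
            for j, c in enumerate(self.columns_)
        }

        self.iterations_: list[_IterationForests] = []
        self.convergence_trace_: list[float] = []
        self.n_iter_ = 1

        # initialise with medians
        imputed = vals.copy()
        for j, c in enumerate(self.columns_):
            imputed[mask[:, j], j] = self.medians_[c]

        if not self.visit_order_:
            self.training_imputed_ = pd.DataFrame(
                imputed, columns=self.columns_, index=X.index
            )
            return self  # nothing to impute: identity behaviour

        col_idx = {c: j for j, c in enumerate(self.columns_)}
        prev_diff = np.inf
        accepted = imputed.copy()
        forest_counter = 0
        for it in range(self.max_iter):
            sweep = _IterationForests()
            new = imputed.copy()
            for var in self.visit_order_:
                j = col_idx[var]
                obs = ~mask[:, j]
                others = [k for k in range(len(self.columns_)) if k != j]
                forest = self._new_forest(forest_counter)
                forest_counter += 1
                forest.fit(new[obs][:, others], new[obs, j])
                sweep.forests[var] = forest
                if mask[:, j].any():
                    new[mask[:, j], j] = forest.predict(new[mask[:, j]][:, others])
            # normalised squared change over imputed continuous cells
            num = float(np.sum((new[mask] - imputed[mask]) ** 2))
            den = float(np.sum(new[mask] ** 2))
            diff = num / den if den > 0 else 0.0
            self.convergence_trace_.append(diff)
            if diff > prev_diff:  # got worse: keep previous sweep's values
                break
            self.iterations_.append(sweep)
            accepted = new
            imputed = new
            prev_diff = diff
            if diff == 0.0:
                break

        self.n_iter_ = max(len(self.iterations_), 1)
        self.training_imputed_ = pd.DataFrame(
            accepted, columns=self.columns_, index=X.index
        )
        return self

    # -- transform --------------------------------------------------------

    def transform(self, X) -> pd.DataFrame:
        """Impute missing cells of ``X`` by replaying the fitted forests.

        Observed cells are never altered; complete rows pass through
        unchanged.
        """
        check_is_fitted(self, "columns_")
        X = self._as_frame(X)
        if list(X.columns) != self.columns_:
            raise ValueError(
                f"schema mismatch: expected columns {self.columns_}, "
                f"got {list(X.columns)}"
            )
        vals = X.to_numpy(dtype=float)
        mask = np.isnan(vals)
        if not mask.any():
            return X.copy()

        unexpected = [
            c for j, c in enumerate(self.columns_)
            if mask[:, j].any() and c not in self.visit_order_
        ]
        if unexpected:
            warnings.warn(
                f"variables {unexpected} were complete at fit time; their "
                "missing cells are filled with training medians",
                RuntimeWarning,
                stacklevel=2,
            )

        imputed = vals.copy()
        for j, c in enumerate(self.columns_):
            imputed[mask[:, j], j] = self.medians_[c]

        col_idx = {c: j for j, c in enumerate(self.columns_)}
        for sweep in self.iterations_:
            for var in self.visit_order_:
                j = col_idx[var]
                if not mask[:, j].any():
                    continue
                others = [k for k in range(len(self.columns_)) if k != j]
                imputed[mask[:, j], j] = sweep.forests[var].predict(
                    imputed[mask[:, j]][:, others]
                )
        return pd.DataFrame(imputed, columns=self.columns_, index=X.index)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "columns_")
        return np.asarray(self.columns_, dtype=object)
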