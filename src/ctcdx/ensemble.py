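"""Monte-Carlo cross-validation (MCCV) ensemble classifiers.

The core method: after a stratified holdout of a fixed-size test set, the
remaining subjects are randomly split into training (75%) and validation
(25%) portions many times (1000 in the study design).  Within each split a
base learner is tuned by 10-fold cross-validation on the training portion
(grid search, accuracy criterion), refit, and evaluated on the validation
portion (classification error rate, AUC).  All per-split models are retained
as members of the final ensemble; test-set prediction averages the members'
predicted cancer probabilities (a vote-fraction rule over hard member calls
is available as an option) and calls cancer when the aggregate strictly
exceeds the decision threshold (default 0.5).  Families are compared by mean
validation CER; the family with the lowest mean CER is selected, subject to
configurable exclusions/preferences.

Missing covariates are imputed inside each split: the imputer is fitted on
the split's training portion only and applied to validation (and later test)
rows, so no held-out information leaks into preprocessing.  Continuous
features are standardised by training-fold statistics inside every tuning
fold and in the final refit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .cohort import Cohort, OUTCOME_CANCER
from .impute import MissForestImputer
from .metrics import mann_whitney_auc

__all__ = [
    "FAMILIES",
    "FEATURE_SETS",
    "SplitPlan",
    "SmallModel",
    "MCCVEnsembleClassifier",
    "stratified_holdout",
    "mc_splits",
    "tune_small_model",
    "evaluate_small_model",
    "compare_families",
    "default_grid",
]

logger = logging.getLogger(__name__)

FAMILIES = (
    "svm_linear",
    "svm_radial",
    "svm_polynomial",
    "svm_sigmoid",
    "gbm",
    "rf",
    "adaboost",
    "xgb",
)

FEATURE_SETS = {
    "model1": ["age", "ck18", "mgb", "wbc", "platelet"],
    "model2": ["age", "ck18", "mgb"],
}

_SVM_KERNELS = {
    "svm_linear": "linear",
    "svm_radial": "rbf",
    "svm_polynomial": "poly",
    "svm_sigmoid": "sigmoid",
}

# Full grids: printed ranges discretised (cost on a log scale; depth-like
# integers over their full stated range).  RF/AdaBoost grids and the SVM
# kernel-specific parameters are unprinted in the source study and are
# reconstructions.  n.trees for GBM at full scale is 10,000.
_SVM_COSTS_FULL = [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
_SVM_COSTS_DESK = [0.1, 1.0, 10.0]

FULL_GRIDS: dict[str, dict[str, list]] = {
    **{fam: {"C": _SVM_COSTS_FULL} for fam in _SVM_KERNELS},
    "gbm": {
        "max_depth": list(range(1, 10)),
        "learning_rate": [0.01, 0.1, 0.2],
        "min_samples_leaf": [5, 10, 15, 20],
        "subsample": [0.5, 0.75, 1.0],
        "n_estimators": [10_000],
    },
    "rf": {"n_estimators": [500], "max_features": [1, 2, 3, 4, 5]},
    "adaboost": {"n_estimators": [50, 100, 500], "learning_rate": [0.1, 0.5, 1.0]},
    "xgb": {
        "learning_rate": [0.01, 0.1, 0.2],
        "max_depth": list(range(1, 10)),
        "min_child_weight": list(range(1, 10)),
        "subsample": [0.7, 0.8, 0.9, 1.0],
        "colsample_bytree": [0.7, 0.8, 0.9, 1.0],
    },
}

# Desk-scale grids keep one or two values per knob so a full run fits on a
# single CPU in minutes; coverage of the printed ranges is delegated to the
# full grids.
DESK_GRIDS: dict[str, dict[str, list]] = {
    **{fam: {"C": _SVM_COSTS_DESK} for fam in _SVM_KERNELS},
    "gbm": {
        "max_depth": [1, 3],
        "learning_rate": [0.1],
        "min_samples_leaf": [10],
        "subsample": [1.0],
        "n_estimators": [100],
    },
    "rf": {"n_estimators": [100], "max_features": [1, 3]},
    "adaboost": {"n_estimators": [50], "learning_rate": [1.0]},
    "xgb": {
        "learning_rate": [0.1],
        "max_depth": [1, 3],
        "min_child_weight": [1],
        "subsample": [1.0],
        "colsample_bytree": [1.0],
    },
}


def default_grid(family: str, scale: str = "desk") -> dict[str, list]:
    """Default hyperparameter grid for a learner family at a given scale."""
    grids = {"desk": DESK_GRIDS, "paper": FULL_GRIDS, "full": FULL_GRIDS}[scale]
    if family not in grids:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    return {k: list(v) for k, v in grids[family].items()}


@dataclass(frozen=True)
class SplitPlan:
    """Holdout and MCCV split geometry.

    Defaults follow the study design: a stratified test set of 48 subjects,
    then 1000 random 75/25 train/validation splits of the remainder (262/88
    when 350 subjects remain).
    """

    seed: int = 0
    test_size: int = 48
    n_mc_splits: int = 1000
    train_fraction: float = 0.75
    stratify_mc: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.test_size < 0 or self.n_mc_splits < 1:
            raise ValueError("test_size >= 0 and n_mc_splits >= 1 required")

    def sizes(self, n_after_holdout: int) -> tuple[int, int]:
        n_train = int(np.floor(self.train_fraction * n_after_holdout))
        return n_train, n_after_holdout - n_train


def _largest_remainder(counts: dict, total: int) -> dict:
    """Proportional integer allocation by the largest-remainder rule."""
    n = sum(counts.values())
    quotas = {k: total * v / n for k, v in counts.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = total - sum(alloc.values())
    by_rem = sorted(
        quotas, key=lambda k: (quotas[k] - alloc[k], counts[k]), reverse=True
    )
    for k in by_rem[:short]:
        alloc[k] += 1
    return alloc


def stratified_holdout(cohort: Cohort, plan: SplitPlan) -> tuple[Cohort, Cohort]:
    """Split off a class-proportional test set (largest-remainder rounding)."""
    frame = cohort.frame
    counts = frame["outcome"].value_counts().to_dict()
    if len(counts) < 2:
        raise ValueError("both outcome classes must be present")
    alloc = _largest_remainder(counts, plan.test_size)
    for k, want in alloc.items():
        if want >= counts[k]:
            raise ValueError(
                f"test allocation {want} for class {k!r} leaves no training rows"
            )
    rng = np.random.default_rng(plan.seed)
    test_idx: list[int] = []
    for outcome in sorted(alloc):
        members = frame.index[frame["outcome"] == outcome].to_numpy()
        test_idx.extend(rng.choice(members, size=alloc[outcome], replace=False))
    test_mask = frame.index.isin(test_idx)
    train = Cohort(frame[~test_mask].reset_index(drop=True), provenance=cohort.provenance)
    test = Cohort(frame[test_mask].reset_index(drop=True), provenance=cohort.provenance)
    return train, test


def _one_mc_split(
    n: int,
    k: int,
    plan: SplitPlan,
    y: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Regenerate MC split ``k`` in isolation (counter-based seeding)."""
    rng = np.random.default_rng([plan.seed, k])
    n_train, _ = plan.sizes(n)
    for attempt in range(1000):
        if plan.stratify_mc and y is not None:
            order = []
            for cls in np.unique(y):
                order.append(rng.permutation(np.flatnonzero(y == cls)))
            perm = np.concatenate(order)
            take = _largest_remainder(
                {int(c): int((y == c).sum()) for c in np.unique(y)}, n_train
            )
            tr_parts, va_parts = [], []
            for cls_idx in order:
                cls = int(y[cls_idx[0]])
                tr_parts.append(cls_idx[: take[cls]])
                va_parts.append(cls_idx[take[cls]:])
            tr = np.sort(np.concatenate(tr_parts))
            va = np.sort(np.concatenate(va_parts))
        else:
            perm = rng.permutation(n)
            tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if y is None:
            return tr, va
        if len(set(y[tr])) == 2 and len(set(y[va])) == 2:
            if attempt:
                logger.info("split %d redrawn %d time(s) (class guard)", k, attempt)
            return tr, va
    raise RuntimeError(f"could not draw split {k} with both classes in both parts")


def mc_splits(
    n: int, plan: SplitPlan, y: np.ndarray | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All Monte-Carlo train/validation index pairs under the plan.

    Splits are plain random partitions (stratified if the plan says so); any
    split leaving a class absent from either part is redrawn.  Split ``k`` is
    seeded by ``(plan.seed, k)``, so each split is reproducible in isolation
    and results are independent of execution order or process count.
    """
    if n < 2:
        raise ValueError("need at least two rows to split")
    return [_one_mc_split(n, k, plan, y) for k in range(plan.n_mc_splits)]


# ---------------------------------------------------------------------------
# Base learners
# ---------------------------------------------------------------------------


class _PlattSVC(BaseEstimator, ClassifierMixin):
    """SVC with explicit Platt scaling of the decision values.

    A one-dimensional logistic regression is fitted to the training decision
    values, giving a deterministic, monotone probability for the SVM
    families (whose raw output is a margin, not a probability).
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0):
        self.kernel = kernel
        self.C = C

    def fit(self, X, y):
        self.svc_ = SVC(kernel=self.kernel, C=self.C, gamma="scale", max_iter=200_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # bounded-iteration convergence noise
            self.svc_.fit(X, y)
        d = self.svc_.decision_function(X).reshape(-1, 1)
        self.classes_ = self.svc_.classes_
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.platt_ = LogisticRegression(C=1.0)
        self.platt_.fit(d, y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(X)

    def predict_proba(self, X):
        check_is_fitted(self, "svc_")
        d = self.svc_.decision_function(X).reshape(-1, 1)
        return self.platt_.predict_proba(d)

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(X)


def _make_estimator(family: str, params: dict, seed: int, n_features: int):
    params = dict(params)
    if family in _SVM_KERNELS:
        return _PlattSVC(kernel=_SVM_KERNELS[family], C=params.get("C", 1.0))
    if family == "gbm":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "rf":
        if "max_features" in params:
            params["max_features"] = min(int(params["max_features"]), n_features)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "xgb":
        return XGBClassifier(
            n_estimators=100,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def _grid_points(grid: dict[str, list]) -> list[dict]:
    """Grid points in documented lexicographic order (declaration order of
    parameters, listed order of values); ties in tuning resolve to the first."""
    if not grid:
        return [{}]
    names = list(grid)
    for name in names:
        if not grid[name]:
            raise ValueError(f"empty grid for parameter {name!r}")
    return [dict(zip(names, combo)) for combo in itertools.product(*(grid[n] for n in names))]


def _make_pipeline(family: str, params: dict, seed: int, n_features: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("model", _make_estimator(family, params, seed, n_features)),
        ]
    )


@dataclass
class SmallModel:
    """One tuned base learner from one MC split."""

    family: str
    params: dict
    pipeline: Pipeline
    imputer: MissForestImputer | None
    cer: float
    auc: float
    split_index: int
    cv_accuracy: float = float("nan")

    def predict_proba_pos(self, X: pd.DataFrame) -> np.ndarray:
        """Member cancer probability; rows are imputed with the member's own
        split-fitted imputer."""
        if self.imputer is not None:
            X = self.imputer.transform(X)
        proba = self.pipeline.predict_proba(np.asarray(X, dtype=float))
        pos = list(self.pipeline.classes_).index(1)
        return proba[:, pos]


def tune_small_model(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    grid: dict[str, list],
    seed: int,
    cv_folds: int = 10,
) -> tuple[dict, float, Pipeline]:
    """Exhaustive grid search with stratified k-fold CV accuracy.

    Returns ``(best_params, best_cv_accuracy, fitted_pipeline)``; the winning
    point is refit on all rows.  Fold statistics (standardisation) never
    leak: scaling lives inside the pipeline and is refit per fold.  If a
    class has fewer members than ``cv_folds`` the fold count drops to the
    largest feasible k >= 2.
    """
    y = np.asarray(y, dtype=int)
    n_min = int(min(np.bincount(y, minlength=2)))
    k = min(cv_folds, n_min)
    if k < cv_folds:
        k = max(k, 2)
        logger.info("fold count reduced to %d (smallest class has %d rows)", k, n_min)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31 - 1))
    folds = list(skf.split(X, y))
    Xv = X.to_numpy(dtype=float)

    best_params, best_acc = None, -np.inf
    for point in _grid_points(grid):
        accs = []
        for tr, va in folds:
            pipe = _make_pipeline(family, point, seed, X.shape[1])
            pipe.fit(Xv[tr], y[tr])
            accs.append(float(np.mean(pipe.predict(Xv[va]) == y[va])))
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict: ties keep the earlier grid point
            best_acc, best_params = acc, point
    final = _make_pipeline(family, best_params, seed, X.shape[1])
    final.fit(Xv, y)
    return best_params, best_acc, final


def evaluate_small_model(
    model: SmallModel, X_val: pd.DataFrame, y_val: np.ndarray
) -> tuple[float, float]:
    """Validation CER (probability threshold 0.5) and AUC of one member."""
    y_val = np.asarray(y_val, dtype=int)
    p = model.predict_proba_pos(X_val)
    cer = float(np.mean((p > 0.5).astype(int) != y_val))
    if len(set(y_val.tolist())) < 2:
        return cer, float("nan")
    return cer, mann_whitney_auc(y_val, p)


# ---------------------------------------------------------------------------
# Ensemble estimator
# ---------------------------------------------------------------------------


class MCCVEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of per-split tuned base learners built by MCCV.

    scikit-learn compatible: ``fit(X, y)`` / ``predict`` / ``predict_proba``.
    ``X`` must be a DataFrame (or array) of the chosen features and may
    contain missing values — each ensemble member imputes incoming rows with
    the missForest imputer fitted on its own split's training portion.

    Parameters
    ----------
    family : str
        Base-learner family (one of :data:`FAMILIES`).
    n_mc_splits : int
        Number of Monte-Carlo train/validation splits, i.e. ensemble size
        (study design: 1000).
    train_fraction : float
        Training share of each split (study design: 0.75).
    param_grid : dict or None
        Hyperparameter grid; ``None`` selects the family default at ``scale``.
    scale : str
        ``"desk"`` (small grids) or ``"paper"`` (full printed ranges).
    cv_folds : int
        Folds for within-split tuning (study design: 10).
    threshold : float
        Decision threshold on the aggregated probability; cancer is called
        when the aggregate *strictly exceeds* it (ties -> benign).
    vote_rule : str
        ``"mean"`` averages member probabilities (default; matches the
        study's probability-threshold wording); ``"vote"`` thresholds the
        fraction of members whose individual probability exceeds 0.5.
    impute : bool
        Fit a per-split missForest imputer (needed whenever features can be
        missing).
    imputer_trees, imputer_max_iter : int
        Forwarded to :class:`~ctcdx.impute.MissForestImputer`.
    stratify_mc : bool
        Stratify the MC splits by class (plain random by default).
    n_jobs : int
        Parallelism over splits; per-split counter seeding makes results
        independent of execution order.
    random_state : int
        Master seed.
    """

    def __init__(
        self,
        family: str = "svm_linear",
        n_mc_splits: int = 1000,
        train_fraction: float = 0.75,
        param_grid: dict | None = None,
        scale: str = "desk",
        cv_folds: int = 10,
        threshold: float = 0.5,
        vote_rule: str = "mean",
        impute: bool = True,
        imputer_trees: int = 100,
        imputer_max_iter: int = 10,
        stratify_mc: bool = False,
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.family = family
        self.n_mc_splits = n_mc_splits
        self.train_fraction = train_fraction
        self.param_grid = param_grid
        self.scale = scale
        self.cv_folds = cv_folds
        self.threshold = threshold
        self.vote_rule = vote_rule
        self.impute = impute
        self.imputer_trees = imputer_trees
        self.imputer_max_iter = imputer_max_iter
        self.stratify_mc = stratify_mc
        self.n_jobs = n_jobs
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _fit_one_split(
        self, X: pd.DataFrame, y: np.ndarray, k: int, plan: SplitPlan, grid: dict
    ) -> SmallModel:
        tr, va = _one_mc_split(len(X), k, plan, y)
        X_tr, X_va = X.iloc[tr], X.iloc[va]
        y_tr, y_va = y[tr], y[va]
        imputer = None
        if self.impute:
            imputer = MissForestImputer(
                n_estimators=self.imputer_trees,
                max_iter=self.imputer_max_iter,
                random_state=int(
                    np.random.default_rng([self.random_state, k, 1]).integers(2**31 - 1)
                ),
            )
            X_tr = imputer.fit(X_tr).training_imputed_
            X_va = imputer.transform(X_va)
        seed_k = int(np.random.default_rng([self.random_state, k, 2]).integers(2**31 - 1))
        params, cv_acc, pipe = tune_small_model(
            X_tr, y_tr, self.family, grid, seed_k, cv_folds=self.cv_folds
        )
        member = SmallModel(
            family=self.family,
            params=params,
            pipeline=pipe,
            imputer=imputer,
            cer=float("nan"),
            auc=float("nan"),
            split_index=k,
            cv_accuracy=cv_acc,
        )
        # validation rows are already imputed by this member's imputer
        p = member.pipeline.predict_proba(X_va.to_numpy(dtype=float))
        pos = list(member.pipeline.classes_).index(1)
        p = p[:, pos]
        member.cer = float(np.mean((p > 0.5).astype(int) != y_va))
        member.auc = (
            mann_whitney_auc(y_va, p) if len(set(y_va.tolist())) == 2 else float("nan")
        )
        logger.info(
            "split %d: params=%s cv_acc=%.3f val_cer=%.3f val_auc=%.3f",
            k, params, cv_acc, member.cer, member.auc,
        )
        return member

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y) -> "MCCVEnsembleClassifier":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=int)
        if set(np.unique(y).tolist()) != {0, 1}:
            raise ValueError("y must contain both classes, coded 0/1")
        if len(X) != len(y):
            raise ValueError("X and y must align")
        if not self.impute and X.isna().any().any():
            raise ValueError("X contains missing values but impute=False")
        grid = (
            {k: list(v) for k, v in self.param_grid.items()}
            if self.param_grid is not None
            else default_grid(self.family, self.scale)
        )
        plan = SplitPlan(
            seed=self.random_state,
            test_size=0,
            n_mc_splits=self.n_mc_splits,
            train_fraction=self.train_fraction,
            stratify_mc=self.stratify_mc,
        )
        X = X.reset_index(drop=True)
        members = Parallel(n_jobs=self.n_jobs)(
            delayed(self._fit_one_split)(X, y, k, plan, grid)
            for k in range(self.n_mc_splits)
        )
        self.members_ = list(members)
        cers = np.array([m.cer for m in self.members_])
        aucs = np.array([m.auc for m in self.members_])
        self.cer_mean_ = float(np.nanmean(cers))
        self.cer_sd_ = float(np.nanstd(cers, ddof=1)) if len(cers) > 1 else 0.0
        self.auc_mean_ = float(np.nanmean(aucs))
        self.auc_sd_ = float(np.nanstd(aucs, ddof=1)) if len(aucs) > 1 else 0.0
        # dispersion interval across splits (mean +/- 1.96 SD), labelled as such
        self.auc_ci_ = (
            max(self.auc_mean_ - 1.96 * self.auc_sd_, 0.0),
            min(self.auc_mean_ + 1.96 * self.auc_sd_, 1.0),
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def _member_probas(self, X) -> np.ndarray:
        check_is_fitted(self, "members_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [str(c) for c in X.columns]
        return np.vstack([m.predict_proba_pos(X) for m in self.members_])

    def predict_proba(self, X) -> np.ndarray:
        """Ensemble probability = mean of member cancer probabilities."""
        p = self._member_probas(X).mean(axis=0)
        return np.column_stack([1.0 - p, p])

    def vote_fraction(self, X) -> np.ndarray:
        """Share of members whose individual probability exceeds 0.5."""
        return (self._member_probas(X) > 0.5).mean(axis=0)

    def decision_scores(self, X) -> np.ndarray:
        """Aggregate score under the configured vote rule."""
        if self.vote_rule == "mean":
            return self.predict_proba(X)[:, 1]
        if self.vote_rule == "vote":
            return self.vote_fraction(X)
        raise ValueError(f"unknown vote_rule {self.vote_rule!r}")

    def predict(self, X) -> np.ndarray:
        """Cancer iff the aggregate strictly exceeds the threshold."""
        return (self.decision_scores(X) > self.threshold).astype(int)

    @property
    def summary_(self) -> dict:
        check_is_fitted(self, "members_")
        return {
            "family": self.family,
            "n_members": len(self.members_),
            "cer_mean": self.cer_mean_,
            "cer_sd": self.cer_sd_,
            "auc_mean": self.auc_mean_,
            "auc_sd": self.auc_sd_,
            "auc_ci": list(self.auc_ci_),
        }


# ---------------------------------------------------------------------------
# Family comparison
# ---------------------------------------------------------------------------


def compare_families(
    X: pd.DataFrame,
    y: np.ndarray,
    families=FAMILIES,
    feature_sets: dict[str, list[str]] | None = None,
    *,
    exclude: tuple[str, ...] = (),
    prefer: str | None = None,
    return_models: bool = False,
    **ensemble_kwargs,
):
    """Build one ensemble per (family, feature set) and rank by mean CER.

    ``exclude`` removes named families from selection (they are still
    reported); ``prefer`` overrides the argmin-CER winner with a named family
    on stability/cost grounds.  Returns ``(table, selected)`` and, if
    ``return_models``, the fitted ensembles keyed by (family, feature set).
    """
    if not families:
        raise ValueError("at least one family required")
    feature_sets = feature_sets or {"all": list(X.columns)}
    rows, models = [], {}
    for fam in families:
        for fs_name, cols in feature_sets.items():
            model = MCCVEnsembleClassifier(family=fam, **ensemble_kwargs)
            model.fit(X[cols], y)
            models[(fam, fs_name)] = model
            rows.append(
                {
                    "family": fam,
                    "feature_set": fs_name,
                    "auc_mean": model.auc_mean_,
                    "auc_ci_lo": model.auc_ci_[0],
                    "auc_ci_hi": model.auc_ci_[1],
                    "cer_mean": model.cer_mean_,
                    "cer_sd": model.cer_sd_,
                }
            )
    table = pd.DataFrame(rows)
    eligible = table[~table["family"].isin(exclude)]
    if eligible.empty:
        raise ValueError("all families excluded from selection")
    if prefer is not None and (table["family"] == prefer).any():
        sel = table[table["family"] == prefer].sort_values("cer_mean").iloc[0]
    else:
        sel = eligible.sort_values(["cer_mean", "family", "feature_set"]).iloc[0]
    selected = (str(sel["family"]), str(sel["feature_set"]))
    if return_models:
        return table, selected, models
    return table, selected


def cohort_to_xy(cohort: Cohort, feature_set: str = "model1"):
    """Convenience: (X, y) for a named feature set from a cohort."""
    cols = FEATURE_SETS[feature_set]
    X = cohort.frame[cols].copy()
    y = (cohort.frame["outcome"] == OUTCOME_CANCER).to_numpy(dtype=int)
    return X, y
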