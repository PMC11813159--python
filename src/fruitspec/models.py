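"""Grid-searched ANN / RF / DT regression of fruit traits from spectral indices.

Protocol: the dataset is split 70/30 with a fixed random state; candidate
hyperparameters are evaluated by 5-fold cross-validated mean squared error on
the training split only; the winning combination (lowest mean CV MSE, ties
broken by grid order) is refit on the full training set and scored on both
splits with MSE, MAE and the coefficient of determination R² = 1 - SS_res/SS_tot.

Default hyperparameter grids:

* ANN (``MLPRegressor``, SGD optimizer, learning rate 0.001): neurons per
  hidden layer 2-10, hidden layers 1-3, activation in {tanh, logistic, relu,
  identity}, max_iter in {500, ..., 1000}.
* RF: 1-20 trees, depth 1-10, criterion in {squared_error, absolute_error}.
* DT: depth 1-10, criterion in {squared_error, absolute_error}.

ANN inputs are standardized on training statistics inside the estimator
pipeline (SGD-trained networks need comparable feature scales); tree models
are scale-free and use raw index values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

from .indices import index_table
from .spectra import SpectraSet, TraitTable

__all__ = [
    "MODEL_FAMILIES",
    "default_grid",
    "ModelSpec",
    "MetricReport",
    "FitResult",
    "split_data",
    "evaluate",
    "select_inputs",
    "SRIRegressor",
    "grid_search_fit",
    "run_trait_models",
    "results_frame",
]

MODEL_FAMILIES = ("ann", "rf", "dt")

_ANN_FIXED = {"solver": "sgd", "learning_rate_init": 0.001}


def default_grid(family: str) -> dict[str, list]:
    """The canonical hyperparameter grid for a model family."""
    family = family.lower()
    if family == "ann":
        return {
            "hidden_layer_sizes": [
                (n,) * layers for layers in (1, 2, 3) for n in range(2, 11)
            ],
            "activation": ["tanh", "logistic", "relu", "identity"],
            "max_iter": [500, 600, 700, 800, 900, 1000],
        }
    if family == "rf":
        return {
            "n_estimators": list(range(1, 21)),
            "max_depth": list(range(1, 11)),
            "criterion": ["squared_error", "absolute_error"],
        }
    if family == "dt":
        return {
            "max_depth": list(range(1, 11)),
            "criterion": ["squared_error", "absolute_error"],
        }
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


@dataclass
class ModelSpec:
    """A model family plus its hyperparameter search grid."""

    family: str
    hyper_grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.family = self.family.lower()
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.hyper_grid:
            self.hyper_grid = default_grid(self.family)


@dataclass
class MetricReport:
    """Regression quality metrics: R², MSE, MAE."""

    r2: float
    mse: float
    mae: float


@dataclass
class FitResult:
    """Outcome of one (trait, family) grid-search fit."""

    trait: str
    family: str
    input_names: list[str]
    best_params: dict
    train: MetricReport
    test: MetricReport
    seed: int
    cv_mse: float  # mean CV MSE of the winning combination


def split_data(X, y, train_fraction: float = 0.7, seed: int = 0):
    """Deterministic shuffled 70/30 split.

    The training size is ``round(train_fraction * n)`` (Python round-half-even,
    so n=75 gives 52 train / 23 test).  Returns
    ``(X_train, X_test, y_train, y_test, idx_train, idx_test)``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y have inconsistent sample counts")
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    idx_train, idx_test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return X[idx_train], X[idx_test], y[idx_train], y[idx_test], idx_train, idx_test


def evaluate(y_actual, y_pred) -> MetricReport:
    """MSE, MAE and R² = 1 - SS_res / SS_tot.

    R² is NaN when the actual values have zero variance.
    """
    ya = np.asarray(y_actual, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if ya.size != yp.size:
        raise ValueError("y_actual and y_pred must have equal length")
    if ya.size < 2:
        raise ValueError("need at least 2 observations")
    resid = ya - yp
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = np.nan if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return MetricReport(r2=r2, mse=mse, mae=mae)


def select_inputs(index_df: pd.DataFrame, y, threshold: float = 0.5
                  ) -> tuple[list[str], pd.DataFrame]:
    """Retain indices whose univariate r² with the trait is >= ``threshold``.

    Ordered by descending r², ties broken alphabetically; raises if nothing
    survives the threshold.
    """
    y = np.asarray(y, dtype=float)
    scores: dict[str, float] = {}
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    for name in index_df.columns:
        v = index_df[name].to_numpy(dtype=float)
        vc = v - v.mean()
        ss_v = float(vc @ vc)
        if not np.all(np.isfinite(v)) or ss_v == 0 or ss_y == 0:
            scores[name] = np.nan
            continue
        r = float(yc @ vc) / np.sqrt(ss_v * ss_y)
        scores[name] = r * r
    kept = [n for n, s in scores.items() if np.isfinite(s) and s >= threshold]
    kept.sort(key=lambda n: (-scores[n], n))
    if not kept:
        best = max((s for s in scores.values() if np.isfinite(s)), default=np.nan)
        raise ValueError(
            f"no index reaches r² >= {threshold} (best {best:.3f}); lower the threshold"
        )
    return kept, index_df[kept]


class SRIRegressor(RegressorMixin, BaseEstimator):
    """Grid-search cross-validated regressor over spectral-index features.

    A thin sklearn estimator around the family-specific protocol: exhaustive
    grid evaluation by k-fold CV mean MSE on the data passed to ``fit``,
    winner refit on the full data.

    Parameters
    ----------
    family : {"ann", "rf", "dt"}
    param_grid : dict, optional
        Hyperparameter grid; ``None`` uses :func:`default_grid`.
    cv : int
        Number of CV folds (default 5), shuffled with ``random_state``.
    random_state : int
        Seeds the learner and the fold assignment.

    Attributes
    ----------
    best_params_ : dict
        Winning hyperparameters (always a subset of the grid).
    best_estimator_ : fitted sklearn estimator
    cv_mse_ : float
        Mean CV MSE of the winner.
    """

    def __init__(self, family="rf", param_grid=None, cv=5, random_state=0):
        self.family = family
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def _base_estimator(self):
        family = self.family.lower()
        if family == "ann":
            mlp = MLPRegressor(random_state=self.random_state, **_ANN_FIXED)
            return Pipeline([("scale", StandardScaler()), ("mlp", mlp)]), "mlp__"
        if family == "rf":
            return RandomForestRegressor(random_state=self.random_state), ""
        if family == "dt":
            return DecisionTreeRegressor(random_state=self.random_state), ""
        raise ValueError(f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D and aligned with y")
        base, prefix = self._base_estimator()
        grid = self.param_grid if self.param_grid is not None else default_grid(self.family)
        grid = {f"{prefix}{k}": list(v) for k, v in grid.items()}
        if any(len(v) == 0 for v in grid.values()):
            raise ValueError("hyperparameter grid values must be non-empty")
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            base, grid, scoring="neg_mean_squared_error", cv=folds, n_jobs=None,
            refit=True, error_score="raise",
        )
        with warnings.catch_warnings():
            # SGD networks are run for a fixed iteration budget by design;
            # non-convergence at the cap is part of the protocol, not an error.
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            search.fit(X, y)
        self.search_ = search
        self.best_estimator_ = search.best_estimator_
        self.best_params_ = {
            k.removeprefix(prefix): v for k, v in search.best_params_.items()
        }
        self.cv_mse_ = float(-search.best_score_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if not hasattr(self, "best_estimator_"):
            raise ValueError("SRIRegressor is not fitted")
        return self.best_estimator_.predict(np.asarray(X, dtype=float))


def grid_search_fit(spec: ModelSpec, X_train, y_train, folds: int = 5,
                    seed: int = 0) -> SRIRegressor:
    """Exhaustive grid evaluation by ``folds``-fold CV mean MSE; lowest wins
    (deterministic tie-break by grid order); winner refit on all of train."""
    if np.asarray(X_train).shape[0] < folds:
        raise ValueError("training set smaller than the number of CV folds")
    reg = SRIRegressor(family=spec.family, param_grid=spec.hyper_grid, cv=folds,
                       random_state=seed)
    return reg.fit(X_train, y_train)


def run_trait_models(
    s: SpectraSet,
    t: TraitTable,
    trait: str,
    families: Sequence[str] = MODEL_FAMILIES,
    threshold: float = 0.5,
    seed: int = 0,
    train_fraction: float = 0.7,
    folds: int = 5,
    grids: Mapping[str, dict] | None = None,
    selection_on: str = "train",
) -> list[FitResult]:
    """End-to-end protocol for one trait: indices -> split -> select -> grid
    search per family -> metrics on both splits.

    ``selection_on`` controls whether the index threshold is applied on the
    training split only (``"train"``, leakage-safe default) or on all samples
    (``"all"``).
    """
    if not t.aligned_with(s):
        raise ValueError("spectra and trait table sample ids are not aligned")
    if selection_on not in ("train", "all"):
        raise ValueError("selection_on must be 'train' or 'all'")
    for fam in families:
        if fam.lower() not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {fam!r}; choose from {MODEL_FAMILIES}")
    idx_df = index_table(s)
    y = t.values(trait)
    X_all = idx_df.to_numpy(dtype=float)
    _, _, y_tr, y_te, itr, ite = split_data(X_all, y, train_fraction, seed)
    if selection_on == "train":
        names, _ = select_inputs(idx_df.iloc[itr], y_tr, threshold)
    else:
        names, _ = select_inputs(idx_df, y, threshold)
    X_sel = idx_df[names].to_numpy(dtype=float)
    X_tr, X_te = X_sel[itr], X_sel[ite]

    results: list[FitResult] = []
    for fam in families:
        fam = fam.lower()
        grid = None if grids is None else grids.get(fam)
        spec = ModelSpec(fam, dict(grid) if grid else {})
        reg = grid_search_fit(spec, X_tr, y_tr, folds=folds, seed=seed)
        results.append(FitResult(
            trait=trait,
            family=fam,
            input_names=list(names),
            best_params=dict(reg.best_params_),
            train=evaluate(y_tr, reg.predict(X_tr)),
            test=evaluate(y_te, reg.predict(X_te)),
            seed=seed,
            cv_mse=reg.cv_mse_,
        ))
    return results


def results_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Tabular report: one row per (trait, family) with inputs and metrics."""
    rows = []
    for r in results:
        rows.append({
            "trait": r.trait,
            "model": r.family.upper(),
            "inputs": "; ".join(r.input_names),
            "best_params": "; ".join(f"{k}={v}" for k, v in sorted(r.best_params.items())),
            "train_R2": r.train.r2, "train_MSE": r.train.mse, "train_MAE": r.train.mae,
            "test_R2": r.test.r2, "test_MSE": r.test.mse, "test_MAE": r.test.mae,
            "cv_MSE": r.cv_mse, "seed": r.seed,
        })
    return pd.DataFrame(rows)
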