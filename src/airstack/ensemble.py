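"""Super-learner ensemble: base learners, NNLS meta-learner, prediction.

The stacking scheme combines five base learners — random forest (RF),
extreme gradient boosting (XGB), light gradient boosting machine (LGBM),
and ridge/lasso as fast linear alternatives — through a non-negative
least squares (NNLS) meta-learner:

    f̂(x) = Σᵢ wᵢ fᵢ(x),   wᵢ ≥ 0

with the weights constant over space and time within a yearly model, no
intercept, and no sum-to-one constraint (an optional rescaling is
provided but off by default).  The weights are fitted on *out-of-fold*
(OOF) base predictions from a 10-fold monitor-blocked cross-validation,
so no base prediction used by the meta-learner was made by a model that
saw that monitor.

RF is not tuned: it uses conventional regression defaults (500 trees, a
third of the variables tried per split, minimum node size 5).  XGB and
LGBM (and the linear learners' penalties) are tuned by random search
over a configurable space, selecting the draw with the lowest blocked-CV
RMSE; ties break to the first draw.

Determinism: boosted-tree libraries are row-order sensitive, so every
fit first sorts the training rows canonically on (block id, target,
features); with fixed seeds the whole stage is then invariant to input
row permutations.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as scipy_nnls
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .evaluation import CVAssignment, make_folds
from .grids import GridDomain, RasterField

# lightgbm registers auto-generated column names even for ndarray input and
# sklearn then warns on every ndarray predict; purely cosmetic, columns align
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning)

__all__ = [
    "BaseLearnerSpec",
    "EnsembleWeights",
    "SuperLearner",
    "DEFAULT_SEARCH_SPACES",
    "tune_learner",
    "oof_predictions",
    "fit_meta_nnls",
    "fit_final",
    "crossvalidate_superlearner",
    "predict_grid",
    "variable_importance",
]

ALGORITHMS = ("RF", "XGB", "LGBM", "ridge", "lasso")

#: conventional regression defaults for the untuned random forest
RF_DEFAULTS = {"n_estimators": 500, "max_features": 1 / 3, "min_samples_leaf": 5}

DEFAULT_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "XGB": {
        "n_estimators": [100, 200, 300, 400],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "max_depth": [3, 5, 7, 9],
        "subsample": [0.7, 0.85, 1.0],
        "colsample_bytree": [0.7, 0.85, 1.0],
    },
    "LGBM": {
        "n_estimators": [100, 200, 300, 400],
        "learning_rate": [0.03, 0.05, 0.1, 0.2],
        "num_leaves": [15, 31, 63, 127],
        "min_child_samples": [5, 10, 20, 40],
        "subsample": [0.7, 0.85, 1.0],
    },
    "ridge": {"alpha": list(10.0 ** np.arange(-3, 4))},
    "lasso": {"alpha": list(10.0 ** np.arange(-4, 2))},
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner: algorithm, hyperparameters, seed."""

    algorithm: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.algorithm == "RF":
            params = {**RF_DEFAULTS, **hp}
            return RandomForestRegressor(random_state=self.seed, n_jobs=1, **params)
        if self.algorithm == "XGB":
            from xgboost import XGBRegressor
            params = {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 6,
                      "tree_method": "hist", **hp}
            return XGBRegressor(random_state=self.seed, n_jobs=1, verbosity=0, **params)
        if self.algorithm == "LGBM":
            from lightgbm import LGBMRegressor
            params = {"n_estimators": 200, "learning_rate": 0.1, "num_leaves": 31, **hp}
            return LGBMRegressor(random_state=self.seed, n_jobs=1, verbose=-1, **params)
        # linear learners are standardized internally
        if self.algorithm == "ridge":
            return make_pipeline(StandardScaler(), Ridge(alpha=hp.get("alpha", 1.0)))
        return make_pipeline(StandardScaler(),
                             Lasso(alpha=hp.get("alpha", 0.01), max_iter=10000))


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative meta-learner coefficients, constant across the domain."""

    labels: tuple[str, ...]
    weights: np.ndarray
    rss: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels),):
            raise ValueError("one weight per base learner required")
        if (w < 0).any():
            raise ValueError("ensemble weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def m(self) -> int:
        return len(self.labels)

    def combine(self, base_predictions: np.ndarray) -> np.ndarray:
        return np.asarray(base_predictions, dtype=float) @ self.weights

    def normalized(self) -> "EnsembleWeights":
        """Optional sum-to-one rescaling (off by default in the pipeline)."""
        s = self.weights.sum()
        if s == 0:
            return self
        return EnsembleWeights(self.labels, self.weights / s, self.rss)


def _canonical_sort(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray):
    """Row-permutation-invariant ordering: sort by (block, target, features)."""
    keys = [X[c].to_numpy(dtype=float) for c in reversed(list(X.columns))]
    keys += [np.asarray(y, dtype=float), np.asarray(groups).astype(str)]
    order = np.lexsort(keys)
    return X.iloc[order], np.asarray(y)[order], np.asarray(groups, dtype=object)[order], order


def _fit(spec: BaseLearnerSpec, X: pd.DataFrame, y: np.ndarray, groups: np.ndarray):
    Xs, ys, _, _ = _canonical_sort(X, y, groups)
    model = spec.build()
    model.fit(Xs.to_numpy(dtype=float), ys)
    return model


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def tune_learner(
    spec: BaseLearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    budget: int = 100,
    space: Mapping[str, list] | None = None,
    n_folds: int = 3,
    seed: int | None = None,
) -> tuple[BaseLearnerSpec, pd.DataFrame]:
    """Random hyperparameter search minimising blocked-CV RMSE.

    Draws ``budget`` configurations uniformly from ``space`` (defaults to
    the learner's entry in ``DEFAULT_SEARCH_SPACES``), scores each with a
    monitor-blocked CV, and returns the first-drawn argmin.  RF bypasses
    tuning and keeps its conventional defaults.
    """
    if budget < 1:
        raise ValueError("tuning budget must be >= 1")
    if spec.algorithm == "RF":
        log = pd.DataFrame([{"draw": 0, "params": dict(RF_DEFAULTS), "cv_rmse": np.nan,
                             "note": "RF uses fixed defaults; tuning bypassed"}])
        return spec, log
    space = dict(space if space is not None else DEFAULT_SEARCH_SPACES[spec.algorithm])
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    blocks = pd.unique(groups)
    folds = make_folds(list(blocks), n_folds=min(n_folds, len(blocks)),
                       seed=int(rng.integers(2 ** 31)))
    fold_of_row = folds.fold_of(groups)

    records = []
    best: tuple[float, BaseLearnerSpec] | None = None
    for draw in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in space.items()}
        cand = replace(spec, hyperparameters=params)
        pred = np.empty_like(y)
        for f in range(1, folds.n_folds + 1):
            test = fold_of_row == f
            model = _fit(cand, X[~test], y[~test], groups[~test])
            pred[test] = model.predict(X[test].to_numpy(dtype=float))
        score = _rmse(y, pred)
        records.append({"draw": draw, "params": params, "cv_rmse": score})
        if best is None or score < best[0]:  # strict: ties break to first draw
            best = (score, cand)
    return best[1], pd.DataFrame(records)


def _labels(specs: Sequence[BaseLearnerSpec]) -> list[str]:
    labels, seen = [], {}
    for s in specs:
        k = seen.get(s.algorithm, 0)
        labels.append(s.algorithm if k == 0 else f"{s.algorithm}_{k}")
        seen[s.algorithm] = k + 1
    return labels


def oof_predictions(
    specs: Sequence[BaseLearnerSpec],
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    folds: CVAssignment,
) -> pd.DataFrame:
    """Leakage-safe out-of-fold predictions of every base learner.

    Each row's prediction comes from the model trained with that row's
    entire block (monitor/cell) held out; every learner is fitted once
    per fold.  Returns a DataFrame aligned with ``X`` with one column per
    learner plus a ``fold`` column.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    missing = set(pd.unique(groups)) - set(folds.assignment)
    if missing:
        raise ValueError(f"blocks without a fold assignment: {sorted(map(str, missing))[:5]}")
    fold_of_row = folds.fold_of(groups)
    out = pd.DataFrame(index=X.index)
    out["fold"] = fold_of_row
    for spec, label in zip(specs, _labels(specs)):
        pred = np.empty(len(X))
        for f in range(1, folds.n_folds + 1):
            test = fold_of_row == f
            if not test.any():
                continue
            model = _fit(spec, X[~test], y[~test], groups[~test])
            pred[test] = model.predict(X[test].to_numpy(dtype=float))
        out[label] = pred
    return out


def fit_meta_nnls(oof: pd.DataFrame | np.ndarray, target: np.ndarray,
                  labels: Sequence[str] | None = None) -> EnsembleWeights:
    """Fit the NNLS meta-learner on out-of-fold base predictions.

    Minimises ‖y − Fw‖² subject to w ≥ 0, with no intercept.  Because
    every unit-weight vector is feasible, the fitted residual sum of
    squares never exceeds that of any single base learner.
    """
    if isinstance(oof, pd.DataFrame):
        cols = [c for c in oof.columns if c != "fold"]
        F = oof[cols].to_numpy(dtype=float)
        labels = labels or cols
    else:
        F = np.atleast_2d(np.asarray(oof, dtype=float))
        labels = list(labels) if labels is not None else [f"f{i}" for i in range(F.shape[1])]
    y = np.asarray(target, dtype=float)
    if F.shape[1] < 1:
        raise ValueError("need at least one base-learner column")
    if F.shape[0] != y.size:
        raise ValueError("prediction matrix and target length mismatch")
    if np.all(F == 0):
        warnings.warn("all base predictions are zero; returning all-zero weights")
        return EnsembleWeights(tuple(labels), np.zeros(F.shape[1]), float((y ** 2).sum()))
    w, rnorm = scipy_nnls(F, y)
    return EnsembleWeights(tuple(labels), w, float(rnorm ** 2))


@dataclass
class SuperLearner:
    """Base models fitted on all data plus the OOF-fitted NNLS weights."""

    specs: tuple[BaseLearnerSpec, ...]
    labels: tuple[str, ...]
    models: dict
    weights: EnsembleWeights
    feature_cols: tuple[str, ...]
    manifest: dict
    clip_count: int = 0

    def base_predictions(self, X: pd.DataFrame) -> np.ndarray:
        arr = X[list(self.feature_cols)].to_numpy(dtype=float)
        return np.column_stack([self.models[l].predict(arr) for l in self.labels])

    def predict(self, X: pd.DataFrame, floor_at_zero: bool = True) -> np.ndarray:
        yhat = self.weights.combine(self.base_predictions(X))
        if floor_at_zero:
            neg = yhat < 0
            self.clip_count += int(neg.sum())
            yhat = np.where(neg, 0.0, yhat)
        return yhat

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "SuperLearner":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def fit_final(
    specs: Sequence[BaseLearnerSpec],
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    folds: CVAssignment,
    oof: pd.DataFrame | None = None,
) -> SuperLearner:
    """Fit the deployable ensemble.

    Weights come from NNLS on pooled OOF predictions (computed here
    unless passed in); base models are then refitted on all rows.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = _labels(specs)
    if oof is None:
        oof = oof_predictions(specs, X, y, groups, folds)
    weights = fit_meta_nnls(oof[labels], y, labels=labels)
    models = {label: _fit(spec, X, y, groups) for spec, label in zip(specs, labels)}
    manifest = {
        "learners": [{"algorithm": s.algorithm, "hyperparameters": dict(s.hyperparameters),
                      "seed": s.seed} for s in specs],
        "labels": labels,
        "weights": [float(w) for w in weights.weights],
        "n_folds": folds.n_folds,
        "fold_seed": folds.seed,
        "feature_cols": list(X.columns),
        "n_train": int(len(X)),
    }
    return SuperLearner(specs=tuple(specs), labels=tuple(labels), models=models,
                        weights=weights, feature_cols=tuple(X.columns), manifest=manifest)


def crossvalidate_superlearner(
    specs: Sequence[BaseLearnerSpec],
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    folds: CVAssignment,
) -> dict:
    """Leakage-safe cross-validated predictions of base learners *and* the
    stacked ensemble.

    Base OOF predictions are computed once over the folds.  To score fold
    f, the NNLS weights are fitted on the OOF predictions of the other
    nine folds and applied to fold f's OOF predictions — no base or meta
    model scoring fold f ever saw fold f.

    Returns dict with keys ``oof`` (base OOF table), ``ensemble`` (CV
    ensemble predictions aligned with X), ``weights_by_fold``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = _labels(specs)
    oof = oof_predictions(specs, X, y, groups, folds)
    ens = np.empty(len(X))
    weights_by_fold = {}
    for f in range(1, folds.n_folds + 1):
        test = (oof["fold"] == f).to_numpy()
        w = fit_meta_nnls(oof.loc[~test, labels], y[~test], labels=labels)
        ens[test] = w.combine(oof.loc[test, labels].to_numpy(dtype=float))
        weights_by_fold[f] = w
    return {"oof": oof, "ensemble": ens, "weights_by_fold": weights_by_fold,
            "labels": labels}


def predict_grid(
    ensemble: SuperLearner,
    table: pd.DataFrame,
    grid: GridDomain,
    dates: pd.DatetimeIndex,
    floor_at_zero: bool = True,
) -> RasterField:
    """Predict concentrations on the full grid from a cell-day table.

    ``table`` needs columns ``cell`` (flat id) and ``date`` plus the
    training feature columns; negative combined predictions are floored
    at zero with a count kept on the ensemble.
    """
    missing = [c for c in ensemble.feature_cols if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table is missing feature columns: {missing}")
    yhat = ensemble.predict(table, floor_at_zero=floor_at_zero)
    dates = pd.DatetimeIndex(dates)
    values = np.full((len(dates), grid.ny, grid.nx), np.nan)
    ti = dates.get_indexer(pd.DatetimeIndex(table["date"]).normalize())
    iy, ix = grid.unflatten(table["cell"].to_numpy(np.int64))
    values[ti, iy, ix] = yhat
    return RasterField(grid, values, dates=dates, name="prediction", units="ug/m3")


def _importance(model, algorithm: str) -> np.ndarray:
    if algorithm in ("ridge", "lasso"):
        return np.abs(model[-1].coef_)  # coefficients on standardized features
    return np.asarray(model.feature_importances_, dtype=float)


def variable_importance(
    models_by_year: Mapping[int, Mapping[str, object]],
    feature_names: Sequence[str],
    algorithms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Proportional variable contributions, averaged across yearly models.

    Per learner: importances are normalised to sum 1 within each year,
    averaged across years, and renormalised.  Tree learners use impurity
    /gain importances; linear learners use |coefficient| on standardized
    features (i.e. |raw coefficient| × feature scale).  Output is sorted
    descending within learner.
    """
    rows = []
    learners = sorted({l for year in models_by_year.values() for l in year})
    for label in learners:
        algo = (algorithms or {}).get(label, label.split("_")[0])
        yearly = []
        for year, models in models_by_year.items():
            if label not in models:
                continue
            imp = _importance(models[label], algo)
            total = imp.sum()
            yearly.append(imp / total if total > 0 else imp)
        mean_imp = np.mean(yearly, axis=0)
        total = mean_imp.sum()
        if total > 0:
            mean_imp = mean_imp / total
        for name, v in zip(feature_names, mean_imp):
            rows.append({"learner": label, "feature": name, "proportion": float(v)})
    out = pd.DataFrame(rows)
    return out.sort_values(["learner", "proportion"], ascending=[True, False]).reset_index(drop=True)
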