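"""Kennard-Stone partitioning and the four regression model families.

The calibration/validation split uses the classical Kennard-Stone max-min
Euclidean-distance algorithm on the smoothed reflectance spectra.  Four
model families are supported, each tuned by grid search with 10-fold
cross-validated RMSE on the calibration set:

* RF   — random forest; grid over number of trees (100-2000) and number of
  candidate predictors per split (1-5);
* SVR  — linear-kernel support vector regression; penalty C over 2^-4..2^4,
  features and target standardized;
* DNN  — multilayer perceptron with ReLU activation, hidden layers
  400/600/500 and 1000 training epochs; the regularization strength is the
  tuned penalty;
* PLSR — partial least squares regression; component count by cross
  validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.compose import TransformedTargetRegressor
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .exceptions import DegenerateInputError, ParameterError

METHODS = ("RF", "SVR", "DNN", "PLSR")


@dataclass
class SplitResult:
    calibration_ids: list
    validation_ids: list

    @property
    def n_cal(self) -> int:
        return len(self.calibration_ids)


def kennard_stone_split(
    x: np.ndarray, n_cal: int, sample_ids: Optional[list] = None
) -> SplitResult:
    """Kennard-Stone selection of ``n_cal`` calibration samples.

    Seeds with the two samples at maximal Euclidean distance, then
    repeatedly adds the sample whose minimum distance to the selected set is
    maximal.  Ties break to the lower row index, making the split
    deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError("X must be 2-D")
    n = x.shape[0]
    if not 2 <= n_cal <= n:
        raise ParameterError(f"n_cal must lie in [2, {n}], got {n_cal}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("X contains non-finite values")
    if sample_ids is None:
        sample_ids = list(range(n))

    d = cdist(x, x)
    # argmax of the flattened matrix hits the lexicographically smallest
    # (row, col) among tied maxima
    a, b = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(a, b), max(a, b)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        min_dist[in_set] = -1.0
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, d[nxt])
    val = [i for i in range(n) if not in_set[i]]
    return SplitResult(
        [sample_ids[i] for i in selected],
        [sample_ids[i] for i in val],
    )


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------


def _default_grid(method: str) -> dict:
    if method == "RF":
        return {
            "n_estimators": [100, 500, 1000, 1500, 2000],
            "max_features": [1, 2, 3, 4, 5],
        }
    if method == "SVR":
        return {"C": [2.0**e for e in range(-4, 5)]}
    if method == "DNN":
        return {"alpha": [0.0, 1e-5, 1e-4], "hidden_layer_sizes": [(400, 600, 500)]}
    if method == "PLSR":
        return {"n_components": None}  # resolved against p and n_cal at fit time
    raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")


@dataclass
class ModelSpec:
    """One model family plus its hyperparameter grid and CV settings."""

    method: str
    grid: Optional[dict] = None
    cv_folds: int = 10
    seed: int = 0
    max_pls_components: int = 20
    dnn_max_iter: int = 1000

    def __post_init__(self):
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.grid is None:
            self.grid = _default_grid(self.method)


@dataclass
class FitResult:
    method: str
    best_params: dict
    pred_cal: np.ndarray
    pred_val: np.ndarray
    estimator: object = field(repr=False, default=None)


def _build(spec: ModelSpec, n_cal: int, p: int):
    """Estimator + grid-search parameter grid for one spec."""
    if spec.method == "RF":
        est = RandomForestRegressor(random_state=spec.seed, n_jobs=1)
        grid = {
            "n_estimators": list(spec.grid.get("n_estimators", [500])),
            "max_features": [m for m in spec.grid.get("max_features", [3]) if m <= p] or [p],
        }
        return est, grid
    if spec.method == "SVR":
        est = TransformedTargetRegressor(
            regressor=Pipeline(
                [("scale", StandardScaler()), ("svr", SVR(kernel="linear"))]
            ),
            transformer=StandardScaler(),
        )
        grid = {"regressor__svr__C": list(spec.grid["C"])}
        return est, grid
    if spec.method == "DNN":
        est = TransformedTargetRegressor(
            regressor=Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPRegressor(
                            activation="relu",
                            max_iter=spec.dnn_max_iter,
                            random_state=spec.seed,
                            early_stopping=False,
                        ),
                    ),
                ]
            ),
            transformer=StandardScaler(),
        )
        grid = {
            "regressor__mlp__alpha": list(spec.grid.get("alpha", [1e-4])),
            "regressor__mlp__hidden_layer_sizes": list(
                spec.grid.get("hidden_layer_sizes", [(400, 600, 500)])
            ),
        }
        return est, grid
    # PLSR
    est = PLSRegression(scale=True)
    comps = spec.grid.get("n_components")
    if comps is None:
        hi = max(1, min(spec.max_pls_components, p, n_cal - n_cal // spec.cv_folds - 1))
        comps = list(range(1, hi + 1))
    grid = {"n_components": list(comps)}
    return est, grid


def fit_predict_model(
    spec: ModelSpec, x_cal: np.ndarray, y_cal: np.ndarray, x_val: np.ndarray
) -> FitResult:
    """Grid-search (10-fold CV RMSE) on the calibration set, refit, predict.

    Deterministic for a fixed spec and seed: folds are unshuffled and all
    stochastic estimators are seeded.
    """
    x_cal = np.asarray(x_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    x_val = np.asarray(x_val, dtype=float)
    if x_cal.shape[0] != y_cal.size:
        raise ParameterError("X_cal and y_cal are not aligned")
    if x_cal.shape[0] < spec.cv_folds:
        raise ParameterError("need at least cv_folds calibration samples")
    if np.var(y_cal) == 0:
        raise DegenerateInputError("calibration target has zero variance")

    est, grid = _build(spec, x_cal.shape[0], x_cal.shape[1])
    search = GridSearchCV(
        est,
        grid,
        scoring="neg_root_mean_squared_error",
        cv=KFold(n_splits=spec.cv_folds, shuffle=False),
        n_jobs=1,
        refit=True,
    )
    search.fit(x_cal, y_cal)
    pred_cal = np.asarray(search.predict(x_cal), dtype=float).ravel()
    pred_val = (
        np.asarray(search.predict(x_val), dtype=float).ravel()
        if x_val.shape[0]
        else np.empty(0)
    )
    return FitResult(spec.method, dict(search.best_params_), pred_cal, pred_val, search)
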