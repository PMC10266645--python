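"""Competitive adaptive reweighted sampling (CARS) for band selection.

Each Monte Carlo run fits a PLS model on a random calibration subsample,
weights the currently retained bands by the absolute value of their PLS
regression coefficients, then shrinks the retained set twice:

1. *forced selection* — keep the top ``ceil(edf_ratio(i) * p)`` bands, where
   the exponentially decaying retention schedule runs from 1 (all bands,
   run 1) down to 2/p (two bands, final run);
2. *adaptive reweighted sampling* — draw bands with replacement with
   probability proportional to weight and retain the distinct picks.

After each run the retained subset is scored by k-fold cross-validated RMSE
(RMSECV) over all calibration samples; the subset with the minimum RMSECV
wins (earliest run on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .exceptions import ParameterError


@dataclass
class CARSConfig:
    """Monte Carlo schedule and PLS settings for one CARS execution."""

    n_runs: int = 50
    mc_sample_ratio: float = 0.8
    cv_folds: int = 10
    max_pls_components: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ParameterError("n_runs must be >= 2")
        if not 0.0 < self.mc_sample_ratio < 1.0:
            raise ParameterError("mc_sample_ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.max_pls_components < 1:
            raise ParameterError("max_pls_components must be >= 1")


@dataclass
class CARSResult:
    retained_ratio_trace: list
    subset_trace: list  # per run: ndarray of retained wavelengths (nm)
    rmsecv_trace: list  # g/kg
    best_run: int  # 0-based index into the traces
    best_bands_nm: np.ndarray
    n_components_trace: list = field(default_factory=list)

    @property
    def n_completed_runs(self) -> int:
        return len(self.rmsecv_trace)


def edf_ratio(run_index: int, n_runs: int, n_bands: int) -> float:
    """Exponential damping function: retention ratio at run ``run_index``.

    ratio(i) = exp(-k (i - 1)) with k = ln(p/2) / (N - 1), so ratio(1) = 1
    and ratio(N) = 2/p.
    """
    if n_bands < 2:
        raise ParameterError("need at least 2 bands")
    if n_runs < 2:
        raise ParameterError("n_runs must be >= 2")
    if not 1 <= run_index <= n_runs:
        raise ParameterError(f"run_index {run_index} outside 1..{n_runs}")
    k = math.log(n_bands / 2.0) / (n_runs - 1)
    return math.exp(-k * (run_index - 1))


def _fit_pls(x: np.ndarray, y: np.ndarray, n_comp: int) -> PLSRegression:
    m = PLSRegression(n_components=n_comp, scale=True)
    m.fit(x, y)
    return m


def _max_components(cap: int, n: int, p: int) -> int:
    return max(1, min(cap, p, n - 1))


def rmsecv(
    x: np.ndarray, y: np.ndarray, cv_folds: int, max_components: int
) -> tuple[float, int]:
    """Minimum k-fold cross-validated RMSE of PLS over component counts.

    One PLS fit per fold covers every component count: NIPALS components are
    extracted greedily, so the K-component coefficient vector is the partial
    sum of the rank-one terms of a larger fit.  Returns (rmse, n_components);
    ties go to the fewest components.
    """
    n, p = x.shape
    folds = min(cv_folds, n)
    cmax = _max_components(max_components, n - n // folds, p)
    sse = np.zeros(cmax)
    counts = np.zeros(cmax)
    for tr, te in KFold(n_splits=folds, shuffle=False).split(x):
        mu_x = x[tr].mean(axis=0)
        sd_x = x[tr].std(axis=0)
        sd_x[sd_x == 0] = 1.0
        mu_y, sd_y = y[tr].mean(), y[tr].std() or 1.0
        c = _max_components(cmax, len(tr), p)
        m = PLSRegression(n_components=c, scale=False)
        m.fit((x[tr] - mu_x) / sd_x, (y[tr] - mu_y) / sd_y)
        scores = ((x[te] - mu_x) / sd_x) @ m.x_rotations_
        preds = np.cumsum(scores * m.y_loadings_.ravel()[:c], axis=1) * sd_y + mu_y
        sse[:c] += ((y[te][:, None] - preds) ** 2).sum(axis=0)
        counts[:c] += len(te)
    with np.errstate(invalid="ignore", divide="ignore"):
        errs = np.sqrt(sse / counts)
    best = int(np.nanargmin(errs))  # argmin ties -> fewest components
    return float(errs[best]), best + 1


def run_cars(
    x: np.ndarray,
    y: np.ndarray,
    cfg: CARSConfig,
    wavelengths_nm: np.ndarray | None = None,
) -> CARSResult:
    """Run CARS on a calibration matrix; fully reproducible given cfg.seed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if len(y) != n:
        raise ParameterError("X and y are not aligned")
    if p < 3:
        raise ParameterError("CARS needs at least 3 bands")
    if n < cfg.cv_folds:
        raise ParameterError("fewer samples than cv_folds")
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(p)
    wavelengths_nm = np.asarray(wavelengths_nm)
    if wavelengths_nm.size != p:
        raise ParameterError("wavelengths do not match the band count")

    rng = np.random.default_rng(cfg.seed)
    n_sub = math.ceil(cfg.mc_sample_ratio * n)
    retained = np.arange(p)

    ratios, subsets, errors, comps = [], [], [], []
    for i in range(1, cfg.n_runs + 1):
        if retained.size < 2:
            break  # run failure: traces stay truncated at the last good run
        ratio = edf_ratio(i, cfg.n_runs, p)
        sub = rng.choice(n, size=n_sub, replace=False)

        # PLS on the Monte Carlo subsample; components by inner CV, capped
        xs, ys = x[np.sort(sub)][:, retained], y[np.sort(sub)]
        _, n_comp = rmsecv(xs, ys, min(5, cfg.cv_folds), cfg.max_pls_components)
        weights = np.abs(_fit_pls(xs, ys, n_comp).coef_).ravel()

        # forced selection by the damping schedule
        n_keep = min(retained.size, math.ceil(ratio * p))
        top = np.argsort(-weights, kind="stable")[:n_keep]
        forced = retained[np.sort(top)]
        w = weights[np.sort(top)]

        # adaptive reweighted sampling: p weighted draws with replacement
        # (canonical draw count = the full band count, constant across runs)
        if w.sum() <= 0:
            w = np.ones_like(w)
        picks = rng.choice(forced, size=p, replace=True, p=w / w.sum())
        retained = np.unique(picks)
        if retained.size < 2:
            break

        err, c_full = rmsecv(x[:, retained], y, cfg.cv_folds, cfg.max_pls_components)
        ratios.append(ratio)
        subsets.append(wavelengths_nm[retained].copy())
        errors.append(err)
        comps.append(c_full)

    if not errors:
        raise ParameterError("CARS retained fewer than 2 bands before any run completed")
    best = int(np.argmin(errors))  # first minimum on ties
    return CARSResult(
        retained_ratio_trace=ratios,
        subset_trace=subsets,
        rmsecv_trace=errors,
        best_run=best,
        best_bands_nm=subsets[best],
        n_components_trace=comps,
    )
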