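"""Model evaluation: R², RMSE, RPD and Lin's concordance (LCCC).

Conventions follow the standard chemometrics usage: R² = 1 - SSE/SST and
RMSE uses the divisor ``n``, while the standard deviations inside RPD and
LCCC are sample standard deviations (divisor ``n - 1``).  RPD classes are
the Chang thresholds: < 1.4 poor, 1.4-2.0 moderate, > 2.0 high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import DegenerateInputError, ParameterError


def r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    """R² = 1 - Σ(o - p)² / Σ(o - ō)²."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DegenerateInputError("observed values have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    """Root mean square error with divisor n (g/kg)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    return math.sqrt(float(np.mean((obs - pred) ** 2)))


def rpd(obs: np.ndarray, pred: np.ndarray) -> float:
    """Ratio of performance to deviation: sd(obs, ddof=1) / RMSE."""
    e = rmse(obs, pred)
    so = float(np.std(np.asarray(obs, dtype=float), ddof=1))
    if e == 0:
        return math.inf
    return so / e


def lccc(obs: np.ndarray, pred: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    Covariance form 2 s_op / (s_o² + s_p² + (ō - p̄)²) with ddof=1, which is
    identically 2 r s_o s_p / (...) and is 0 when predictions are constant.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    so2 = float(np.var(obs, ddof=1))
    sp2 = float(np.var(pred, ddof=1))
    sop = float(np.cov(obs, pred, ddof=1)[0, 1])
    denom = so2 + sp2 + (obs.mean() - pred.mean()) ** 2
    if denom == 0:
        return 1.0  # both series constant and identical
    return 2.0 * sop / denom


def rpd_class(value: float) -> str:
    """Chang class of an RPD value: poor (<1.4), moderate (1.4-2.0), high (>2)."""
    if not value > 0:
        raise ParameterError("RPD must be positive")
    if value < 1.4:
        return "poor"
    if value <= 2.0:
        return "moderate"
    return "high"


@dataclass
class EvalReport:
    """One table row of model accuracy (calibration + validation metrics)."""

    r2_val: float
    rmse_val: float
    rpd: float
    lccc: float
    rpd_class: str
    r2_cal: Optional[float] = None
    rmse_cal: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "r2_cal": self.r2_cal,
            "rmse_cal": self.rmse_cal,
            "r2_val": self.r2_val,
            "rmse_val": self.rmse_val,
            "rpd": self.rpd,
            "lccc": self.lccc,
            "rpd_class": self.rpd_class,
        }


def evaluate_predictions(
    obs: np.ndarray,
    pred: np.ndarray,
    obs_cal: Optional[np.ndarray] = None,
    pred_cal: Optional[np.ndarray] = None,
) -> EvalReport:
    """Full accuracy report; RPD and LCCC are computed on the validation set."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ParameterError("obs and pred must be aligned 1-D vectors")
    if obs.size < 2:
        raise ParameterError("need at least 2 observations")
    r2v = r_squared(obs, pred)
    rmsev = rmse(obs, pred)
    rpdv = rpd(obs, pred)
    report = EvalReport(
        r2_val=r2v,
        rmse_val=rmsev,
        rpd=rpdv,
        lccc=lccc(obs, pred),
        rpd_class=rpd_class(rpdv) if math.isfinite(rpdv) else "high",
    )
    if obs_cal is not None and pred_cal is not None:
        report.r2_cal = r_squared(obs_cal, pred_cal)
        report.rmse_cal = rmse(obs_cal, pred_cal)
    return report
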