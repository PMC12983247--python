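"""Prediction metrics and a ridge-regression linear baseline.

R-squared is, by default, the squared Pearson correlation between predicted
and observed phenotypes — the convention under which a linear predictor's
R2 is bounded by the trait's heritability — with the coefficient-of-
determination form (1 - SSres/SStot) available via ``r2_definition``.
Both are always computed and stored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge

__all__ = ["Metrics", "compute_metrics", "ridge_baseline"]


@dataclass(frozen=True)
class Metrics:
    """Prediction-quality summary for one (trait, environment, split)."""

    R2: float          # per the configured definition
    PCC: float         # Pearson correlation
    MAE: float         # trait units
    NMSE: float        # MSE / Var(y)
    RRMSE: float       # RMSE / mean(y)
    MAPE: float        # percent, zero-observation samples excluded
    R2_pearson: float  # squared Pearson (always)
    R2_cod: float      # 1 - SSres/SStot (always)

    def as_rows(self, trait: str = "trait", environment: str = "E1",
                split: str = "test") -> list[tuple]:
        return [(trait, environment, split, k, getattr(self, k))
                for k in ("R2", "PCC", "MAE", "NMSE", "RRMSE", "MAPE")]


def compute_metrics(y: np.ndarray, yhat: np.ndarray,
                    r2_definition: str = "pearson") -> Metrics:
    """Compute R2, PCC, MAE, NMSE, RRMSE and MAPE for one prediction vector.

    A constant observed or predicted vector makes the Pearson correlation
    undefined; it is reported as 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if y.size < 2:
        raise ValueError("metrics need at least 2 observations")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise ValueError("non-finite values in metric inputs")
    if r2_definition not in ("pearson", "cod"):
        raise ValueError("r2_definition must be 'pearson' or 'cod'")

    resid = y - yhat
    mae = float(np.abs(resid).mean())
    mse = float((resid ** 2).mean())
    var_y = float(np.var(y))

    if np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("constant vector: Pearson correlation undefined, "
                      "reported as 0")
        pcc = 0.0
    else:
        pcc = float(stats.pearsonr(y, yhat)[0])

    r2_pearson = pcc * pcc
    r2_cod = 1.0 - mse / var_y if var_y > 0 else 0.0
    nmse = mse / var_y if var_y > 0 else np.inf
    mean_y = float(y.mean())
    rrmse = np.sqrt(mse) / mean_y if mean_y != 0 else np.inf
    nz = y != 0
    mape = float((np.abs(resid[nz]) / np.abs(y[nz])).mean() * 100.0) \
        if nz.any() else np.inf

    return Metrics(
        R2=r2_pearson if r2_definition == "pearson" else r2_cod,
        PCC=pcc, MAE=mae, NMSE=float(nmse), RRMSE=float(rrmse),
        MAPE=mape, R2_pearson=float(r2_pearson), R2_cod=float(r2_cod))


def ridge_baseline(X_train: np.ndarray, y_train: np.ndarray,
                   X_test: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Closed-form ridge regression on encoded genotypes, with intercept.

    Serves as the linear oracle: a trait whose genetic variance is purely
    epistatic gives this baseline essentially no signal, so beating it
    demonstrates nonlinearity capture.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if alpha == 0 and X_train.shape[1] >= X_train.shape[0]:
        raise np.linalg.LinAlgError(
            "alpha = 0 with p >= n gives a singular system")
    model = Ridge(alpha=alpha, solver="cholesky" if alpha > 0 else "svd")
    model.fit(X_train, np.asarray(y_train, dtype=float))
    return model.predict(X_test)
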