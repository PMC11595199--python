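"""Training, cross-validation and external validation statistics.

All quantities are kept at full precision internally; :meth:`ValidationReport.rounded`
gives the conventional 3-decimal display form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ValidationReport",
    "adjusted_r2",
    "f_statistic",
    "training_stats",
    "q2_loo",
    "rmsecv_lmo",
    "external_stats",
]

#: ``fit(X, y)`` returns a ``predict(X) -> y_hat`` callable.
FitProcedure = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class ValidationReport:
    """Container for every statistic reported per model."""

    r2: float = math.nan
    r2_adj: float = math.nan
    f_value: float = math.nan
    q2_loo: float = math.nan
    rmsecv: float = math.nan
    q2_f1: float = math.nan
    q2_f2: float = math.nan
    rmsep: float = math.nan
    r2_ext: float = math.nan
    n_train: int = 0
    n_test: int = 0
    n_params: int = 0

    def rounded(self, ndigits: int = 3) -> dict[str, float | int]:
        out: dict[str, float | int] = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = round(v, ndigits) if isinstance(v, float) else v
        return out


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    """R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n - n_params - 1 <= 0:
        raise ValidationError("need n > n_params + 1 for adjusted R2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def f_statistic(r2: float, n: int, n_params: int) -> float:
    """F = [R²/(1 − R²)] · [(n − p − 1)/p]; +inf at R² = 1."""
    if n_params < 1:
        raise ValidationError("n_params must be >= 1")
    if r2 >= 1.0:
        return math.inf
    return (r2 / (1.0 - r2)) * ((n - n_params - 1) / n_params)


def training_stats(
    y: Sequence[float], y_hat: Sequence[float], n_params: int
) -> tuple[float, float, float]:
    """(R², R²_adj, F) of a fit with ``n_params`` descriptors or latent variables."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError("y and y_hat must have equal length")
    n = y.size
    if n < n_params + 2:
        raise ValidationError(f"need n >= n_params + 2, got n={n}, p={n_params}")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("zero response variance")
    rss = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - rss / tss
    return r2, adjusted_r2(r2, n, n_params), f_statistic(r2, n, n_params)


def q2_loo(
    fit_procedure: FitProcedure, X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Leave-one-out Q² and PRESS by explicit per-row refitting.

    For each row the model is refit on the remaining rows and used to predict
    the held-out row; Q² = 1 − PRESS/TSS with TSS about the full-train mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValidationError("need at least 3 rows for LOO cross-validation")
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            predict = fit_procedure(X[keep], y[keep])
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise ValidationError(f"LOO refit failed on fold {i}: {exc}") from exc
        pred = float(np.asarray(predict(X[i : i + 1]))[0])
        press += (y[i] - pred) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("zero response variance")
    return 1.0 - press / tss, press


def rmsecv_lmo(
    fit_procedure: FitProcedure,
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 8,
    seed: int = 1,
) -> float:
    """Root mean squared held-out error pooled over seeded k-fold splits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    if n < k_folds:
        raise ValidationError("need at least k_folds rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sq_errors = np.empty(n)
    for fold in np.array_split(order, k_folds):
        keep = np.setdiff1d(np.arange(n), fold)
        predict = fit_procedure(X[keep], y[keep])
        sq_errors[fold] = (y[fold] - np.asarray(predict(X[fold]))) ** 2
    return float(np.sqrt(sq_errors.mean()))


def external_stats(
    y_test: Sequence[float],
    y_hat_test: Sequence[float],
    y_train_mean: float,
) -> tuple[float, float, float, float]:
    """(Q²_F1, Q²_F2, RMSEP, R²_ext) for an external test set.

    Q²_F1 scales prediction error by scatter about the training mean, Q²_F2 by
    scatter about the test mean; R²_ext is the squared Pearson correlation of
    observed and predicted values.
    """
    y = np.asarray(y_test, dtype=float)
    y_hat = np.asarray(y_hat_test, dtype=float)
    if y.shape != y_hat.shape:
        raise ValidationError("y_test and y_hat_test must have equal length")
    n = y.size
    if n < 2:
        raise ValidationError("need at least 2 test compounds")
    sse = float(np.sum((y - y_hat) ** 2))
    ss_train = float(np.sum((y - y_train_mean) ** 2))
    ss_test = float(np.sum((y - y.mean()) ** 2))
    if ss_test == 0.0:
        raise ValidationError("zero test response variance: Q2_F2 undefined")
    q2_f1 = 1.0 - sse / ss_train if ss_train > 0 else -math.inf
    q2_f2 = 1.0 - sse / ss_test
    rmsep = math.sqrt(sse / n)
    if float(np.std(y_hat)) == 0.0:
        r2_ext = 0.0
    else:
        r2_ext = float(np.corrcoef(y, y_hat)[0, 1]) ** 2
    return q2_f1, q2_f2, rmsep, r2_ext
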