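"""Model-building machinery: OLS, forward stepwise selection, NIPALS PLS with
VIP-based iterative variable reduction, and exhaustive best-subset search.

All entry points take the descriptor block as a pandas DataFrame so that
selections can be reported by name. Fits are deterministic for fixed input.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RankError, ValidationError
from .model_bank import LinearModel
from .validation_metrics import q2_loo, training_stats

__all__ = [
    "PLSModel",
    "SelectionTrace",
    "OLSFit",
    "StepwiseFit",
    "SubsetCandidate",
    "drop_collinear",
    "fit_ols",
    "ols_fit_procedure",
    "press_loo_ols",
    "forward_stepwise",
    "pls_fit",
    "vip",
    "vip_reduce",
    "best_subset",
]

#: |Pearson r| above which two columns are treated as the same variable.
COLLINEARITY_R = 0.99
#: Variance below which a column counts as constant.
ZERO_VARIANCE_TOL = 1e-12


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])


def drop_collinear(
    X: pd.DataFrame,
    r_threshold: float = COLLINEARITY_R,
    var_tol: float = ZERO_VARIANCE_TOL,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove zero-variance columns and near-duplicates (|r| > threshold).

    Of each correlated group only the first-listed column survives. Returns
    the reduced frame and the dropped names.
    """
    X = _as_frame(X)
    dropped: list[str] = []
    keep: list[str] = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if float(np.var(col)) <= var_tol:
            dropped.append(name)
            continue
        redundant = False
        for prev in keep:
            r = float(np.corrcoef(X[prev].to_numpy(dtype=float), col)[0, 1])
            if abs(r) > r_threshold:
                redundant = True
                break
        if redundant:
            dropped.append(name)
        else:
            keep.append(name)
    return X[keep], dropped


# ---------------------------------------------------------------------------
# Ordinary least squares


@dataclass
class OLSFit:
    model: LinearModel
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    r2_adj: float
    f_value: float
    names: list[str]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.model.coefficients[n] for n in self.names])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(_as_frame(X)[self.names] if isinstance(X, pd.DataFrame) else X,
                       dtype=float)
        return self.model.intercept + X @ self.coefficients


def _solve_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients (intercept first) of the least-squares fit."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def _name_collinear(X: pd.DataFrame) -> str:
    culprits = []
    cols = list(X.columns)
    for name in cols:
        if float(np.var(X[name].to_numpy(dtype=float))) <= ZERO_VARIANCE_TOL:
            culprits.append(name)
    corr = X.corr().to_numpy()
    for i, j in itertools.combinations(range(len(cols)), 2):
        if abs(corr[i, j]) > 0.9999:
            culprits.extend([cols[i], cols[j]])
    return ", ".join(dict.fromkeys(culprits)) or "unidentified columns"


def fit_ols(X, y, model_id: str = "ols") -> OLSFit:
    """Least-squares linear fit with training statistics.

    Requires n > p + 1 and a full-rank design; a rank-deficient design raises
    :class:`RankError` naming the collinear columns.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, p = Xf.shape
    if n <= p + 1:
        raise ValidationError(f"need n > n_descriptors + 1 (n={n}, p={p})")
    A = np.column_stack([np.ones(n), Xf.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise RankError(f"rank-deficient design; collinear: {_name_collinear(Xf)}")
    beta = _solve_ols(Xf.to_numpy(dtype=float), y)
    fitted = A @ beta
    r2, r2_adj, f_value = training_stats(y, fitted, p)
    model = LinearModel(
        model_id=model_id,
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(Xf.columns, beta[1:])},
        model_family="MLR",
    )
    return OLSFit(model, fitted, y - fitted, r2, r2_adj, f_value, list(Xf.columns))


def ols_fit_procedure(X, y):
    """OLS as a :data:`~plperm.validation_metrics.FitProcedure` (for CV)."""
    beta = _solve_ols(np.asarray(X, dtype=float), np.asarray(y, dtype=float))

    def predict(Xnew):
        Xnew = np.asarray(Xnew, dtype=float)
        return beta[0] + Xnew @ beta[1:]

    return predict


def press_loo_ols(X: np.ndarray, y: np.ndarray) -> float:
    """Exact LOO PRESS of OLS from one fit, via e_i / (1 - h_ii)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # hat diagonal via the economy QR of the design
    q, _ = np.linalg.qr(A)
    h = np.sum(q * q, axis=1)
    loo_resid = resid / (1.0 - h)
    return float(np.sum(loo_resid ** 2))


# ---------------------------------------------------------------------------
# Forward stepwise selection


@dataclass
class StepwiseFit:
    model: LinearModel | None
    entry_order: list[str]
    empty: bool = False  # warning flag: nothing qualified at step 1
    fit: OLSFit | None = None


def forward_stepwise(
    X,
    y,
    p_enter: float = 0.05,
    max_terms: int | None = None,
) -> StepwiseFit:
    """Greedy forward selection on the partial-F p-value.

    At each step the candidate with the smallest p-value below ``p_enter``
    enters (ties broken by lowest column index); selection stops when no
    candidate qualifies or ``max_terms`` is reached. If nothing qualifies at
    step 1 an empty model is returned with the ``empty`` flag set.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_terms is None:
        max_terms = Xf.shape[1]
    selected: list[str] = []
    rss_current = float(np.sum((y - y.mean()) ** 2))
    while len(selected) < max_terms:
        best_name, best_p, best_rss = None, None, None
        p_new = len(selected) + 1
        df_resid = n - p_new - 1
        if df_resid < 1:
            break
        for name in Xf.columns:
            if name in selected:
                continue
            Xc = Xf[selected + [name]].to_numpy(dtype=float)
            A = np.column_stack([np.ones(n), Xc])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                continue  # candidate collinear with current model
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ beta) ** 2))
            if rss >= rss_current:
                pval = 1.0
            else:
                f_part = (rss_current - rss) / (rss / df_resid)
                pval = float(stats.f.sf(f_part, 1, df_resid))
            if best_p is None or pval < best_p - 1e-15:
                best_name, best_p, best_rss = name, pval, rss
        if best_name is None or best_p >= p_enter:
            break
        selected.append(best_name)
        rss_current = best_rss
    if not selected:
        return StepwiseFit(model=None, entry_order=[], empty=True)
    fit = fit_ols(Xf[selected], y, model_id="stepwise")
    return StepwiseFit(model=fit.model, entry_order=selected, fit=fit)


# ---------------------------------------------------------------------------
# NIPALS PLS and VIP reduction


@dataclass
class PLSModel:
    """Univariate-response PLS fit (NIPALS, auto-scaled X and y)."""

    n_latent: int
    feature_names: list[str]
    x_weights: np.ndarray  # (p, a), unit-norm per component
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    x_scores: np.ndarray  # (n, a) training scores
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    coef_: np.ndarray = field(default=None)  # original-scale slopes
    intercept_: float = 0.0

    def predict(self, X) -> np.ndarray:
        X = np.asarray(_as_frame(X)[self.feature_names]
                       if isinstance(X, pd.DataFrame) else X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def as_linear_model(self, model_id: str = "pls") -> LinearModel:
        return LinearModel(
            model_id=model_id,
            intercept=float(self.intercept_),
            coefficients={n: float(c) for n, c in
                          zip(self.feature_names, self.coef_)},
            model_family="q-RASAR-PLS",
        )


def pls_fit(X, y, n_latent: int) -> PLSModel:
    """NIPALS PLS with auto-scaling of X and y.

    With a single response the NIPALS inner loop converges in one pass per
    component, so the fit is exactly deterministic.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, p = Xf.shape
    if not 1 <= n_latent <= p:
        raise ValidationError(f"n_latent must be in [1, {p}], got {n_latent}")
    Xv = Xf.to_numpy(dtype=float)
    x_mean = Xv.mean(axis=0)
    x_sd = Xv.std(axis=0, ddof=1)
    if np.any(x_sd <= 0):
        bad = [Xf.columns[j] for j in np.flatnonzero(x_sd <= 0)]
        raise ValidationError(f"zero-variance column(s): {', '.join(map(str, bad))}")
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd <= 0:
        raise ValidationError("zero response variance")
    E = (Xv - x_mean) / x_sd
    f = (y - y_mean) / y_sd

    if n_latent > np.linalg.matrix_rank(E):
        raise ValidationError("n_latent exceeds rank of auto-scaled X")

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    Q = np.zeros(n_latent)
    T = np.zeros((n, n_latent))
    for a in range(n_latent):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError(
                f"response fully explained before component {a + 1}"
            )
        w /= norm
        t = E @ w
        tt = float(t @ t)
        pvec = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, qa, t

    # equivalent regression vector on the auto-scaled space
    B = W @ np.linalg.solve(P.T @ W, Q)
    coef = y_sd * B / x_sd
    intercept = y_mean - float(coef @ x_mean)
    return PLSModel(
        n_latent=n_latent,
        feature_names=list(Xf.columns),
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        coef_=coef,
        intercept_=intercept,
    )


def vip(model: PLSModel) -> np.ndarray:
    """Variable Importance in Projection; satisfies mean(VIP²) = 1."""
    ss = model.y_loadings ** 2 * np.sum(model.x_scores ** 2, axis=0)  # per-LV SSY
    p = len(model.feature_names)
    w2 = model.x_weights ** 2  # weights are unit-norm per component
    return np.sqrt(p * (w2 @ ss) / ss.sum())


@dataclass
class SelectionTrace:
    iterations: list[tuple[list[str], np.ndarray]]
    stopping_reason: str  # all_vip_ge_1 | max_iter | floor_reached


def vip_reduce(
    X,
    y,
    n_latent: int = 2,
    vip_floor: float = 1.0,
    max_iter: int = 50,
) -> tuple[SelectionTrace, list[str]]:
    """Iterative PLS/VIP variable reduction.

    Each round fits a PLS model, computes VIP and drops every descriptor with
    VIP < ``vip_floor``, repeating until no descriptor is dropped (or the
    iteration cap is hit). Columns should already be cleaned of zero-variance
    and near-collinear members (see :func:`drop_collinear`).
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    retained = list(Xf.columns)
    iterations: list[tuple[list[str], np.ndarray]] = []
    reason = "max_iter"
    for _ in range(max_iter):
        a = min(n_latent, len(retained))
        model = pls_fit(Xf[retained], y, a)
        scores = vip(model)
        iterations.append((list(retained), scores))
        keep = [name for name, v in zip(retained, scores) if v >= vip_floor]
        if not keep:
            raise ValidationError(
                "VIP reduction dropped every descriptor; lower vip_floor"
            )
        if len(keep) == len(retained):
            reason = "all_vip_ge_1"
            retained = keep
            break
        retained = keep
    return SelectionTrace(iterations, reason), retained


# ---------------------------------------------------------------------------
# Best-subset search


@dataclass
class SubsetCandidate:
    names: tuple[str, ...]
    q2_loo: float
    press: float
    fit: OLSFit


def best_subset(
    X,
    y,
    max_size: int,
    criterion: str = "q2_loo",
    guard_limit: int = 200_000,
) -> list[SubsetCandidate]:
    """Exhaustive subset enumeration ranked by LOO Q² (descending).

    Enumerates every descriptor combination of size 1..max_size, fits OLS and
    scores it by Q²_LOO (computed from the exact single-fit PRESS identity).
    Ties are broken lexicographically on the name tuple, making the ranking
    deterministic.
    """
    if criterion != "q2_loo":
        raise ValidationError(f"unsupported criterion {criterion!r}")
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    names = list(Xf.columns)
    n = len(y)
    total = sum(math.comb(len(names), k) for k in range(1, max_size + 1))
    if total > guard_limit:
        raise ValidationError(
            f"{total} candidate subsets exceeds guard limit {guard_limit}; "
            "reduce the pool or max_size"
        )
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("zero response variance")
    candidates: list[SubsetCandidate] = []
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(names, k):
            if n <= k + 1:
                continue
            Xc = Xf[list(combo)]
            A = np.column_stack([np.ones(n), Xc.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                continue
            press = press_loo_ols(Xc.to_numpy(dtype=float), y)
            q2 = 1.0 - press / tss
            candidates.append(
                SubsetCandidate(combo, q2, press, fit_ols(Xc, y, "subset"))
            )
    candidates.sort(key=lambda c: (-c.q2_loo, c.names))
    return candidates
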