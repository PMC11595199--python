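"""Similarity-based Read-Across prediction and q-RASAR model assembly.

A query compound's response is predicted as the similarity-weighted mean of
the responses of its ``n_close`` most similar source (training) compounds.
Distances are Euclidean on auto-scaled descriptors; three kernels turn a
distance into a similarity in (0, 1]:

* ``euclidean``:  s = 1 / (1 + d)
* ``gaussian``:   s = exp(−d² / (2σ²))
* ``laplacian``:  s = exp(−d / γ)

The same close-compound neighborhood yields the similarity/concordance
descriptors (RA function, Avg_Sim, SD_Sim, MaxPos, MaxNeg, gm) that are fused
with conventional descriptors to build q-RASAR models. ``gm`` is implemented
as the binary concordance indicator ``max_pos >= max_neg`` — an operational
stand-in, since no closed definition of the reference tool's quantity is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import Dataset
from .errors import ApplicabilityError, ValidationError
from .regression_engine import (
    PLSModel,
    SubsetCandidate,
    best_subset,
    drop_collinear,
    pls_fit,
)
from .validation_metrics import (
    ValidationReport,
    external_stats,
    q2_loo,
    rmsecv_lmo,
    training_stats,
)

__all__ = [
    "SimilarityConfig",
    "RASARFeatures",
    "ReadAcrossModel",
    "similarity",
    "ra_predict",
    "default_grid",
    "optimize_hyperparameters",
    "compute_rasar_descriptors",
    "build_qrasar",
    "QRASARResult",
    "RASAR_FEATURE_NAMES",
]

KERNELS = ("euclidean", "gaussian", "laplacian")
RASAR_FEATURE_NAMES = ["RA_function", "Avg_Sim", "SD_Sim", "MaxPos", "MaxNeg", "gm"]


@dataclass(frozen=True)
class SimilarityConfig:
    """Kernel choice plus its width parameter and neighborhood size."""

    kernel: str = "gaussian"
    sigma: float | None = 1.0
    gamma: float | None = 1.0
    n_close: int = 5

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValidationError(
                f"unknown kernel {self.kernel!r}; choose from {KERNELS}"
            )
        if self.kernel == "gaussian" and not (self.sigma and self.sigma > 0):
            raise ValidationError("gaussian kernel needs sigma > 0")
        if self.kernel == "laplacian" and not (self.gamma and self.gamma > 0):
            raise ValidationError("laplacian kernel needs gamma > 0")
        if self.n_close < 1:
            raise ValidationError("n_close must be >= 1")


@dataclass
class RASARFeatures:
    """Similarity-derived descriptors of one query compound."""

    ra_function: float  # similarity-weighted predicted response (log FM)
    avg_sim: float
    sd_sim: float
    max_pos: float  # max similarity to a higher-response close source
    max_neg: float  # max similarity to a lower-response close source
    gm: int  # 1 iff max_pos >= max_neg
    close_ids: list[str]
    close_similarities: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {
            "RA_function": self.ra_function,
            "Avg_Sim": self.avg_sim,
            "SD_Sim": self.sd_sim,
            "MaxPos": self.max_pos,
            "MaxNeg": self.max_neg,
            "gm": float(self.gm),
        }


def _kernel_similarity(d: np.ndarray, config: SimilarityConfig) -> np.ndarray:
    if config.kernel == "euclidean":
        return 1.0 / (1.0 + d)
    if config.kernel == "gaussian":
        return np.exp(-(d ** 2) / (2.0 * config.sigma ** 2))
    return np.exp(-d / config.gamma)


def similarity(a: Sequence[float], b: Sequence[float], config: SimilarityConfig) -> float:
    """Kernel similarity of two (already auto-scaled) descriptor vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have the same length")
    d = float(np.linalg.norm(a - b))
    return float(_kernel_similarity(np.asarray(d), config))


class ReadAcrossModel:
    """Source set + auto-scaling + kernel config, ready to predict queries.

    Source compounds are split at their response median into higher- and
    lower-response members (ties to the lower half), which MaxPos/MaxNeg and
    gm refer to. ``exclude_id`` enables leave-self-out feature computation
    for training compounds.
    """

    def __init__(
        self,
        source_ids: Sequence[str],
        source_X: np.ndarray,
        source_y: Sequence[float],
        config: SimilarityConfig,
    ) -> None:
        self.ids = [str(i) for i in source_ids]
        X = np.asarray(source_X, dtype=float)
        y = np.asarray(source_y, dtype=float)
        if len(self.ids) != len(y) or X.shape[0] != len(y):
            raise ValidationError("sources: ids, X and y lengths must agree")
        if config.n_close > len(y):
            raise ValidationError(
                f"n_close={config.n_close} exceeds source count {len(y)}"
            )
        self.config = config
        self.y = y
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValidationError("zero-variance descriptor among sources")
        self.x_sd = sd
        self.X_scaled = (X - self.x_mean) / self.x_sd
        self.higher = y > float(np.median(y))

    def scale(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def _close_set(self, query_scaled: np.ndarray, exclude_id: str | None):
        mask = np.ones(len(self.ids), dtype=bool)
        if exclude_id is not None and exclude_id in self.ids:
            mask[self.ids.index(exclude_id)] = False
        if mask.sum() < self.config.n_close:
            raise ValidationError("not enough sources after self-exclusion")
        d = np.linalg.norm(self.X_scaled[mask] - query_scaled, axis=1)
        sims = _kernel_similarity(d, self.config)
        idx_all = np.flatnonzero(mask)
        # highest similarity first; ties by lexicographically lower id
        order = sorted(
            range(len(sims)), key=lambda i: (-sims[i], self.ids[idx_all[i]])
        )
        chosen = [idx_all[i] for i in order[: self.config.n_close]]
        chosen_sims = np.array([sims[i] for i in order[: self.config.n_close]])
        if not np.any(chosen_sims > 0):
            raise ApplicabilityError(
                "all similarities are numerically zero; query outside "
                "applicability domain"
            )
        return chosen, chosen_sims

    def predict_one(
        self, query: Sequence[float], exclude_id: str | None = None
    ) -> tuple[float, list[str], np.ndarray]:
        """Similarity-weighted mean response over the close set."""
        q = self.scale(np.asarray(query, dtype=float))
        chosen, sims = self._close_set(q, exclude_id)
        pred = float(np.sum(sims * self.y[chosen]) / np.sum(sims))
        return pred, [self.ids[i] for i in chosen], sims

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(row)[0] for row in np.asarray(X, dtype=float)])

    def features_one(
        self, query: Sequence[float], exclude_id: str | None = None
    ) -> RASARFeatures:
        q = self.scale(np.asarray(query, dtype=float))
        chosen, sims = self._close_set(q, exclude_id)
        ra = float(np.sum(sims * self.y[chosen]) / np.sum(sims))
        pos_sims = [s for i, s in zip(chosen, sims) if self.higher[i]]
        neg_sims = [s for i, s in zip(chosen, sims) if not self.higher[i]]
        max_pos = max(pos_sims) if pos_sims else 0.0
        max_neg = max(neg_sims) if neg_sims else 0.0
        return RASARFeatures(
            ra_function=ra,
            avg_sim=float(sims.mean()),
            sd_sim=float(sims.std(ddof=0)),
            max_pos=float(max_pos),
            max_neg=float(max_neg),
            gm=1 if max_pos >= max_neg else 0,
            close_ids=[self.ids[i] for i in chosen],
            close_similarities=sims,
        )


def ra_predict(
    query: Sequence[float],
    source_ids: Sequence[str],
    source_X: np.ndarray,
    source_y: Sequence[float],
    config: SimilarityConfig,
) -> tuple[float, list[str], np.ndarray]:
    """One-shot Read-Across prediction; see :class:`ReadAcrossModel`."""
    model = ReadAcrossModel(source_ids, source_X, source_y, config)
    return model.predict_one(query)


def compute_rasar_descriptors(
    query: Sequence[float],
    source_ids: Sequence[str],
    source_X: np.ndarray,
    source_y: Sequence[float],
    config: SimilarityConfig,
) -> RASARFeatures:
    """One-shot RASAR feature computation; see :class:`ReadAcrossModel`."""
    model = ReadAcrossModel(source_ids, source_X, source_y, config)
    return model.features_one(query)


def default_grid(
    widths: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    n_close_values: Sequence[int] = tuple(range(2, 9)),
) -> list[SimilarityConfig]:
    """Small bounded lattice over kernels, widths and neighborhood sizes."""
    grid: list[SimilarityConfig] = []
    for n_close in n_close_values:
        grid.append(SimilarityConfig("euclidean", n_close=n_close))
        for w in widths:
            grid.append(SimilarityConfig("gaussian", sigma=w, n_close=n_close))
        for w in widths:
            grid.append(SimilarityConfig("laplacian", gamma=w, n_close=n_close))
    return grid


def optimize_hyperparameters(
    train_ids: Sequence[str],
    train_X: np.ndarray,
    train_y: Sequence[float],
    grid: Sequence[SimilarityConfig] | None = None,
    split_fraction: float = 0.75,
    seed: int = 1,
) -> tuple[SimilarityConfig, pd.DataFrame]:
    """Grid search over similarity configs on a seeded sub-train/validation split.

    Scores each config by the RMSE of Read-Across predictions for the held-out
    validation compounds (sub-training compounds as sources); returns the
    minimizer (ties go to the earlier grid entry) plus the full grid report.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise ValidationError("hyperparameter grid is empty")
    X = np.asarray(train_X, dtype=float)
    y = np.asarray(train_y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_sub = int(round(split_fraction * n))
    if n_sub < 5:
        raise ValidationError("sub-training set must have at least 5 compounds")
    if n_sub >= n:
        raise ValidationError("validation set is empty; lower split_fraction")
    sub, val = order[:n_sub], order[n_sub:]
    sub_ids = [str(train_ids[i]) for i in sub]

    rows = []
    best: tuple[float, int] | None = None
    for g, config in enumerate(grid):
        if config.n_close > n_sub:
            rows.append({**_config_row(config), "rmse": math.nan, "feasible": False})
            continue
        model = ReadAcrossModel(sub_ids, X[sub], y[sub], config)
        try:
            preds = model.predict(X[val])
        except ApplicabilityError:
            rows.append({**_config_row(config), "rmse": math.nan, "feasible": False})
            continue
        rmse = float(np.sqrt(np.mean((y[val] - preds) ** 2)))
        rows.append({**_config_row(config), "rmse": rmse, "feasible": True})
        if best is None or rmse < best[0] - 1e-15:
            best = (rmse, g)
    if best is None:
        raise ValidationError("no feasible grid point")
    return grid[best[1]], pd.DataFrame(rows)


def _config_row(config: SimilarityConfig) -> dict:
    return {
        "kernel": config.kernel,
        "sigma": config.sigma if config.kernel == "gaussian" else math.nan,
        "gamma": config.gamma if config.kernel == "laplacian" else math.nan,
        "n_close": config.n_close,
    }


@dataclass
class QRASARResult:
    selected: list[str]
    pls_model: PLSModel
    report: ValidationReport
    fused_train: pd.DataFrame
    fused_test: pd.DataFrame
    candidates: list[SubsetCandidate]
    config: SimilarityConfig


def rasar_feature_table(
    model: ReadAcrossModel,
    ids: Sequence[str],
    X: np.ndarray,
    leave_self_out: bool = False,
) -> pd.DataFrame:
    """RASAR features for a block of compounds as a DataFrame."""
    rows = []
    for cid, row in zip(ids, np.asarray(X, dtype=float)):
        feats = model.features_one(row, exclude_id=cid if leave_self_out else None)
        rows.append(feats.as_dict())
    return pd.DataFrame(rows, index=pd.Index([str(i) for i in ids], name="id"))


def build_qrasar(
    dataset: Dataset,
    qsar_descriptors: Sequence[str],
    config: SimilarityConfig,
    max_size: int = 5,
    n_latent: int = 2,
    seed: int = 1,
) -> QRASARResult:
    """Assemble a q-RASAR PLS model from a dataset and an optimized config.

    RASAR features are computed for every train compound leave-self-out (so
    no row informs its own features) and for test compounds against the full
    training source set. The fused pool (QSAR descriptors + RASAR features)
    is reduced by best-subset search on Q²_LOO, and a PLS model with
    ``n_latent`` components is fit on the winning subset.
    """
    qsar_descriptors = list(qsar_descriptors)
    train_ids = dataset.ids("train")
    X_train = dataset.X("train", qsar_descriptors)
    y_train = dataset.y("train")
    ra_model = ReadAcrossModel(train_ids, X_train, y_train, config)

    fused_train = pd.concat(
        [
            pd.DataFrame(X_train, index=pd.Index(train_ids, name="id"),
                         columns=qsar_descriptors),
            rasar_feature_table(ra_model, train_ids, X_train, leave_self_out=True),
        ],
        axis=1,
    )
    test_ids = dataset.ids("test")
    if test_ids:
        X_test = dataset.X("test", qsar_descriptors)
        fused_test = pd.concat(
            [
                pd.DataFrame(X_test, index=pd.Index(test_ids, name="id"),
                             columns=qsar_descriptors),
                rasar_feature_table(ra_model, test_ids, X_test),
            ],
            axis=1,
        )
    else:
        fused_test = fused_train.iloc[:0]

    pool, _dropped = drop_collinear(fused_train)
    candidates = best_subset(pool, y_train, max_size=max_size)
    if not candidates:
        raise ValidationError("best-subset search produced no candidate")
    selected = list(candidates[0].names)
    if n_latent > len(selected):
        raise ValidationError(
            f"n_latent={n_latent} exceeds selected descriptor count {len(selected)}"
        )
    pls = pls_fit(fused_train[selected], y_train, n_latent)

    report = ValidationReport(n_train=len(y_train), n_test=len(test_ids),
                              n_params=n_latent)
    fitted = pls.predict(fused_train[selected])
    report.r2, report.r2_adj, report.f_value = training_stats(
        y_train, fitted, n_latent
    )

    def pls_procedure(Xa, ya):
        m = pls_fit(Xa, ya, min(n_latent, Xa.shape[1]))
        return m.predict

    Xsel = fused_train[selected].to_numpy(dtype=float)
    report.q2_loo, _press = q2_loo(pls_procedure, Xsel, y_train)
    report.rmsecv = rmsecv_lmo(pls_procedure, Xsel, y_train, k_folds=8, seed=seed)
    if test_ids:
        y_test = dataset.y("test")
        y_hat = pls.predict(fused_test[selected])
        report.q2_f1, report.q2_f2, report.rmsep, report.r2_ext = external_stats(
            y_test, y_hat, float(np.mean(y_train))
        )
    return QRASARResult(
        selected=selected,
        pls_model=pls,
        report=report,
        fused_train=fused_train,
        fused_test=fused_test,
        candidates=candidates,
        config=config,
    )
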