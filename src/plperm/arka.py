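"""Supervised reduction of a descriptor set into two group-wise aggregates.

The training compounds are split at the response median into a
higher-response and a lower-response half. Each (min-max scaled) descriptor
joins group 1 if its mean scaled value is larger in the higher-response half,
else group 2. A compound's ARKA1/ARKA2 values are the means of its scaled
group-1/group-2 descriptors. Compounds whose two aggregates carry the same
sign (after optional mean-centering) sit in the first or third quadrant of
the ARKA plane and are flagged as less-confident predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ScalingParams",
    "ARKAFeatures",
    "scale_minmax",
    "assign_groups",
    "compute_arka",
    "confidence_quadrants",
    "arka_features",
]

GROUP1 = "group1"
GROUP2 = "group2"
CONFIDENT = "confident"
LESS_CONFIDENT = "less_confident"


@dataclass
class ScalingParams:
    """Per-descriptor training min and max used by the [0,1] mapping."""

    names: list[str]
    minima: np.ndarray
    maxima: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.minima) / (
            self.maxima - self.minima
        )


@dataclass
class ARKAFeatures:
    compound_ids: list[str]
    arka1: np.ndarray
    arka2: np.ndarray
    group_assignment: dict[str, str]
    scaling: ScalingParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ARKA1": self.arka1, "ARKA2": self.arka2},
            index=pd.Index(self.compound_ids, name="id"),
        )


def scale_minmax(
    train_X: np.ndarray,
    apply_X: np.ndarray | None = None,
    names: list[str] | None = None,
) -> tuple[np.ndarray, ScalingParams]:
    """Map training columns to [0,1]; apply the training params elsewhere.

    Values of ``apply_X`` transformed with training minima/maxima may fall
    outside [0,1]; no clipping happens.
    """
    train_X = np.asarray(train_X, dtype=float)
    if names is None:
        names = [f"x{j + 1}" for j in range(train_X.shape[1])]
    minima = train_X.min(axis=0)
    maxima = train_X.max(axis=0)
    degenerate = np.flatnonzero(maxima <= minima)
    if degenerate.size:
        raise ValidationError(
            f"degenerate (constant) column(s): "
            f"{', '.join(names[j] for j in degenerate)}"
        )
    params = ScalingParams(list(names), minima, maxima)
    target = train_X if apply_X is None else np.asarray(apply_X, dtype=float)
    return params.transform(target), params


def assign_groups(
    scaled_train: np.ndarray,
    y: np.ndarray,
    names: list[str],
    split_rule: str = "median",
    split_value: float | None = None,
) -> dict[str, str]:
    """Assign each descriptor to group 1 or group 2 by response contrast.

    The training set is split at the response median (ties go to the
    lower-response half); a descriptor joins group 1 iff its mean scaled
    value among higher-response compounds strictly exceeds that among
    lower-response compounds. ``split_rule="threshold"`` with an explicit
    ``split_value`` (e.g. log10 of the FM class cutoff) is available as a
    config option.
    """
    scaled_train = np.asarray(scaled_train, dtype=float)
    y = np.asarray(y, dtype=float)
    if split_rule == "median":
        cut = float(np.median(y))
    elif split_rule == "threshold":
        if split_value is None:
            raise ValidationError("threshold split needs split_value")
        cut = float(split_value)
    else:
        raise ValidationError(f"unknown split_rule {split_rule!r}")
    high = y > cut
    low = ~high
    if high.sum() < 2 or low.sum() < 2:
        raise ValidationError(
            "need at least 2 compounds on each side of the response split"
        )
    assignment = {}
    for j, name in enumerate(names):
        mean_high = float(scaled_train[high, j].mean())
        mean_low = float(scaled_train[low, j].mean())
        assignment[name] = GROUP1 if mean_high > mean_low else GROUP2
    return assignment


def compute_arka(
    scaled_X: np.ndarray,
    group_assignment: dict[str, str],
    names: list[str],
    compound_ids: list[str],
    scaling: ScalingParams | None = None,
) -> ARKAFeatures:
    """Per-compound group means of the scaled descriptors.

    An empty group yields 0 for the corresponding aggregate (with a warning);
    screening runs must not crash on degenerate assignments.
    """
    scaled_X = np.asarray(scaled_X, dtype=float)
    missing = [n for n in names if n not in group_assignment]
    if missing:
        raise ValidationError(f"no group assignment for: {', '.join(missing)}")
    idx1 = [j for j, n in enumerate(names) if group_assignment[n] == GROUP1]
    idx2 = [j for j, n in enumerate(names) if group_assignment[n] == GROUP2]
    n = scaled_X.shape[0]

    def group_mean(idx: list[int], label: str) -> np.ndarray:
        if not idx:
            warnings.warn(f"{label} is empty; aggregate set to 0", stacklevel=2)
            return np.zeros(n)
        return scaled_X[:, idx].mean(axis=1)

    return ARKAFeatures(
        compound_ids=list(compound_ids),
        arka1=group_mean(idx1, GROUP1),
        arka2=group_mean(idx2, GROUP2),
        group_assignment=dict(group_assignment),
        scaling=scaling,
    )


def confidence_quadrants(
    arka1: np.ndarray, arka2: np.ndarray
) -> list[str]:
    """Label compounds by ARKA-plane quadrant.

    ``less_confident`` iff both coordinates are strictly positive or both
    strictly negative (first/third quadrant); points on an axis are
    ``confident``.
    """
    arka1 = np.asarray(arka1, dtype=float)
    arka2 = np.asarray(arka2, dtype=float)
    if not (np.all(np.isfinite(arka1)) and np.all(np.isfinite(arka2))):
        raise ValidationError("ARKA values must be finite")
    labels = []
    for a1, a2 in zip(arka1, arka2):
        same_sign = (a1 > 0 and a2 > 0) or (a1 < 0 and a2 < 0)
        labels.append(LESS_CONFIDENT if same_sign else CONFIDENT)
    return labels


def arka_features(
    train_X: np.ndarray,
    train_y: np.ndarray,
    names: list[str],
    train_ids: list[str],
    apply_X: np.ndarray | None = None,
    apply_ids: list[str] | None = None,
    split_rule: str = "median",
    split_value: float | None = None,
    center: bool = True,
) -> tuple[ARKAFeatures, ARKAFeatures | None, list[str]]:
    """End-to-end ARKA computation: scale, group, aggregate, label quadrants.

    ``center=True`` mean-centers the aggregates by their training means before
    quadrant labeling, so all four quadrants of the ARKA plane are populated
    (raw min-max aggregates are non-negative). Returns (train features,
    apply features or None, train quadrant labels).
    """
    scaled_train, params = scale_minmax(train_X, names=names)
    assignment = assign_groups(
        scaled_train, train_y, names, split_rule=split_rule, split_value=split_value
    )
    feats_train = compute_arka(scaled_train, assignment, names, train_ids, params)
    feats_apply = None
    if apply_X is not None:
        scaled_apply = params.transform(apply_X)
        feats_apply = compute_arka(
            scaled_apply, assignment, names,
            apply_ids or [str(i) for i in range(len(scaled_apply))], params,
        )
    if center:
        c1 = float(feats_train.arka1.mean())
        c2 = float(feats_train.arka2.mean())
        labels = confidence_quadrants(feats_train.arka1 - c1, feats_train.arka2 - c2)
    else:
        labels = confidence_quadrants(feats_train.arka1, feats_train.arka2)
    return feats_train, feats_apply, labels
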