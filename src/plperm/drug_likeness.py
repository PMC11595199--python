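"""Absorption / drug-likeness rule filters and their relation to permeability.

Eight filter variants are evaluated from descriptor values:

* ``lipinski_mordred`` — M_w <= 500, MLOGP <= 4.15, HA <= 10, HD <= 5;
  strict (no violation allowed).
* ``lipinski_swiss``   — same sub-rules with cLogP <= 5 as the lipophilicity
  bound; up to one violation allowed.
* ``veber``            — TPSA <= 140, FRB <= 10.
* ``ghose_mordred``    — 160 <= M_w <= 480, −0.4 <= WLOGP <= 5.6,
  40 <= MR <= 130, 20 <= Atoms <= 70; strict.
* ``ghose_swiss``      — same bounds, up to one violation allowed.
* ``palm``             — TPSA <= 140.
* ``egan``             — TPSA <= 131.6, WLOGP < 5.88 (exclusive bound).
* ``muegge``           — 200 <= M_w <= 600, −2 <= XLOGP <= 5, Rings <= 7,
  Carbons > 4, Heteroatoms > 1, FRB <= 15, HA <= 10.

Variant tolerances for the Lipinski/Ghose pairs are fixed (strict vs
allow-one); the ``tolerance`` argument governs the single-source filters.
A filter whose input columns are absent is reported as not-evaluable
(``None``), never as failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError

__all__ = [
    "FilterVerdict",
    "FILTER_NAMES",
    "evaluate_filters",
    "permeability_filter_matrix",
    "cluster_filter_profiles",
    "ClusterResult",
]

FILTER_NAMES = [
    "lipinski_mordred",
    "lipinski_swiss",
    "veber",
    "ghose_mordred",
    "ghose_swiss",
    "palm",
    "egan",
    "muegge",
]

STRICT = "strict"
ALLOW_ONE = "allow_one"


@dataclass
class FilterVerdict:
    """Pass/fail per filter (None = not evaluable) plus Lipinski diagnostics."""

    passes: dict[str, bool | None]
    lipinski_violations: int | None
    violation_tolerance: str

    def as_row(self) -> dict[str, bool | None]:
        return dict(self.passes)


def _violations(row: Mapping[str, float], rules) -> int | None:
    """Count violated sub-rules; None if any input column is missing."""
    count = 0
    for column, check in rules:
        if column not in row:
            return None
        value = float(row[column])
        if not check(value):
            count += 1
    return count


def evaluate_filters(
    row: Mapping[str, float], tolerance: str = STRICT
) -> FilterVerdict:
    """Evaluate all eight filters on one compound's descriptor values.

    ``row`` maps descriptor names (M_w, MLOGP, cLogP, WLOGP, XLOGP, HA, HD,
    FRB, TPSA, MR, Atoms, Rings, Carbons, Heteroatoms) to values.
    """
    if tolerance not in (STRICT, ALLOW_ONE):
        raise ValidationError(f"unknown tolerance {tolerance!r}")

    lipinski_mordred_rules = [
        ("M_w", lambda v: v <= 500),
        ("MLOGP", lambda v: v <= 4.15),
        ("HA", lambda v: v <= 10),
        ("HD", lambda v: v <= 5),
    ]
    lipinski_swiss_rules = [
        ("M_w", lambda v: v <= 500),
        ("cLogP", lambda v: v <= 5),
        ("HA", lambda v: v <= 10),
        ("HD", lambda v: v <= 5),
    ]
    veber_rules = [
        ("TPSA", lambda v: v <= 140),
        ("FRB", lambda v: v <= 10),
    ]
    ghose_rules = [
        ("M_w", lambda v: 160 <= v <= 480),
        ("WLOGP", lambda v: -0.4 <= v <= 5.6),
        ("MR", lambda v: 40 <= v <= 130),
        ("Atoms", lambda v: 20 <= v <= 70),
    ]
    palm_rules = [("TPSA", lambda v: v <= 140)]
    egan_rules = [
        ("TPSA", lambda v: v <= 131.6),
        ("WLOGP", lambda v: v < 5.88),  # exclusive, as published
    ]
    muegge_rules = [
        ("M_w", lambda v: 200 <= v <= 600),
        ("XLOGP", lambda v: -2 <= v <= 5),
        ("Rings", lambda v: v <= 7),
        ("Carbons", lambda v: v > 4),
        ("Heteroatoms", lambda v: v > 1),
        ("FRB", lambda v: v <= 15),
        ("HA", lambda v: v <= 10),
    ]

    def verdict(violations: int | None, allowed: int) -> bool | None:
        if violations is None:
            return None
        return violations <= allowed

    general_allowed = 0 if tolerance == STRICT else 1
    lip_mordred = _violations(row, lipinski_mordred_rules)
    passes = {
        "lipinski_mordred": verdict(lip_mordred, 0),
        "lipinski_swiss": verdict(_violations(row, lipinski_swiss_rules), 1),
        "veber": verdict(_violations(row, veber_rules), general_allowed),
        "ghose_mordred": verdict(_violations(row, ghose_rules), 0),
        "ghose_swiss": verdict(_violations(row, ghose_rules), 1),
        "palm": verdict(_violations(row, palm_rules), 0),
        "egan": verdict(_violations(row, egan_rules), general_allowed),
        "muegge": verdict(_violations(row, muegge_rules), general_allowed),
    }
    return FilterVerdict(
        passes=passes,
        lipinski_violations=lip_mordred,
        violation_tolerance=tolerance,
    )


def permeability_filter_matrix(
    verdicts: Sequence[FilterVerdict],
    pl_calls: Sequence[int | str],
    compound_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary compounds × (filters + PL) matrix for cluster analysis.

    ``pl_calls`` accepts 0/1 or "PL0"/"PL1". Filters that are not evaluable
    for any compound are dropped column-wise with a warning.
    """
    if not verdicts:
        raise ValidationError("no verdicts supplied")
    if len(verdicts) != len(pl_calls):
        raise ValidationError("verdicts and pl_calls lengths differ")
    pl = []
    for call in pl_calls:
        if isinstance(call, str):
            pl.append(1 if call == "PL1" else 0)
        else:
            pl.append(int(call))
    ids = (
        [str(i) for i in compound_ids]
        if compound_ids is not None
        else [str(i) for i in range(len(verdicts))]
    )
    columns = {}
    for name in FILTER_NAMES:
        values = [v.passes.get(name) for v in verdicts]
        if any(value is None for value in values):
            warnings.warn(
                f"filter {name!r} not evaluable for all compounds; dropped",
                stacklevel=2,
            )
            continue
        columns[name] = [int(bool(value)) for value in values]
    columns["PL"] = pl
    return pd.DataFrame(columns, index=pd.Index(ids, name="id"))


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    column_order: list[str]  # dendrogram leaf order
    columns: list[str]
    pl_nearest: str  # filter merging with PL at the smallest height
    distance: str
    linkage: str
    warnings: list[str] = field(default_factory=list)


def cluster_filter_profiles(
    matrix: pd.DataFrame,
    linkage: str = "complete",
    distance: str = "jaccard",
) -> ClusterResult:
    """Agglomerative clustering of the binary filter/PL columns.

    Clusters the columns of a :func:`permeability_filter_matrix` output and
    reports which filter column first joins the cluster containing ``PL``.
    ``distance`` is ``jaccard`` or ``matching`` (simple matching distance).
    """
    if linkage not in ("single", "complete", "average"):
        raise ValidationError(f"unknown linkage {linkage!r}")
    if distance not in ("jaccard", "matching"):
        raise ValidationError(f"unknown distance {distance!r}")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 columns to cluster")
    notes: list[str] = []
    data = matrix.to_numpy(dtype=float).T  # observations = columns
    metric = "jaccard" if distance == "jaccard" else "hamming"
    if distance == "jaccard" and np.any(data.sum(axis=1) == 0):
        notes.append(
            "all-zero column under jaccard distance; falling back to matching"
        )
        warnings.warn(notes[-1], stacklevel=2)
        metric = "hamming"
    condensed = pdist(data, metric=metric)
    Z = hierarchy.linkage(condensed, method=linkage)
    columns = list(matrix.columns)
    leaf_order = [columns[i] for i in hierarchy.leaves_list(Z)]
    pl_nearest = _first_merge_partner(Z, columns, columns.index("PL"))
    return ClusterResult(
        linkage_matrix=Z,
        column_order=leaf_order,
        columns=columns,
        pl_nearest=pl_nearest,
        distance=distance,
        linkage=linkage,
        warnings=notes,
    )


def _first_merge_partner(Z: np.ndarray, columns: list[str], leaf: int) -> str:
    """Name of the first-listed column merging with ``leaf``'s cluster first."""
    n = len(columns)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (a, b, _h, _c) in enumerate(Z):
        a, b = int(a), int(b)
        new = n + k
        members[new] = members[a] | members[b]
        if leaf in members[a] or leaf in members[b]:
            own, other = (a, b) if leaf in members[a] else (b, a)
            partner_leaves = sorted(members[other])
            return columns[partner_leaves[0]]
    raise ValidationError("linkage matrix does not merge the PL column")
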