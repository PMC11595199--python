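"""Descriptor-table and dataset I/O.

Tables are delimited text (default comma, UTF-8, ``.`` decimal mark) with a
header row; the first column holds compound identifiers, every other column a
numeric molecular descriptor. Missing values are hard errors — no imputation
happens anywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "DescriptorTable",
    "Dataset",
    "read_descriptor_table",
    "make_dataset",
    "write_predictions",
]

ROLE_TRAIN = "train"
ROLE_TEST = "test"
ROLE_SCREEN = "screen"


@dataclass
class DescriptorTable:
    """Compound-by-descriptor numeric matrix with string identifiers.

    Rows are compounds, columns are named descriptors. All values must be
    finite; ids and descriptor names must be unique. Ids are case-sensitive
    opaque strings.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1:
            raise ValidationError("descriptor table must have at least one row")
        if n != len(self.compound_ids):
            raise ValidationError(
                f"{len(self.compound_ids)} ids but {n} value rows"
            )
        if p != len(self.descriptor_names):
            raise ValidationError(
                f"{len(self.descriptor_names)} descriptor names but {p} value columns"
            )
        if any(not c for c in self.compound_ids):
            raise ValidationError("empty compound identifier")
        dup = _first_duplicate(self.compound_ids)
        if dup is not None:
            raise ValidationError(f"duplicate compound id {dup!r}")
        dup = _first_duplicate(self.descriptor_names)
        if dup is not None:
            raise ValidationError(f"duplicate descriptor name {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for compound {self.compound_ids[i]!r}, "
                f"descriptor {self.descriptor_names[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"descriptor column {name!r} not present") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        """Column-subset preserving the requested order."""
        idx = []
        for name in names:
            if name not in self.descriptor_names:
                raise KeyError(f"descriptor column {name!r} not present")
            idx.append(self.descriptor_names.index(name))
        return DescriptorTable(
            list(self.compound_ids), list(names), self.values[:, idx].copy()
        )

    def row(self, compound_id: str) -> dict[str, float]:
        try:
            i = self.compound_ids.index(compound_id)
        except ValueError:
            raise KeyError(f"compound {compound_id!r} not present") from None
        return dict(zip(self.descriptor_names, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.compound_ids, name="id"),
            columns=self.descriptor_names,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorTable":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(dtype=float),
        )


@dataclass
class Dataset:
    """Descriptor table plus per-compound log FM response and role labels.

    Roles partition the compounds into ``train``/``test``/``screen``; the
    response (log10 fetal/maternal concentration ratio) must be finite for
    every train and test compound and may be NaN for screen compounds.
    """

    table: DescriptorTable
    response: np.ndarray
    roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        n = self.table.n_compounds
        if self.response.shape != (n,):
            raise ValidationError("response length must match compound count")
        if len(self.roles) != n:
            raise ValidationError("roles length must match compound count")
        bad = set(self.roles) - {ROLE_TRAIN, ROLE_TEST, ROLE_SCREEN}
        if bad:
            raise ValidationError(f"unknown roles: {sorted(bad)}")
        roles = np.asarray(self.roles)
        if not np.any(roles == ROLE_TRAIN):
            raise ValidationError("training set is empty")
        modeled = (roles == ROLE_TRAIN) | (roles == ROLE_TEST)
        if not np.all(np.isfinite(self.response[modeled])):
            i = int(np.flatnonzero(modeled & ~np.isfinite(self.response))[0])
            raise ValidationError(
                f"missing response for {self.roles[i]} compound "
                f"{self.table.compound_ids[i]!r}"
            )

    def _mask(self, role: str) -> np.ndarray:
        return np.asarray(self.roles) == role

    @property
    def train_mask(self) -> np.ndarray:
        return self._mask(ROLE_TRAIN)

    @property
    def test_mask(self) -> np.ndarray:
        return self._mask(ROLE_TEST)

    @property
    def screen_mask(self) -> np.ndarray:
        return self._mask(ROLE_SCREEN)

    def ids(self, role: str) -> list[str]:
        mask = self._mask(role)
        return [c for c, m in zip(self.table.compound_ids, mask) if m]

    def X(self, role: str, names: Sequence[str] | None = None) -> np.ndarray:
        tab = self.table if names is None else self.table.subset(names)
        return tab.values[self._mask(role)]

    def y(self, role: str) -> np.ndarray:
        return self.response[self._mask(role)]

    def frame(self, role: str) -> pd.DataFrame:
        return self.table.to_frame()[self._mask(role)]


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_descriptor_table(path, delimiter: str = ",") -> DescriptorTable:
    """Parse a delimited text file into a :class:`DescriptorTable`.

    First row is the header, first column the compound identifier. A
    non-numeric or empty descriptor cell is a :class:`ParseError` naming the
    offending row and column; duplicate ids are a :class:`ValidationError`.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need an id column plus >=1 descriptor column")
    id_col = raw.columns[0]
    ids = [str(v) for v in raw[id_col]]
    names = [str(c) for c in raw.columns[1:]]
    values = np.empty((len(ids), len(names)), dtype=float)
    for j, name in enumerate(names):
        for i, cell in enumerate(raw[name]):
            text = str(cell).strip()
            if text == "":
                raise ParseError(
                    f"{path}: empty cell for compound {ids[i]!r}, column {name!r}"
                )
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {text!r} for compound "
                    f"{ids[i]!r}, column {name!r}"
                ) from None
    return DescriptorTable(ids, names, values)


def make_dataset(
    table: DescriptorTable,
    response_name: str,
    train_ids: Sequence[str],
    test_ids: Sequence[str] = (),
) -> Dataset:
    """Assemble a :class:`Dataset` with a fixed train/test split.

    Ids not in either list become role ``screen``. The response column is
    removed from the descriptor matrix.
    """
    train = [str(i) for i in train_ids]
    test = [str(i) for i in test_ids]
    if not train:
        raise ValidationError("train_ids must be non-empty")
    overlap = set(train) & set(test)
    if overlap:
        raise ValidationError(f"train/test overlap: {sorted(overlap)}")
    known = set(table.compound_ids)
    for cid in train + test:
        if cid not in known:
            raise ValidationError(f"unknown compound id {cid!r} in split lists")
    if response_name not in table.descriptor_names:
        raise ValidationError(f"response column {response_name!r} not present")

    response = table.column(response_name)
    keep = [d for d in table.descriptor_names if d != response_name]
    stripped = table.subset(keep)

    train_set, test_set = set(train), set(test)
    roles = []
    for cid in table.compound_ids:
        if cid in train_set:
            roles.append(ROLE_TRAIN)
        elif cid in test_set:
            roles.append(ROLE_TEST)
        else:
            roles.append(ROLE_SCREEN)
    return Dataset(stripped, response.copy(), roles)


def write_predictions(
    dataset: Dataset,
    predictions: Mapping[str, float],
    path,
    fm_cutoff: float = 0.3,
    delimiter: str = ",",
) -> None:
    """Write per-compound predictions as delimited text.

    Columns: id, predicted log FM, derived FM ratio, crossing flag (1 = C)
    and PL score — all numeric so the file round-trips through
    :func:`read_descriptor_table`.
    """
    known = set(dataset.table.compound_ids)
    for cid in predictions:
        if cid not in known:
            raise ValidationError(f"prediction for unknown compound id {cid!r}")
    order = [c for c in dataset.table.compound_ids if c in predictions]
    rows = []
    for cid in order:
        log_fm = float(predictions[cid])
        fm = 10.0 ** log_fm
        crossing = 1 if fm >= fm_cutoff else 0
        rows.append((cid, log_fm, fm, crossing, crossing))
    frame = pd.DataFrame(
        rows, columns=["id", "log_FM", "FM", "crossing", "PL"]
    ).set_index("id")
    frame.to_csv(path, sep=delimiter, float_format="%.6f")


def write_table(table: DescriptorTable, path, delimiter: str = ",") -> None:
    """Write a descriptor table; inverse of :func:`read_descriptor_table`."""
    table.to_frame().to_csv(path, sep=delimiter)
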