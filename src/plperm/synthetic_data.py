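"""Seeded synthetic descriptor tables with a known linear log FM truth.

Default property envelopes follow the reference compound set: molecular
weight up to ~700 Da, TPSA in 0–271 Å², log P roughly −1 to 6. The response
is a linear combination of named descriptors plus Gaussian noise, so every
downstream fitting stage has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import Dataset, DescriptorTable
from .drug_likeness import evaluate_filters
from .errors import ValidationError

__all__ = [
    "DescriptorSpec",
    "TrueModel",
    "GeneratorSpec",
    "generate_dataset",
    "generate_reference_like",
]


@dataclass(frozen=True)
class DescriptorSpec:
    """One descriptor column: uniform(low, high) or normal(mean, sd)."""

    name: str
    distribution: str = "uniform"  # uniform | normal
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.distribution not in ("uniform", "normal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "uniform" and not self.low < self.high:
            raise ValidationError(f"{self.name}: need low < high")
        if self.distribution == "normal" and self.sd <= 0:
            raise ValidationError(f"{self.name}: need sd > 0")


@dataclass(frozen=True)
class TrueModel:
    intercept: float
    coefficients: dict[str, float]
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def default_descriptor_specs() -> list[DescriptorSpec]:
    return [
        DescriptorSpec("M_w", "uniform", low=100.0, high=700.0),
        DescriptorSpec("TPSA", "uniform", low=0.0, high=271.0),
        DescriptorSpec("iLOGP", "uniform", low=-1.0, high=6.0),
    ]


@dataclass
class GeneratorSpec:
    """Full recipe for one synthetic dataset."""

    n_compounds: int
    descriptor_specs: list[DescriptorSpec] = field(
        default_factory=default_descriptor_specs
    )
    true_model: TrueModel = field(
        default_factory=lambda: TrueModel(
            0.14, {"M_w": -0.0022, "TPSA": 0.0040}, noise_sd=0.2
        )
    )
    correlation: dict[tuple[str, str], float] = field(default_factory=dict)
    n_test: int = 0
    seed: int = 1
    derive_lipinski: bool = False  # add binary Lipinski column from the rules

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValidationError("n_compounds must be >= 1")
        if not 0 <= self.n_test < self.n_compounds:
            raise ValidationError("need 0 <= n_test < n_compounds")
        names = {d.name for d in self.descriptor_specs}
        derived = {"Lipinski"} if self.derive_lipinski else set()
        unknown = set(self.true_model.coefficients) - names - derived
        if unknown:
            raise ValidationError(
                f"true-model coefficients name unknown descriptors: "
                f"{sorted(unknown)}"
            )
        for (a, b), r in self.correlation.items():
            if a not in names or b not in names:
                raise ValidationError(f"correlation names unknown pair ({a}, {b})")
            if not -1 < r < 1:
                raise ValidationError("correlations must be in (-1, 1)")


def _draw_columns(spec: GeneratorSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = spec.n_compounds
    # draw standard normals first so named pairs can be correlated, then map
    # through each descriptor's marginal
    z = {d.name: rng.standard_normal(n) for d in spec.descriptor_specs}
    for (a, b), r in spec.correlation.items():
        z[b] = r * z[a] + np.sqrt(1.0 - r * r) * z[b]
    from scipy.stats import norm

    columns = {}
    for d in spec.descriptor_specs:
        u = norm.cdf(z[d.name])
        if d.distribution == "uniform":
            columns[d.name] = d.low + u * (d.high - d.low)
        else:
            columns[d.name] = d.mean + d.sd * z[d.name]
    return columns


def generate_dataset(spec: GeneratorSpec) -> Dataset:
    """Draw a descriptor table and linear-plus-noise response from a spec.

    Fully reproducible from ``spec.seed``. With ``derive_lipinski`` the binary
    Lipinski column is computed from the drawn M_w/MLOGP/HA/HD values through
    the drug-likeness rules (strict, Mordred variant), keeping the generator
    consistent with :mod:`plperm.drug_likeness`.
    """
    rng = np.random.default_rng(spec.seed)
    columns = _draw_columns(spec, rng)
    if spec.derive_lipinski:
        needed = {"M_w", "MLOGP", "HA", "HD"}
        missing = needed - set(columns)
        if missing:
            raise ValidationError(
                f"derive_lipinski requires drawn columns {sorted(missing)}"
            )
        lipinski = np.array(
            [
                1.0
                if evaluate_filters(
                    {k: columns[k][i] for k in needed}
                ).passes["lipinski_mordred"]
                else 0.0
                for i in range(spec.n_compounds)
            ]
        )
        columns["Lipinski"] = lipinski

    names = list(columns)
    values = np.column_stack([columns[name] for name in names])
    response = np.full(spec.n_compounds, spec.true_model.intercept)
    for name, coeff in spec.true_model.coefficients.items():
        response = response + coeff * columns[name]
    if spec.true_model.noise_sd > 0:
        response = response + rng.normal(0.0, spec.true_model.noise_sd,
                                         spec.n_compounds)

    ids = [f"C{i + 1}" for i in range(spec.n_compounds)]
    table = DescriptorTable(ids, names, values)
    n_train = spec.n_compounds - spec.n_test
    roles = ["train"] * n_train + ["test"] * spec.n_test
    return Dataset(table, response, roles)


def generate_reference_like(seed: int = 1) -> Dataset:
    """54-compound dataset shaped like the reference split (40 train, 14 test).

    The truth has a negative M_w coefficient and positive TPSA coefficient
    with noise sd 0.2 on the log FM scale, mirroring the simplest published
    model's structure.
    """
    spec = GeneratorSpec(
        n_compounds=54,
        descriptor_specs=default_descriptor_specs()
        + [
            DescriptorSpec("MLOGP", "uniform", low=-1.0, high=6.0),
            DescriptorSpec("HA", "uniform", low=0.0, high=12.0),
            DescriptorSpec("HD", "uniform", low=0.0, high=6.0),
        ],
        true_model=TrueModel(0.14, {"M_w": -0.0022, "TPSA": 0.0040}, noise_sd=0.2),
        n_test=14,
        seed=seed,
        derive_lipinski=True,
    )
    return generate_dataset(spec)
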