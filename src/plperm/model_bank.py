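"""Fixed-coefficient predictor bank for log FM and permeability classification.

The bank holds nine published linear predictors on the log FM scale
(log10 of the fetal/maternal blood concentration ratio), transcribed with
their central coefficient estimates. Models ``eq1``–``eq5`` consume plain
molecular descriptors, ``eq6``/``eq7`` consume ARKA aggregate descriptors
(see :mod:`plperm.arka`), and ``eq8``/``eq9`` consume a mix of descriptors and
similarity-derived quantities (``RA_function``, ``MaxPos``, ``gm``; see
:mod:`plperm.read_across_rasar`). The bank never computes those inputs itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from .data_io import DescriptorTable
from .errors import ValidationError

__all__ = [
    "LinearModel",
    "PermeabilityCall",
    "FM_CUTOFF",
    "MODEL_IDS",
    "get_model",
    "predict_log_fm",
    "classify_permeability",
]

#: FM ratio above which a compound is called "crossing" (class C / PL1).
#: The alternative clearance-index classification (cutoff 0.8) is not modeled
#: here; when the two disagree the FM-based call prevails.
FM_CUTOFF = 0.3


@dataclass(frozen=True)
class LinearModel:
    """Intercept + named coefficients on the log FM scale."""

    model_id: str
    intercept: float
    coefficients: dict[str, float]
    model_family: str  # MLR | ARKA-MLR | q-RASAR-PLS
    printed_stats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValidationError("coefficient map must be non-empty")
        if not all(math.isfinite(v) for v in self.coefficients.values()):
            raise ValidationError("coefficients must be finite")

    @property
    def required_inputs(self) -> list[str]:
        return list(self.coefficients)


@dataclass(frozen=True)
class PermeabilityCall:
    """Quantitative prediction plus the binary crossing / PL calls."""

    log_fm: float
    fm: float
    crossing_class: str  # "C" | "NC"
    pl_score: str  # "PL1" | "PL0"


def _model(model_id, family, intercept, coeffs, **stats) -> LinearModel:
    return LinearModel(model_id, intercept, dict(coeffs), family, dict(stats))


# Coefficients are the printed central estimates. printed_stats keeps the
# published statistic blocks for reference; it is metadata only and never
# enters a computation. eq8's source prints two conflicting adjusted-R2
# values (0.838 on the equation line, 0.789 in the comparison table; the
# analytic identity from R2=0.800, n=40, p=2 gives 0.789) -- both are kept.
_BANK: dict[str, LinearModel] = {
    m.model_id: m
    for m in [
        _model(
            "eq1", "MLR", 0.14,
            {"M_w": -0.0022, "TPSA": 0.0040},
            n=40, r2=0.588, r2_adj=0.568, f=26.46, q2_loo=0.523,
            rmsecv=0.254, rmsep=0.276, r2_ext=0.468,
        ),
        _model(
            "eq2", "MLR", -0.038,
            {"ZMIC1": -0.0081, "EState_VSA8": -0.011, "GATS7Z": 0.20,
             "Lipinski": -0.12},
            n=40, r2=0.804, r2_adj=0.781, f=35.86, q2_loo=0.754,
            rmsecv=0.184, rmsep=0.196, r2_ext=0.721,
        ),
        _model(
            "eq3", "MLR", -0.68,
            {"Lipinski": 0.53, "AATSC3s": -0.58, "EState_VSA8": -0.0058,
             "JGI9": -9.78, "AMID_N": 0.45, "AATSC6se": -1.69},
            n=40, r2=0.851, r2_adj=0.824, f=31.49, q2_loo=0.776,
            rmsep=0.231, r2_ext=0.617,
        ),
        _model(
            "eq4", "MLR", -0.51,
            {"Lipinski": 0.29, "AATSC3s": -0.70, "PNSA1": -0.0013,
             "EState_VSA8": -0.0096, "MATS7Z": -0.41, "AATS3s": 0.13},
            n=40, r2=0.862, r2_adj=0.837, f=34.43, q2_loo=0.813,
            rmsep=0.270, r2_ext=0.517,
        ),
        _model(
            "eq5", "MLR", -0.42,
            {"Lipinski": 0.55, "iLOGP": -0.12},
            n=40, r2=0.715, r2_adj=0.699, f=46.34, q2_loo=0.673,
            rmsep=0.268, r2_ext=0.513,
        ),
        _model(
            "eq6", "ARKA-MLR", -0.3285,
            {"ARKA1": 0.31401, "ARKA2": -0.26045},
            n=40, r2=0.846, r2_adj=0.838, q2_loo=0.820, f=101.62,
            q2_f1=0.603, q2_f2=0.602, rmsep=0.233,
        ),
        _model(
            "eq7", "ARKA-MLR", -0.3285,
            {"ARKA1": 0.19721, "ARKA2": -0.28725},
            n=40, r2=0.778, r2_adj=0.766, q2_loo=0.746, f=65.0,
            q2_f1=0.481, q2_f2=0.480, rmsep=0.266,
        ),
        _model(
            "eq8", "q-RASAR-PLS", -0.23463,
            {"Lipinski": 0.33214, "EState_VSA8": -0.00721,
             "RA_function": 0.65269, "MaxPos": -0.22397},
            n=40, lv=2, r2=0.800, r2_adj_printed=0.838, r2_adj_table=0.789,
            q2_loo=0.757, f=74.0, q2_f1=0.742, q2_f2=0.741, rmsep=0.188,
        ),
        _model(
            "eq9", "q-RASAR-PLS", -0.34744,
            {"MATS7Z": -0.21423, "PNSA1": -0.00061, "Lipinski": 0.24892,
             "EState_VSA8": -0.00714, "gm": 0.25888},
            n=40, lv=2, r2=0.819, r2_adj=0.809, q2_loo=0.781, f=83.71,
            q2_f1=0.627, q2_f2=0.626, rmsep=0.226,
        ),
    ]
}

MODEL_IDS: tuple[str, ...] = tuple(_BANK)


def get_model(model_id: str) -> LinearModel:
    """Look up one of the nine fixed models by id (``eq1`` ... ``eq9``)."""
    try:
        return _BANK[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model id {model_id!r}; valid ids: {', '.join(MODEL_IDS)}"
        ) from None


def predict_log_fm(
    model: LinearModel, table: DescriptorTable
) -> dict[str, float]:
    """Apply a fixed linear model to every compound of a table.

    Returns ``{compound_id: intercept + sum(coeff * descriptor)}``. Every
    required input must be a column of the table.
    """
    for name in model.required_inputs:
        if name not in table.descriptor_names:
            raise ValidationError(
                f"model {model.model_id!r} requires descriptor column {name!r}"
            )
    preds = {}
    for i, cid in enumerate(table.compound_ids):
        row = table.values[i]
        value = model.intercept
        for name, coeff in model.coefficients.items():
            value += coeff * row[table.descriptor_names.index(name)]
        preds[cid] = float(value)
    return preds


def classify_permeability(
    log_fm: float, fm_cutoff: float = FM_CUTOFF
) -> PermeabilityCall:
    """Binary crossing call from a predicted log FM value.

    Class C (score PL1) iff FM = 10**log_fm >= cutoff; the boundary is
    inclusive by convention.
    """
    if not math.isfinite(log_fm):
        raise ValidationError("log_fm must be finite")
    if fm_cutoff <= 0:
        raise ValidationError("fm_cutoff must be positive")
    fm = 10.0 ** log_fm
    # inclusive boundary, robust to log/exp roundoff at fm == cutoff
    crossing = fm >= fm_cutoff or math.isclose(fm, fm_cutoff, rel_tol=1e-12)
    return PermeabilityCall(
        log_fm=float(log_fm),
        fm=float(fm),
        crossing_class="C" if crossing else "NC",
        pl_score="PL1" if crossing else "PL0",
    )
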