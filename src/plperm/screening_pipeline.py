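"""End-to-end screening workflow: predict, classify, filter, summarize.

Given a descriptor table and a pipeline config, applies the selected
fixed-coefficient models, calls permeability (C/NC, PL1/PL0) from the primary
model, evaluates the drug-likeness filters, optionally attaches ARKA
features, and summarizes how the PL1 and PL0 groups differ on key properties
(lipophilicity, size, polarizability, polarity) with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import model_bank
from .arka import arka_features
from .data_io import DescriptorTable
from .drug_likeness import FILTER_NAMES, evaluate_filters
from .errors import ValidationError

__all__ = ["ScreeningConfig", "ScreeningReport", "run_screening", "summarize_groups"]

GROUP_FEATURES = ["iLOGP", "M_w", "MR", "TPSA"]


@dataclass
class ScreeningConfig:
    models: list[str] = field(default_factory=lambda: ["eq1"])
    fm_cutoff: float = model_bank.FM_CUTOFF
    filters: bool = True
    tolerance: str = "strict"
    arka_descriptors: list[str] = field(default_factory=list)
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("at least one model id required")
        for mid in self.models:
            model_bank.get_model(mid)  # raises on unknown id

    def snapshot(self) -> dict:
        return {
            "models": list(self.models),
            "fm_cutoff": self.fm_cutoff,
            "filters": self.filters,
            "tolerance": self.tolerance,
            "arka_descriptors": list(self.arka_descriptors),
            "seed": self.seed,
        }


@dataclass
class ScreeningReport:
    per_compound: pd.DataFrame
    group_summary: pd.DataFrame
    group_tests: pd.DataFrame
    provenance: dict


def run_screening(
    table: DescriptorTable,
    config: ScreeningConfig,
    train_response: np.ndarray | None = None,
) -> ScreeningReport:
    """Apply the configured models and filters to every compound of a table.

    The first model in ``config.models`` is the primary one: its prediction
    drives the C/NC and PL1/PL0 calls. ARKA features are attached when
    ``config.arka_descriptors`` names columns and a training response is
    supplied. Deterministic given (table, config).
    """
    predictions: dict[str, dict[str, float]] = {}
    for mid in config.models:
        model = model_bank.get_model(mid)
        try:
            predictions[mid] = model_bank.predict_log_fm(model, table)
        except ValidationError as exc:
            raise ValidationError(f"model {mid!r}: {exc}") from exc

    primary = config.models[0]
    rows = []
    for cid in table.compound_ids:
        row: dict[str, object] = {"id": cid}
        for mid in config.models:
            row[f"log_FM_{mid}"] = predictions[mid][cid]
        call = model_bank.classify_permeability(
            predictions[primary][cid], config.fm_cutoff
        )
        row["FM"] = call.fm
        row["crossing_class"] = call.crossing_class
        row["PL"] = call.pl_score
        if config.filters:
            verdict = evaluate_filters(table.row(cid), config.tolerance)
            for name in FILTER_NAMES:
                row[f"filter_{name}"] = verdict.passes[name]
            row["lipinski_violations"] = verdict.lipinski_violations
        rows.append(row)
    per_compound = pd.DataFrame(rows).set_index("id")

    if config.arka_descriptors:
        if train_response is None:
            raise ValidationError(
                "ARKA features need a training response (train_response)"
            )
        sub = table.subset(config.arka_descriptors)
        feats, _, _ = arka_features(
            sub.values, np.asarray(train_response, dtype=float),
            config.arka_descriptors, table.compound_ids,
        )
        per_compound["ARKA1"] = feats.arka1
        per_compound["ARKA2"] = feats.arka2

    summary, tests = summarize_groups(per_compound, table)
    return ScreeningReport(
        per_compound=per_compound,
        group_summary=summary,
        group_tests=tests,
        provenance={"config": config.snapshot(), "n_compounds": table.n_compounds},
    )


def summarize_groups(
    per_compound: pd.DataFrame,
    table: DescriptorTable,
    features: Sequence[str] = tuple(GROUP_FEATURES),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-PL-group feature summaries plus a rank-sum two-sample test.

    For each available feature, reports mean/median/min/max per group and a
    Mann–Whitney U statistic with p-value. If either group is empty the
    summaries are still emitted and the test row carries a note.
    """
    available = [f for f in features if f in table.descriptor_names]
    pl = per_compound["PL"].to_numpy()
    summary_rows, test_rows = [], []
    for feature in available:
        values = table.column(feature)
        for group in ("PL1", "PL0"):
            sel = values[pl == group]
            summary_rows.append(
                {
                    "feature": feature,
                    "group": group,
                    "n": int(sel.size),
                    "mean": float(sel.mean()) if sel.size else np.nan,
                    "median": float(np.median(sel)) if sel.size else np.nan,
                    "min": float(sel.min()) if sel.size else np.nan,
                    "max": float(sel.max()) if sel.size else np.nan,
                }
            )
        a, b = values[pl == "PL1"], values[pl == "PL0"]
        if a.size and b.size:
            stat, pval = mannwhitneyu(a, b, alternative="two-sided")
            test_rows.append(
                {"feature": feature, "statistic": float(stat),
                 "p_value": float(pval), "note": ""}
            )
        else:
            test_rows.append(
                {"feature": feature, "statistic": np.nan, "p_value": np.nan,
                 "note": "a group is empty; test skipped"}
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)
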