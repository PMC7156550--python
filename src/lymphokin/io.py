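"""Tidy CSV / JSON readers and writers for every pipeline artifact.

All tabular data is long-format CSV with a header; days are floats (sampling
at non-integer days is allowed even though the simulation steps daily — curve
values are interpolated linearly).  Fits, comparisons and run manifests are
JSON.  Readers validate headers and monotonicity and raise descriptive
errors rather than producing silently empty objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import LabelingDataset
from .event_time import PopulationSpec
from .fitting import ComparisonTable, FitResult
from .label_kinetics import EnrichmentSeries, GlucoseProtocol, HeavyWaterProtocol

__all__ = [
    "read_labeling_csv",
    "write_labeling_csv",
    "read_enrichment_csv",
    "write_enrichment_csv",
    "read_annexin_csv",
    "write_annexin_csv",
    "fit_result_to_dict",
    "write_fit_json",
    "comparison_to_dict",
    "write_comparison_json",
    "comparison_to_frame",
    "protocol_from_config",
    "write_manifest",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_labeling_csv(path) -> LabelingDataset:
    """Read a (day, fraction_labeled) time course; extra columns become metadata."""
    df = _read_csv(path)
    _require_columns(df, ["day", "fraction_labeled"], path)
    days = df["day"].to_numpy(dtype=float)
    dup = pd.Series(days)[pd.Series(days).duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate day row(s) at day {sorted(set(dup))}")
    order = np.argsort(days)
    meta = {
        c: df[c].iloc[0]
        for c in df.columns
        if c not in ("day", "fraction_labeled") and df[c].nunique() == 1
    }
    return LabelingDataset(
        times=days[order],
        fraction_labeled=df["fraction_labeled"].to_numpy(dtype=float)[order],
        meta=meta,
    )


def write_labeling_csv(dataset: LabelingDataset, path) -> None:
    df = pd.DataFrame(
        {"day": dataset.times, "fraction_labeled": dataset.fraction_labeled}
    )
    for key, value in dataset.meta.items():
        if np.isscalar(value):
            df[key] = value
    df.to_csv(path, index=False)


def read_enrichment_csv(path) -> EnrichmentSeries:
    df = _read_csv(path)
    _require_columns(df, ["day", "enrichment"], path)
    df = df.sort_values("day")
    return EnrichmentSeries(
        times=df["day"].to_numpy(dtype=float),
        enrichment=df["enrichment"].to_numpy(dtype=float),
    )


def write_enrichment_csv(series: EnrichmentSeries, path) -> None:
    pd.DataFrame({"day": series.times, "enrichment": series.enrichment}).to_csv(
        path, index=False
    )


ANNEXIN_COLUMNS = ["subject", "day", "annexin_class", "fraction_labeled"]


def read_annexin_csv(path) -> pd.DataFrame:
    """Read a sorted-subset dataset (subject, day, annexin_class, fraction_labeled)."""
    df = _read_csv(path)
    _require_columns(df, ANNEXIN_COLUMNS, path)
    bad = set(df["annexin_class"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"{path}: annexin_class must be positive/negative, found {bad}")
    return df


def write_annexin_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in ANNEXIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annexin frame missing column(s) {missing}")
    df.to_csv(path, index=False)


# -- fits and comparisons --------------------------------------------------


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "model": fit.model.name,
        "paradigm": fit.model.paradigm.value,
        "heterogeneity": fit.model.heterogeneity,
        "family": fit.model.family,
        "k": fit.model.k,
        "params": fit.params,
        "spec": fit.spec.to_config(),
        "ssr": fit.ssr,
        "aicc": fit.aicc,
        "n_obs": fit.n_obs,
        "engine": fit.engine,
        "seeds_used": list(fit.seeds_used),
        "param_se": fit.param_se,
    }


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))


def comparison_to_dict(table: ComparisonTable) -> dict:
    return {
        "winner": table.winner.name,
        "entries": [
            {
                **fit_result_to_dict(e.fit),
                "normalized_aicc": e.normalized_aicc,
            }
            for e in table.entries
        ],
    }


def write_comparison_json(table: ComparisonTable, path) -> None:
    Path(path).write_text(json.dumps(comparison_to_dict(table), indent=2))


def comparison_to_frame(table: ComparisonTable) -> pd.DataFrame:
    """Flat report table: one row per model with k, ssr, AICc, normalized AICc."""
    return pd.DataFrame(
        [
            {
                "model": e.model.name,
                "k": e.model.k,
                "ssr": e.fit.ssr,
                "aicc": e.aicc,
                "normalized_aicc": e.normalized_aicc,
                "winner": e.model == table.winner,
            }
            for e in table.entries
        ]
    )


def protocol_from_config(cfg: dict) -> HeavyWaterProtocol | GlucoseProtocol:
    kind = cfg.get("kind")
    if kind == "heavy_water":
        return HeavyWaterProtocol.from_config(cfg)
    if kind == "glucose":
        return GlucoseProtocol.from_config(cfg)
    raise ValueError(f"unknown protocol kind {kind!r}; expected heavy_water or glucose")


def write_manifest(path, *, command: str, seed: int | None, config: dict) -> None:
    """Record everything needed to reproduce a run (command, seed, full config)."""
    import lymphokin

    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "lymphokin_version": lymphokin.__version__,
        "numpy_version": np.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
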