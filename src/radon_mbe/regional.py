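"""Regional radon proxies from winter survey data.

Soil radon (per district) and outdoor radon (per province) are not measured
directly; they are proxied by weighting a reference level with the ratio of
each region's geometric mean winter indoor radon to the national geometric
mean.  Winter measurements are used because ventilation is low then, so the
regional contrast mostly reflects the local source term (e.g. granite
geology).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["regional_weights", "scale_reference", "LEVEL_COLUMNS"]

LEVEL_COLUMNS = {"district": "district_id", "province": "province_id"}


def regional_weights(
    records: pd.DataFrame,
    level: str = "district",
    value_col: str = "radon_bq_m3",
) -> pd.DataFrame:
    """Per-region GM-ratio weights from survey records.

    Parameters
    ----------
    records : DataFrame
        One row per surveyed residence, with columns ``district_id``,
        ``province_id`` and ``value_col`` (measured radon, Bq m-3, > 0).
    level : {"district", "province"}
        Aggregation level; outdoor radon uses the same construction at
        province level as soil radon does at district level.

    Returns
    -------
    DataFrame with columns ``region_id``, ``n``, ``gm`` (regional geometric
    mean) and ``weight`` = gm / GM(all records).  The record-count-weighted
    mean of log(weight) is zero by construction.
    """
    if level not in LEVEL_COLUMNS:
        raise ValueError(f"level must be one of {sorted(LEVEL_COLUMNS)}, got {level!r}")
    col = LEVEL_COLUMNS[level]
    if len(records) == 0:
        raise ValueError("no survey records")
    values = np.asarray(records[value_col], dtype=float)
    if np.any(~(values > 0)):
        raise ValueError("all survey radon values must be positive (log scale)")
    logs = np.log(values)
    total_log_gm = logs.mean()
    grouped = (
        pd.DataFrame({"region_id": records[col].to_numpy(), "log": logs})
        .groupby("region_id", sort=True)["log"]
        .agg(n="size", log_gm="mean")
        .reset_index()
    )
    grouped["gm"] = np.exp(grouped.pop("log_gm"))
    grouped["weight"] = grouped["gm"] / np.exp(total_log_gm)
    return grouped[["region_id", "n", "gm", "weight"]]


def scale_reference(table: pd.DataFrame, reference: float) -> pd.DataFrame:
    """Turn weights into concentration estimates: estimate = weight * reference."""
    if not reference > 0:
        raise ValueError("reference level must be positive")
    out = table.copy()
    out["estimate"] = out["weight"] * float(reference)
    return out
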