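"""Raw residence measurements -> analysis-ready annual concentrations.

Fixed pipeline order: two-point geometric mean -> seasonal correction ->
log transform -> outlier screen (single pass, within stratum) -> stratum
assignment.  Radon is log-normally distributed, so all location/spread
statistics and the outlier screen operate on natural-log values.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_Z_MAX",
    "DEFAULT_HABIT_WEIGHTS",
    "two_point_gm",
    "seasonal_correction",
    "screen_outliers",
    "ScreenResult",
    "assign_stratum",
    "annualize",
]

DEFAULT_Z_MAX = 3.0

#: Ordinal ventilation-habit categories and their default multipliers for
#: the habit-weighted ventilation factor N.
DEFAULT_HABIT_WEIGHTS = {"low": 0.8, "medium": 1.0, "high": 1.2}

# Stratum layout: residence type crossed with groundwater usage.
_STRATA = {
    ("detached", "yes"): 1,
    ("detached", "no"): 2,
    ("other", "yes"): 3,
    ("other", "no"): 4,
}


def two_point_gm(radon_pt1, radon_pt2):
    """Geometric mean sqrt(pt1 * pt2) of the two in-residence measurement points."""
    a = np.asarray(radon_pt1, dtype=float)
    b = np.asarray(radon_pt2, dtype=float)
    if np.any(~(a > 0)) or np.any(~(b > 0)):
        raise ValueError("radon measurements must be positive")
    gm = np.sqrt(a * b)
    return float(gm) if np.ndim(gm) == 0 else gm


def seasonal_correction(c, season: str, factors: Mapping[str, float]):
    """Convert a seasonal measurement to an annual-mean-equivalent value.

    ``annual = c * factors[season]``; an unknown season raises an error
    naming the known labels.
    """
    if season not in factors:
        raise KeyError(
            f"unknown season {season!r}; known seasons: {sorted(factors)}"
        )
    factor = float(factors[season])
    if not factor > 0:
        raise ValueError(f"seasonal factor for {season!r} must be positive")
    c = np.asarray(c, dtype=float)
    out = c * factor
    return float(out) if np.ndim(out) == 0 else out


class ScreenResult(NamedTuple):
    kept: np.ndarray
    removed: np.ndarray
    keep_mask: np.ndarray


def screen_outliers(values: Iterable[float], z_max: float = DEFAULT_Z_MAX) -> ScreenResult:
    """Single-pass z-score screen on log-scale values.

    A value is removed when |value - mean| / sd > z_max, with mean and sd
    (sample sd, ddof=1) computed once on the full input.  With zero
    variance nothing is removed.  Deterministic.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if v.size < 3:
        raise ValueError("outlier screening needs at least 3 values")
    if not z_max > 0:
        raise ValueError("z_max must be positive")
    sd = v.std(ddof=1)
    if sd == 0:
        mask = np.ones(v.size, dtype=bool)
    else:
        mask = np.abs(v - v.mean()) / sd <= z_max
    return ScreenResult(kept=v[mask], removed=v[~mask], keep_mask=mask)


def assign_stratum(res_type: str, groundwater: str) -> int:
    """Map (residence type, groundwater usage) to stratum Type 1-4.

    detached+yes -> 1, detached+no -> 2, other+yes -> 3, other+no -> 4.
    """
    key = (str(res_type).strip().lower(), str(groundwater).strip().lower())
    try:
        return _STRATA[key]
    except KeyError:
        raise ValueError(
            f"cannot assign stratum for res_type={res_type!r}, "
            f"groundwater={groundwater!r}; expected res_type in "
            "{'detached','other'} and groundwater in {'yes','no'}"
        ) from None


def annualize(
    residences: pd.DataFrame,
    seasonal_factors: Mapping[str, float] | None = None,
    z_max: float = DEFAULT_Z_MAX,
    within_stratum: bool = True,
) -> pd.DataFrame:
    """Run the full preprocessing pipeline on a residence table.

    Expects the columns ``residence_id``, ``res_type``, ``groundwater``,
    ``radon_pt1``, ``radon_pt2`` and ``season``.  Returns a copy with added
    columns ``stratum``, ``c_annual``, ``log_c`` and ``outlier_flag``
    (True = removed by the screen).  Seasonal factors default to the
    identity map over the seasons present.
    """
    df = residences.copy()
    gm = two_point_gm(df["radon_pt1"].to_numpy(), df["radon_pt2"].to_numpy())
    if seasonal_factors is None:
        seasonal_factors = {s: 1.0 for s in df["season"].unique()}
    factors = df["season"].map(
        lambda s: seasonal_factors[s] if s in seasonal_factors else None
    )
    if factors.isna().any():
        bad = sorted(df.loc[factors.isna(), "season"].unique())
        raise KeyError(f"unknown seasons {bad}; known: {sorted(seasonal_factors)}")
    df["c_annual"] = gm * factors.astype(float).to_numpy()
    df["log_c"] = np.log(df["c_annual"].to_numpy())
    df["stratum"] = [
        assign_stratum(rt, gw) for rt, gw in zip(df["res_type"], df["groundwater"])
    ]
    flag = np.zeros(len(df), dtype=bool)
    groups = df.groupby("stratum").indices if within_stratum else {0: np.arange(len(df))}
    for idx in groups.values():
        if len(idx) < 3:
            continue  # too few points to screen; keep all
        res = screen_outliers(df["log_c"].to_numpy()[idx], z_max=z_max)
        flag[idx] = ~res.keep_mask
    df["outlier_flag"] = flag
    return df
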