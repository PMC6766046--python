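"""Stratified linear model of the infiltration factor S.

The infiltration factor (radon entry rate into indoor air, Bq m-3 h-1) is
regressed, separately within four residence strata (detached vs other
residence, crossed with groundwater usage), on

* ``X1`` — greenery ratio of the administrative district (%),
* ``X2`` — geometric mean of indoor radon of the district (Bq m-3),
* ``Y1`` — wall building material (dummy-coded, reference = concrete),
* ``Y2`` — number of crack locations (>=2 vs 0-1),
* ``Y3`` — floors (>=2 vs <=1),

by ordinary least squares.  The predictor set is stratum-specific metadata:
Type 3 (other residence, groundwater) carries no crack/floor terms and only
the concrete / red-brick / cement-block material levels; Type 4 has no
soil/wood levels.  Published reference coefficients for all four strata
ship with the package and double as the default ground truth of the
synthetic-data generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mass_balance import RADON_DECAY_CONSTANT, steady_state_ci

__all__ = [
    "InfiltrationModel",
    "stratum_metadata",
    "reference_model",
    "design_columns",
    "build_design",
    "fit_infiltration",
    "predict_s",
    "predict_ci",
]

CRACK_LEVELS = ("0-1", ">=2")
FLOOR_LEVELS = ("<=1", ">=2")
MATERIAL_REFERENCE = "concrete"


def _load_fixture() -> dict:
    with resources.files("radon_mbe.data").joinpath(
        "infiltration_coefficients.json"
    ).open() as fh:
        return {int(k): v for k, v in json.load(fh).items()}


_FIXTURE = _load_fixture()


@dataclass(frozen=True)
class InfiltrationModel:
    """Fitted (or reference) per-stratum infiltration-factor model."""

    stratum: int
    coefficients: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    sigma: float
    materials: tuple[str, ...]
    has_cracks: bool
    has_floors: bool
    nobs: int = 0

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "coefficients": dict(self.coefficients),
            "se": dict(self.se),
            "pvalues": dict(self.pvalues),
            "sigma": self.sigma,
            "materials": list(self.materials),
            "has_cracks": self.has_cracks,
            "has_floors": self.has_floors,
            "nobs": self.nobs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InfiltrationModel":
        return cls(
            stratum=int(d["stratum"]),
            coefficients=dict(d["coefficients"]),
            se=dict(d.get("se", {})),
            pvalues=dict(d.get("pvalues", {})),
            sigma=float(d.get("sigma", 0.0)),
            materials=tuple(d["materials"]),
            has_cracks=bool(d["has_cracks"]),
            has_floors=bool(d["has_floors"]),
            nobs=int(d.get("nobs", 0)),
        )


def stratum_metadata(stratum: int) -> dict:
    """Predictor-set metadata (materials, crack/floor terms) for a stratum."""
    try:
        meta = _FIXTURE[int(stratum)]
    except KeyError:
        raise ValueError(f"unknown stratum {stratum!r}; expected 1-4") from None
    return {
        "materials": tuple(meta["materials"]),
        "has_cracks": meta["has_cracks"],
        "has_floors": meta["has_floors"],
    }


def reference_model(stratum: int) -> InfiltrationModel:
    """Packaged published coefficients for a stratum, as an InfiltrationModel."""
    meta = _FIXTURE[int(stratum)]
    return InfiltrationModel(
        stratum=int(stratum),
        coefficients=dict(meta["coefficients"]),
        se=dict(meta["se"]),
        pvalues={},
        sigma=0.0,
        materials=tuple(meta["materials"]),
        has_cracks=meta["has_cracks"],
        has_floors=meta["has_floors"],
    )


def design_columns(stratum: int) -> list[str]:
    meta = stratum_metadata(stratum)
    cols = ["intercept", "greenery", "district_gm"]
    cols += [f"material:{m}" for m in meta["materials"] if m != MATERIAL_REFERENCE]
    if meta["has_cracks"]:
        cols.append("cracks_ge2")
    if meta["has_floors"]:
        cols.append("floors_ge2")
    return cols


def _encode(df: pd.DataFrame, stratum: int) -> pd.DataFrame:
    meta = stratum_metadata(stratum)
    n = len(df)
    out = pd.DataFrame(index=df.index)
    out["intercept"] = 1.0
    greenery = np.asarray(df["greenery"], dtype=float)
    if np.any((greenery < 0) | (greenery > 100)):
        raise ValueError("greenery ratio must lie in [0, 100]")
    x2 = np.asarray(df["district_gm"], dtype=float)
    if np.any(~(x2 > 0)):
        raise ValueError("district geometric mean must be positive")
    out["greenery"] = greenery
    out["district_gm"] = x2
    materials = df["material"].astype(str)
    unseen = sorted(set(materials) - set(meta["materials"]))
    if unseen:
        raise ValueError(
            f"material level(s) {unseen} not allowed in stratum Type {stratum} "
            f"(allowed: {list(meta['materials'])})"
        )
    for m in meta["materials"]:
        if m == MATERIAL_REFERENCE:
            continue
        out[f"material:{m}"] = (materials == m).astype(float)
    if meta["has_cracks"]:
        cracks = df["cracks"].astype(str)
        bad = sorted(set(cracks) - set(CRACK_LEVELS))
        if bad:
            raise ValueError(f"unknown crack level(s) {bad}; expected {CRACK_LEVELS}")
        out["cracks_ge2"] = (cracks == ">=2").astype(float)
    if meta["has_floors"]:
        floors = df["floors"].astype(str)
        bad = sorted(set(floors) - set(FLOOR_LEVELS))
        if bad:
            raise ValueError(f"unknown floor level(s) {bad}; expected {FLOOR_LEVELS}")
        out["floors_ge2"] = (floors == ">=2").astype(float)
    return out


def build_design(records: pd.DataFrame, response: str | None = "s"):
    """Per-stratum design matrices from annualized residences.

    ``records`` needs columns ``stratum``, ``greenery``, ``district_gm``,
    ``material``, ``cracks``, ``floors`` and (when fitting) the response
    column.  Returns ``{stratum: (X, y)}`` with dummy coding against the
    reference cell (concrete, 0-1 cracks, <=1 floors); ``y`` is None when
    ``response`` is None or absent.  Rows partition exactly by stratum.
    """
    designs = {}
    for stratum, sub in records.groupby("stratum", sort=True):
        X = _encode(sub, int(stratum))
        y = None
        if response is not None and response in sub.columns:
            y = sub[response].astype(float)
        designs[int(stratum)] = (X, y)
    return designs


def fit_infiltration(X: pd.DataFrame, y, stratum: int) -> InfiltrationModel:
    """OLS fit of the infiltration factor within one stratum.

    Reports coefficient, standard error and two-sided t-test p-value per
    predictor.  Dummy columns that are identically zero (allowed level not
    present in the data) are dropped and excluded from the model's level
    set; genuine rank deficiency raises an error naming the collinear
    columns.
    """
    meta = stratum_metadata(stratum)
    X = X.copy()
    dummy_cols = [c for c in X.columns if c.startswith(("material:", "cracks", "floors"))]
    absent = [c for c in dummy_cols if not X[c].any()]
    if absent:
        X = X.drop(columns=absent)
    if len(X) <= X.shape[1]:
        raise ValueError(
            f"stratum Type {stratum}: {len(X)} rows cannot identify "
            f"{X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a minimal set of columns that complete the rank deficiency
        bad = []
        cols = list(X.columns)
        kept: list[str] = []
        for c in cols:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(
            f"stratum Type {stratum}: design is rank deficient; collinear "
            f"column(s): {bad}"
        )
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    materials = tuple(
        m for m in meta["materials"]
        if m == MATERIAL_REFERENCE or f"material:{m}" in X.columns
    )
    return InfiltrationModel(
        stratum=int(stratum),
        coefficients={k: float(v) for k, v in res.params.items()},
        se={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        sigma=float(np.sqrt(res.scale)),
        materials=materials,
        has_cracks=meta["has_cracks"] and "cracks_ge2" in X.columns,
        has_floors=meta["has_floors"] and "floors_ge2" in X.columns,
        nobs=int(res.nobs),
    )


def _row_vector(model: InfiltrationModel, row: Mapping) -> float:
    s = model.coefficients["intercept"]
    s += model.coefficients["greenery"] * float(row["greenery"])
    s += model.coefficients["district_gm"] * float(row["district_gm"])
    material = str(row.get("material", MATERIAL_REFERENCE))
    if material not in model.materials:
        raise ValueError(
            f"material {material!r} absent from Type {model.stratum} model "
            f"(levels: {list(model.materials)})"
        )
    if material != MATERIAL_REFERENCE:
        s += model.coefficients[f"material:{material}"]
    if model.has_cracks:
        cracks = str(row.get("cracks", CRACK_LEVELS[0]))
        if cracks not in CRACK_LEVELS:
            raise ValueError(f"unknown crack level {cracks!r}; expected {CRACK_LEVELS}")
        if cracks == ">=2":
            s += model.coefficients["cracks_ge2"]
    if model.has_floors:
        floors = str(row.get("floors", FLOOR_LEVELS[0]))
        if floors not in FLOOR_LEVELS:
            raise ValueError(f"unknown floor level {floors!r}; expected {FLOOR_LEVELS}")
        if floors == ">=2":
            s += model.coefficients["floors_ge2"]
    return float(s)


def predict_s(model: InfiltrationModel, row: Mapping) -> float:
    """Deterministic linear predictor of S (Bq m-3 h-1) for one residence."""
    return _row_vector(model, row)


def predict_ci(
    model: InfiltrationModel,
    row: Mapping,
    Cs: float,
    Co: float,
    lam: float = RADON_DECAY_CONSTANT,
    lam_v: float = 0.0,
) -> float:
    """Predicted steady-state indoor radon from the fitted S model.

    Building-material compartment radon is folded into the soil term
    (Cs + Cbm ~= Cs), so Cbm is fixed at zero here.
    """
    return steady_state_ci(
        predict_s(model, row), Cs=Cs, Cbm=0.0, Co=Co, lam=lam, lam_v=lam_v
    )
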