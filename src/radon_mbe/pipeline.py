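"""End-to-end orchestration: CSVs in, fitted models and predictions out.

Stage order is fixed: load -> preprocess (annualize, screen) -> regional
estimates (district soil radon, province outdoor radon) -> per-residence
ventilation rates -> infiltration-factor inversion -> per-stratum OLS fit
-> prediction of S and indoor radon -> agreement report.  A stage failure
aborts the run with the stage name and cause; outputs are only written
after every stage has succeeded, so no partial files are left behind.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .infiltration import InfiltrationModel, build_design, fit_infiltration
from .mass_balance import (
    RADON_DECAY_CONSTANT,
    infiltration_from_measurement,
    steady_state_ci,
    ventilation_rate_profile,
)
from .preprocessing import DEFAULT_HABIT_WEIGHTS, DEFAULT_Z_MAX, annualize
from .regional import regional_weights, scale_reference

__all__ = [
    "RunConfig",
    "PipelineError",
    "PipelineResult",
    "province_base_ventilation",
    "run_pipeline",
    "evaluate_agreement",
]

log = logging.getLogger("radon_mbe.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    residences_csv: str
    districts_csv: str
    meteo_csv: str
    survey_csv: str
    ft: float
    fw: float
    indoor_temp: float = 20.0
    habit_weights: dict = field(default_factory=lambda: dict(DEFAULT_HABIT_WEIGHTS))
    seasonal_factors: dict | None = None
    z_max: float = DEFAULT_Z_MAX
    soil_reference: float = 86.52
    outdoor_reference: float = 10.0
    lam: float = RADON_DECAY_CONSTANT
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        # input paths are relative to the config file's directory
        for attr in ("residences_csv", "districts_csv", "meteo_csv", "survey_csv"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(path.parent / p))
        if cfg.out_dir is not None and not Path(cfg.out_dir).is_absolute():
            cfg.out_dir = str(path.parent / cfg.out_dir)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def province_base_ventilation(
    meteo: pd.DataFrame, ft: float, fw: float, indoor_temp: float
) -> pd.Series:
    """Annual-mean meteorological ventilation rate per province at N = 1.

    Averages the monthly rate (ft*|Ti - To| + fw*u^2) over the 12 monthly
    normals of each province; a residence's rate is this base times its
    habit multiplier N.
    """
    out = {}
    for pid, grp in meteo.groupby("province_id", sort=True):
        rates = ventilation_rate_profile(
            ft, fw, indoor_temp, grp["temp_c"].to_numpy(), grp["wind_ms"].to_numpy()
        )
        out[pid] = float(rates.mean())
    return pd.Series(out, name="lam_v_base")


@dataclass
class PipelineResult:
    models: dict[int, InfiltrationModel]
    predictions: pd.DataFrame
    report: dict
    district_table: pd.DataFrame
    province_table: pd.DataFrame


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _agreement_stats(measured: np.ndarray, estimated: np.ndarray) -> dict:
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    stats = {
        "n": int(measured.size),
        "rmse": _rmse(estimated, measured),
        "bias": float(np.mean(estimated - measured)),
    }
    # least-squares concordance line: estimated ~ slope * measured + intercept
    var = np.var(measured)
    if measured.size >= 2 and var > 0:
        slope = float(np.cov(measured, estimated, bias=True)[0, 1] / var)
        stats["slope"] = slope
        stats["intercept"] = float(estimated.mean() - slope * measured.mean())
    else:
        stats["slope"] = float("nan")
        stats["intercept"] = float("nan")
    return stats


def evaluate_agreement(measured, estimated, strata) -> dict:
    """Per-stratum and overall RMSE, mean bias and concordance line.

    ``measured`` and ``estimated`` are paired vectors; ``strata`` assigns
    each pair to a stratum.  Identical vectors give RMSE 0, slope 1,
    intercept 0; a constant offset d gives bias d and RMSE |d|.
    """
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    strata = np.asarray(strata)
    if not (measured.size == estimated.size == strata.size):
        raise ValueError("measured, estimated and strata must have equal length")
    report = {"overall": _agreement_stats(measured, estimated)}
    for s in np.unique(strata):
        mask = strata == s
        report[str(int(s))] = _agreement_stats(measured[mask], estimated[mask])
    return report


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full estimation chain and (optionally) write outputs.

    Writes ``models.json``, ``predictions.csv`` and ``report.json`` to
    ``cfg.out_dir`` when set.  Deterministic for fixed inputs and config.
    """
    stage = "load"
    try:
        residences = pd.read_csv(cfg.residences_csv)
        districts = pd.read_csv(cfg.districts_csv)
        meteo = pd.read_csv(cfg.meteo_csv)
        survey = pd.read_csv(cfg.survey_csv)
        log.info("load: %d residences, %d districts, %d survey records",
                 len(residences), len(districts), len(survey))

        stage = "preprocess"
        annual = annualize(residences, cfg.seasonal_factors, z_max=cfg.z_max)
        kept = annual[~annual["outlier_flag"]].copy()
        log.info("preprocess: kept %d of %d residences (%d outliers removed)",
                 len(kept), len(annual), int(annual["outlier_flag"].sum()))

        stage = "regional"
        district_tab = scale_reference(
            regional_weights(survey, "district"), cfg.soil_reference
        )
        province_tab = scale_reference(
            regional_weights(survey, "province"), cfg.outdoor_reference
        )
        cs_by_district = district_tab.set_index("region_id")["estimate"]
        gm_by_district = district_tab.set_index("region_id")["gm"]
        co_by_province = province_tab.set_index("region_id")["estimate"]

        stage = "ventilation"
        base = province_base_ventilation(meteo, cfg.ft, cfg.fw, cfg.indoor_temp)
        n_mult = kept["vent_habit"].map(cfg.habit_weights)
        if n_mult.isna().any():
            bad = sorted(kept.loc[n_mult.isna(), "vent_habit"].unique())
            raise KeyError(f"unknown ventilation habit(s) {bad}")
        kept["lam_v"] = kept["province_id"].map(base).to_numpy() * n_mult.to_numpy()

        stage = "invert"
        kept["cs"] = kept["district_id"].map(cs_by_district).to_numpy()
        kept["co"] = kept["province_id"].map(co_by_province).to_numpy()
        for col, what in (("cs", "district"), ("co", "province")):
            if kept[col].isna().any():
                missing = sorted(
                    kept.loc[kept[col].isna(), f"{what}_id"].unique()
                )
                raise KeyError(f"no survey records for {what}(s) {missing}")
        kept["s_obs"] = infiltration_from_measurement(
            kept["c_annual"].to_numpy(), kept["cs"].to_numpy(), 0.0,
            kept["co"].to_numpy(), cfg.lam, kept["lam_v"].to_numpy(),
        )

        stage = "fit"
        kept["greenery"] = kept["district_id"].map(
            districts.set_index("district_id")["greenery"]
        ).to_numpy()
        kept["district_gm"] = kept["district_id"].map(gm_by_district).to_numpy()
        designs = build_design(kept.rename(columns={"s_obs": "s"}), response="s")
        models = {
            stratum: fit_infiltration(X, y, stratum)
            for stratum, (X, y) in designs.items()
        }
        for stratum, model in models.items():
            log.info("fit: Type %d, n=%d, sigma=%.3f", stratum, model.nobs, model.sigma)

        stage = "predict"
        parts = []
        for stratum, (X, _y) in designs.items():
            model = models[stratum]
            beta = np.array([model.coefficients.get(c, 0.0) for c in X.columns])
            sub = kept.loc[X.index].copy()
            sub["s_hat"] = X.to_numpy() @ beta
            sub["ci_hat"] = steady_state_ci(
                sub["s_hat"].to_numpy(), sub["cs"].to_numpy(), 0.0,
                sub["co"].to_numpy(), cfg.lam, sub["lam_v"].to_numpy(),
            )
            parts.append(sub)
        predictions = pd.concat(parts).sort_index()[
            ["residence_id", "stratum", "district_id", "province_id", "c_annual",
             "lam_v", "cs", "co", "s_obs", "s_hat", "ci_hat"]
        ]

        stage = "evaluate"
        strata = predictions["stratum"].to_numpy()
        report = {
            "counts": {
                "input": int(len(annual)),
                "outliers_removed": int(annual["outlier_flag"].sum()),
                "analysed": int(len(predictions)),
            },
            "ci": evaluate_agreement(
                predictions["c_annual"], predictions["ci_hat"], strata
            ),
            "s": evaluate_agreement(
                predictions["s_obs"], predictions["s_hat"], strata
            ),
        }
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        raise PipelineError(stage, exc) from exc

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "models.json", "w") as fh:
            json.dump({str(k): m.to_dict() for k, m in models.items()},
                      fh, indent=2, sort_keys=True)
        predictions.to_csv(out / "predictions.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("wrote models.json, predictions.csv, report.json to %s", out)

    return PipelineResult(
        models=models,
        predictions=predictions,
        report=report,
        district_table=district_tab,
        province_table=province_tab,
    )
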