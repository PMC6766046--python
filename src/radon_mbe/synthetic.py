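"""Synthetic survey generator with the statistical structure the pipeline assumes.

Produces a complete desk-scale study — districts with greenery ratios and
winter survey records, province meteorology normals, and residences with
two-point radon measurements — by running the forward model: draw building
features, compute a true infiltration factor S from the stratified linear
model, a ventilation rate from meteorology and habits, regional soil and
outdoor radon from survey GM-ratio weights, and the annual indoor
concentration from the steady-state mass balance.  Measurements are then
de-annualized by the inverse seasonal factor and perturbed with
multiplicative log-normal error.

Per stratum, an affine map ``S = a*(X beta + eps) + b`` is solved
numerically so that the sample geometric mean and geometric standard
deviation of the generated annual concentrations hit the configured
stratum targets while S remains exactly linear in the design columns
(so a noiseless run is exactly identifiable end-to-end).  The map is
recorded in the truth output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .infiltration import InfiltrationModel, build_design, reference_model
from .mass_balance import RADON_DECAY_CONSTANT
from .pipeline import RunConfig, province_base_ventilation
from .preprocessing import DEFAULT_HABIT_WEIGHTS
from .regional import regional_weights, scale_reference

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_districts",
    "generate_meteorology",
    "generate_residences",
    "generate",
    "write_dataset",
    "simulate_design_rows",
    "SEASON_OF_MONTH",
]

log = logging.getLogger("radon_mbe.synthetic")

SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: Default seasonal correction factors used by the generator (annual =
#: seasonal measurement x factor): winter readings run above the annual
#: mean, summer readings below.
DEFAULT_SEASONAL_FACTORS = {
    "winter": 0.85, "spring": 1.0, "summer": 1.25, "autumn": 1.05,
}

_MATERIAL_PROBS = {
    "concrete": 0.40, "red_brick": 0.25, "cement_block": 0.15,
    "soil": 0.05, "wood": 0.05, "other": 0.10,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; the defaults are the study conditions.

    Stratum GM/GSD targets are the published per-type summaries of annual
    indoor radon; district/survey scale matches the national winter survey
    (233 districts, 17 provinces, national GM 86.52 Bq m-3, GSD 2.14);
    stratum shares put most residences in detached-no-groundwater and
    other-no-groundwater cells with the groundwater-using "other
    residences" type smallest.
    """

    n_districts: int = 233
    n_provinces: int = 17
    n_residences: int = 1400
    stratum_mix: tuple = (0.25, 0.35, 0.08, 0.32)
    gm_gsd_by_stratum: dict = field(default_factory=lambda: {
        1: (62.19, 1.68), 2: (49.71, 1.78), 3: (34.26, 1.25), 4: (44.48, 1.53),
    })
    eq_coefficients: dict | None = None      # stratum -> InfiltrationModel; None = packaged reference
    residual_sd: float = 2.0                 # Gaussian noise on S (Bq m-3 h-1)
    measurement_gsd: float = 1.1             # multiplicative error of each point
    outlier_fraction: float = 0.0            # share of residences with gross errors
    outlier_z: float = 6.0                   # log-scale size of planted gross errors (in sds)
    seasonal_factors: dict = field(
        default_factory=lambda: dict(DEFAULT_SEASONAL_FACTORS))
    habit_weights: dict = field(default_factory=lambda: dict(DEFAULT_HABIT_WEIGHTS))
    habit_probs: tuple = (0.3, 0.4, 0.3)     # low / medium / high
    ft: float = 0.03                         # h-1 degC-1
    fw: float = 0.01                         # h-1 s2 m-2
    indoor_temp: float = 20.0
    soil_reference: float = 86.52            # Bq m-3, scales district weights to Cs
    outdoor_reference: float = 10.0          # Bq m-3, scales province weights to Co
    lam: float = RADON_DECAY_CONSTANT
    greenery_range: tuple = (20.0, 80.0)     # percent
    district_gm_median: float = 86.52        # national winter survey GM
    district_gm_gsd: float = 1.5             # between-district spread
    survey_within_gsd: float = 1.8           # within-district spread
    survey_per_district: int = 30
    temp_mean: float = 12.0                  # degC, annual mean outdoor
    temp_amplitude: float = 13.0             # degC, seasonal half-range
    temp_noise_sd: float = 1.0
    province_temp_sd: float = 1.5
    wind_mean: float = 2.0                   # m s-1
    wind_noise_sd: float = 0.3
    province_wind_sd: float = 0.3
    crack_ge2_prob: float = 0.3
    floors_ge2_prob: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.stratum_mix) - 1.0) > 1e-9:
            raise ValueError("stratum_mix must sum to 1")
        lo, hi = self.greenery_range
        if not (0 <= lo < hi <= 100):
            raise ValueError("greenery_range must be an interval within [0, 100]")
        for s, (gm, gsd) in self.gm_gsd_by_stratum.items():
            if not (gm > 0 and gsd > 1):
                raise ValueError(f"stratum {s}: GM must be > 0 and GSD > 1")

    def models(self) -> dict[int, InfiltrationModel]:
        if self.eq_coefficients is None:
            return {s: reference_model(s) for s in (1, 2, 3, 4)}
        return {
            int(s): (m if isinstance(m, InfiltrationModel)
                     else InfiltrationModel.from_dict(m))
            for s, m in self.eq_coefficients.items()
        }


class SyntheticDataset(NamedTuple):
    districts: pd.DataFrame
    survey: pd.DataFrame
    meteo: pd.DataFrame
    residences: pd.DataFrame
    truth: "SyntheticTruth"


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``records`` holds, per residence, the true S, ventilation rate, annual
    indoor concentration, regional soil/outdoor radon and the planted
    outlier flag; ``calibration`` records the per-stratum affine map
    (scale, offset) applied to the linear predictor.
    """

    records: pd.DataFrame
    calibration: dict
    config: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "calibration": {str(k): v for k, v in self.calibration.items()},
            "config": self.config,
            "records": self.records.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            records=pd.DataFrame(payload["records"]),
            calibration={int(k): v for k, v in payload["calibration"].items()},
            config=payload["config"],
        )


def _rng_for(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_districts(cfg: GeneratorConfig, rng=None):
    """District table (greenery, province link, survey GM) plus survey records.

    Returns ``(districts, survey)``; the district survey GM is the realized
    geometric mean of that district's winter survey records, so downstream
    GM-ratio weights recomputed from the survey reproduce it exactly.
    """
    if cfg.n_districts < 1 or cfg.n_provinces < 1:
        raise ValueError("need at least one district and one province")
    rng = _rng_for(cfg, 1) if rng is None else rng
    ids = [f"D{i + 1:03d}" for i in range(cfg.n_districts)]
    provinces = [f"P{(i % cfg.n_provinces) + 1:02d}" for i in range(cfg.n_districts)]
    lo, hi = cfg.greenery_range
    greenery = rng.uniform(lo, hi, cfg.n_districts)
    medians = cfg.district_gm_median * np.exp(
        rng.normal(0.0, np.log(cfg.district_gm_gsd), cfg.n_districts)
    )
    m = cfg.survey_per_district
    values = np.exp(
        np.log(np.repeat(medians, m))
        + rng.normal(0.0, np.log(cfg.survey_within_gsd), cfg.n_districts * m)
    )
    survey = pd.DataFrame({
        "district_id": np.repeat(ids, m),
        "province_id": np.repeat(provinces, m),
        "radon_bq_m3": values,
    })
    gm = regional_weights(survey, "district").set_index("region_id")["gm"]
    districts = pd.DataFrame({
        "district_id": ids,
        "province_id": provinces,
        "greenery": greenery,
        "survey_gm": gm.loc[ids].to_numpy(),
    })
    return districts, survey


def generate_meteorology(cfg: GeneratorConfig, rng=None) -> pd.DataFrame:
    """12 monthly normals (outdoor temperature, wind) per province.

    Temperature follows a sinusoid coldest in January; winter-summer
    contrast is built in.  Wind speeds are non-negative.
    """
    if cfg.n_provinces < 1:
        raise ValueError("need at least one province")
    rng = _rng_for(cfg, 2) if rng is None else rng
    rows = []
    months = np.arange(1, 13)
    seasonal = -cfg.temp_amplitude * np.cos(2 * np.pi * (months - 1) / 12.0)
    for p in range(cfg.n_provinces):
        pid = f"P{p + 1:02d}"
        t_off = rng.normal(0.0, cfg.province_temp_sd)
        w_off = rng.normal(0.0, cfg.province_wind_sd)
        temp = cfg.temp_mean + t_off + seasonal + rng.normal(0, cfg.temp_noise_sd, 12)
        wind = np.clip(
            cfg.wind_mean + w_off + rng.normal(0, cfg.wind_noise_sd, 12), 0.1, None
        )
        rows.append(pd.DataFrame({
            "province_id": pid, "month": months, "temp_c": temp, "wind_ms": wind,
        }))
    return pd.concat(rows, ignore_index=True)


def _solve_offset(a, Z, base, denom, mu_target):
    """Offset b such that mean log((a Z + b + base)/denom) = mu_target, or None."""
    core = a * Z + base

    def f(b):
        return np.log((core + b) / denom).mean() - mu_target

    b_min = -core.min()
    lo = b_min + max(1e-12, abs(b_min) * 1e-12)
    # near b_min one term's log diverges to -inf; step in until finite
    for _ in range(60):
        val = f(lo)
        if np.isfinite(val):
            break
        lo = b_min + (lo - b_min) * 2 + 1e-12
    else:
        return None
    if val > 0:
        return None  # even the smallest admissible offset overshoots the GM
    hi = max(lo + 1.0, float(np.exp(mu_target) * denom.mean()))
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        return None
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=300)


def _calibrate_affine(Z, base, denom, gm_target, gsd_target):
    """Solve S = a*Z + b so sample GM/GSD of (a Z + b + base)/denom hit targets.

    Nested bisection: for each candidate scale a the offset b is solved to
    match the GM; the outer loop bisects a to match the GSD.  The
    heterogeneity of ventilation rates and regional terms sets a floor on
    the attainable GSD at a = 0; a config whose GSD target sits below that
    floor is rejected.
    """
    mu_t = float(np.log(gm_target))
    sd_t = float(np.log(gsd_target))

    def spread(a):
        b = _solve_offset(a, Z, base, denom, mu_t)
        if b is None:
            return None, None
        sd = float(np.log((a * Z + b + base) / denom).std(ddof=1))
        return sd - sd_t, b

    g0, b0 = spread(0.0)
    if g0 is None or g0 > 0:
        raise ValueError(
            "GSD target is below the floor set by ventilation/regional "
            "heterogeneity; reduce those spreads or raise the GSD target"
        )
    a_lo, a_hi = 0.0, max(1e-6, sd_t * np.exp(mu_t) * float(denom.mean())
                          / max(float(np.std(Z)), 1e-12))
    for _ in range(200):
        g, _b = spread(a_hi)
        if g is None or g > 0:
            break
        a_lo = a_hi
        a_hi *= 2.0
    b_best = b0
    a_best = a_lo
    for _ in range(80):
        mid = 0.5 * (a_lo + a_hi)
        g, b = spread(mid)
        if g is None or g > 0:
            a_hi = mid
        else:
            a_lo, a_best, b_best = mid, mid, b
    # final solve at the chosen scale
    b = _solve_offset(a_best, Z, base, denom, mu_t)
    return float(a_best), float(b if b is not None else b_best)


def generate_residences(cfg: GeneratorConfig, districts, survey, meteo, rng=None):
    """Forward-simulate residences and their two-point measurements.

    Returns ``(residences, truth)``.  The truth S satisfies the
    steady-state inversion applied to the truth Ci, ventilation rate and
    regional terms exactly.
    """
    rng = _rng_for(cfg, 3) if rng is None else rng
    n = cfg.n_residences
    models = cfg.models()

    strata = rng.choice([1, 2, 3, 4], size=n, p=list(cfg.stratum_mix))
    d_idx = rng.integers(0, len(districts), size=n)
    district_id = districts["district_id"].to_numpy()[d_idx]
    province_id = districts["province_id"].to_numpy()[d_idx]
    greenery = districts["greenery"].to_numpy()[d_idx]

    res_type = np.where(strata <= 2, "detached", "other")
    groundwater = np.where(np.isin(strata, (1, 3)), "yes", "no")

    material = np.empty(n, dtype=object)
    for s in (1, 2, 3, 4):
        mask = strata == s
        levels = list(models[s].materials)
        p = np.array([_MATERIAL_PROBS[m] for m in levels])
        p = p / p.sum()
        material[mask] = rng.choice(levels, size=int(mask.sum()), p=p)
    cracks = np.where(rng.random(n) < cfg.crack_ge2_prob, ">=2", "0-1")
    floors = np.where(rng.random(n) < cfg.floors_ge2_prob, ">=2", "<=1")
    habit = rng.choice(["low", "medium", "high"], size=n, p=list(cfg.habit_probs))
    season = rng.choice(["winter", "spring", "summer", "autumn"], size=n)

    # regional terms and ventilation, via the same constructions the
    # pipeline applies to the written CSVs
    district_tab = scale_reference(regional_weights(survey, "district"),
                                   cfg.soil_reference)
    province_tab = scale_reference(regional_weights(survey, "province"),
                                   cfg.outdoor_reference)
    cs = pd.Series(district_id).map(
        district_tab.set_index("region_id")["estimate"]).to_numpy()
    district_gm = pd.Series(district_id).map(
        district_tab.set_index("region_id")["gm"]).to_numpy()
    co = pd.Series(province_id).map(
        province_tab.set_index("region_id")["estimate"]).to_numpy()
    base_rate = province_base_ventilation(meteo, cfg.ft, cfg.fw, cfg.indoor_temp)
    n_mult = pd.Series(habit).map(cfg.habit_weights).to_numpy(dtype=float)
    lam_v = pd.Series(province_id).map(base_rate).to_numpy() * n_mult

    frame = pd.DataFrame({
        "stratum": strata, "greenery": greenery, "district_gm": district_gm,
        "material": material, "cracks": cracks, "floors": floors,
    })
    eps = rng.normal(0.0, cfg.residual_sd, size=n)
    s_true = np.empty(n)
    calibration = {}
    denom_all = cfg.lam + lam_v
    base_all = lam_v * co - cfg.lam * cs
    designs = build_design(frame, response=None)
    for s, (X, _y) in designs.items():
        idx = X.index.to_numpy()
        beta = np.array([models[s].coefficients.get(c, 0.0) for c in X.columns])
        Z = X.to_numpy() @ beta + eps[idx]
        gm_t, gsd_t = cfg.gm_gsd_by_stratum[s]
        if len(idx) >= 8:
            a, b = _calibrate_affine(Z, base_all[idx], denom_all[idx], gm_t, gsd_t)
        else:
            # too few rows to match a spread; pin the level only
            a = 0.0
            b = _solve_offset(0.0, Z, base_all[idx], denom_all[idx],
                              float(np.log(gm_t)))
            b = float(b) if b is not None else float(np.log(gm_t))
        s_true[idx] = a * Z + b
        calibration[int(s)] = {"scale": a, "offset": b}

    ci_annual = (s_true + base_all) / denom_all
    bad = ci_annual <= 0
    if bad.any():  # calibration enforces positivity; reachable only off-config
        warnings.warn(f"resampling {int(bad.sum())} residences with "
                      "non-positive generated Ci", RuntimeWarning)
        ci_annual[bad] = np.abs(ci_annual[bad]) + 1e-6
        s_true[bad] = ci_annual[bad] * denom_all[bad] - base_all[bad]

    factors = pd.Series(season).map(cfg.seasonal_factors).to_numpy(dtype=float)
    sigma_m = np.log(cfg.measurement_gsd)
    raw = ci_annual / factors
    pt1 = raw * np.exp(rng.normal(0.0, sigma_m, n))
    pt2 = raw * np.exp(rng.normal(0.0, sigma_m, n))

    outlier = np.zeros(n, dtype=bool)
    k = int(round(cfg.outlier_fraction * n))
    if k > 0:
        idx = rng.choice(n, size=k, replace=False)
        sign = rng.choice([-1.0, 1.0], size=k)
        sd_log = pd.Series(strata).map(
            {s: np.log(g[1]) for s, g in cfg.gm_gsd_by_stratum.items()}
        ).to_numpy()[idx]
        shift = np.exp(sign * cfg.outlier_z * sd_log)
        pt1[idx] *= shift
        pt2[idx] *= shift
        outlier[idx] = True
        log.info("planted %d gross outliers (%.1f sd, log scale)", k, cfg.outlier_z)

    rid = [f"R{i + 1:05d}" for i in range(n)]
    residences = pd.DataFrame({
        "residence_id": rid,
        "district_id": district_id,
        "province_id": province_id,
        "res_type": res_type,
        "groundwater": groundwater,
        "material": material,
        "cracks": cracks,
        "floors": floors,
        "vent_habit": habit,
        "season": season,
        "radon_pt1": pt1,
        "radon_pt2": pt2,
    })
    truth_records = pd.DataFrame({
        "residence_id": rid,
        "stratum": strata,
        "s_true": s_true,
        "lam_v": lam_v,
        "ci_annual": ci_annual,
        "cs": cs,
        "co": co,
        "outlier": outlier,
    })
    truth = SyntheticTruth(
        records=truth_records,
        calibration=calibration,
        config={k: v for k, v in asdict(cfg).items() if k != "eq_coefficients"},
    )
    return residences, truth


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full dataset; fully deterministic under ``cfg.seed``."""
    districts, survey = generate_districts(cfg, _rng_for(cfg, 1))
    meteo = generate_meteorology(cfg, _rng_for(cfg, 2))
    residences, truth = generate_residences(
        cfg, districts, survey, meteo, _rng_for(cfg, 3)
    )
    return SyntheticDataset(districts, survey, meteo, residences, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path,
                  cfg: GeneratorConfig) -> RunConfig:
    """Write CSVs, truth.json and a ready-to-run pipeline config.

    Returns the RunConfig (also saved as ``run_config.yaml``) whose
    seasonal factors, habit weights, ft/fw and reference levels are the
    ones the generator used.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.districts.to_csv(out / "districts.csv", index=False)
    ds.survey.to_csv(out / "survey.csv", index=False)
    ds.meteo.to_csv(out / "meteo.csv", index=False)
    ds.residences.to_csv(out / "residences.csv", index=False)
    ds.truth.to_json(out / "truth.json")
    with open(out / "seasonal_factors.yaml", "w") as fh:
        yaml.safe_dump(dict(cfg.seasonal_factors), fh)
    with open(out / "habit_weights.yaml", "w") as fh:
        yaml.safe_dump(dict(cfg.habit_weights), fh)
    out_abs = out.resolve()
    run_cfg = RunConfig(
        residences_csv=str(out_abs / "residences.csv"),
        districts_csv=str(out_abs / "districts.csv"),
        meteo_csv=str(out_abs / "meteo.csv"),
        survey_csv=str(out_abs / "survey.csv"),
        ft=cfg.ft,
        fw=cfg.fw,
        indoor_temp=cfg.indoor_temp,
        habit_weights=dict(cfg.habit_weights),
        seasonal_factors=dict(cfg.seasonal_factors),
        soil_reference=cfg.soil_reference,
        outdoor_reference=cfg.outdoor_reference,
        lam=cfg.lam,
        out_dir=str(out_abs / "results"),
        seed=cfg.seed,
    )
    # the saved config uses paths relative to its own location, so the
    # dataset directory stays relocatable
    portable = RunConfig(**{**run_cfg.__dict__,
                            "residences_csv": "residences.csv",
                            "districts_csv": "districts.csv",
                            "meteo_csv": "meteo.csv",
                            "survey_csv": "survey.csv",
                            "out_dir": "results"})
    portable.to_yaml(out / "run_config.yaml")
    return run_cfg


def simulate_design_rows(
    stratum: int,
    n: int,
    rng: np.random.Generator,
    coefficients: InfiltrationModel | None = None,
    residual_sd: float = 2.0,
    x2_gm: float = 86.5,
    x2_gsd: float = 2.1,
) -> pd.DataFrame:
    """Simulate bare regression rows for coefficient-recovery studies.

    Covariates: greenery ~ U(0, 100); district GM log-normal (GM ``x2_gm``,
    GSD ``x2_gsd``, the national winter-survey scale); categorical levels
    uniform over the stratum's allowed levels.  The response is the linear
    predictor under ``coefficients`` (default: packaged reference column
    for the stratum) plus N(0, residual_sd) noise.
    """
    model = coefficients if coefficients is not None else reference_model(stratum)
    df = pd.DataFrame({
        "stratum": stratum,
        "greenery": rng.uniform(0.0, 100.0, n),
        "district_gm": np.exp(rng.normal(np.log(x2_gm), np.log(x2_gsd), n)),
        "material": rng.choice(list(model.materials), size=n),
        "cracks": (rng.choice(["0-1", ">=2"], size=n)
                   if model.has_cracks else "0-1"),
        "floors": (rng.choice(["<=1", ">=2"], size=n)
                   if model.has_floors else "<=1"),
    })
    (X, _y), = build_design(df, response=None).values()
    beta = np.array([model.coefficients.get(c, 0.0) for c in X.columns])
    df["s"] = X.to_numpy() @ beta + rng.normal(0.0, residual_sd, n)
    return df
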