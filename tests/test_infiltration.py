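"""Stratified OLS infiltration-factor model: design, fit, prediction."""

import numpy as np
import pandas as pd
import pytest

from radon_mbe.infiltration import (
    build_design,
    design_columns,
    fit_infiltration,
    predict_ci,
    predict_s,
    reference_model,
    stratum_metadata,
)
from radon_mbe.mass_balance import RADON_DECAY_CONSTANT, steady_state_ci
from radon_mbe.synthetic import simulate_design_rows


class TestReferenceMetadata:
    def test_type3_predictor_set_is_reduced(self):
        meta = stratum_metadata(3)
        assert meta["materials"] == ("concrete", "red_brick", "cement_block")
        assert not meta["has_cracks"] and not meta["has_floors"]
        cols = design_columns(3)
        assert "cracks_ge2" not in cols and "floors_ge2" not in cols

    def test_full_strata_carry_all_terms(self):
        for s in (1, 2):
            cols = design_columns(s)
            assert "material:wood" in cols
            assert "cracks_ge2" in cols and "floors_ge2" in cols
        assert "material:soil" not in design_columns(4)


class TestBuildDesign:
    def _records(self):
        return pd.DataFrame({
            "stratum": [1, 1, 3, 4],
            "greenery": [10.0, 20.0, 30.0, 40.0],
            "district_gm": [50.0, 60.0, 70.0, 80.0],
            "material": ["concrete", "wood", "red_brick", "other"],
            "cracks": ["0-1", ">=2", "0-1", ">=2"],
            "floors": ["<=1", ">=2", ">=2", "<=1"],
            "s": [1.0, 2.0, 3.0, 4.0],
        })

    def test_reference_cell_has_zero_dummies(self):
        designs = build_design(self._records())
        X1, _ = designs[1]
        ref_row = X1.iloc[0]
        dummies = [c for c in X1.columns
                   if c.startswith(("material:", "cracks", "floors"))]
        assert all(ref_row[c] == 0.0 for c in dummies)
        assert ref_row["intercept"] == 1.0

    def test_rows_partition_by_stratum(self):
        designs = build_design(self._records())
        assert sorted(designs) == [1, 3, 4]
        assert sum(len(X) for X, _ in designs.values()) == 4

    def test_type3_never_emits_crack_or_floor_columns(self):
        designs = build_design(self._records())
        X3, _ = designs[3]
        assert not any(c.startswith(("cracks", "floors")) for c in X3.columns)

    def test_unseen_material_level_named_in_error(self):
        records = self._records()
        records.loc[2, "material"] = "wood"  # not allowed in Type 3
        with pytest.raises(ValueError, match="wood"):
            build_design(records)


class TestFit:
    def test_zero_noise_recovers_reference_exactly(self, rng):
        for stratum in (1, 2, 3, 4):
            df = simulate_design_rows(stratum, 400, rng, residual_sd=0.0)
            (X, _), = build_design(df, response=None).values()
            model_ref = reference_model(stratum)
            y = df["s"]
            fitted = fit_infiltration(X, y, stratum)
            for name, value in model_ref.coefficients.items():
                assert fitted.coefficients[name] == pytest.approx(value, abs=1e-8)
            assert fitted.sigma == pytest.approx(0.0, abs=1e-7)

    def test_doubling_response_doubles_coefficients(self, rng):
        df = simulate_design_rows(2, 300, rng, residual_sd=1.0)
        (X, _), = build_design(df, response=None).values()
        m1 = fit_infiltration(X, df["s"], 2)
        m2 = fit_infiltration(X, 2.0 * df["s"], 2)
        for name in m1.coefficients:
            assert m2.coefficients[name] == pytest.approx(
                2 * m1.coefficients[name], rel=1e-9, abs=1e-9)

    def test_residuals_orthogonal_to_design(self, rng):
        df = simulate_design_rows(1, 500, rng, residual_sd=2.0)
        (X, _), = build_design(df, response=None).values()
        m = fit_infiltration(X, df["s"], 1)
        beta = np.array([m.coefficients.get(c, 0.0) for c in X.columns])
        resid = df["s"].to_numpy() - X.to_numpy() @ beta
        scale = np.abs(X.to_numpy()).sum(axis=0)
        assert np.all(np.abs(X.to_numpy().T @ resid) / scale < 1e-8)

    def test_stochastic_recovery_near_published_value(self, rng):
        # district-GM slope, detached+groundwater stratum: published 2.73 (SE 0.07)
        estimates = [
            fit_infiltration(
                *(lambda d: (build_design(d, None)[1][0], d["s"]))(
                    simulate_design_rows(1, 500, rng, residual_sd=2.0)
                ), 1,
            ).coefficients["district_gm"]
            for _ in range(3)
        ]
        assert abs(np.mean(estimates) - 2.73) < 3 * 0.07

    def test_rank_deficiency_names_columns(self, rng):
        df = simulate_design_rows(1, 100, rng, residual_sd=1.0)
        df["greenery"] = 0.0  # constant column duplicates the intercept
        (X, _), = build_design(df, response=None).values()
        with pytest.raises(ValueError, match="greenery"):
            fit_infiltration(X, df["s"], 1)

    def test_too_few_rows_rejected(self, rng):
        df = simulate_design_rows(1, 6, rng, residual_sd=1.0)
        (X, _), = build_design(df, response=None).values()
        with pytest.raises(ValueError, match="rows"):
            fit_infiltration(X, df["s"], 1)


class TestPredict:
    def test_reference_residence_intercepts(self):
        # reference cell at zero covariates returns the stratum intercept
        m4 = reference_model(4)
        row = {"greenery": 0.0, "district_gm": 0.0, "material": "concrete",
               "cracks": "0-1", "floors": "<=1"}
        assert predict_s(m4, row) == pytest.approx(11.09)
        m1 = reference_model(1)
        row1 = dict(row, greenery=10.0, district_gm=50.0)
        assert predict_s(m1, row1) == pytest.approx(-15.89 + 0.18 * 10 + 2.73 * 50)

    def test_unknown_level_rejected(self):
        m3 = reference_model(3)
        row = {"greenery": 10.0, "district_gm": 50.0, "material": "wood"}
        with pytest.raises(ValueError, match="wood"):
            predict_s(m3, row)

    def test_mean_design_point_prediction_equals_mean_fit(self, rng):
        df = simulate_design_rows(2, 400, rng, residual_sd=2.0)
        (X, _), = build_design(df, response=None).values()
        m = fit_infiltration(X, df["s"], 2)
        beta = np.array([m.coefficients.get(c, 0.0) for c in X.columns])
        fitted_mean = float(X.to_numpy().mean(axis=0) @ beta)
        assert fitted_mean == pytest.approx(float(df["s"].mean()), rel=1e-10)

    def test_predict_ci_composes_steady_state(self):
        m1 = reference_model(1)
        row = {"greenery": 10.0, "district_gm": 50.0, "material": "concrete",
               "cracks": "0-1", "floors": "<=1"}
        s = predict_s(m1, row)
        ci = predict_ci(m1, row, Cs=100.0, Co=10.0, lam_v=0.34)
        assert ci == pytest.approx(
            steady_state_ci(s, 100.0, 0.0, 10.0, RADON_DECAY_CONSTANT, 0.34))

    def test_predict_ci_monotone_in_s(self):
        m1 = reference_model(1)
        lo = dict(greenery=0.0, district_gm=30.0, material="concrete",
                  cracks="0-1", floors="<=1")
        hi = dict(lo, district_gm=60.0)
        assert (predict_ci(m1, hi, Cs=80.0, Co=10.0, lam_v=0.3)
                > predict_ci(m1, lo, Cs=80.0, Co=10.0, lam_v=0.3))


def test_model_round_trips_through_dict(rng):
    from radon_mbe.infiltration import InfiltrationModel
    df = simulate_design_rows(4, 200, rng, residual_sd=1.0)
    (X, _), = build_design(df, response=None).values()
    m = fit_infiltration(X, df["s"], 4)
    again = InfiltrationModel.from_dict(m.to_dict())
    assert again == m
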