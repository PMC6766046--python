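"""Physical core: ventilation, steady state, inversion, dynamics, dose."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radon_mbe.mass_balance import (
    RADON_DECAY_CONSTANT,
    CompartmentState,
    MassBalanceParams,
    Trajectory,
    VentilationInputs,
    annual_effective_dose,
    infiltration_from_measurement,
    simulate_dynamics,
    steady_state,
    steady_state_ci,
    ventilation_rate,
)

finite = st.floats(allow_nan=False, allow_infinity=False)


class TestVentilationRate:
    def test_hand_example(self):
        v = VentilationInputs(ft=0.01, fw=0.005, Ti=20, To=0, u=2, N=1)
        assert ventilation_rate(v) == pytest.approx(0.22)

    def test_vanishes_without_driving_forces(self):
        v = VentilationInputs(ft=0.5, fw=0.3, Ti=15, To=15, u=0, N=2)
        assert ventilation_rate(v) == 0.0

    @given(
        ft=st.floats(0, 1), fw=st.floats(0, 1),
        Ti=st.floats(-30, 40), To=st.floats(-30, 40),
        u=st.floats(0, 20), N=st.floats(0, 5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_homogeneous_in_n_and_temperature_symmetric(self, ft, fw, Ti, To, u, N):
        base = ventilation_rate(VentilationInputs(ft, fw, Ti, To, u, N))
        doubled = ventilation_rate(VentilationInputs(ft, fw, Ti, To, u, 2 * N))
        swapped = ventilation_rate(VentilationInputs(ft, fw, To, Ti, u, N))
        assert doubled == pytest.approx(2 * base, rel=1e-12, abs=1e-12)
        assert swapped == pytest.approx(base, rel=1e-12, abs=1e-12)
        assert base >= 0

    @pytest.mark.parametrize("bad", [
        dict(ft=-0.1), dict(fw=-0.1), dict(N=-1.0), dict(u=-2.0),
    ])
    def test_negative_inputs_rejected(self, bad):
        kwargs = dict(ft=0.01, fw=0.005, Ti=20, To=0, u=2, N=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            VentilationInputs(**kwargs)


class TestSteadyState:
    def test_hand_example(self):
        ci = steady_state_ci(S=10, Cs=100, Cbm=0, Co=10, lam=7.56e-3, lam_v=0.34)
        assert ci == pytest.approx(12.644 / 0.34756, rel=1e-9)
        assert ci == pytest.approx(36.38, abs=0.01)

    def test_no_sources_gives_zero(self):
        assert steady_state_ci(0, 0, 0, 0, lam=7.56e-3, lam_v=0.1) == 0.0

    def test_high_ventilation_limit_is_outdoor_level(self):
        ci = steady_state_ci(50, 300, 50, Co=8.0, lam=7.56e-3, lam_v=1e9)
        assert ci == pytest.approx(8.0, rel=1e-6)

    def test_negative_value_returned_with_warning(self):
        with pytest.warns(RuntimeWarning):
            ci = steady_state_ci(0, 1e4, 0, 0, lam=7.56e-3, lam_v=0.3)
        assert ci < 0  # algebraic value, not clamped

    def test_monotone_in_s_and_co_and_ventilation(self):
        kw = dict(Cs=50, Cbm=0, lam=7.56e-3)
        assert (steady_state_ci(S=20, Co=10, lam_v=0.3, **kw)
                > steady_state_ci(S=10, Co=10, lam_v=0.3, **kw))
        assert (steady_state_ci(S=10, Co=20, lam_v=0.3, **kw)
                > steady_state_ci(S=10, Co=10, lam_v=0.3, **kw))
        # when indoor exceeds outdoor, more ventilation dilutes
        lo = steady_state_ci(S=50, Co=5, lam_v=0.6, **kw)
        hi = steady_state_ci(S=50, Co=5, lam_v=0.3, **kw)
        assert lo < hi

    def test_zero_rate_sum_rejected(self):
        with pytest.raises(ValueError):
            steady_state_ci(10, 0, 0, 0, lam=0.0, lam_v=0.0)


class TestInfiltrationInversion:
    def test_round_trip_of_hand_example(self):
        ci = steady_state_ci(10, 100, 0, 10, 7.56e-3, 0.34)
        s = infiltration_from_measurement(ci, 100, 0, 10, 7.56e-3, 0.34)
        assert s == pytest.approx(10.0, rel=1e-12)

    def test_zero_measurement_zero_background(self):
        assert infiltration_from_measurement(0, 0, 0, 0, 7.56e-3, 0.2) == 0.0

    @given(
        S=st.floats(0.01, 500), Cs=st.floats(0, 1000), Cbm=st.floats(0, 200),
        Co=st.floats(0, 50), lam_v=st.floats(0, 3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_algebraic_inverse_property(self, S, Cs, Cbm, Co, lam_v):
        ci = steady_state_ci(S, Cs, Cbm, Co, RADON_DECAY_CONSTANT, lam_v)
        back = infiltration_from_measurement(ci, Cs, Cbm, Co,
                                             RADON_DECAY_CONSTANT, lam_v)
        assert back == pytest.approx(S, rel=1e-9, abs=1e-9)


def _random_params(rng):
    return MassBalanceParams(
        Es=rng.uniform(0, 500), Ebm=rng.uniform(0, 50),
        kd_s=rng.uniform(1e-3, 0.05), kd_bm=rng.uniform(1e-3, 0.05),
        ka=rng.uniform(1e-4, 1e-2), dP_si=rng.uniform(0, 5),
        Sg=rng.uniform(20, 200), Sbm=rng.uniform(50, 500),
        V=rng.uniform(100, 500), Co=rng.uniform(0, 20),
    )


def _random_vent(rng):
    return VentilationInputs(
        ft=rng.uniform(0, 0.05), fw=rng.uniform(0, 0.02), Ti=20.0,
        To=rng.uniform(-5, 30), u=rng.uniform(0, 5), N=rng.uniform(0.5, 1.5),
    )


class TestDynamics:
    def test_zero_sources_stay_zero(self):
        p = MassBalanceParams(Es=0, Ebm=0, kd_s=0.01, kd_bm=0.01, ka=1e-3,
                              dP_si=1, Sg=50, Sbm=100, V=250, Co=0)
        v = VentilationInputs(ft=0.02, fw=0.01, Ti=20, To=5, u=2)
        traj = simulate_dynamics(p, v, CompartmentState(0, 0, 0), t_end=100.0)
        assert isinstance(traj, Trajectory)
        assert np.allclose([traj.Ci, traj.Cs, traj.Cbm], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_converges_to_linear_fixed_point_and_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        p, v = _random_params(rng), _random_vent(rng)
        traj = simulate_dynamics(p, v, CompartmentState(0, 0, 0), t_end=1e4)
        fp = steady_state(p, v)
        final = traj.final()
        assert final.Ci == pytest.approx(fp.Ci, rel=1e-6)
        assert final.Cs == pytest.approx(fp.Cs, rel=1e-6)
        assert final.Cbm == pytest.approx(fp.Cbm, rel=1e-6)
        # closed form with S = Es*Sg/V + Ebm*Sbm/V at the converged state
        from radon_mbe.mass_balance import ventilation_rate as vr
        ci = steady_state_ci(p.infiltration_factor, fp.Cs, fp.Cbm, p.Co,
                             p.lam, vr(v))
        assert fp.Ci == pytest.approx(ci, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        p = _random_params(np.random.default_rng(0))
        v = _random_vent(np.random.default_rng(0))
        with pytest.raises(ValueError):
            simulate_dynamics(p, v, CompartmentState(0, 0, 0), t_end=-1.0)
        with pytest.raises(ValueError):
            simulate_dynamics(p, v, CompartmentState(-1, 0, 0), t_end=10.0)


class TestDose:
    def test_hand_product(self):
        assert annual_effective_dose(50, 0.4, 7000, 9e-9) == pytest.approx(1.26e-3)

    def test_any_zero_factor_zeroes_dose_and_identity(self):
        assert annual_effective_dose(0, 0.4, 7000, 9e-9) == 0.0
        assert annual_effective_dose(1, 1, 1, 1) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            annual_effective_dose(-1, 0.4, 7000, 9e-9)


def test_params_invariants_enforced():
    with pytest.raises(ValueError):
        MassBalanceParams(Es=1, Ebm=1, kd_s=0.01, kd_bm=0.01, ka=1e-3,
                          dP_si=1, Sg=0, Sbm=10, V=100)
    with pytest.raises(ValueError):
        MassBalanceParams(Es=1, Ebm=1, kd_s=0.01, kd_bm=0.01, ka=1e-3,
                          dP_si=1, Sg=10, Sbm=10, V=100, lam=0.0)
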