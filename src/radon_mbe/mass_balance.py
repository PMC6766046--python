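"""Physical core: three-compartment mass balance of indoor radon.

Indoor radon concentration ``Ci`` is modelled with a linear mass-balance
system coupling three compartments — indoor air, the soil beneath the
building and the radon-bearing building materials.  Radon enters indoors by
diffusion and pressure-driven advection from soil, by diffusion from
building materials, and with outdoor make-up air; it is removed by
ventilation and radioactive decay.  The system is linear, so it has a
unique fixed point that can be written in closed form; at steady state the
combined entry term ``S = Es*Sg/V + Ebm*Sbm/V`` (the *infiltration factor*,
Bq m-3 h-1) relates measured indoor radon to its sources and can be
recovered algebraically from a measurement.

All rates are per hour; concentrations are Bq m-3; temperatures are deg C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RADON_DECAY_CONSTANT",
    "RADON_HALF_LIFE_DAYS",
    "MassBalanceParams",
    "VentilationInputs",
    "CompartmentState",
    "Trajectory",
    "ventilation_rate",
    "steady_state_ci",
    "infiltration_from_measurement",
    "steady_state",
    "simulate_dynamics",
    "annual_effective_dose",
]

#: Radon-222 decay constant (h-1) as conventionally used in indoor-radon
#: modelling; consistent with the 3.82-day half-life.
RADON_DECAY_CONSTANT = 7.56e-3

#: Radon-222 half-life in days (for the analytic cross-check ln2 / (T1/2 * 24)).
RADON_HALF_LIFE_DAYS = 3.8235


@dataclass(frozen=True)
class MassBalanceParams:
    """Physical parameters of the three-compartment model.

    Attributes
    ----------
    Es, Ebm : float
        Effective radon exhalation rates of soil / building materials
        (Bq m-2 h-1).
    kd_s, kd_bm : float
        Diffusion transfer coefficients of soil / building materials (m h-1).
    ka : float
        Advection transfer coefficient of soil (m Pa-1 h-1).
    dP_si : float
        Soil-indoor pressure difference (Pa).
    Sg : float
        Building area towards the ground (m2).
    Sbm : float
        Indoor surface area of radon-containing building materials (m2).
    V : float
        Indoor volume (m3).
    lam : float
        Radon decay constant (h-1).
    Co : float
        Outdoor radon concentration (Bq m-3).
    """

    Es: float
    Ebm: float
    kd_s: float
    kd_bm: float
    ka: float
    dP_si: float
    Sg: float
    Sbm: float
    V: float
    lam: float = RADON_DECAY_CONSTANT
    Co: float = 0.0

    def __post_init__(self) -> None:
        if self.Sg <= 0 or self.V <= 0:
            raise ValueError("Sg and V must be positive")
        if self.Sbm < 0:
            raise ValueError("Sbm must be non-negative")
        if self.lam <= 0:
            raise ValueError("decay constant lam must be positive")
        for name in ("Es", "Ebm", "kd_s", "kd_bm", "ka", "Co"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def infiltration_factor(self) -> float:
        """Entry-rate term S = Es*Sg/V + Ebm*Sbm/V (Bq m-3 h-1)."""
        return self.Es * self.Sg / self.V + self.Ebm * self.Sbm / self.V


@dataclass(frozen=True)
class VentilationInputs:
    """Inputs to the meteorological ventilation-rate model.

    ``ft`` (h-1 degC-1) and ``fw`` (h-1 s2 m-2) are empirical fitting
    parameters; ``N`` is the dimensionless habit-weighted ventilation
    multiplier.
    """

    ft: float
    fw: float
    Ti: float
    To: float
    u: float
    N: float = 1.0

    def __post_init__(self) -> None:
        if self.ft < 0 or self.fw < 0 or self.N < 0:
            raise ValueError("ft, fw and N must be non-negative")
        if self.u < 0:
            raise ValueError("wind speed u must be non-negative")


@dataclass(frozen=True)
class CompartmentState:
    """Concentrations of the three compartments at time ``t`` (hours)."""

    Ci: float
    Cs: float
    Cbm: float
    t: float = 0.0


@dataclass(frozen=True)
class Trajectory:
    """Time series of compartment concentrations from an ODE integration."""

    t: np.ndarray
    Ci: np.ndarray
    Cs: np.ndarray
    Cbm: np.ndarray

    def final(self) -> CompartmentState:
        return CompartmentState(
            Ci=float(self.Ci[-1]),
            Cs=float(self.Cs[-1]),
            Cbm=float(self.Cbm[-1]),
            t=float(self.t[-1]),
        )


def ventilation_rate(v: VentilationInputs) -> float:
    """Air-exchange rate lambda_v = (ft*|Ti - To| + fw*u^2) * N, in h-1.

    Linear in the habit multiplier ``N`` and symmetric in the indoor and
    outdoor temperatures (only their absolute difference matters).
    """
    return (v.ft * abs(v.Ti - v.To) + v.fw * v.u**2) * v.N


def ventilation_rate_profile(ft, fw, Ti, To, u, N=1.0):
    """Vectorised ventilation rate over arrays of To / u (e.g. 12 months)."""
    ft, fw, N = float(ft), float(fw), float(N)
    if ft < 0 or fw < 0 or N < 0:
        raise ValueError("ft, fw and N must be non-negative")
    To = np.asarray(To, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("wind speed u must be non-negative")
    return (ft * np.abs(Ti - To) + fw * u**2) * N


def steady_state_ci(S, Cs, Cbm, Co, lam=RADON_DECAY_CONSTANT, lam_v=0.0):
    """Closed-form steady-state indoor radon concentration (Bq m-3).

    ``Ci = (S + lam_v*Co - lam*(Cs + Cbm)) / (lam + lam_v)``.

    The algebraic value is returned even when negative (physically
    inconsistent inputs); a warning is emitted in that case rather than
    clamping, so that the inversion ``infiltration_from_measurement`` remains
    an exact inverse.  Accepts scalars or aligned arrays.
    """
    lam = np.asarray(lam, dtype=float)
    lam_v = np.asarray(lam_v, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("decay constant lam must be positive")
    if np.any(lam_v < 0):
        raise ValueError("ventilation rate lam_v must be non-negative")
    denom = lam + lam_v
    if np.any(denom == 0):
        raise ZeroDivisionError("lam + lam_v must be positive")
    ci = (np.asarray(S, dtype=float) + lam_v * np.asarray(Co, dtype=float)
          - lam * (np.asarray(Cs, dtype=float) + np.asarray(Cbm, dtype=float))) / denom
    if np.any(ci < 0):
        warnings.warn(
            "steady-state Ci is negative for some inputs (inconsistent "
            "source/sink balance); returning the algebraic value",
            RuntimeWarning,
            stacklevel=2,
        )
    if np.ndim(ci) == 0:
        return float(ci)
    return ci


def infiltration_from_measurement(Ci, Cs, Cbm, Co, lam=RADON_DECAY_CONSTANT, lam_v=0.0):
    """Invert the steady state for the infiltration factor S (Bq m-3 h-1).

    ``S = Ci*(lam + lam_v) + lam*(Cs + Cbm) - lam_v*Co`` — the exact
    algebraic inverse of :func:`steady_state_ci`.  Accepts scalars or arrays.
    """
    lam = np.asarray(lam, dtype=float)
    lam_v = np.asarray(lam_v, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("decay constant lam must be positive")
    if np.any(lam_v < 0):
        raise ValueError("ventilation rate lam_v must be non-negative")
    s = (np.asarray(Ci, dtype=float) * (lam + lam_v)
         + lam * (np.asarray(Cs, dtype=float) + np.asarray(Cbm, dtype=float))
         - lam_v * np.asarray(Co, dtype=float))
    if np.ndim(s) == 0:
        return float(s)
    return s


def _system_matrices(p: MassBalanceParams, lam_v: float):
    """Coefficient matrix A and constant vector c of dx/dt = A x + c."""
    g = p.Sg / p.V
    bm = p.Sbm / p.V
    a_soil = p.kd_s * g          # diffusive soil<->indoor exchange
    a_adv = p.ka * p.dP_si * g   # one-way advective soil->indoor entry
    a_bm = p.kd_bm * bm
    A = np.array(
        [
            [-(a_soil + a_bm + lam_v + p.lam), a_soil + a_adv, a_bm],
            [a_soil, -(a_soil + a_adv + p.lam), 0.0],
            [a_bm, 0.0, -(a_bm + p.lam)],
        ]
    )
    c = np.array([lam_v * p.Co, p.Es * g, p.Ebm * bm])
    return A, c


def steady_state(p: MassBalanceParams, v: VentilationInputs) -> CompartmentState:
    """Fixed point of the linear system, by direct 3x3 solve.

    At the fixed point the indoor concentration also satisfies the
    closed-form :func:`steady_state_ci` with ``S = p.infiltration_factor``
    and the converged soil / building-material concentrations.
    """
    lam_v = ventilation_rate(v)
    A, c = _system_matrices(p, lam_v)
    x = np.linalg.solve(A, -c)
    return CompartmentState(Ci=float(x[0]), Cs=float(x[1]), Cbm=float(x[2]), t=np.inf)


def simulate_dynamics(
    p: MassBalanceParams,
    v: VentilationInputs,
    init: CompartmentState,
    t_end: float,
    n_eval: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the three coupled mass-balance ODEs from ``init`` to ``t_end`` h.

    Uses a stiff-capable adaptive integrator (LSODA).  Raises
    ``RuntimeError`` with the solver diagnostic if the trajectory fails to
    integrate or turns non-finite.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if min(init.Ci, init.Cs, init.Cbm) < 0:
        raise ValueError("initial concentrations must be non-negative")
    lam_v = ventilation_rate(v)
    A, c = _system_matrices(p, lam_v)

    def rhs(_t, x):
        return A @ x + c

    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [init.Ci, init.Cs, init.Cbm],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"mass-balance integration failed: {sol.message}")
    return Trajectory(t=sol.t, Ci=sol.y[0], Cs=sol.y[1], Cbm=sol.y[2])


def annual_effective_dose(Q: float, F: float, T: float, K: float) -> float:
    """Annual effective dose E = Q * F * T * K.

    Q: mean annual radon concentration (Bq m-3); F: equilibrium factor
    between radon and its short-lived progeny; T: annual residential time
    (h); K: dose conversion coefficient (the result carries K's units,
    e.g. Sv per Bq h m-3).
    """
    if min(Q, F, T, K) < 0:
        raise ValueError("all dose inputs must be non-negative")
    return Q * F * T * K
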