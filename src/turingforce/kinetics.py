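"""CIMA kinetics: dimensional rate laws -> dimensionless feed parameters,
and the stirred-tank feed-forcing model.

The estimation chain follows the empirical rate laws of the
chlorite-iodide-malonic-acid system.  The intermediates ClO2* (chlorine
dioxide radical) and I2 are not fed directly; their tank concentrations
are estimated from fixed stoichiometric fractions of the fed species
(valid for excess iodate and excess iodine), after which

    a = k1 [MA]0 / (k2 [ClO2*]0 sqrt(alpha)),
    b = k3 [I2]0 / (k2 [ClO2*]0 sqrt(alpha)),

with k1 = k1a [I2]0 / (k1b + [I2]0) the saturating effective rate of
iodide production from malonic acid.

The tank model describes a continuously stirred tank fed by a
sinusoidally programmed pump (malonic-acid stock, flow q1(t)) and a
constant co-feed (flow q2); mixing gives a linear ODE for the
malonic-acid feed concentration [MA]0(t).  Interfaces use the lab units
(mL/h for flows, minutes for time, M for concentrations); internally
flows are converted to mL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "RateConstants",
    "TankConcentrations",
    "TankSystem",
    "EstimatedParams",
    "estimate_clo2_radical",
    "estimate_i2",
    "k1_effective",
    "dimensionless_a",
    "dimensionless_b",
    "estimate_dimensionless_params",
    "inflow_rate",
    "tank_ma_trajectory",
    "symmetric_modulation_design",
]


@dataclass(frozen=True)
class RateConstants:
    """Measured rate constants of the CIMA skeleton mechanism.

    Defaults are the literature values for the chlorite-iodide-malonic
    acid system at the experimental conditions: k1a [1/s] and k1b [M]
    parameterize the saturating MA + I2 rate, k2 [1/(M s)] the
    chlorite-iodide step, k3 [1/s] the autocatalytic step, alpha [M^2]
    its kinetic saturation constant.  D_X, D_Y are the activator and
    inhibitor diffusion coefficients (only their ratio c = D_Y/D_X
    enters the dimensionless model).
    """

    k1a: float = 7.5e-3
    k1b: float = 5e-5
    k2: float = 6e3
    k3: float = 2.65e-3
    alpha: float = 1e-14
    K_complex: float = 7.0
    D_X: float = 1.0
    D_Y: float = 1.5

    def __post_init__(self) -> None:
        for name in ("k1a", "k1b", "k2", "k3", "alpha", "K_complex", "D_X", "D_Y"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass
class TankConcentrations:
    """Feed concentrations [M] in the two tanks, plus estimated
    intermediates (set by the estimation chain, not by the user)."""

    NaClO2_0: float = 10e-3
    KIO3_0: float = 2e-3
    NaOH_0: float = 12e-3
    KI_0: float = 2e-3
    H2SO4_0: float = 10e-3
    MA_0: float = 0.0
    ClO2_rad: float = field(default=0.0, init=False)
    I2: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        for name in ("NaClO2_0", "KIO3_0", "NaOH_0", "KI_0", "H2SO4_0", "MA_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TankSystem:
    """CSTR feed geometry: stock concentration MA_s [M], tank volume V
    [mL], modulated-pump base flow q0 [mL/h], modulation amplitude
    A_flow [mL/h], constant co-feed q2 [mL/h], forcing period T [min]."""

    MA_s: float
    V: float = 26.0
    q0: float = 130.0
    q2: float = 499.0
    A_flow: float = 0.0
    T: float = 10.0

    def __post_init__(self) -> None:
        if not (self.V > 0):
            raise ValueError("V must be > 0")
        if not (self.q2 > 0):
            raise ValueError("q2 must be > 0")
        if self.A_flow < 0:
            raise ValueError("A_flow must be >= 0")
        if self.q0 < self.A_flow:
            raise ValueError(
                f"q0 ({self.q0}) must be >= A_flow ({self.A_flow}): "
                "the pump cannot run backwards"
            )
        if not (self.T > 0):
            raise ValueError("T must be > 0")

    @property
    def residence_time(self) -> float:
        """Mean residence time V/(q0+q2) in minutes."""
        return self.V / ((self.q0 + self.q2) / 60.0)


def estimate_clo2_radical(clo2_anion: float) -> float:
    """Equilibrium ClO2 radical concentration with excess iodine:
    0.2 x the fed chlorite concentration [M]."""
    if clo2_anion < 0:
        raise ValueError("chlorite concentration must be >= 0")
    return 0.2 * clo2_anion


def estimate_i2(iodide: float, clo2_rad: float) -> float:
    """Iodine concentration [M]: produced at 3/5 of the fed iodide by
    the iodate-iodide reaction (excess iodate), minus 1/6 of the ClO2
    radical consumed by the chlorite-iodine equilibrium."""
    if iodide < 0 or clo2_rad < 0:
        raise ValueError("concentrations must be >= 0")
    i2 = 0.6 * iodide - clo2_rad / 6.0
    if i2 < 0:
        raise ValueError(
            "inconsistent feed composition: estimated I2 is negative "
            f"({i2:.3e} M); increase iodide or decrease chlorite"
        )
    return i2


def k1_effective(rc: RateConstants, i2: float) -> float:
    """Effective first-order rate [1/s] of iodide production from MA:
    k1a * [I2] / (k1b + [I2]).  Saturates at k1a."""
    if i2 < 0:
        raise ValueError("I2 concentration must be >= 0")
    return rc.k1a * i2 / (rc.k1b + i2)


def dimensionless_a(rc: RateConstants, ma0: float, clo2_rad: float, i2: float) -> float:
    """Feed parameter a = k1 [MA]0 / (k2 [ClO2*]0 sqrt(alpha)).

    Linear in ma0; with the default constants the coefficient a/[MA]0
    is about 5.9e3 per molar.
    """
    if clo2_rad <= 0:
        raise ValueError("ClO2 radical concentration must be > 0")
    return k1_effective(rc, i2) * ma0 / (rc.k2 * clo2_rad * math.sqrt(rc.alpha))


def dimensionless_b(rc: RateConstants, i2: float, clo2_rad: float) -> float:
    """Feed parameter b = k3 [I2]0 / (k2 [ClO2*]0 sqrt(alpha))."""
    if clo2_rad <= 0:
        raise ValueError("ClO2 radical concentration must be > 0")
    return rc.k3 * i2 / (rc.k2 * clo2_rad * math.sqrt(rc.alpha))


@dataclass(frozen=True)
class EstimatedParams:
    """Output of the full estimation chain."""

    clo2_rad: float
    i2: float
    k1: float
    a_coefficient: float  # a per molar of [MA]0, in 1/M
    b: float

    def a_of_ma0(self, ma0: float) -> float:
        return self.a_coefficient * ma0


def estimate_dimensionless_params(
    rc: RateConstants, tanks: TankConcentrations
) -> EstimatedParams:
    """Run the whole chain: fed species -> intermediates -> (a, b)."""
    clo2_rad = estimate_clo2_radical(tanks.NaClO2_0)
    i2 = estimate_i2(tanks.KI_0, clo2_rad)
    tanks.ClO2_rad = clo2_rad
    tanks.I2 = i2
    k1 = k1_effective(rc, i2)
    a_coeff = dimensionless_a(rc, 1.0, clo2_rad, i2)
    b = dimensionless_b(rc, i2, clo2_rad)
    return EstimatedParams(clo2_rad=clo2_rad, i2=i2, k1=k1, a_coefficient=a_coeff, b=b)


def inflow_rate(ts: TankSystem, t) -> float | np.ndarray:
    """Programmed pump flow q1(t) = q0 + A_flow sin(2 pi t / T) [mL/h],
    t in minutes.  Nonnegative by the q0 >= A_flow invariant."""
    t = np.asarray(t, dtype=float)
    out = ts.q0 + ts.A_flow * np.sin(2.0 * np.pi * t / ts.T)
    return out if out.ndim else float(out)


def _ma_rhs(ts: TankSystem, t: float, ma: float) -> float:
    # flows in mL/min, t in min
    q1 = (ts.q0 + ts.A_flow * math.sin(2.0 * math.pi * t / ts.T)) / 60.0
    q2 = ts.q2 / 60.0
    return ts.MA_s * q1 / ts.V - ma * (q1 + q2) / ts.V


def tank_ma_trajectory(
    ts: TankSystem, t_grid: np.ndarray, ma_init: float, dt: float = 0.01
) -> np.ndarray:
    """[MA]0(t) on t_grid [min] from the tank mixing ODE

        d[MA]0/dt = MA_s q1(t)/V - [MA]0 (q1(t)+q2)/V,

    integrated with classical fixed-step RK4 at step ``dt`` minutes and
    linearly sampled onto t_grid.  With A_flow=0 the solution relaxes to
    MA_s q0/(q0+q2).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if ma_init < 0:
        raise ValueError("ma_init must be >= 0")
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be a nondecreasing 1-D array")
    t_end = float(t_grid[-1])
    n = max(1, int(math.ceil(t_end / dt)))
    h = t_end / n if t_end > 0 else dt
    ts_dense = np.empty(n + 1)
    ma_dense = np.empty(n + 1)
    t, ma = 0.0, float(ma_init)
    ts_dense[0], ma_dense[0] = t, ma
    for i in range(n):
        k1 = _ma_rhs(ts, t, ma)
        k2 = _ma_rhs(ts, t + h / 2, ma + h / 2 * k1)
        k3 = _ma_rhs(ts, t + h / 2, ma + h / 2 * k2)
        k4 = _ma_rhs(ts, t + h, ma + h * k3)
        ma += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (i + 1) * h
        ts_dense[i + 1], ma_dense[i + 1] = t, ma
    return np.interp(t_grid, ts_dense, ma_dense)


def _long_run_extremes(ts: TankSystem, n_settle: int = 12, dt: float = 0.01):
    """(min, max) of [MA]0 over one period after the transient."""
    ma0 = ts.MA_s * inflow_rate(ts, 0.0) / (inflow_rate(ts, 0.0) + ts.q2)
    t_end = (n_settle + 1) * ts.T
    tg = np.arange(0.0, t_end + dt / 2, dt)
    ma = tank_ma_trajectory(ts, tg, ma0, dt=dt)
    last = tg >= n_settle * ts.T
    return float(ma[last].min()), float(ma[last].max())


def symmetric_modulation_design(
    target_basis: float,
    target_amplitude: float,
    ts: TankSystem,
) -> TankSystem:
    """Find pump settings (q0, A_flow) whose long-run [MA]0(t) extremes
    are symmetric about ``target_basis`` with half-range
    ``target_amplitude`` [M].

    The tank low-pass filters the sinusoidal pump program, so the
    concentration modulation is neither perfectly sinusoidal nor
    symmetric for a naive choice of q0; the settings are obtained by
    root-finding on the simulated long-run trajectory.  ``ts`` supplies
    MA_s, V, q2 and T.  Raises ValueError with the achievable range if
    the request needs a negative pump flow or exceeds the stock
    concentration.
    """
    if not (0 < target_basis < ts.MA_s):
        raise ValueError(
            f"target basis {target_basis} M must lie in (0, MA_s={ts.MA_s} M)"
        )
    if target_amplitude < 0:
        raise ValueError("target amplitude must be >= 0")
    q0_guess = target_basis * ts.q2 / (ts.MA_s - target_basis)
    if target_amplitude == 0:
        return TankSystem(MA_s=ts.MA_s, V=ts.V, q0=q0_guess, q2=ts.q2,
                          A_flow=0.0, T=ts.T)
    if target_basis + target_amplitude >= ts.MA_s:
        raise ValueError(
            f"requested maximum {target_basis + target_amplitude} M exceeds "
            f"the stock concentration {ts.MA_s} M; achievable range is "
            f"(0, {ts.MA_s}) M"
        )
    # initial guess: steady gain of [MA]inf wrt q0, attenuated by the
    # first-order tank pole at 1/tau
    qtot = (q0_guess + ts.q2) / 60.0  # mL/min
    dma_dq0 = ts.MA_s * ts.q2 / (q0_guess + ts.q2) ** 2
    omega_tau = 2.0 * math.pi / ts.T * (ts.V / qtot)
    atten = 1.0 / math.hypot(1.0, omega_tau)
    s_guess = min(target_amplitude / (dma_dq0 * atten) / q0_guess, 0.9)

    def extremes(q0: float, s: float):
        sys = TankSystem(MA_s=ts.MA_s, V=ts.V, q0=q0, q2=ts.q2,
                         A_flow=s * q0, T=ts.T)
        return _long_run_extremes(sys)

    def resid(x):
        # residuals relative to the basis so the optimizer sees O(1)
        # quantities regardless of the molar scale
        lo, hi = extremes(x[0], x[1])
        return [((hi + lo) / 2.0 - target_basis) / target_basis,
                ((hi - lo) / 2.0 - target_amplitude) / target_basis]

    # A_flow = s*q0 with s in [0, 1] keeps the pump flow nonnegative
    sol = optimize.least_squares(
        resid, x0=[q0_guess, s_guess],
        bounds=([1e-6, 0.0], [np.inf, 1.0]),
        x_scale=[q0_guess, 1.0], diff_step=1e-3,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    q0, s = sol.x
    designed = TankSystem(MA_s=ts.MA_s, V=ts.V, q0=float(q0), q2=ts.q2,
                          A_flow=float(s * q0), T=ts.T)
    lo, hi = _long_run_extremes(designed)
    tol = 5e-3 * target_basis
    if abs((hi + lo) / 2.0 - target_basis) > tol or \
       abs((hi - lo) / 2.0 - target_amplitude) > tol:
        # report the amplitude reachable at full modulation (s = 1)
        # while holding the basis, as the achievable range
        def basis_resid(q0_full):
            lo_f, hi_f = extremes(q0_full[0], 1.0)
            return [(hi_f + lo_f) / 2.0 - target_basis]

        sol_f = optimize.least_squares(basis_resid, x0=[q0_guess],
                                       bounds=([1e-6], [np.inf]))
        lo_f, hi_f = extremes(float(sol_f.x[0]), 1.0)
        raise ValueError(
            f"no symmetric modulation of half-range {target_amplitude:.4g} M "
            f"about {target_basis:.4g} M is reachable with nonnegative "
            f"pumping; the achievable half-range at this basis is at most "
            f"{(hi_f - lo_f) / 2.0:.4g} M"
        )
    return designed
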