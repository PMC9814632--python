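"""Floquet stability of the uniform oscillatory state under forcing.

The spatially uniform, time-periodic solution (u_p(t), v_p(t)) of the
forced kinetics is obtained as the large-time behavior of the space-free
system, integrated with explicit Euler at step dt = T/N.  A wavenumber-k
perturbation about it obeys the linear nonautonomous system
d/dt (du, dv) = L(t; k) (du, dv) with

    L(t;k) = [[-1 + 4 v_p (u_p^2 - 1)/(u_p^2+1)^2 - k^2,
               -4 u_p/(u_p^2+1)],
              [sigma b (1 + v_p (u_p^2-1)/(u_p^2+1)^2),
               -sigma (b u_p/(u_p^2+1) + c k^2)]].

The linearized Poincare map over one forcing period is approximated by
the ordered Euler product

    P(k) = (I + dt L((N-1)T/N; k)) ... (I + dt L(0; k)),

with L evaluated at the left endpoint of each step (matching the
rightmost factor at t=0).  The uniform oscillation is unstable at
wavenumber k when an eigenvalue modulus of P(k) exceeds one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import euler_orbit
from .model import ForcingParams, ModelParams, steady_state

__all__ = [
    "PeriodicOrbit",
    "StabilitySpectrum",
    "PhaseDiagramTA",
    "OrbitConvergenceError",
    "compute_periodic_orbit",
    "linearization_matrix",
    "poincare_map",
    "stability_spectrum",
    "phase_diagram",
]

#: moduli up to 1 + this are treated as stable (neutral modes at marginality)
INSTABILITY_TOL = 1e-9

#: default wavenumber grid, covering the unstable band with wide margin
DEFAULT_K_GRID = np.arange(0.0, 3.0 + 1e-12, 0.01)


class OrbitConvergenceError(RuntimeError):
    """Raised when the space-free integration does not settle onto a
    periodic solution within the period cap."""

    def __init__(self, message: str, residual: float, periods: int):
        super().__init__(message)
        self.residual = residual
        self.periods = periods


@dataclass(frozen=True)
class PeriodicOrbit:
    """One-period sample of the uniform oscillatory solution.

    u_p and v_p have length N+1 (samples at t = i T/N, i = 0..N);
    convergence_residual is the max-norm mismatch between the last two
    sampled periods.
    """

    params: ModelParams
    forcing: ForcingParams
    N: int
    u_p: np.ndarray
    v_p: np.ndarray
    convergence_residual: float
    periods_used: int

    @property
    def dt(self) -> float:
        return self.forcing.T / self.N


@dataclass(frozen=True)
class StabilitySpectrum:
    """Floquet multiplier moduli |lambda_1(k)| >= |lambda_2(k)| per
    wavenumber."""

    k_values: np.ndarray
    lambda1_abs: np.ndarray
    lambda2_abs: np.ndarray

    @property
    def lambda_max(self) -> np.ndarray:
        return np.maximum(self.lambda1_abs, self.lambda2_abs)

    @property
    def argmax_k(self) -> float:
        return float(self.k_values[int(np.argmax(self.lambda_max))])

    @property
    def max_modulus(self) -> float:
        return float(np.max(self.lambda_max))

    @property
    def is_unstable(self) -> bool:
        return self.max_modulus > 1.0 + INSTABILITY_TOL


@dataclass(frozen=True)
class PhaseDiagramTA:
    """Stability of the uniform oscillatory state on a T-A grid.

    stability[i, j] refers to (T_values[i], A_values[j]):
    1 = stable, 0 = unstable, -1 = indeterminate (orbit did not
    converge within the period cap).
    """

    T_values: np.ndarray
    A_values: np.ndarray
    stability: np.ndarray
    max_moduli: np.ndarray = field(default=None)  # type: ignore[assignment]


def compute_periodic_orbit(
    p: ModelParams,
    f: ForcingParams,
    N: int = 10_000,
    init: tuple[float, float] | None = None,
    max_periods: int = 500,
    tol: float = 1e-6,
) -> PeriodicOrbit:
    """Settle the space-free forced kinetics onto its periodic solution.

    Integrates with explicit Euler at dt = T/N from ``init`` (default:
    the unforced steady state a/5, 1+a^2/25), one forcing period at a
    time, until two consecutive sampled periods agree to ``tol`` in max
    norm.  Convergence depends on the parameters; a cap of
    ``max_periods`` periods guards against non-convergence.
    """
    if N < 100:
        raise ValueError("N must be >= 100 for a usable orbit sample")
    u0, v0 = init if init is not None else steady_state(p)
    u_p, v_p, residual, periods = euler_orbit(
        p.a, f.A, f.T, p.b, p.sigma, N, float(u0), float(v0), max_periods, tol
    )
    if not np.isfinite(residual) or residual >= tol:
        raise OrbitConvergenceError(
            f"no periodic solution after {periods} periods "
            f"(residual {residual:.3e}, tol {tol:.1e}) at a={p.a}, "
            f"A={f.A}, T={f.T}",
            residual=float(residual),
            periods=periods,
        )
    return PeriodicOrbit(
        params=p, forcing=f, N=N, u_p=u_p, v_p=v_p,
        convergence_residual=float(residual), periods_used=periods,
    )


def linearization_matrix(u: float, v: float, p: ModelParams, k: float) -> np.ndarray:
    """L(t; k) evaluated at an orbit point (u, v): the kinetics Jacobian
    plus the diffusion contribution diag(-k^2, -sigma c k^2)."""
    d = u * u + 1.0
    core = v * (u * u - 1.0) / (d * d)
    return np.array(
        [
            [-1.0 + 4.0 * core - k * k, -4.0 * u / d],
            [p.sigma * p.b * (1.0 + core),
             -p.sigma * (p.b * u / d + p.c * k * k)],
        ]
    )


def _orbit_coefficients(orbit: PeriodicOrbit):
    """Per-step k-independent entries of L at the left endpoints."""
    u = orbit.u_p[:-1]
    v = orbit.v_p[:-1]
    p = orbit.params
    d = u * u + 1.0
    core = v * (u * u - 1.0) / (d * d)
    j11 = -1.0 + 4.0 * core
    j12 = -4.0 * u / d
    j21 = p.sigma * p.b * (1.0 + core)
    j22 = -p.sigma * p.b * u / d
    return j11, j12, j21, j22


def poincare_map(orbit: PeriodicOrbit, k: float) -> np.ndarray:
    """Euler-product Poincare map P(k) advancing a wavenumber-k
    perturbation by one forcing period."""
    j11, j12, j21, j22 = _orbit_coefficients(orbit)
    dt = orbit.dt
    p = orbit.params
    l11 = 1.0 + dt * (j11 - k * k)
    l12 = dt * j12
    l21 = dt * j21
    l22 = 1.0 + dt * (j22 - p.sigma * p.c * k * k)
    P = np.eye(2)
    for i in range(orbit.N):
        P = np.array([[l11[i], l12[i]], [l21[i], l22[i]]]) @ P
    return P


def _eig_moduli(p11, p12, p21, p22):
    """Eigenvalue moduli of real 2x2 matrices from the characteristic
    polynomial; complex pairs have common modulus sqrt(det)."""
    tau = p11 + p22
    det = p11 * p22 - p12 * p21
    disc = tau * tau - 4.0 * det
    sq = np.sqrt(np.abs(disc))
    real = disc >= 0.0
    lam_a = np.where(real, np.abs(0.5 * (tau + sq)), np.sqrt(np.abs(det)))
    lam_b = np.where(real, np.abs(0.5 * (tau - sq)), np.sqrt(np.abs(det)))
    return np.maximum(lam_a, lam_b), np.minimum(lam_a, lam_b)


def stability_spectrum(
    orbit: PeriodicOrbit, k_grid: np.ndarray | None = None
) -> StabilitySpectrum:
    """Multiplier moduli over a wavenumber grid.

    The Euler product is accumulated simultaneously for all k: the
    k-dependence of L is a diagonal shift, so per time step the update
    is four fused array operations over the k grid.
    """
    k = np.asarray(DEFAULT_K_GRID if k_grid is None else k_grid, dtype=float)
    j11, j12, j21, j22 = _orbit_coefficients(orbit)
    p = orbit.params
    dt = orbit.dt
    k2 = k * k
    shift_u = k2
    shift_v = p.sigma * p.c * k2
    p11 = np.ones_like(k)
    p12 = np.zeros_like(k)
    p21 = np.zeros_like(k)
    p22 = np.ones_like(k)
    for i in range(orbit.N):
        l11 = 1.0 + dt * (j11[i] - shift_u)
        l12 = dt * j12[i]
        l21 = dt * j21[i]
        l22 = 1.0 + dt * (j22[i] - shift_v)
        q11 = l11 * p11 + l12 * p21
        q12 = l11 * p12 + l12 * p22
        q21 = l21 * p11 + l22 * p21
        q22 = l21 * p12 + l22 * p22
        p11, p12, p21, p22 = q11, q12, q21, q22
    lam1, lam2 = _eig_moduli(p11, p12, p21, p22)
    return StabilitySpectrum(k_values=k, lambda1_abs=lam1, lambda2_abs=lam2)


def phase_diagram(
    p: ModelParams,
    T_grid: np.ndarray,
    A_grid: np.ndarray,
    k_grid: np.ndarray | None = None,
    N: int = 10_000,
    max_periods: int = 500,
) -> PhaseDiagramTA:
    """Stability of the uniform oscillatory state over a T-A grid.

    Cells whose orbit fails to converge are marked indeterminate (-1),
    never stable.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    A_grid = np.asarray(A_grid, dtype=float)
    if T_grid.size == 0 or A_grid.size == 0:
        raise ValueError("T and A grids must be nonempty")
    stab = np.empty((T_grid.size, A_grid.size), dtype=np.int8)
    mods = np.full((T_grid.size, A_grid.size), np.nan)
    for i, T in enumerate(T_grid):
        for j, A in enumerate(A_grid):
            f = ForcingParams(A=float(A), T=float(T))
            try:
                orbit = compute_periodic_orbit(p, f, N=N, max_periods=max_periods)
            except OrbitConvergenceError:
                stab[i, j] = -1
                continue
            spec = stability_spectrum(orbit, k_grid)
            mods[i, j] = spec.max_modulus
            stab[i, j] = 0 if spec.is_unstable else 1
    return PhaseDiagramTA(T_values=T_grid, A_values=A_grid,
                          stability=stab, max_moduli=mods)
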