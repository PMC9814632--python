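"""Linear stability of the unforced homogeneous steady state.

Standard Turing analysis of the two-variable model: linearize the
kinetics about (u*, v*) = (a/5, 1 + a^2/25) and add the diffusion
contribution, giving the wavenumber-dependent matrix

    M(k) = J + diag(-k^2, -sigma c k^2).

The dispersion relation records, per k, the largest real part among the
eigenvalues of M(k).  The Hopf point is the root in a of trace J = 0
(with det J > 0); the Turing point is the smallest a at which the
maximal growth rate over k > 0 crosses zero while the homogeneous mode
(k = 0) stays stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import ModelParams, jacobian, steady_state

__all__ = ["DispersionCurve", "dispersion_relation", "hopf_point", "turing_point"]

#: growth rates within this band of zero are treated as marginal/stable
STABILITY_TOL = 1e-10


@dataclass(frozen=True)
class DispersionCurve:
    """Real growth rate of the leading temporal eigenvalue per wavenumber."""

    k_values: np.ndarray
    growth_rates: np.ndarray

    @property
    def leading_k(self) -> float:
        """Wavenumber of the fastest-growing mode."""
        return float(self.k_values[int(np.argmax(self.growth_rates))])

    @property
    def max_growth(self) -> float:
        return float(np.max(self.growth_rates))


def _growth_rate(p: ModelParams, k2: np.ndarray) -> np.ndarray:
    """Max real eigenvalue part of M(k) for an array of k^2 values,
    via the quadratic characteristic polynomial of the 2x2 matrix."""
    u, v = steady_state(p)
    J = jacobian(u, v, p)
    m11 = J[0, 0] - k2
    m22 = J[1, 1] - p.sigma * p.c * k2
    tau = m11 + m22
    det = m11 * m22 - J[0, 1] * J[1, 0]
    disc = tau * tau - 4.0 * det
    real_branch = 0.5 * (tau + np.sqrt(np.maximum(disc, 0.0)))
    complex_branch = 0.5 * tau
    return np.where(disc >= 0.0, real_branch, complex_branch)


def dispersion_relation(p: ModelParams, k_grid: np.ndarray) -> DispersionCurve:
    """Dispersion curve of the unforced model on a nonnegative k grid."""
    k = np.asarray(k_grid, dtype=float)
    if np.any(k < 0):
        raise ValueError("wavenumbers must be nonnegative")
    return DispersionCurve(k_values=k, growth_rates=_growth_rate(p, k * k))


def _trace_at(a: float, b: float, sigma: float, c: float) -> float:
    p = ModelParams(a=a, b=b, sigma=sigma, c=c)
    u, v = steady_state(p)
    J = jacobian(u, v, p)
    return float(J[0, 0] + J[1, 1])


def hopf_point(
    b: float = 1.9,
    sigma: float = 8.0,
    c: float = 1.5,
    bracket: tuple[float, float] = (5.0, 60.0),
) -> float:
    """Critical a of the Hopf bifurcation: zero of trace J(a) with
    det J > 0, solved by Brent's method to |da| < 1e-8."""
    lo, hi = bracket
    f_lo, f_hi = _trace_at(lo, b, sigma, c), _trace_at(hi, b, sigma, c)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"trace does not change sign on bracket {bracket}: "
            f"f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g}"
        )
    a_c = optimize.brentq(_trace_at, lo, hi, args=(b, sigma, c), xtol=1e-10)
    p = ModelParams(a=a_c, b=b, sigma=sigma, c=c)
    u, v = steady_state(p)
    if np.linalg.det(jacobian(u, v, p)) <= 0:
        raise ValueError(f"trace root at a={a_c:.4f} has det <= 0: not a Hopf point")
    return float(a_c)


def _max_growth(a: float, b: float, sigma: float, c: float,
                k_hi: float = 5.0) -> tuple[float, float]:
    """(max over k>0 of the growth rate, argmax k) by bounded scalar
    minimization with a coarse-scan bracket."""
    p = ModelParams(a=a, b=b, sigma=sigma, c=c)
    ks = np.linspace(1e-3, k_hi, 200)
    g = _growth_rate(p, ks * ks)
    i = int(np.argmax(g))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, len(ks) - 1)]
    res = optimize.minimize_scalar(
        lambda k: -_growth_rate(p, np.array([k * k]))[0],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    return -float(res.fun), float(res.x)


def turing_point(
    b: float = 1.9,
    sigma: float = 8.0,
    c: float = 1.5,
    a_range: tuple[float, float] = (5.0, 40.0),
) -> tuple[float, float]:
    """(critical a, marginal wavenumber k_c) of the Turing bifurcation.

    Smallest a in ``a_range`` at which max_{k>0} growth crosses zero
    while k=0 stays stable, found by bisection on the (monotone near
    onset) maximal growth rate; |da| resolved to < 1e-8.
    """
    lo, hi = a_range
    a_scan = np.linspace(lo, hi, 71)
    g_scan = np.array([_max_growth(a, b, sigma, c)[0] for a in a_scan])
    sign_change = np.nonzero((g_scan[:-1] < 0) & (g_scan[1:] >= 0))[0]
    if sign_change.size == 0:
        raise ValueError(
            f"no Turing onset found for a in {a_range}: max growth spans "
            f"[{g_scan.min():.3g}, {g_scan.max():.3g}]"
        )
    i = int(sign_change[0])
    a_c = optimize.brentq(
        lambda a: _max_growth(a, b, sigma, c)[0],
        a_scan[i], a_scan[i + 1], xtol=1e-10,
    )
    _, k_c = _max_growth(a_c, b, sigma, c)
    # homogeneous mode must still be stable at onset
    if _trace_at(a_c, b, sigma, c) >= STABILITY_TOL:
        raise ValueError(
            f"growth-rate zero at a={a_c:.4f} is not a Turing point: "
            "the k=0 mode is already unstable (Hopf precedes it)"
        )
    return float(a_c), float(k_c)
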