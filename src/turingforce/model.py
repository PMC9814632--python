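"""Forced Lengyel-Epstein kinetics.

The two-variable nondimensional model of the CIMA reaction (u = iodide,
the activator; v = chlorite, the inhibitor) with a sinusoidal modulation
of the feed parameter ``a``::

    du/dt = a + A sin(2 pi t / T) - u - 4 u v / (1 + u^2)
    dv/dt = sigma * b * (u - u v / (1 + u^2))

All other modules (bifurcation, Floquet, PDE solver) consume the kinetics,
steady state and Jacobian defined here.  ``A = 0`` recovers the classical
unforced model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "ForcingParams",
    "forcing_value",
    "reaction_terms",
    "steady_state",
    "jacobian",
]


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless kinetic/diffusion parameters.

    Parameters
    ----------
    a : float
        Feed parameter for the activator supply (proportional to the
        malonic-acid feed concentration).
    b : float
        Feed parameter for inhibitor production (proportional to the
        iodine concentration in the tank).
    sigma : float
        Rescaling parameter ``sigma = 1 + K`` where K is the triiodide
        complexation equilibrium constant; must be >= 1.
    c : float
        Ratio of inhibitor to activator diffusivity, ``D_Y / D_X``.
    """

    a: float
    b: float = 1.9
    sigma: float = 8.0
    c: float = 1.5

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (self.b > 0):
            raise ValueError(f"b must be > 0, got {self.b}")
        if not (self.sigma >= 1):
            raise ValueError(f"sigma must be >= 1, got {self.sigma}")
        if not (self.c > 0):
            raise ValueError(f"c must be > 0, got {self.c}")

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "sigma": self.sigma, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(d[k]) for k in ("a", "b", "sigma", "c") if k in d})


@dataclass(frozen=True)
class ForcingParams:
    """Sinusoidal forcing of the feed parameter: amplitude A and period T.

    ``A = 0`` switches the forcing off (protocol stages before/after the
    modulation are represented this way rather than by a separate code
    path).
    """

    A: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if not (self.A >= 0):
            raise ValueError(f"A must be >= 0, got {self.A}")
        if not (self.T > 0):
            raise ValueError(f"T must be > 0, got {self.T}")

    def to_dict(self) -> dict:
        return {"A": self.A, "T": self.T}

    @classmethod
    def from_dict(cls, d: dict) -> "ForcingParams":
        return cls(A=float(d.get("A", 0.0)), T=float(d.get("T", 1.0)))


def forcing_value(p: ModelParams, f: ForcingParams, t):
    """Effective feed value ``a + A sin(2 pi t / T)`` at time ``t``.

    Periodic in ``t`` with period ``f.T``; accepts scalar or array times.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    out = p.a + f.A * np.sin(2.0 * np.pi * t / f.T)
    return out if out.ndim else float(out)


def reaction_terms(u, v, p: ModelParams, f: ForcingParams = ForcingParams(), t=0.0):
    """Space-free kinetics ``(du/dt, dv/dt)`` at state (u, v) and time t.

    Negative u or v are evaluated as written, never clamped: the solver
    is responsible for monitoring positivity.  Works elementwise on
    arrays.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    aeff = forcing_value(p, f, t)
    denom = 1.0 + u * u
    du = aeff - u - 4.0 * u * v / denom
    dv = p.sigma * p.b * (u - u * v / denom)
    if du.ndim == 0:
        return float(du), float(dv)
    return du, dv


def steady_state(p: ModelParams) -> tuple[float, float]:
    """Homogeneous steady state of the unforced model.

    ``u* = a/5``, ``v* = 1 + a^2/25``; the kinetics with A=0 vanish there
    identically.
    """
    return p.a / 5.0, 1.0 + p.a * p.a / 25.0


def jacobian(u: float, v: float, p: ModelParams) -> np.ndarray:
    """2x2 Jacobian of the reaction terms at state (u, v).

    Rows are (du/dt, dv/dt), columns are d/du, d/dv.  The forcing term is
    additive in time so the Jacobian does not depend on A or T.
    """
    d = 1.0 + u * u
    j11 = -1.0 + 4.0 * v * (u * u - 1.0) / (d * d)
    j12 = -4.0 * u / d
    j21 = p.sigma * p.b * (1.0 + v * (u * u - 1.0) / (d * d))
    j22 = -p.sigma * p.b * u / d
    return np.array([[j11, j12], [j21, j22]], dtype=float)
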