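"""Synthetic field fixtures with known ground-truth labels.

Generates idealized planforms for exercising the pattern analyzer:
hexagonal spot lattices (a resonant triad of three cosines at 120
degrees, whose wavevectors sum to zero), single-orientation stripes,
homogeneous fields, and spatially uniform temporal oscillations.
Wavevectors are snapped to the periodic domain's reciprocal lattice so
spectra are leakage-free.  These fixtures emulate settled model
planforms, not the transients or defects of a real simulation.
"""

from __future__ import annotations

import numpy as np

from .pde import FieldState

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("spots-hex", "stripes", "homogeneous",
                 "homogeneous-oscillatory")


def _lattice_vector(k: float, angle: float, L: float) -> np.ndarray:
    """Nearest reciprocal-lattice vector to k*(cos angle, sin angle)."""
    target = k * np.array([np.cos(angle), np.sin(angle)]) * L / (2.0 * np.pi)
    m = np.round(target)
    if np.all(m == 0):
        raise ValueError(f"wavenumber {k} is not resolvable on a domain of "
                         f"size {L}")
    return 2.0 * np.pi * m / L


def make_fixture(
    kind: str,
    k: float = 1.2,
    nx: int = 128,
    ny: int = 128,
    dx: float = 0.25,
    seed: int = 0,
    n_snapshots: int = 5,
    noise_sd: float = 0.0,
    amplitude: float = 1.0,
    mean: float = 4.0,
    period: float = 1.0,
) -> list[FieldState]:
    """Snapshot sequence of an idealized field of the requested kind.

    ``k`` is the target wavenumber (snapped to the domain lattice and
    required to be below the grid Nyquist limit pi/dx); ``noise_sd``
    adds per-snapshot Gaussian noise.  Snapshot times span one
    ``period`` for the oscillatory kind and are equally spaced
    otherwise.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    if not (0 < k < np.pi / dx):
        raise ValueError(f"wavenumber {k} not resolvable: need 0 < k < "
                         f"pi/dx = {np.pi / dx:.3g}")
    if nx != ny:
        raise ValueError("fixtures use square grids")
    rng = np.random.default_rng(seed)
    L = nx * dx
    x = np.arange(nx) * dx
    X, Y = np.meshgrid(x, x)

    if kind == "spots-hex":
        q1 = _lattice_vector(k, 0.0, L)
        q2 = _lattice_vector(k, 2.0 * np.pi / 3.0, L)
        q3 = -(q1 + q2)  # closes the resonant triad exactly
        base = sum(np.cos(q[0] * X + q[1] * Y) for q in (q1, q2, q3))
        base = mean + amplitude * base / 3.0
    elif kind == "stripes":
        q = _lattice_vector(k, 0.0, L)
        base = mean + amplitude * np.cos(q[0] * X + q[1] * Y)
    else:
        base = np.full((ny, nx), float(mean))

    times = np.linspace(0.0, period, n_snapshots)
    out = []
    for t in times:
        if kind == "homogeneous-oscillatory":
            f = base + amplitude * np.sin(2.0 * np.pi * t / period)
        else:
            f = base.copy()
        if noise_sd > 0:
            f = f + noise_sd * rng.standard_normal(f.shape)
        out.append(FieldState(u=f, v=f.copy(), t=float(t)))
    return out
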