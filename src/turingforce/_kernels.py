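"""Numerical kernels: periodic cyclic-tridiagonal solves, the ADI+Heun
reaction-diffusion stepper, and the Euler integrator for the space-free
forced kinetics.

Each kernel exists twice: a scalar-loop version compiled with numba
(preferred) and a vectorized numpy/scipy version used when numba is not
importable.  Both share the same precomputed Thomas factorization data
(`CyclicFactor`), so they are numerically identical up to floating-point
associativity.

The implicit diffusion operator per axis is (I - r d2), with d2 the
periodic second-difference stencil and r = D dt / (2 dx^2).  The
periodic corners are handled with the Sherman-Morrison rank-one
correction: A = A' + u v^T with gamma = -diag, so each solve is one
constant-coefficient Thomas sweep plus a precomputed correction vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@dataclass(frozen=True)
class CyclicFactor:
    """Precomputed Thomas factorization of (I - r d2) on a periodic
    interval of n points, Sherman-Morrison corrected."""

    n: int
    r: float
    off: float
    gamma: float
    beta: float
    den: np.ndarray  # forward-elimination denominators
    den_inv: np.ndarray  # reciprocals of den (used by the compiled sweeps)
    cp: np.ndarray  # modified superdiagonal factors
    z: np.ndarray  # A'^{-1} u, the correction direction
    zcorr: float  # 1 + z[0] + beta*z[-1]/gamma


def cyclic_factor(n: int, r: float) -> CyclicFactor:
    """Factor the periodic implicit-diffusion matrix for axis length n."""
    if n < 3:
        raise ValueError("periodic tridiagonal systems need n >= 3")
    d = 1.0 + 2.0 * r
    off = -r
    alpha = beta = -r
    gamma = -d
    bb = np.full(n, d)
    bb[0] = d - gamma
    bb[-1] = d - alpha * beta / gamma
    den = np.empty(n)
    cp = np.empty(n)
    den[0] = bb[0]
    cp[0] = off / den[0]
    for i in range(1, n):
        den[i] = bb[i] - off * cp[i - 1]
        cp[i] = off / den[i]
    # solve A' z = u, u = (gamma, 0, ..., 0, alpha)
    u_vec = np.zeros(n)
    u_vec[0] = gamma
    u_vec[-1] = alpha
    y = np.empty(n)
    y[0] = u_vec[0] / den[0]
    for i in range(1, n):
        y[i] = (u_vec[i] - off * y[i - 1]) / den[i]
    z = np.empty(n)
    z[-1] = y[-1]
    for i in range(n - 2, -1, -1):
        z[i] = y[i] - cp[i] * z[i + 1]
    zcorr = 1.0 + z[0] + beta * z[-1] / gamma
    return CyclicFactor(n=n, r=r, off=off, gamma=gamma, beta=beta,
                        den=den, den_inv=1.0 / den, cp=cp, z=z, zcorr=zcorr)


# ---------------------------------------------------------------------------
# numba kernels (scalar loops)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _solve_rows(B, den_inv, cp, z, off, gamma, beta, zcorr):
    """Solve (I - r d2) x = B in place along axis 1 (each row is one
    periodic tridiagonal system)."""
    m, n = B.shape
    for i in range(m):
        B[i, 0] = B[i, 0] * den_inv[0]
        for j in range(1, n):
            B[i, j] = (B[i, j] - off * B[i, j - 1]) * den_inv[j]
        for j in range(n - 2, -1, -1):
            B[i, j] = B[i, j] - cp[j] * B[i, j + 1]
        fact = (B[i, 0] + beta * B[i, n - 1] / gamma) / zcorr
        for j in range(n):
            B[i, j] -= fact * z[j]


@njit(cache=True)
def _solve_cols(B, den_inv, cp, z, off, gamma, beta, zcorr):
    """Solve (I - r d2) x = B in place along axis 0, sweeping rows so
    the inner loops stay contiguous."""
    m, n = B.shape
    for j in range(n):
        B[0, j] = B[0, j] * den_inv[0]
    for i in range(1, m):
        di = den_inv[i]
        for j in range(n):
            B[i, j] = (B[i, j] - off * B[i - 1, j]) * di
    for i in range(m - 2, -1, -1):
        ci = cp[i]
        for j in range(n):
            B[i, j] = B[i, j] - ci * B[i + 1, j]
    for j in range(n):
        fact = (B[0, j] + beta * B[m - 1, j] / gamma) / zcorr
        for i in range(m):
            B[i, j] -= fact * z[i]


@njit(cache=True)
def _expl_axis1(w, out, r):
    """out = w + r * d2 w along axis 1 (periodic)."""
    m, n = w.shape
    for i in range(m):
        out[i, 0] = w[i, 0] + r * (w[i, n - 1] - 2.0 * w[i, 0] + w[i, 1])
        for j in range(1, n - 1):
            out[i, j] = w[i, j] + r * (w[i, j - 1] - 2.0 * w[i, j] + w[i, j + 1])
        out[i, n - 1] = w[i, n - 1] + r * (w[i, n - 2] - 2.0 * w[i, n - 1]
                                           + w[i, 0])


@njit(cache=True)
def _expl_axis0(w, out, r):
    """out = w + r * d2 w along axis 0 (periodic)."""
    m, n = w.shape
    for i in range(m):
        im = m - 1 if i == 0 else i - 1
        ip = 0 if i == m - 1 else i + 1
        for j in range(n):
            out[i, j] = w[i, j] + r * (w[im, j] - 2.0 * w[i, j] + w[ip, j])


@njit(cache=True)
def _heun_reaction(u, v, dt, a0, a1, b, sigma):
    """Second-order Heun update of the kinetics over one full dt, in
    place; a0/a1 are the effective feed values at t_n and t_n + dt."""
    m, n = u.shape
    sb = sigma * b
    for i in range(m):
        for j in range(n):
            uu = u[i, j]
            vv = v[i, j]
            d0 = 1.0 + uu * uu
            fu0 = a0 - uu - 4.0 * uu * vv / d0
            fv0 = sb * (uu - uu * vv / d0)
            up = uu + dt * fu0
            vp = vv + dt * fv0
            d1 = 1.0 + up * up
            fu1 = a1 - up - 4.0 * up * vp / d1
            fv1 = sb * (up - up * vp / d1)
            u[i, j] = uu + 0.5 * dt * (fu0 + fu1)
            v[i, j] = vv + 0.5 * dt * (fv0 + fv1)


@njit(cache=True)
def _adi_heun_advance_numba(
    u, v, nsteps, t0, dt, a, A, T, b, sigma,
    r_u, r_v,
    deni_ux, cp_ux, z_ux, zc_ux, deni_uy, cp_uy, z_uy, zc_uy,
    deni_vx, cp_vx, z_vx, zc_vx, deni_vy, cp_vy, z_vy, zc_vy,
    parity, react,
):
    """Advance (u, v) by nsteps of dt.  Per step: one implicit-axis
    diffusion half step (explicit in the other axis), a full-dt Heun
    reaction update, then the mirror half step; the implicit axis order
    alternates with step parity.  Returns the final (u, v)."""
    off_u = -r_u
    off_v = -r_v
    g_u = -(1.0 + 2.0 * r_u)
    g_v = -(1.0 + 2.0 * r_v)
    bu = np.empty_like(u)
    bv = np.empty_like(v)
    for s in range(nsteps):
        t = t0 + s * dt
        a0 = a + A * math.sin(2.0 * math.pi * t / T)
        a1 = a + A * math.sin(2.0 * math.pi * (t + dt) / T)
        if (parity + s) % 2 == 0:
            # x-implicit first: explicit y half, solve along axis 1
            _expl_axis0(u, bu, r_u)
            _solve_rows(bu, deni_ux, cp_ux, z_ux, off_u, g_u, off_u, zc_ux)
            _expl_axis0(v, bv, r_v)
            _solve_rows(bv, deni_vx, cp_vx, z_vx, off_v, g_v, off_v, zc_vx)
            if react:
                _heun_reaction(bu, bv, dt, a0, a1, b, sigma)
            _expl_axis1(bu, u, r_u)
            _solve_cols(u, deni_uy, cp_uy, z_uy, off_u, g_u, off_u, zc_uy)
            _expl_axis1(bv, v, r_v)
            _solve_cols(v, deni_vy, cp_vy, z_vy, off_v, g_v, off_v, zc_vy)
        else:
            # y-implicit first
            _expl_axis1(u, bu, r_u)
            _solve_cols(bu, deni_uy, cp_uy, z_uy, off_u, g_u, off_u, zc_uy)
            _expl_axis1(v, bv, r_v)
            _solve_cols(bv, deni_vy, cp_vy, z_vy, off_v, g_v, off_v, zc_vy)
            if react:
                _heun_reaction(bu, bv, dt, a0, a1, b, sigma)
            _expl_axis0(bu, u, r_u)
            _solve_rows(u, deni_ux, cp_ux, z_ux, off_u, g_u, off_u, zc_ux)
            _expl_axis0(bv, v, r_v)
            _solve_rows(v, deni_vx, cp_vx, z_vx, off_v, g_v, off_v, zc_vx)
    return u, v


# ---------------------------------------------------------------------------
# numpy fallback (vectorized)
# ---------------------------------------------------------------------------


def _solve_cyclic_rows_np(B: np.ndarray, f: CyclicFactor) -> np.ndarray:
    m, n = B.shape
    y = np.empty_like(B)
    y[:, 0] = B[:, 0] / f.den[0]
    for j in range(1, n):
        y[:, j] = (B[:, j] - f.off * y[:, j - 1]) / f.den[j]
    x = np.empty_like(B)
    x[:, -1] = y[:, -1]
    for j in range(n - 2, -1, -1):
        x[:, j] = y[:, j] - f.cp[j] * x[:, j + 1]
    fact = (x[:, 0] + f.beta * x[:, -1] / f.gamma) / f.zcorr
    return x - fact[:, None] * f.z[None, :]


def _explicit_half_rows_np(w: np.ndarray, r: float) -> np.ndarray:
    return w + r * (np.roll(w, 1, axis=1) - 2.0 * w + np.roll(w, -1, axis=1))


def _adi_heun_advance_numpy(
    u, v, nsteps, t0, dt, a, A, T, b, sigma,
    fac_ux: CyclicFactor, fac_uy: CyclicFactor,
    fac_vx: CyclicFactor, fac_vy: CyclicFactor,
    parity: int, react: bool,
):
    r_u, r_v = fac_ux.r, fac_vx.r
    sb = sigma * b
    for s in range(nsteps):
        t = t0 + s * dt
        a0 = a + A * math.sin(2.0 * math.pi * t / T)
        a1 = a + A * math.sin(2.0 * math.pi * (t + dt) / T)
        x_first = (parity + s) % 2 == 0
        if x_first:
            u = _solve_cyclic_rows_np(_explicit_half_rows_np(u.T, r_u).T, fac_ux)
            v = _solve_cyclic_rows_np(_explicit_half_rows_np(v.T, r_v).T, fac_vx)
        else:
            u = _solve_cyclic_rows_np(_explicit_half_rows_np(u, r_u).T, fac_uy).T
            v = _solve_cyclic_rows_np(_explicit_half_rows_np(v, r_v).T, fac_vy).T
        if react:
            d0 = 1.0 + u * u
            fu0 = a0 - u - 4.0 * u * v / d0
            fv0 = sb * (u - u * v / d0)
            up = u + dt * fu0
            vp = v + dt * fv0
            d1 = 1.0 + up * up
            fu1 = a1 - up - 4.0 * up * vp / d1
            fv1 = sb * (up - up * vp / d1)
            u = u + 0.5 * dt * (fu0 + fu1)
            v = v + 0.5 * dt * (fv0 + fv1)
        if x_first:
            u = _solve_cyclic_rows_np(_explicit_half_rows_np(u, r_u).T, fac_uy).T
            v = _solve_cyclic_rows_np(_explicit_half_rows_np(v, r_v).T, fac_vy).T
        else:
            u = _solve_cyclic_rows_np(_explicit_half_rows_np(u.T, r_u).T, fac_ux)
            v = _solve_cyclic_rows_np(_explicit_half_rows_np(v.T, r_v).T, fac_vx)
    return u, v


# ---------------------------------------------------------------------------
# space-free forced kinetics, explicit Euler (orbit construction)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _euler_orbit_numba(a, A, T, b, sigma, N, u0, v0, max_periods, tol):
    """Integrate the space-free kinetics with Euler at dt = T/N, period
    by period, until two consecutive sampled periods agree to ``tol``
    in max norm.  Returns (u_p, v_p, residual, periods_used); u_p/v_p
    have length N+1 and sample the last period."""
    dt = T / N
    sb = sigma * b
    u_prev = np.empty(N + 1)
    v_prev = np.empty(N + 1)
    u_cur = np.empty(N + 1)
    v_cur = np.empty(N + 1)
    u = u0
    v = v0
    residual = np.inf
    periods = 0
    for p in range(max_periods):
        u_cur[0] = u
        v_cur[0] = v
        for i in range(N):
            t = i * dt
            aeff = a + A * math.sin(2.0 * math.pi * t / T)
            d = 1.0 + u * u
            du = aeff - u - 4.0 * u * v / d
            dv = sb * (u - u * v / d)
            u = u + dt * du
            v = v + dt * dv
            u_cur[i + 1] = u
            v_cur[i + 1] = v
        periods = p + 1
        if p > 0:
            res = 0.0
            for i in range(N + 1):
                r1 = abs(u_cur[i] - u_prev[i])
                r2 = abs(v_cur[i] - v_prev[i])
                if r1 > res:
                    res = r1
                if r2 > res:
                    res = r2
            residual = res
            if res < tol:
                break
        for i in range(N + 1):
            u_prev[i] = u_cur[i]
            v_prev[i] = v_cur[i]
    return u_cur, v_cur, residual, periods


def _euler_orbit_numpy(a, A, T, b, sigma, N, u0, v0, max_periods, tol):
    """Pure-Python fallback of the Euler orbit loop (identical
    arithmetic, vectorized over nothing: the recursion is sequential)."""
    dt = T / N
    sb = sigma * b
    sin_table = np.sin(2.0 * np.pi * np.arange(N) * dt / T)
    u_prev = v_prev = None
    u, v = u0, v0
    residual = np.inf
    periods = 0
    for p in range(max_periods):
        u_cur = np.empty(N + 1)
        v_cur = np.empty(N + 1)
        u_cur[0], v_cur[0] = u, v
        for i in range(N):
            aeff = a + A * sin_table[i]
            d = 1.0 + u * u
            du = aeff - u - 4.0 * u * v / d
            dv = sb * (u - u * v / d)
            u += dt * du
            v += dt * dv
            u_cur[i + 1] = u
            v_cur[i + 1] = v
        periods = p + 1
        if u_prev is not None:
            residual = max(
                float(np.max(np.abs(u_cur - u_prev))),
                float(np.max(np.abs(v_cur - v_prev))),
            )
            if residual < tol:
                return u_cur, v_cur, residual, periods
        u_prev, v_prev = u_cur, v_cur
    return u_cur, v_cur, residual, periods


def euler_orbit(a, A, T, b, sigma, N, u0, v0, max_periods=500, tol=1e-6):
    if HAVE_NUMBA:
        return _euler_orbit_numba(a, A, T, b, sigma, N, u0, v0, max_periods, tol)
    return _euler_orbit_numpy(a, A, T, b, sigma, N, u0, v0, max_periods, tol)


def adi_heun_advance(u, v, nsteps, t0, dt, a, A, T, b, sigma,
                     fac_ux, fac_uy, fac_vx, fac_vy, parity=0, react=True):
    """Dispatch the stepper to the numba or numpy implementation."""
    if HAVE_NUMBA:
        return _adi_heun_advance_numba(
            u, v, nsteps, t0, dt, a, A, T, b, sigma,
            fac_ux.r, fac_vx.r,
            fac_ux.den_inv, fac_ux.cp, fac_ux.z, fac_ux.zcorr,
            fac_uy.den_inv, fac_uy.cp, fac_uy.z, fac_uy.zcorr,
            fac_vx.den_inv, fac_vx.cp, fac_vx.z, fac_vx.zcorr,
            fac_vy.den_inv, fac_vy.cp, fac_vy.z, fac_vy.zcorr,
            parity, react,
        )
    return _adi_heun_advance_numpy(
        u, v, nsteps, t0, dt, a, A, T, b, sigma,
        fac_ux, fac_uy, fac_vx, fac_vy, parity, react,
    )
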