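"""Periodic orbit, Poincare map, multiplier spectra and T-A diagram."""

import numpy as np
import pytest

from turingforce.bifurcation import dispersion_relation
from turingforce.floquet import (
    OrbitConvergenceError,
    PeriodicOrbit,
    compute_periodic_orbit,
    linearization_matrix,
    phase_diagram,
    poincare_map,
    stability_spectrum,
)
from turingforce.model import (
    ForcingParams,
    ModelParams,
    jacobian,
    reaction_terms,
    steady_state,
)

P22 = ModelParams(a=22.0, b=1.9, sigma=8.0, c=1.5)
F6 = ForcingParams(A=6.0, T=1.0)


@pytest.fixture(scope="module")
def orbit_fig4():
    """Converged uniform oscillation at the reference forced point."""
    return compute_periodic_orbit(P22, F6, N=10_000)


class TestPeriodicOrbit:
    def test_unforced_orbit_collapses_to_steady_state(self):
        orbit = compute_periodic_orbit(P22, ForcingParams(A=0.0, T=1.0),
                                       N=1000)
        u_star, v_star = steady_state(P22)
        assert orbit.u_p == pytest.approx(u_star, abs=1e-9)
        assert orbit.v_p == pytest.approx(v_star, abs=1e-9)
        assert orbit.convergence_residual < 1e-10

    def test_forced_orbit_genuinely_oscillates(self, orbit_fig4):
        assert orbit_fig4.u_p.max() - orbit_fig4.u_p.min() > 0.1
        assert orbit_fig4.convergence_residual < 1e-6
        # periodicity of the sampled orbit itself
        assert abs(orbit_fig4.u_p[0] - orbit_fig4.u_p[-1]) < 1e-3

    def test_euler_first_order_convergence(self):
        ref = compute_periodic_orbit(P22, F6, N=80_000)
        errs = []
        for N in (10_000, 20_000):
            orb = compute_periodic_orbit(P22, F6, N=N)
            sub = 80_000 // N
            errs.append(np.max(np.abs(orb.u_p - ref.u_p[::sub])))
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 3.0  # halving dt roughly halves the error

    def test_nonconvergence_raises_with_residual(self):
        with pytest.raises(OrbitConvergenceError) as exc:
            compute_periodic_orbit(P22, F6, N=1000, max_periods=3)
        assert exc.value.residual > 0
        assert exc.value.periods == 3

    def test_small_N_rejected(self):
        with pytest.raises(ValueError):
            compute_periodic_orbit(P22, F6, N=50)


class TestLinearization:
    def test_k_zero_equals_kinetics_jacobian(self):
        L = linearization_matrix(3.1, 12.0, P22, 0.0)
        assert L == pytest.approx(jacobian(3.1, 12.0, P22), abs=1e-14)

    def test_large_k_diagonal_dominance(self):
        k = 100.0
        L = linearization_matrix(3.1, 12.0, P22, k)
        assert L[0, 0] == pytest.approx(-k * k, rel=1e-2)
        assert L[1, 1] == pytest.approx(-P22.sigma * P22.c * k * k, rel=1e-2)

    def test_matches_finite_difference_of_perturbed_kinetics(self):
        # L(t;k) is the Jacobian of the kinetics at the orbit point with
        # the diffusion shift added; differentiate numerically.
        u0, v0, k, h = 2.7, 9.5, 0.8, 1e-6
        L = linearization_matrix(u0, v0, P22, k)
        fd = np.empty((2, 2))
        for col, (du, dv) in enumerate([(h, 0.0), (0.0, h)]):
            fp = reaction_terms(u0 + du, v0 + dv, P22)
            fm = reaction_terms(u0 - du, v0 - dv, P22)
            fd[0, col] = (fp[0] - fm[0]) / (2 * h)
            fd[1, col] = (fp[1] - fm[1]) / (2 * h)
        fd[0, 0] -= k * k
        fd[1, 1] -= P22.sigma * P22.c * k * k
        assert L == pytest.approx(fd, rel=1e-6, abs=1e-6)


class TestPoincareMap:
    def test_frozen_coefficients_give_matrix_power(self):
        N = 500
        orbit = PeriodicOrbit(
            params=P22, forcing=ForcingParams(A=0.0, T=1.0), N=N,
            u_p=np.full(N + 1, 4.4), v_p=np.full(N + 1, 20.36),
            convergence_residual=0.0, periods_used=1,
        )
        k = 0.7
        P = poincare_map(orbit, k)
        L = linearization_matrix(4.4, 20.36, P22, k)
        expected = np.linalg.matrix_power(np.eye(2) + (1.0 / N) * L, N)
        assert P == pytest.approx(expected, rel=1e-12)

    def test_map_equals_direct_euler_iteration(self, orbit_fig4):
        # the product acting on a vector IS the Euler recursion
        k = 1.1
        P = poincare_map(orbit_fig4, k)
        w = np.array([0.3, -1.2])
        dt = orbit_fig4.dt
        z = w.copy()
        for i in range(orbit_fig4.N):
            L = linearization_matrix(orbit_fig4.u_p[i], orbit_fig4.v_p[i],
                                     P22, k)
            z = z + dt * (L @ z)
        assert P @ w == pytest.approx(z, rel=1e-9)

    def test_determinant_obeys_liouville(self):
        # det P(k) ~ exp(integral of trace L over one period); the Euler
        # product carries an O(dt * tr^2) determinant bias, so the
        # quadrature comparison needs the fine discretization
        orbit = compute_periodic_orbit(P22, F6, N=100_000)
        for k in (0.0, 0.5, 0.9):
            P = poincare_map(orbit, k)
            u, v = orbit.u_p, orbit.v_p
            p = orbit.params
            d = u * u + 1.0
            core = v * (u * u - 1.0) / (d * d)
            tr = (-1.0 + 4.0 * core - k * k) + (
                -p.sigma * (p.b * u / d + p.c * k * k))
            integral = np.trapezoid(tr, dx=orbit.dt)
            assert np.linalg.det(P) == pytest.approx(np.exp(integral),
                                                     rel=1e-3)


class TestSpectrum:
    def test_unforced_multipliers_match_dispersion_exponentials(self):
        # A=0: the Poincare map of the constant orbit is the exponential
        # of the autonomous linearization; cross-checks the two modules
        orbit = compute_periodic_orbit(P22, ForcingParams(A=0.0, T=1.0),
                                       N=10_000)
        k = np.array([0.0, 0.4, 0.8, 1.08, 1.5, 2.2])
        spec = stability_spectrum(orbit, k)
        disp = dispersion_relation(P22, k)
        assert spec.lambda1_abs == pytest.approx(
            np.exp(disp.growth_rates), rel=1e-2)

    def test_reference_point_unstable_near_k_one(self, orbit_fig4):
        spec = stability_spectrum(orbit_fig4)
        assert spec.is_unstable
        assert 0.9 < spec.argmax_k < 1.3
        # far tail strongly damped by diffusion
        tail = spec.lambda_max[spec.k_values > 2.5]
        assert np.all(tail < 1.0)

    def test_unforced_point_stable_at_all_k(self):
        orbit = compute_periodic_orbit(P22, ForcingParams(A=0.0, T=1.0),
                                       N=10_000)
        spec = stability_spectrum(orbit)
        # a=22 sits within the marginal band below Turing onset
        assert spec.max_modulus <= 1.0 + 1e-3

    def test_moduli_converged_in_N(self, orbit_fig4):
        spec1 = stability_spectrum(orbit_fig4, np.arange(0.0, 2.0, 0.05))
        orbit2 = compute_periodic_orbit(P22, F6, N=20_000)
        spec2 = stability_spectrum(orbit2, np.arange(0.0, 2.0, 0.05))
        rel = np.abs(spec1.lambda_max - spec2.lambda_max) / spec2.lambda_max
        assert np.max(rel) < 0.005

    def test_moduli_product_equals_abs_det(self, orbit_fig4):
        k = 1.1
        spec = stability_spectrum(orbit_fig4, np.array([k]))
        P = poincare_map(orbit_fig4, k)
        assert spec.lambda1_abs[0] * spec.lambda2_abs[0] == pytest.approx(
            abs(np.linalg.det(P)), rel=1e-9)


class TestPhaseDiagram:
    def test_reference_cells(self):
        diag = phase_diagram(P22, T_grid=np.array([1.0]),
                             A_grid=np.array([0.0, 6.0]), N=4000)
        # A=0 row stable (a=22 below both bifurcation points),
        # (T=1, A=6) unstable (the forced-pattern regime)
        assert diag.stability[0, 0] == 1
        assert diag.stability[0, 1] == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram(P22, np.array([]), np.array([1.0]))
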