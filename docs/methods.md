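# Methods

## Model

The package implements the two-variable Lengyel–Epstein reduction of
the CIMA (chlorite–iodide–malonic acid) reaction with a sinusoidally
modulated activator feed,

    ∂u/∂t = a + A sin(2πt/T) − u − 4uv/(1+u²) + ∇²u
    ∂v/∂t = σ [ b (u − uv/(1+u²)) + c ∇²v ],

on a periodic square domain.  u is the dimensionless iodide (activator)
and v the chlorite (inhibitor) concentration.  The parameters, with the
reference values used throughout:

| symbol | meaning                                   | default |
|--------|-------------------------------------------|---------|
| a      | activator feed (∝ [MA]₀ in the tank)      | varied  |
| b      | inhibitor production (∝ [I₂])             | 1.9     |
| σ      | 1 + K, triiodide-complexation rescaling   | 8       |
| c      | diffusivity ratio D_Y/D_X                 | 1.5     |
| A, T   | forcing amplitude and period              | 0, 1    |

The unforced homogeneous steady state is (u*, v*) = (a/5, 1 + a²/25),
an exact zero of the kinetics.  Kinetics are always evaluated as
written, without clamping negative concentrations: clamping would
silently alter the dynamics, so the solver instead monitors for
non-finite values and reports blow-up.  Under strong forcing
(A > a at the sine minimum) the effective feed goes negative and u can
transiently dip below zero; runs at the reference settings keep u
bounded and finite, and this is surfaced to the user rather than
"fixed".

Assumptions inherited from the model reduction: two space dimensions
(the gel reactor's gradient direction is integrated out), periodic
boundaries, spatially uniform forcing, and feed changes mapping
directly onto the parameter a.

## Bifurcation analysis

Linearizing about (u*, v*) and adding diffusion gives
M(k) = J + diag(−k², −σck²).  The dispersion relation records the
largest real eigenvalue part of M(k) via the quadratic characteristic
polynomial.  The Hopf point is the Brent root of trace J(a) = 0
(checked det J > 0); the Turing point is the Brent root in a of
max_{k>0} Re μ(k) = 0, with the inner maximization by bounded scalar
search over k ∈ (0, 5] seeded from a 200-point scan.  Both roots are
resolved to |Δa| < 1e−8, far below the two decimals quoted for them.
For the reference set this yields a_Hopf = 26.883, a_Turing = 22.070,
k_c = 1.081.  A closed form exists for this model but a numeric root
with an independent brute-force-scan test is less error-prone; growth
rates within 1e−10 of zero are treated as marginal.

## Floquet analysis of the forced uniform state

The spatially uniform periodic solution (u_p, v_p) is computed by
explicit Euler at step Δt = T/N (N = 10,000 by default), integrating
period by period from (u*, v*) until two consecutive sampled periods
agree to 1e−6 in max norm (cap: 500 periods; non-convergence raises,
and phase-diagram cells that fail are marked indeterminate rather than
stable).  Euler — not a higher-order scheme — is deliberately retained
for both the orbit and the map so that the two discretizations cancel
consistently; accuracy is guarded by tests that double N and require
multiplier moduli to move by < 0.5%.

A wavenumber-k perturbation obeys d/dt δw = L(t;k) δw with L the
kinetics Jacobian along the orbit plus diag(−k², −σck²).  The
linearized Poincaré map is the ordered product
P(k) = ∏_{i=N−1..0} (I + Δt·L(t_i;k)) with L evaluated at the *left*
endpoint of each step (the product's rightmost factor is at t = 0).
Eigenvalue moduli come from the characteristic polynomial of the real
2×2 matrix, complex pairs via |λ| = √det.  The state is unstable at k
when max(|λ₁|, |λ₂|) > 1 + 1e−9; the tolerance avoids flagging the
neutral mode exactly at marginality.  The product is accumulated
simultaneously for a whole k-grid (the k-dependence of L is a diagonal
shift), default grid 0..3 in steps of 0.01.

At the reference forced point (a=22, A=6, T=1) the orbit converges in
52 periods and the spectrum peaks at k = 1.10 with max |λ| = 1.114,
unstable for k ∈ [0.94, 1.29]; the instability persists down to A ≈ 2.
Consistency is enforced by tests: at A = 0 the multiplier moduli equal
exp(T·Re μ(k)) from the dispersion relation to 1%, det P(k) matches
Liouville's formula to 0.1%, and frozen coefficients reduce the
product to a matrix power exactly.

## PDE solver

Space: second-order five-point Laplacian on a uniform grid with
dx = dy (reference 0.125, scaled-down preset 0.25).  Time: per step dt
(reference 3.124e−4, preset 1e−3),

1. Peaceman–Rachford diffusion half step — implicit in one axis,
   explicit in the other (r = D·dt/2dx²),
2. full-dt Heun update of the kinetics, forcing evaluated at t_n for
   the predictor and t_n + dt for the corrector (preserving second
   order for the non-autonomous term),
3. the mirror diffusion half step.

The implicit axis order alternates between successive steps to
symmetrize the splitting error; the interleaving of reaction and
diffusion is a documented choice guarded by a dt-halving test (settled
pattern changes < 1% in relative L2 when dt halves).  Periodic
tridiagonal systems are solved by a cached constant-coefficient Thomas
factorization with a Sherman–Morrison corner correction; because both
explicit and implicit periodic operators are zero-column-sum, diffusion
conserves each field's spatial sum to round-off (asserted at 1e−9).
The single-mode decay factor of the scheme is tested against the
analytic ADI symbol.  Kernels are numba-compiled scalar loops with a
vectorized numpy fallback that is verified to agree to machine
precision.

Initial conditions: u = v = 0 plus independent Gaussian noise
(sd 0.01), one seed for the single noise draw, everything after
deterministic.  Protocols run stage by stage with a continuous state;
the forcing phase restarts at each stage onset (matching the convention
that t is measured from the start of the modulation).

## Pattern classification

Per stage the runner records a dense burst of frames over the final
forcing period (or a 4-time-unit window when unforced, sampled at a
spacing incommensurate with the bulk-oscillation period) and
classifies:

- homogeneous (spatial sd < 1e−3 × amplitude scale, where the scale is
  max(1, |mean u|)): steady vs oscillatory by the temporal sd at 16
  fixed probe points across the frames, same relative threshold;
- otherwise patterned: dominant wavenumber = peak of the
  annulus-integrated power spectrum (bin width 2π/L, the domain's
  quantization); hexagonal spot lattices are asymmetric about the mean,
  so |skewness| > 0.3 ⇒ spots; otherwise angular spectral concentration
  (largest 15° orientation-bin share of the dominant annulus, folded
  mod π) > 0.6 ⇒ stripes; else mixed.  A dominant annulus holding
  < 15% of the structured power falls through to "irregular".

The skewness and concentration thresholds were calibrated on the
synthetic fixtures (ideal hexagonal triads score |skew| ≈ 0.8,
concentration ≈ 1 for stripes vs ≈ 1/3 for triads) and sit roughly
midway between the populations.  Wavelength locking across a forcing
episode is agreement of dominant wavenumbers within one spectral bin.

## Synthetic fixtures

The fixture generator produces idealized planforms with known labels:
resonant hexagonal triads (three cosines at 120° whose wavevectors sum
to zero exactly, after snapping to the reciprocal lattice), single
cosines (stripes), constants, and uniform temporal sinusoids.  They
emulate settled, defect-free planforms only — no transients, defects,
curvature or amplitude modulation of real simulations — so analyzer
tests passing on fixtures demonstrate the measurement conventions, not
robustness to every real-world planform; the simulation-backed tests
cover the latter.

## Tank feed model and parameter estimation

The estimation chain uses the measured CIMA rate laws
(k1a = 7.5e−3 s⁻¹, k1b = 5e−5 M, k2 = 6e3 M⁻¹s⁻¹, k3 = 2.65e−3 s⁻¹,
α = 1e−14 M²) and fixed stoichiometric fractions valid for the
reference feed composition ([NaClO₂]₀ = 10 mM, [KI]₀ = 2 mM, excess
iodate): [ClO₂·] = 0.2[ClO₂⁻], [I₂] = (3/5)[I⁻] − (1/6)[ClO₂·].  No
equilibrium speciation is solved.  Operations return full precision
(b = 1.914); comparisons against the rounded literature value 1.9 use
±0.05 because the published chain rounds intermediates.

The stirred tank obeys the linear mixing ODE
d[MA]₀/dt = [MA]_s q₁(t)/V − [MA]₀ (q₁(t)+q₂)/V with
q₁ = q₀ + A_flow sin(2πt/T), integrated by fixed-step RK4 at 0.01 min
(the ODE is linear and non-stiff; step halving changes the solution by
< 1e−8 M).  Interfaces use lab units (mL/h, minutes, M); flows are
converted to mL/min internally.  Because the tank low-pass filters the
pump program, a naive q₀ gives an asymmetric concentration swing; the
design routine root-finds (q₀, A_flow) on the simulated long-run
trajectory so the extremes are symmetric about the requested basis to
0.5%.  Designs for the published operating range land at q₀ within
90–170 mL/h and residence times of 2–3 min.

## Problem sizes and scaled-down conditions

The reference simulation (50×50 domain, dx=0.125, dt=3.124e−4,
t = 600) is faithful but long; the package's standard test and
reproduction conditions use the coarser of the two published grid
spacings (dx = 0.25) on a 25×25 domain with dt = 1e−3, which the
dt- and dx-robustness tests show preserves classification and
wavelength to within one spectral bin.  The pattern-window scans run
to t = 150 with a majority vote over 3 seeds per integer a — the
slowest-growing case (a = 23, max growth rate ≈ 0.074) saturates from
sd-0.01 noise well before t = 100.  The forcing scenarios use stages
150 / 25 / 225 (suppression) and 50 / 150 / 150 (induction): strong
forcing flattens the field toward round-off at ≈ 0.7/unit, so the
suppression stage is kept short enough (25 units) that the remnant
amplitude can regrow within the post stage at the a = 24 linear rate
(≈ 0.15/unit).

## Known limitations

- No analysis of the patterned (non-uniform) state's stability under
  forcing, and no spot-vs-stripe selection mechanism: only the uniform
  state's Floquet problem is solved.
- No 1-D/3-D solvers and no cross-gradient (two-sided-feed) boundary
  conditions; the reduced periodic-domain model cannot reproduce
  boundary-gradient effects.
- The classifier's "irregular" bucket absorbs spatiotemporal-wave-like
  states rather than detecting waves explicitly.
- The tank model covers a single modulated species; co-feed residence
  changes (< 10% in practice) are ignored.
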