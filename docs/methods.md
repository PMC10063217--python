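# Methods

## Model

`archswim` simulates the planar beating of a human-sperm-like cell: a rigid
ellipsoidal head attached to an inextensible, geometrically nonlinear
elastic flagellum of unit dimensionless length, immersed in Stokes flow.
Beating is driven by a coarse-grained axonemal *active moment density*
m(s, t) obeying a hysteretic curvature-threshold rate law,

    dm/dt = -(m - 2 sgn(m)) H(kappa_c - sgn(m) kappa) - sgn(m),

after rescaling position by flagellum length L, time by the switching time
tau_d and moment by the fully-engaged moment density m_c.  Below threshold
the engaged states m = ±1 attract; when the local curvature (signed, in
units of 1/L) crosses ±kappa_c the moment decays at unit rate, crosses
zero, and is captured by the opposite branch.  The moment acts on the
proximal 95% of the flagellum (`ell = 0.95`); the distal end piece is
passive but hydrodynamically loaded.

Force balance on the massless filament, integrated twice from the free
distal end, gives the elastohydrodynamic constraint

    E(s) dtheta/ds - M \int_s^1 m H(ell-s') ds'
        + S^4 e3 . \int_s^1 (X(s') - X(s)) x f(s') ds' = 0,

with E(s) = (rho-1)((s-d)/d)^2 + 1 for s <= d (and 1 beyond) the tapered
bending stiffness, f the force per unit length exerted by the flagellum on
the fluid, and the dimensionless groups

| group   | meaning                         | definition              | default |
|---------|---------------------------------|-------------------------|---------|
| S       | viscous/elastic force ratio     | L (mu/(E_d tau_d))^(1/4)| 18      |
| rho     | proximal/distal stiffness ratio | E_p / E_d               | 36.4    |
| M       | active/elastic moment ratio     | L^2 m_c / E_d           | 900     |
| kappa_c | critical curvature threshold    | —                       | 1.5     |
| d       | stiffness taper fraction        | —                       | 1.0     |
| ell     | active fraction                 | —                       | 0.95    |

The default taper fraction d = 1 spreads the stiffness decay over the whole
flagellum; it is exposed in the configuration because the taper extent is a
modelling choice rather than a measured constant.

Hydrodynamics is nonlocal: the velocity induced by the flagellar force
density and the head surface traction phi is evaluated with the method of
regularized Stokeslets (kernel `S_ij = [delta_ij (r^2+2 eps^2) + r_i r_j] /
(8 pi mu r_eps^3)`, viscosity scaled to one).  No-slip on the flagellar
centerline and on the head surface, together with total force- and
(in-plane) moment-free conditions over the cell, closes the system.  The
head is clamped to the proximal tangent (head angle = theta(0) + offset,
offset 0 by default); cell length for velocity normalization is
1 + 2 x 0.04 = 1.08 flagellar lengths (the head axes 0.04/0.032/0.02 are
read as semi-axes).

## Smoothed switching law

The discontinuous rate law is kept as the reference implementation
(`moment_rate`), with the conventions sgn(0) = 0 and H(0) = 0 (attaining
the threshold counts as crossing, so the supra-threshold rate is exactly
-sgn(m)).  Inside the stiff time integrator a smoothed variant of width
`delta_smooth` (default 1e-2) is used.  The smoothing is a sigmoid-weighted
blend of the two exact sign branches,

    F+ = -(m-2) H_d(kappa_c - kappa) - 1,
    F- = -(m+2) H_d(kappa_c + kappa) + 1,
    dm/dt = w(m) F+ + (1-w(m)) F-,    w = (1 + tanh(m/delta)) / 2,

with H_d the tanh step of width delta *in curvature only*.  Substituting a
sigmoid directly for sgn() inside the formula would sweep the Heaviside
argument kappa_c - sgn(m) kappa through +kappa_c as the sigmoid
interpolates, re-enabling the engaged branch and creating a spurious stable
equilibrium just above m = 0 whenever |kappa| > kappa_c — the branch blend
avoids this while converging pointwise to the exact law away from m = 0.
The blend preserves the transversal crossing at m = 0 (both one-sided
limits equal -sgn just above/below) and the forward invariance of
[-2, 2].

## Discretization

*Flagellum.*  The filament is a chain of N straight segments (default
N = 40, h = 1/N): the state carries one tangent angle per segment, joint
positions are exact polyline sums (inextensibility exact by construction),
and signed curvature is the exact joint difference (theta_j -
theta_{j-1})/h at the N-1 interior joints.  This staircase representation
is the standard segment discretization of regularized-Stokeslet filament
models; it was chosen over a nodal angle field with centered differencing
because the latter's curvature operator annihilates the grid-scale zigzag
mode, which the coupled system then amplifies into a sawtooth instability
at moderate N.  The moment balance is collocated at the interior joints;
the active-moment integral uses the trapezoid rule on joint values of m
(collocated with the curvature on the active joints), and the hydrodynamic
moment arm uses the midpoint rule per segment, matching the
piecewise-constant force density.

*Head.*  A two-grid nearest-neighbor (NEAREST) boundary-element scheme:
tractions on Q coarse nodes (default 16), quadrature on
`head_refinement x Q` fine nodes (default 4x).  Both grids are mirrored
Fibonacci lattices mapped to the ellipsoid with the exact surface Jacobian
as quadrature weight, so the fine weights sum to the surface area and the
mesh is exactly symmetric about the beat plane (out-of-plane resultants
cancel by symmetry; they are asserted, not constrained).  Each fine node
maps to its nearest coarse node (ties to the lowest index; an orphaned
coarse node adopts its nearest fine node).  The rigid-sphere validation
settings (Q = 32, refinement 4, eps = 0.02 on a unit sphere) reproduce
Stokes drag 6 pi mu a within 1.3%, improving monotonically with Q.

*Regularization.*  eps defaults to 0.25 h, tying the kernel width to the
segment length as is standard for line distributions of regularized
Stokeslets; it is configurable and the drag tests document the
sensitivity.

*Repulsion.*  Self-intersection is penalized by a short-range pair force
`A exp(-B d)(1 - exp(-B d))` along the separation vector with A = 100 and
B = 4/eps, integrated over the centerline outside an arclength exclusion
window (default 2h) and over the head surface, with a hard cutoff at 4 eps.
At the defaults the junction-adjacent flagellum-head pairs contribute a
negligible O(1e-5) force density in non-contacting configurations.

## Time stepping and the instantaneous solve

At a given state (X0, theta, m) the unknown rates and forces
(Xdot0, thetadot, f, phi) satisfy one square dense linear system:
moment-balance rows (algebraic in f), flagellar no-slip at segment
midpoints (exact chain kinematics vs. boundary-integral velocities of
f + f_rep and phi), head no-slip (rigid-body left side with the clamped
head), and the force/moment closure.  Solving it reduces the dynamics to
an ODE in z = (X0, theta, m), integrated with SciPy's BDF (variable-order
implicit multistep; default rtol 1e-5, atol 1e-7).  A fused numba kernel
evaluates the right-hand side; it mirrors the transparent numpy assembly
term by term and the two are asserted equal to 1e-12 in the test suite
(numpy remains the reference and the fallback).

Simulations start from the unit-arclength section of the low-amplitude
parabola y = 0.1 x^2 (segment angles sampled at segment midpoints, base at
the origin) with the moment field uniformly at m0 = +1, the engaged
equilibrium; the long-run beat is insensitive to this choice because the
limit cycle attracts.

## Steady-beat protocol

`run_to_steady_beat` integrates in windows (default 30 time units) up to
`max_time` (default 400).  Beats are delimited by a Poincare section on
the proximal tangent angle: rising zero crossings of the signal minus its
running mean (odd-reflection padding avoids edge bias), debounced by a
hysteresis threshold at 25% of the 90th percentile amplitude.  The run is
*converged* when the relative L2 distance between successive per-beat
mean-|kappa| profiles stays below `steady_rtol` (default 1e-2) for two
consecutive beat pairs; *no_beat* when the trailing half-window contains
no beat boundary and the proximal-angle amplitude falls below
max(1e-3 rad, 5% of the largest excursion seen) — the relative floor
matters because the approach to a stable focus (e.g. M = 100,
kappa_c = 5) is a slowly decaying spiral; otherwise *not_converged*.

## Waveform analytics

Velocity is |Delta X0| per complete beat averaged over complete beats, in
cell lengths per beat; frequency is the reciprocal mean beat interval;
the curvature statistic is the time average of |kappa(s, t)| over the last
three complete beats on the interior-joint grid; yaw amplitude is the
half peak-to-peak proximal angle over the last three beats.  Wave
direction is diagnosed from the phase slope of the fundamental beat
harmonic of kappa(s, t) (negative slope = anterograde).  The qualitative
mode label uses configurable thresholds (no-beat floor 1e-3 rad;
progressive velocity 0.01 cell lengths/beat; penetrative/activated yaw
split 0.6 rad; hyperactivated peak curvature 25) — the boundaries between
modes are conventionally drawn by eye, so these defaults were placed at
the observed gaps of the simulated distributions and are stored in
configuration, not hard-coded.

## Sweeps, hysteresis, fitting

Parameter sweeps run the steady-beat protocol independently and
deterministically per grid point, persisting summaries incrementally;
failures are flagged and kept.  The hysteresis continuation increments
kappa_c along an ordered path warm-starting each run from the previous
final state, then retraces backwards; where a single attractor exists the
passes coincide, and their separation is the hysteresis signature.

The tracked-waveform curvature estimator differentiates ONCE: per frame
the chord tangent angles between consecutive tracked points are splined
against arclength (generalized-cross-validation smoothing by default) and
kappa = dtheta/ds is the spline derivative — far better conditioned on
noisy points than the second derivative of position splines.  Two further
noise defenses are on by default: the tracked point coordinates are
low-passed across frames (quadratic Savitzky-Golay with a ~quarter-beat
window; localization noise is independent between frames while the
waveform moves smoothly), and the signed curvature is low-passed the same
way before rectification, since zero-mean noise biases a time-averaged
|kappa| upward.  The profile
grid keeps one point-spacing clear of the spline support ends, where
boundary conditions distort derivatives.  On noise-free synthetic tracks
the pipeline reproduces the simulator's own profile to ~3% (N = 16) and
within 2% at N = 40; 0.275 um positional noise (5% of the ~5.5 um lateral
beat envelope at L = 55 um) raises the floor to ~7%.

The fitting pipeline compares a tracked flagellum's mean-|kappa| profile
(1/um) against a library of simulated profiles: the simulated arclength is
rescaled by a length parameter l on a 30-60 um grid at 0.5 um spacing
(curvature divided by l), interpolated to the experimental arclength
samples truncated at the tracked length, and scored by sum squared
difference; the reported error is
R = sqrt(sum(|k_sim|-|k_exp|)^2) / sqrt(sum |k_sim|^2) over the tracked
samples.  The search is an exhaustive grid lookup (no continuous
optimization): the goal is waveform-family identification, not maximum
likelihood.  The length scale is searched jointly with the four
dimensionless groups and both are reported.

## Synthetic tracked waveforms

`generate_synthetic_track` emulates tracked imaging data from a simulated
record: the mean beat period is mapped to 1/`beat_hz` seconds (default
10 Hz), the centerline is sampled at the frame rate (default 200 Hz),
scaled to `L_um` (default 55 um), truncated by a distal fraction (the tip
is the hardest part to track in real data), and perturbed with i.i.d.
Gaussian positional noise; generation is deterministic per seed.  The
generator reproduces sampling, truncation and additive localization noise;
it does **not** emulate out-of-plane excursions, tracker drop-outs,
motion blur, or systematic point-spread biases, so passing recovery tests
demonstrate robustness to sampling and noise only, not to every failure
mode of real microscopy.

## Problem sizes used by the test suite and acceptance script

The reference simulation runs at N = 40 segments, 16 coarse/64 fine head
nodes, to t = 150 (converged limit cycle, beat period ~9.5).  Companion
regime checks (kappa_c = 8 and the M = 100 equilibrium) use N = 24; the
hysteresis continuation N = 16-24 with looser solver tolerances
(rtol 1e-4, delta_smooth 0.02); the fitting-recovery experiment builds its
3x3x3x3 profile library at N = 16 with 70-time-unit runs.  These reduced
settings are the package's documented trade-off between discretization
error and turnaround; the reference beat period changes by about 5%
between N = 20 and N = 40.

## Known limitations

* Exact identification of a generating parameter set from a noisy
  synthetic track against a dense candidate library is marginal: the
  mean-|kappa| statistic with the joint length-scale search leaves
  neighbouring grid candidates within the noise-induced profile
  perturbation of one another (tracked-profile shapes shift by 5-10%
  under 0.275 um positional noise, comparable to the inter-candidate
  spacing), so the generating point is recovered for most but not all
  noise realizations; noise-free recovery is exact.  The statistic is
  informative at the level of waveform families (penetrative vs activated
  vs hyperactivated), which is what profile fitting is for.

* Quantitative regime boundaries are resolution-sensitive: the
  penetrative-to-activated jump and the onset of nonprogressive beating
  shift with N (the kappa_c = 8 attractor is a slow looping pattern at
  N = 24 but a fast high-yaw progressive pattern at N = 40).  Qualitative
  structure (limit cycle, anterograde wave, bistability with warm-start
  dependence, equilibrium at low M) is robust.
* Very large kappa_c at large M drives tight coiling that the repulsive
  force cannot always regularize at practical resolutions; such runs abort
  with a step-size diagnostic rather than return a spurious beat.
* Planar beats only; no walls or background flow; Newtonian fluid only.
* The head-flagellum junction is rigidly clamped; no compliant neck.
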