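# Methods

`fscvmodels` simulates and fits evoked dopamine transients recorded by
fast-scan cyclic voltammetry (FSCV) in the dorsal striatum. This note
describes the model equations, the numerical schemes, the inference
machinery, the synthetic-data generator used for validation, and the
design choices that were genuinely open.

## Stimulation and plasticity

A stimulation protocol is a train of electrical bursts; burst *i* starts
at `t_i` and lasts `NP/f` seconds (`NP` pulses at `f` Hz; the standard
protocol is 30 pulses at 50 Hz, i.e. 0.6 s). The indicator

    S(t) = 1  if t lies inside any burst window [t_i, t_i + NP/f]

treats the burst as a continuous on-period; individual pulses are not
resolved. Interval edges are closed, so boundary membership is
deterministic. The Repeated Burst protocol places six bursts with a 5 s
interstimulus period, read as **offset-to-onset** (onsets 5.6 s apart);
an onset-to-onset convention is available via
`make_repeated_burst(..., spacing_convention="onset_to_onset")`. The
protocol carries an `onset_shift` so the spatial models can start their
bursts slightly earlier, compensating for the diffusion lag through the
dead space (default 0).

Release per pulse is modulated by A(t), the product of three kinetic
components H_j (short-term facilitation, short-term depression,
long-term depression), each obeying

    dH_j/dt = f * p_j * H_j * S + (1 - S) * (1 - H_j) / tau_j .

Positive plasticity factors p_j facilitate, negative ones depress; tau_j
sets the relaxation back to the equilibrium value 1 between bursts. The
equation is scalar and piecewise linear wherever S is constant, so the
implementation propagates the **exact closed form** between burst edges
(growth factor `exp(f p_j T)` while stimulated, exponential relaxation
otherwise). A fixed-step RK4 stepper sits behind the same interface
purely as a cross-check; the analytic path is the implementation. The
component ordering is fixed and named so published parameter rows are
unambiguous, and a component value can be carried across runs (e.g. a
long-term depression state surviving the 2-min gap between protocols).

## Release models

All three variants share the drive `DA_P * I * f * S(t) * A(t)` (DA_P =
dopamine released per mA of stimulus current I) and Michaelis–Menten
uptake `Vm*C/(C+Km)` by the dopamine transporter. K_m defaults to
0.2 uM, the consensus value for mice, and is fixed (not fitted) by
default. An optional dimensionless `scale` factor multiplies the drive
and defaults to 1.

* **SUR** (Simple Uniform Release): a single well-mixed compartment,
  `dC/dt = drive - uptake`, integrated with classical RK4 at `dt = 1 ms`
  with the drive evaluated analytically at half steps.
* **STUR** (Spatiotemporal Uniform Release): radial reaction–diffusion
  in a tissue cylinder of radius `R_L = 50 um` with diffusion
  coefficient `D = 240 um^2/s` (tortuosity-corrected). A dead-space
  annulus of width `R_D` (default 3 um) just inside the outer boundary
  has diffusion only — no release, no uptake (both are masked by the
  Heaviside indicator eta). The electrode reads the concentration at
  `R = R_L`; both boundaries are no-flux (the FSCV electrode reflects
  rather than consumes dopamine), and `R = 0` carries the cylindrical
  symmetry condition. `R_D = 0` disables the dead space, the limit in
  which STUR must reproduce SUR.
* **STDR** (Spatiotemporal Discrete Release): as STUR, but release
  enters at discrete radii R_i, each a concentric shell source (the
  radial rendering of a Dirac delta). Sites default to 6 um spacing
  across the active region; DA_P then carries units uM*um/mA.

### Spatial discretization

The cylindrical diffusion operator is discretized in **conservative
finite-volume form**: node i owns the annulus `[r_i - dr/2, r_i + dr/2]`
(half cells at the boundaries) and fluxes are exchanged through faces
with conductance `2*pi*r_{i+1/2}*D/dr`. With no-flux closures the
discrete mass `sum_i V_i C_i` is conserved to round-off, which is what
the mass-conservation checks measure. The default grid spacing is
`dr = 0.5 um`.

Two grid renderings deserve mention:

* The dead-space mask is applied as the **exact active-volume fraction
  of each cell**, not a 0/1 nodal value. A sharp nodal mask pins the
  mask edge to the nearest node — an O(dr) geometry error that dominates
  grid-convergence error; the fractional rendering keeps the scheme
  second-order in space. The public `dead_space_mask` remains the exact
  binary Heaviside.
* Each shell source is deposited into the single nearest grid cell
  (ties toward smaller R), scaled by `R_i / (r_cell * dr)`, so the
  injected mass per unit axial length is `2*pi*R_i * DA_P * I` per pulse
  **exactly**, independent of dr.

### Time stepping

Each step is Strang-split: half a reaction step (explicit midpoint rule,
drive evaluated at the quarter-step time), a diffusion step, and the
second reaction half-step. The diffusion step uses **TR-BDF2**
(trapezoidal stage over `gamma*dt`, `gamma = 2 - sqrt(2)`, then BDF2),
which is second-order, unconditionally stable, L-stable and exactly
mass-conservative on the finite-volume operator. L-stability matters
here: a plain Crank–Nicolson step is only A-stable and rings visibly
around the stiff shell sources of the discrete model, driving the field
below zero by several percent of its maximum. With TR-BDF2, halving
both dr and dt changes the electrode trace by ~0.02%.

An explicit-Euler scheme (`scheme="euler"`) is kept as a cross-check; it
refuses to run unless `D*dt/dr^2 <= 0.5`.

Concentrations are clamped at zero with a warning only for undershoot
within the solver tolerance `max(1e-6 uM, 5e-3 * field max)`; anything
larger aborts the run as an instability. The default solver step is
`dt = 1 ms`, with outputs reported on the 10 Hz FSCV grid. The initial
condition is zero dopamine everywhere: tonic background levels are below
FSCV detection and the data are background-subtracted.

## Electrode response and adsorption

The measured signal is not the striatal concentration. Dopamine
transfers toward the electrode at rate k_S, away at k_E, and transiently
adsorbs to the carbon surface:

    d[DA]_E/dt = k_S [DA]_S - k_E [DA]_E + k_Gamma Gamma
    dGamma/dt  = k1 [DA]_E - k2 [DA]_E Gamma - k3 Gamma

`k_Gamma` is fixed at 1/s (overridable). The adsorbed pool returns
dopamine to the electrode, which is what makes the inter-burst baseline
creep upward across rapid successive bursts, and the system as printed
does not conserve mass between the two pools — it is implemented exactly
as stated. The coupled ODEs are integrated with RK4 on the solver grid
and the trace is **decimated** (instantaneous samples, not bin averages)
to the 10 Hz scan grid, since each FSCV scan is an instantaneous
measurement every 100 ms. A `bypass` flag returns [DA]_S itself — the
simulation with the recording artifacts removed.

The transfer/adsorption rates are package defaults chosen once as
plausible carbon-fiber kinetics: `k_S = k_E = 6 /s` (unit steady-state
gain, ~0.17 s response time), `k1 = 0.12 /s`, `k2 = 0.10 /(uM*s)`,
`k3 = 0.05 /s`. They give a visible but modest baseline creep and are
freely fittable or overridable.

## Inference (ADVI)

Fitting follows automatic-differentiation variational inference: each
free parameter (any of DA_P, V_m, p_j, tau_j, k_S, k_E, k1–k3) is mapped
to the real line by a logit-style bijection between its bounds (or
`log` for half-open supports), a Gaussian variational posterior is
placed on the unconstrained vector, and the ELBO

    E_q[ log p(y|theta) + log p(theta) + log|J| ] + H[q]

is maximized with Adam using reparameterized stochastic gradients
(default 2 Monte Carlo samples per step, learning rate 0.05). Priors are
independent Gaussians on the constrained scale, truncated by the bounds;
the likelihood treats each 10 Hz sample as Gaussian around the model
trace with standard deviation `v = 0.05 uM`. The model value entering
the likelihood at time t is the ODE/PDE solution [DA]_E(t) itself
(pointwise, not a cumulative integral).

No automatic-differentiation backend is used: gradients of the log-joint
with respect to the (at most 13) unconstrained coordinates are taken by
central finite differences around each draw, which costs `2k + 1`
forward simulations per Monte Carlo sample. The numba-compiled solvers
make this a few milliseconds per simulation for SUR, so a full fit runs
in seconds; the spatial variants fit through the identical interface at
higher cost. Results record `gradient_method = "finite_difference"`.

Two variational families are provided. The default is **mean-field**
(diagonal covariance). The **full-rank** family (dense Cholesky factor)
exists because the posterior over (DA_P, V_m) is strongly correlated —
about 0.97 on synthetic wildtype data, measured against a brute-force
grid posterior — and a factorized Gaussian then understates the marginal
standard deviations roughly two-fold while leaving the posterior means
essentially unchanged. Recovery experiments default to full-rank so the
two-standard-deviation coverage column is meaningful.

Convergence is declared when consecutive 80-iteration ELBO window means
agree to 1e-3 relative — the window averaging tames the O(1) noise of
the per-iteration ELBO estimate. Non-convergence raises a warning and is
flagged on the result, never silent. All posterior means lie strictly
inside their declared bounds by construction of the bijections, and this
is asserted in the tests.

Default bounds are package choices: release/uptake magnitudes in
`(0, 4x the prior center)`, facilitation factor in (0, 0.05), depression
factors in (-0.05, 0.005) (the small positive margin keeps the knockout
value p3 = 0 strictly interior), short time constants in (0.5, 100–200 s),
the long one in (100, 3600 s), transfer rates in (0.05, 50 /s),
adsorption rates in (0, 2). Prior standard deviations default to 50% of
the center value with per-kind floors.

## Synthetic data and parameter recovery

The generator produces what the fitting machinery expects from a real
experiment: a stimulus-locked rise over ~0.6 s, a decay over seconds
governed by uptake, baseline creep across repeated bursts from
adsorption, and i.i.d. Gaussian measurement noise (default sd 0.05 uM,
matching the likelihood) added on the 10 Hz grid. Negative noisy samples
are kept — background-subtracted FSCV signals dip below zero. Traces are
deterministic given the seed and carry their generating parameters,
protocol and seed in their metadata.

What it does **not** emulate: autocorrelated or signal-dependent noise,
scan-to-scan background drift, electrode calibration error, and
averaging across animals. Passing recovery tests therefore demonstrate
that the estimator is correct and calibrated when the model and noise
assumptions hold, not that those assumptions hold for any particular
recording.

`run_recovery` generates replicate traces at a published parameter row,
fits each, and reports per-parameter truth, posterior mean/sd, errors
and two-sd coverage, plus a residual diagnostic: a median residual sd
above twice the generating noise level flags model mismatch. Fitting a
uniform-release model to discrete-release data does *not* trigger the
flag — the variants are functionally near-equivalent by design — whereas
wrong fixed electrode constants do.

Typical results at the wildtype sweep-1 row (Single Burst, noise sd
0.05 uM, 10 replicates, kinetics fixed at truth): median relative errors
of ~1–2% for both DA_P and V_m, with full two-sd coverage; the exact
numbers for a given seed are recomputed by `scripts/acceptance.py`.

## Problem sizes

The default experiment sizes used throughout the tests and the
acceptance script are the package's standard operating points: single
protocols of 8–45 s simulated at 1 ms resolution, a 101-node radial grid
(dr = 0.5 um), 10-replicate recovery batches, and fits capped at
400–600 ADVI iterations (convergence typically occurs near 200–400).

## Known limitations

* The electrode rate constants are package defaults, not published
  estimates; fits of real data should free or re-center them.
* The STUR/STDR fits use the same finite-difference ADVI path as SUR and
  are simply slower; there is no adjoint/autodiff gradient.
* The coordinate layout follows the model equations literally: the
  electrode surface is the outer cylinder boundary `R = R_L` with the
  dead space just inside it. An inverted layout (electrode on the axis)
  would change the curvature weighting and is not provided.
* Axial and angular diffusion, anisotropic tortuosity, and consuming
  (amperometric) electrodes are out of scope.
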