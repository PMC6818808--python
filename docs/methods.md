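# Methods

## Model

A myelinated axon is modelled as an infinite passive cable (the internodes)
studded with periodically spaced active point sites (the nodes of Ranvier).
Below threshold the trans-membrane potential V(x, t) obeys

    tau dV/dt = lam^2 V'' - V + R_m I_chan(t),

with tau = C_m R_m and lam = sqrt(R_m/R_c).  When a node crosses the firing
threshold V_thr it releases a current with a *prescribed* time course —
voltage dependence of the gating is deliberately discarded, which is what
makes the model solvable in closed form.  Four release profiles are
implemented:

- **A** — instantaneous impulse `I0 δ(t)`,
- **B** — impulse after a hard delay Delta,
- **C** — instantaneous onset, exponential decay with constant tau_c,
- **D** — gated profile `(1 - e^(-t/tau_m))^gamma e^(-t/tau_h)` (sodium;
  gamma = 1 by default, any gamma >= 1 supported), optionally minus a slower
  potassium profile `(1 - e^(-t/tau_n))^4 e^(-t/tau_k)` with peak density
  7.5% of the sodium peak (the ratio of the nodal K and Na conductances,
  0.09/1.2 S/cm^2).

Gated profiles are normalised so their maximum equals I0 and expanded into
signed sums of pure exponentials (binomial expansion), each of which
convolves with the cable Green's function in closed form.

### Current division at a node

Of the channel current entering a node, only the fraction
`beta = 1/(1 + R_lam/(2 R_node))` flows into the axial cable; the rest leaks
back across the nodal membrane.  `R_node = R_n/(pi d l)` takes the nodal
membrane to be the side wall of a cylinder — the membrane area formula is
not uniquely determined by the specific resistance alone, and this choice
makes the total channel current (density x area) linear in node length
while the cable-bound current `l beta(l)` saturates, the behaviour the model
is built around.  Note beta decreases with node length (a vanishing node
leaks nothing).

### Threshold condition and velocity

Periodic saltatory conduction means node n fires t_sp after node n-1.
Summing the single-node responses at the electrotonically corrected node
spacing `x_1 = L + l lam/lam_n` (a node of length l adds l/lam_n to the
dimensionless cable distance) gives the implicit condition

    V_thr = sum_{n=1..N} U(n x_1, n t_sp),

solved for the smallest positive root by Newton iteration with a
central-difference derivative, safeguarded inside a bracket found by a
geometric scan over t in [1e-6, 10] ms; bisection takes over whenever a
Newton step leaves the bracket.  Convergence is declared at a residual of
1e-9 mV.  An unreachable threshold returns an explicit propagation-failure
result rather than raising.  N = 1000 nodes per side is the default; N = 20
already reproduces t_sp to ~0.3% at standard parameters, but small N
genuinely slows the computed velocity at short internodes, so sweeps expose
N.  Velocities are reported node-corrected,

    v = (L + l) / (L/v_internode + l/v_node),

where v_node is the conduction velocity of an unmyelinated axon with nodal
membrane properties (computed once per parameter set and cached).  For the
impulse scenarios the unmyelinated chain does not reach threshold at the
calibration amplitude, so no correction is applied there (the correction is
< 2% whenever it exists, since l << L).

### Unmyelinated axons

An unmyelinated axon is the L = 0 limit: segments of length l_disc fire
sequentially along a cable whose constants are the nodal ones scaled by the
relative channel density rho (conductivity ~ density):
`lam_tilde = lam_n/sqrt(rho)`, `tau_tilde = tau_n/rho`, membrane resistances
x 1/rho.  The peak current density is kept at its nodal value; scaling it
with rho as well would make the rho = 0.1 and 0.02 densities sub-threshold
(maximum summed depolarisation ~4 mV and ~0.6 mV against V_thr = 15 mV),
i.e. sparse-channel axons could never conduct, contrary to the behaviour
the model is meant to capture.  A refinement check halves l_disc and flags
discretisations whose velocity moves by more than 2%.

## Units and amplitude conventions

All internal quantities use (um, ms, mV, nA, MOhm, nF), chosen because
mV = nA x MOhm and ms = MOhm x nF close exactly; every tabulated constant is
converted once at load time (conversion factors unit-tested, round-trip
exact).  Current densities (pA/um^2) times the nodal area pi d l give total
currents in nA.

The delta-current response is evaluated literally as
`U = tau R_lam beta I0 / sqrt(4 pi t) exp(-x^2 tau/(4 lam^2 t) - t/tau)`
with t in ms, equivalent to assigning the impulse the magnitude
`beta I0 tau^(3/2)` (nA ms).  The response at the firing node is singular at
t -> 0+, so amplitudes of impulse scenarios are defined on a recording grid
with 0.5 us resolution aligned to the firing instant: the first sample after
the impulse caps the singular term.  Resolution and prefactor together
constitute the impulse normalisation; they are calibrated by the convention
that an instantaneous-current amplitude of 6.6 pA/um^2 produces a ~100 mV
action potential at standard parameters (we obtain 97 mV).  The gated and
exponential scenarios have no such singularity and are
resolution-independent.

With the standard gated sodium current (50 pA/um^2) the computed peak
depolarisation is ~69 mV (~67 mV with potassium included, followed by an
after-hyperpolarisation of ~-6 mV), somewhat below the ~100 mV sometimes
quoted for this amplitude.

## Closed-form responses and numerics

The convolution of a unit exponential current (constant tau_s) with the
Green's function reduces to

    phi = (1/(4 sqrt(tau) p)) e^(-a/t - t/tau)
          [w(i(q - p sqrt(t))) - w(i(q + p sqrt(t)))],

with a = x^2 tau/(4 lam^2), q = sqrt(a/t), p = sqrt(-(1/tau_s - 1/tau)) and
w the Faddeeva function.  Conventions and stability:

- tau_hat = (1/tau - 1/tau_s)^(-1) may carry either sign in the published
  forms of this solution; internally the signed rate difference
  c = 1/tau_s - 1/tau is used and the complex square root absorbs the sign,
  so fast (tau_s < tau) and slow (tau_s > tau) currents share one code path.
- The degenerate case |1/tau - 1/tau_s| < 1e-12 /ms uses the analytic limit
  `F = 2 (sqrt(t) e^(-a/t) - sqrt(pi a) erfc(q))`.
- For slow currents the lower Faddeeva argument is purely imaginary with a
  possibly large negative imaginary part, where w(z) ~ exp(|z|^2); the
  reflection w(-iy) = 2 e^(y^2) - w(iy) is applied and the growing
  exponential combined analytically with the damping factor into
  `exp(-2 p sqrt(a) - t/tau_s)`, which always decays.  Evaluation is finite
  for x up to 2000 lam and t from 1e-6 tau to hundreds of tau (tested).
- Correctness anchor: the closed form matches adaptive quadrature of the
  convolution integral to better than 1e-8 of the maximum over a grid
  spanning x in {lam/2, lam, 2 lam}, t in (0, 5 tau], for fast and slow
  constants alike (the test suite's master check).

## Linearised time-to-spike

The rising phase of U(x, t) is linearised at its inflection point t_i
(`t_sp ≈ t_i + (V_thr - V(t_i))/V'(t_i)`), giving explicit estimates:

- **Impulse:** t_i is the smaller positive root of the quadratic truncation
  of t^4 V''/V; proximally t_i = zeta x^2 tau/lam^2 with
  zeta = (1 - sqrt(2/3))/2 ≈ 0.0918 (the value sometimes typeset as
  "1/2 - 1/6" with the radical lost), distally t_i -> sqrt(2) (x/lam) tau/4.
  The closed V(t_i) and V'(t_i) drop the leak term (exact to O(t_i/tau)).
  Against the exact single-node solve the linearised t_sp is within ~15%
  for thresholds up to ~75% of the single-node peak.
- **Exponential:** branch formulas for tau_c < tau and tau_c > tau from the
  analogous truncation; the tau_c << tau limit is implemented as the
  algebraic limit of the fast branch (the separately printed limit formula
  carries an inconsistent factor 4 under its root).  These branch formulas
  are coarse — 30-60% off the numerically located inflection in our checks —
  and are kept as published, tested only to bracket the true inflection
  within a factor of 3.
- **Gated:** t_i = t_cab(x) + t_chan, the cable inflection plus the
  x-independent inflection of the rising current.  t_cab uses the full
  impulse quadratic rather than its distal limit: at internode-scale
  distances (x ~ 0.17 lam at standard geometry) the distal form errs by
  more than 2x while the full quadratic is within ~5% of the numerical
  inflection.

The linearisation is single-node (N = 1) and is a diagnostic, not the
production solver.

## Ephaptic coupling

Axons sharing restricted extracellular space couple through the
extracellular potential; the coupling parameter is
`alpha = 1/(R_ex^-1 + sum_m R_ax,m^-1)`.  The coupled linear system is
decoupled into modes `P_1 + c P_2`; for identical axons c = +/-1 (sum and
difference).  The effective length constant of a mode folds the shared
return path into the axial resistance (a series term):

    lam_tilde^2 = lam^2 / (1 + alpha R_ax^-1 (1 + c lam_2^2/lam_1^2)),

so for identical axons at R_ex^-1 = 0 the sum mode has lam/sqrt(2) and the
difference mode exactly lam (it drives no net extracellular current and
unit tests confirm it reproduces uncoupled propagation exactly).  Two other
conventions exist and were rejected: an additive form with the coupling
*increasing* lam_tilde reverses every qualitative phenomenon below
(synchronous pairs come out faster, the passive neighbour depolarises before
hyperpolarising, offsets grow); the strict linearisation of the coupled
system collapses to lam_tilde = 0 at R_ex^-1 = 0 (with no extracellular
return path the common mode cannot diffuse at all), extinguishing paired
propagation entirely.  The series-resistance form agrees with the strict
linearisation to first order in alpha, stays finite at strong coupling, and
yields the expected phenomenology, all of which the test suite asserts:

- a synchronous identical pair propagates slower than a single AP
  (4.61 vs 6.11 m/s at standard parameters),
- a passive neighbour is first hyperpolarised (~-3.7 mV), then weakly
  depolarised (~+2.4 mV),
- an initial offset of 0.02 ms between paired APs contracts (to ~0.017 ms
  after one internode) and the synchronous state is a fixed point,
- the velocity gap grows monotonically with alpha.

The current division (beta) uses the uncoupled cable's longitudinal
resistance for every mode: the division happens at the physical node before
the mode transformation.  Mode spacing applies each mode's own electrotonic
correction `L + l lam_tilde/lam_n`.  For n > 2 axons the mode operator
`M_nm = lam_n^-2 (delta_nm + alpha R_ax,m^-1)` is diagonalised numerically;
its eigenvalues reproduce the two-axon closed form exactly.

Entrainment is computed self-consistently: both axons carry incoming APs
with the synchronous-pair period and a relative offset; the
threshold-crossing times of the next node in each axon are solved jointly
(the earlier axon's freshly fired node feeds into the later axon's
depolarisation, iterated to a fixed point).

## Sweeps and the g-ratio fit

`fit_gratio_exponent` computes v(g) at fixed axon diameter (d and L held,
lam rescaling as d sqrt(ln(1/g))) on 26 g values in [0.5, 0.9] by default
and fits `v = kappa (ln(1/g))^alpha` by Levenberg-Marquardt least squares
with deterministic initialisation (alpha = 0.5, kappa from the smallest-g
endpoint); `fixed_half` pins alpha = 0.5 for comparison with the classical
scaling.  For the fitted parameter set the exponent comes out at 0.66
(node-corrected) / 0.67 (raw), and it increases monotonically with L/l
(0.17 at L/l = 2 up to 0.75 at L/l = 150), vanishing toward the
unmyelinated limit.

The node/internode velocity surface (l in [0.5, 3.5] um x L in [27, 152] um)
is computed at N = 1000.  Its maximum sits at the smallest node and
internode lengths and the velocity rises steadily when both shrink
together; however the full surface spans 47% of its maximum for the
standard set (64% for the fitted set), considerably more variation than the
">= 70% of maximum everywhere" sometimes claimed for this model — the slow
extremes are the corners (l = 0.5, L = 152) and (l = 3.5, L = 27).  We
found no parameter convention (raw vs corrected velocity, threshold value,
nodal length-constant variant, spacing convention) under which the surface
flattens to 70%, and report the property as not reproduced.

## Parameter sets

Two packaged sets: **standard** (everything derived from first-principles
constants: k1 = 3.6 pF/cm, k2 = 130 MOhm cm, rho_ax = 110 Ohm cm,
R_n = 33 Ohm cm^2, C_n = 1 uF/cm^2, i_Na = 50 pA/um^2, whence tau = 0.47 ms,
lam = 965 d sqrt(ln(1/g)) um, tau_n = 33 us) and **fitted** (a calibration
against a detailed biophysical model: tau = 1.45 ms,
lam = 1200 d sqrt(ln(1/g)) um, lam_n = 48.1 sqrt(d) um, tau_n = 20 us,
tau_m = 70 us, tau_h = 160 us, I0 = 200 pA/um^2, V_thr = 4 mV, d = 0.73 um,
g = 0.81; quantities without fitted values keep their standard derivations).
The tabulated nodal length constant lam_n = 38.9 sqrt(d) um differs from the
first-principles value sqrt(R_n d/(4 rho_ax)) ≈ 27.4 sqrt(d) um by ~sqrt(2);
the tabulated value is the default and the derivation is available behind a
flag (`nodal_length_constant(..., derived=True)`).  The two tabulated
potassium-related "tau_n" entries (33 us nodal membrane constant; 150 us K
activation) are stored as distinct fields (`tau_node` vs `tau_nK`) and never
aliased.  Scenario C's decay constant defaults to tau_c = 100 us and
scenario B's amplitude to the scenario-A calibration I0 = 6.6 pA/um^2.

## Problem sizes

Default computations use N = 1000 contributing nodes per side; the velocity
surface tests use 5 x 5 grids and the g-ratio fit 26 (acceptance) or 8
(auxiliary sweeps) g values; the entrainment and passive-trace computations
use N = 300, where contributions are converged to well below the asserted
effect sizes.  The full test suite runs in under a minute on one CPU; the
acceptance script in a few seconds.

## Limitations

- Ion currents are threshold-triggered templates: no voltage-dependent
  gating, refractory dynamics, or channel noise; time constants are fixed
  through the AP.
- The axon is strictly periodic (constant d, g, L, l); aperiodic or
  partially demyelinated fibres would need per-node threshold times.
- The ephaptic model assumes distance-independent coupling within the
  bundle and identical fibres for the shipped experiments (the general
  two-fibre and n-fibre formulas are implemented and unit-tested at the
  transform level only).
- All results here are properties of the closed-form model evaluated at the
  packaged parameter sets; nothing is fit to experimental recordings, so
  agreement with the quantitative anchors shows internal reproduction, not
  validation against new data.
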