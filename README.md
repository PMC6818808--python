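# sdspike

Analytic modelling of action-potential propagation along myelinated axons
with a **spike-diffuse-spike (SDS)** model: the myelinated internodes are
passive leaky cables, and the nodes of Ranvier release prescribed,
threshold-triggered ion-channel currents.  Because the cable equation is
linear, the membrane potential is a closed-form superposition of single-node
responses, and the conduction velocity follows from a one-dimensional root
find instead of a spatial PDE simulation.  The package is for computational
neuroscientists who need fast, interpretable velocity estimates as a function
of axon microstructure (diameter, g-ratio, node and internode length) — for
example to map MRI-derived axon geometry onto conduction delays — and for
studying ephaptic interactions between neighbouring fibres.

## Model

Sub-threshold, the trans-membrane potential obeys the cable equation

    tau dV/dt = lam^2 d^2V/dx^2 - V + R_m I_chan(t),

with tau = C_m R_m and lam = sqrt(R_m/R_c) set by the myelin sheath
(tau = 0.47 ms, lam ≈ 689 um for a 1 um axon with g = 0.6).  A node that
reaches the firing threshold V_thr releases a current with one of four
profiles: an instantaneous impulse (A), a delayed impulse (B), an
instantaneous-onset exponential (C), or a gated profile
(1 - e^(-t/tau_m))^gamma e^(-t/tau_h) matching measured sodium currents (D),
optionally with a slower potassium counter-current.  The depolarisation a
single node produces at distance x is the convolution of its cable-bound
current (fraction beta of the channel current) with the cable Green's
function; for exponential currents it evaluates to a complex-error-function
expression computed stably via the Faddeeva function.

Saltatory conduction is periodic: node n fires t_sp after node n-1, where
t_sp solves

    V_thr = sum_{n=1..N} U(n (L + l lam/lam_n), n t_sp),

and the velocity is v = (L + l)/t_sp, corrected for the finite transit speed
across the nodes themselves.  Paired fibres sharing restricted extracellular
space are handled by decoupling the coupled cable equations into sum and
difference modes with modified length constants.

## Worked example

Velocity of a 1 um axon (g = 0.6, L = 100 um, l = 1 um) with the gated
sodium current and standard parameters:

    $ sds velocity --set standard --scenario D --d 1.0
    {
      "t_sp_ms": 0.016220641263632006,
      "v_mps": 6.107901518541905,
      "v_internode_mps": 6.226634222313405,
      "v_node_mps": 2.1012082363683233,
      ...
    }

Each node reaches threshold 16.2 us after its neighbour, giving 6.23 m/s
across the 101 um node-to-node span; accounting for the slower (2.1 m/s)
transit across the 1 um node itself corrects this to 6.11 m/s, inside the
experimentally observed range for fibres of this calibre.  How strongly the
velocity depends on myelin thickness:

    $ sds fit-g --set fitted --scenario D
    {
      "kappa": 6.968195241783155,
      "alpha": 0.6620256686498134,
      ...
    }

The fitted exponent alpha ≈ 0.66 of v = kappa (ln(1/g))^alpha exceeds the
classical value 0.5, i.e. conduction speed is more sensitive to the g-ratio
than the textbook scaling suggests.

Other entry points: `sds sweep` (long-format CSV velocity surfaces),
`sds profile` (voltage traces), `sds ephaptic` (paired-fibre traces and
entrainment), `sds run` (flat key=value config files with a JSON provenance
sidecar).  Everything is importable from Python (`sdspike.velocity`,
`sdspike.fit_gratio_exponent`, ...).

## Layout

- `src/sdspike/params.py` — unit system, first-principles parameter
  derivations, the packaged standard/fitted parameter sets, config I/O
- `src/sdspike/currents.py` — the four channel-current scenarios and their
  exponential expansions
- `src/sdspike/cable_response.py` — Green's function and closed-form
  single-node responses
- `src/sdspike/propagation.py` — superposition, threshold solver,
  myelinated/unmyelinated velocities
- `src/sdspike/linearize.py` — explicit inflection-point approximations of
  the time-to-spike
- `src/sdspike/ephaptic.py` — paired-fibre coupling, entrainment, passive
  neighbour responses
- `src/sdspike/sweeps.py`, `src/sdspike/cli.py` — parameter sweeps, the
  power-law fit, and the `sds` command-line tool

See `docs/methods.md` for the modelling assumptions, numerical conventions
and known limitations.
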