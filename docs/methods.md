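# Methods

This note records the model equations as implemented, the numerical choices,
what the built-in test networks emulate, and the known limitations.

## Membrane and channel model

Point compartments only — no cable morphology, no temperature dependence.
The membrane balance per compartment is

    Cm dV/dt = I_app − ΣI(vd) − ΣI(es) − ΣI(cs) − I(noise)

with the closed unit system µF / µS / mV / s / nA / mM, in which every
product above lands in nA without conversion factors.

Channel currents are `ḡ·Aᵖ·Bᑫ·(V−E)·f[reg]` with `q ∈ {0,1}` and `p ≥ q`.
Gates follow first-order kinetics `dA/dt = (A∞(V) − A)/τ(V)` with the
logistic steady state `A∞ = 1/(1+exp((h−V)/s))`; a negative slope factor
gives a falling (inactivation-type) gate. The voltage-dependent time
constant, where used, is itself a logistic,
`τ(V) = τ_base + τ_amp/(1+exp((h_τ−V)/s_τ))`, constrained positive. These
closed forms, like the pool and plasticity equations below, are the
standard conductance-based-family choices; they are stated here explicitly
because they are what the package computes and tests.

## Ion pools and regulation

A pool integrates the summed current of its designated source channels:

    dc/dt = k1·(−k2·I_src − c)

Sign convention: inward (negative) current accumulates concentration, so a
steady inward current yields the steady state `c* = −k2·I_src ≥ 0` and the
pool decays at rate `k1` when the source is silent. `k2` is taken in mM/nA —
the numerically closed choice for this unit system (1 mM/nA = 10⁶ M/A; a
workbook migrated from a source quoting M/A must rescale accordingly).

Regulation multiplies a maximal conductance (or is read by a facilitating
synapse) through one of two saturating forms:

* `saturating_activation`: `f = γc/(1+γc)` — 0 at rest, → 1; used for
  Ca-activated K conductances.
* `inhibition`: `f = 1/(1+γc)` — 1 at rest, → 0; used for negative feedback
  of Ca channels by their own pool.

Both are monotone, bounded, and equal ½ at `γc = 1`.

## Synapses

Electrical: `I(es) = ḡ(Vi−Vj)` into cell i, antisymmetric by construction;
a rectifying junction passes current only when `Vi > Vj`. Intra-neuron
compartment coupling uses the same mechanism.

Chemical: `I(cs) = ḡ·M1(t)·M2(t,V_post)·(V_post−E)`. `M1 = Y(t)·X(t)`:

* `Y` is the dual-exponential response (rise τ_r, decay τ_d, τ_d > τ_r)
  accumulated over presynaptic events, normalised so a single event peaks
  at exactly 1 at `t* = τ_r τ_d/(τ_d−τ_r)·ln(τ_d/τ_r)` — so the workbook
  weight `w` is interpretable as a peak conductance in µS. Events are
  upward crossings of the presynaptic threshold (0 mV default), with a 2 ms
  merge window so one spike produces one event.
* `X = (1 + γ_f·c_pre)·d` combines facilitation — gain driven directly by a
  presynaptic ion pool — and depression, a resource variable consumed per
  spike (`d ← d(1−u)`) and recovering between spikes
  (`dd/dt = (1−d)/τ_rec`). Under a periodic train at interval Δ the
  pre-spike resource converges to
  `d* = (1−e^(−Δ/τ_rec))/(1−(1−u)e^(−Δ/τ_rec))`, the oracle used in tests.
* `M2` relaxes first order (τ_m2) toward a logistic of the postsynaptic
  potential, like a channel activation; absent voltage dependence, M2 ≡ 1.

A design choice worth flagging: `X` multiplies `Y` continuously at
evaluation time (not baked into the event increments), so the facilitation
gain read during a PSP follows the instantaneous pool concentration. With
pool and recovery time constants well above the PSP time scale the two
conventions differ negligibly; the continuous product keeps the kernel
accumulators linear, which is what makes their event-driven update exact.

## Balanced background noise

Each noise target owns two independent Poisson-driven conductances
(`dg/dt = −g/τ + w·Σδ(t−Tj)`), inhibitory (E_i = −90 mV) and excitatory
(E_e = +60 mV), each with its own deterministic substream spawned from the
master seed. The user sets w_i; w_e is derived from the mean-current
balance at the resting potential,

    w_e = w_i·|λ_i τ_i (E_i−V_r)| / (λ_e τ_e |E_e−V_r|),

using Campbell's theorem (mean conductance of Poisson shot noise is wλτ).
V_r is the compartment potential after relaxation with noise weights zero,
re-resolved per run. On a passive cell at the reference scale
(λ = 50 Hz, w_i = 10⁻⁵ µS, τ = 25 ms) the measured voltage bias — Gaussian
fit mean of the voltage histogram minus the noiseless rest — is of order
0.1 µV, and grows roughly quadratically with the weights; the acceptance
tests check the sub-µV scale and the monotone growth. The Gaussian fit uses
least squares on a Freedman–Diaconis histogram; both the fit mean and raw
mean are available.

## Integration

* **Forward Euler** (first order) and a **Crank–Nicolson-style
  semi-implicit** step (trapezoidal on the smooth variables, solved by
  fixed-point iteration to 10⁻¹⁰ within 50 iterations; second order on
  smooth problems, first order across input discontinuities — on the
  scalar linear test its one-step multiplier is exactly
  (1−kΔt/2)/(1+kΔt/2)).
* **Adaptive**: scipy `solve_ivp` with LSODA (stiff-capable, embedded error
  control), integrated piecewise between stimulus edges and noise-event
  times; presynaptic threshold crossings are terminal event functions whose
  roots the solver localises, after which the synaptic jumps are applied
  and integration resumes (a 2 ms blanked span absorbs the merge window).
  The contract is tolerance-governed accuracy, not solver identity: at
  abstol 10⁻⁶ the leaky-pulse run lands at RMSE ≈ 1.6·10⁻⁶ mV.

The event-driven variables (kernel accumulators, depression resource, noise
conductances) are linear between events, so they are advanced by exact
exponential decay plus jumps at step boundaries in every method — the
event-driven synaptic time course therefore equals the kernel convolution
of the event train to round-off, which is asserted against a brute-force
convolution oracle. Bounded states are clamped to their ranges after each
step; with the fixture step sizes the clamp never trims more than round-off.

Discrete events at fixed step: crossings are detected by sign change over
the step, the event time linearly interpolated, and the state jumps applied
at the following step boundary.

**Relaxation**: before recording, the network integrates with stimuli and
noise disabled until `max|dV/dt| < 10⁻³ mV/s` (configurable) or the cap
(default 1 s, at most 10 s) is reached; hitting the cap logs a warning —
tonically active networks never settle, by design. Recording restarts at
t = 0. Noise is disabled during relaxation because the settling criterion
is unattainable under stochastic drive.

## Test networks and what they show

All test inputs are generated programmatically (`cpgsim.fixtures`); channel
kinetics are frozen constants chosen for robust spiking (membrane τ 100 ms,
Na activation τ 0.2 ms, spike threshold ≈ −40 mV), not a fit to any
biological cell. The fixtures demonstrate mechanisms — analytic agreement
(leaky cell), spike-rate attenuation (Ca pool → K(Ca)), gap-junction
coupling, facilitation/depression, voltage-dependent PSPs, half-centre
alternation — under clean, deterministic conditions. Passing tests show the
equations and numerics are implemented correctly; they do not show that any
particular biological parameterisation is reproduced, and real recordings'
variability (channel noise, slow drift, nonstationary rhythms) is outside
what the generator emulates.

Problem sizes used by the suite: the attenuation protocol is the full
2 nA × 5 s pulse; plasticity and voltage-dependence protocols run 1.6–2.4 s;
the noise-balance run is 500 s at Δt = 1 ms with the bias-monotonicity
comparison over 10 paired seeds × 60 s; sweep machinery is exercised on
mock backends (including a 60×60 mesh) so the exhaustive oracle stays
cheap.

## Numerical details and edge cases

* Fixed-step runs use Δt = 2–2.5·10⁻⁵ s for spiking fixtures (an order
  below the fastest gate τ) and 10⁻³ s for passive noise runs.
* PSP amplitudes are measured per presynaptic event against the event's own
  pre-event baseline where the sequence must track a plasticity variable;
  envelope-from-rest is used where summation is part of the qualitative
  picture (slow postsynaptic membranes).
* Holding potentials are realised by a holding current solved by root
  bracketing on the settled potential (tolerance 10⁻⁶ mV), mirroring how a
  current-clamp experiment adjusts its bias current.
* Grid-search cells get deterministic per-cell seeds (`seed + flat index`);
  failed cells record a +∞ sentinel and the sweep continues; ties resolve
  to the lowest index pair; parallel and serial execution are bitwise
  identical.
* The sweep addresses parameters by workbook coordinate (Sheet:row:column),
  so any numeric cell is sweepable.

## Limitations

* No cable/morphological modeling, temperature dependence, or
  neuromodulator cascades beyond single-pool regulation.
* The depression map acts per synapse, not per presynaptic terminal pool
  shared across synapses.
* The adaptive path assumes events are isolated at the solver's root
  tolerance; pathological chatter exactly at threshold is absorbed by the
  2 ms merge window rather than resolved.
* Phase duration is defined first-to-last spike of a burst; onset-to-onset
  conventions would differ by the interburst interval.
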