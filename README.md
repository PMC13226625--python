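# cpgsim

Spreadsheet-driven simulation of conductance-based neural networks with
complex plastic synapses, and parameter sweeps that fit motor-pattern phase
durations.

`cpgsim` is aimed at modelers of small, biophysically detailed circuits —
central pattern generators (CPGs) of the kind that drive rhythmic motor
behaviors — who want to describe an entire network (channels, ion pools,
second-messenger regulation, electrical and chemical synapses, background
noise, stimuli) in a workbook of tables, simulate it reproducibly, and search
parameter space for combinations that match measured behavior.

## Model

Each neuron is one or more point compartments obeying

```
Cm dVi/dt = Ii(app) − Σj Iij(vd) − Σk Iik(es) − Σl Iil(cs) − Ii(noise)
```

* **Voltage-dependent channels** `I(vd) = ḡ·Aᵖ·Bᑫ·(V−E)·f[reg]` with sigmoid
  steady-state gates `A∞ = 1/(1+exp((h−V)/s))` relaxing first order with a
  constant or voltage-dependent time constant (`q ∈ {0,1}`, `p ≥ q`).
* **Ion pools** `dc/dt = k1·(−k2·I_src − c)`: inward current through the
  designated source channels accumulates a second-messenger concentration
  that regulates conductances multiplicatively, either saturating
  (`f = γc/(1+γc)`) or inhibitory (`f = 1/(1+γc)`).
* **Electrical synapses** `I(es) = ḡ·(Vi−Vj)`, optionally rectifying.
* **Chemical synapses** `I(cs) = ḡ·M1(t)·M2(t,V)·(V−E)`: a peak-normalised
  dual-exponential response accumulated over presynaptic threshold crossings
  (trigger at 0 mV by default), multiplied by a plasticity gain
  `X = (1 + γf·c_pre)·d` — facilitation through a presynaptic ion pool and
  depression through a resource variable (`d ← d·(1−u)` per spike,
  `dd/dt = (1−d)/τ_rec`) — and by a voltage-dependence factor `M2` gated by
  the postsynaptic potential like a channel activation.
* **Balanced background noise**: each target receives independent inhibitory
  and excitatory Poisson-driven conductances
  `dg/dt = −g/τ + w·Σδ(t−Tj)`; the excitatory weight is derived from the
  inhibitory one so that the mean driving currents cancel at the resting
  potential, `w_e·λ_e·τ_e·(E_e−V_r) + w_i·λ_i·τ_i·(E_i−V_r) = 0`.

Units form a closed system: capacitance µF, conductance µS, voltage mV,
current nA, time s, concentration mM.

Three integrators advance the system: fixed-step Forward Euler, a
Crank–Nicolson-style semi-implicit step, and adaptive stiff-capable
integration (scipy LSODA) with event localisation for synaptic triggers.
Every run starts with a relaxation period (stimuli and noise disabled) that
integrates until `dV/dt → 0` before recording begins at t = 0.

The analysis layer extracts bursts from spike trains, computes
protraction/retraction phase durations (first motor pattern excluded), and
drives an exhaustive two-parameter grid search minimising the squared
difference from target phase durations.

## Worked example

The `spiker_capool` fixture is a spiking cell whose N-type Ca channel feeds a
Ca pool that both activates a K(Ca) conductance and feeds back onto the Ca
channel, producing spike-rate attenuation:

```python
import numpy as np
from cpgsim import make_fixture, run_simulation, detect_spikes

prob = make_fixture("spiker_capool")          # 2 nA pulse, 0.5–5.5 s
traces, report = run_simulation(prob.spec)
t = traces.time
spikes = detect_spikes(t, traces.data[("B", "V")]).times
ca = traces.data[("B", "c_Ca")]
early = np.sum((spikes >= 0.5) & (spikes < 1.5))
late = np.sum((spikes >= 4.5) & (spikes < 5.5))
print(f"{len(spikes)} spikes during the 2 nA pulse")
print(f"firing rate: {early} Hz (first second) -> {late} Hz (last second)")
print(f"[Ca] plateau: {ca[t > 5.0].mean():.3f} mM")
print(f"integrator: {report.method}, {report.steps} steps, "
      f"relaxation {report.relax_duration:.2f} s")
```

prints

```
51 spikes during the 2 nA pulse
firing rate: 12 Hz (first second) -> 10 Hz (last second)
[Ca] plateau: 0.257 mM
integrator: adaptive, 16536 steps, relaxation 0.80 s
```

The firing rate falls as the Ca pool charges toward its plateau and the
K(Ca) conductance strengthens — the attenuation mechanism in action.

## Command line

```sh
cpgsim fixtures --id leaky --out nets/          # emit a fixture workbook
cpgsim build --file nets/leaky.xlsx             # validate and report
cpgsim run --file nets/leaky.xlsx --name demo --duration 12 --out out/
cpgsim sweep --file net.xlsx \
    --param Channels:5:gbar --range 0.5,1.8,60 \
    --param ChemicalSynapses:3:w --range 1.3,4.0,60 \
    --target-durations 4.2,6.1 --cells B31,B64 --out sweep/
```

`run` writes a TSV trace table (first column time in s, one column per
recorded quantity, full double precision) plus a JSON manifest with the spec
hash, seed, method, and relaxation duration. `sweep` writes the duration and
objective matrices as TSV plus an argmin manifest.

### Workbook schema

One sheet per entity kind: `Neurons` (neuron, compartment, Cm, V_init),
`Channels` (gbar, E, p, q, gate columns `act_*`/`inact_*`, regulation and
`feeds_pool` columns), `Pools` (k1, k2, c_init), `ElectricalSynapses`,
`ChemicalSynapses` (w, E, tau_rise, tau_decay, threshold, `fac_*`, `dep_*`,
`vd_*`), `Noise` (optional; rate or interval per kind, w_i, taus,
reversals, seed), `Stimuli`, `Simulation`. Unknown sheets are ignored with
a warning; unknown columns inside known sheets are errors. Saving and
re-loading a network reproduces it field for field (neurons ordered
alphabetically, everything else in declaration order).

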