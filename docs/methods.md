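# Methods

This package studies how a small biophysical network carrying a beta1
(~15 Hz) rhythm responds to pulsatile drives at unrelated, faster
frequencies. It contains three layers: a conductance-based simulator
for the four-cell network and its reductions, an abstract discrete
"pulse-gating" model with analytic entrainment guarantees, and an
event-time analysis layer (rates, phase statistics, mode-locking
detection, interburst maps, state-reset diagnostics).

## The membrane model

Every cell/compartment is a point unit obeying

    C dV/dt = -J - I_syn - I_el - I_ext
              - g_L (V - E_L)
              - g_Na m0(V)^3 h (V - E_Na)
              - g_K m^4 (V - E_K)
              - g_AR m_AR (V - E_AR)
              - g_KM m_KM (V - E_KM)
              - g_CaH m_CaH^2 (V - E_CaH)

with first-order gating dx/dt = (x_inf(V) - x)/tau_x(V) (Traub-lineage
kinetics, see `kinetics.py`; sodium activation is instantaneous).  J is
a constant background term (negative = depolarising).  Chemical
synapses are single state variables

    ds/dt = -s/tau_d + (1 - s)/tau_r (1 + tanh(V_pre / 10)),

contributing s·g·(V - V0) to the target; electrical couplings
contribute g·(V - V').  External drives are pulse trains shaped into a
potential V_ext that resets to 25 mV at each pulse and decays to
-70 mV with a 1 ms time constant; drive synapses read V_ext exactly as
they would a presynaptic membrane potential.  The delta-function drive
term is interpreted as an exact reset (V_ext jumps to 25 mV regardless
of its prior value), which makes the trace independent of integration
order.

Cells: regular-spiking (RS, with h-current), fast-spiking (FS, standard
currents only, inhibitory autapse), slow-inhibitory (SI, h-current and
inhibitory autapse), and a four-compartment intrinsically-bursting cell
(IB: soma, axon with M-current, two dendrites with h-, M- and
high-threshold Ca-currents, joined by electrical coupling, plus a slow
axon-to-basal-dendrite synapse).

## Parameter provenance

The original constants were published in an appendix that is not
available to this implementation.  The shipped parameter file
(`configs/parietal_beta1.yaml`) is therefore a *reconstruction*: the
functional forms and cell compositions follow the published parent
model, and the constants were calibrated until the network reproduces
the documented behaviours —

* the free-running four-cell network oscillates in the beta1 band with
  RS and SI in phase, the IB cell in anti-phase, and FS faster;
* the SI cell in the two-input reduction fires in phase with a 40 Hz
  drive, once per slow-drive period, inside a ~25 ms-wide window of
  slow-drive phase starting at c ≈ 16 ms, with a two-fast-cycle
  refractory period (m = 2);
* the FS-SI-IB network at a 40 Hz drive 3:7 mode-locks (mean burst
  rate ≈ 17.15 Hz) with strict SI/IB alternation, interburst intervals
  in the mid-50s to low-60s of ms and 2–4 spikes per burst.

This calibration reproduces the mechanism claims; figure-level details
shift by a few percent (for example the 2:7-without-phase-locking
plateau sits near 60 Hz rather than 62.1 Hz, and the free beta1 rhythm
runs at ~16.5 Hz rather than ~15 Hz).  The background drives `J` encode
the operating points: excitable cells rest a few mV below threshold
(FS -67, SI -62 mV), while the IB dendrites are given enough drive that
they have *no* subthreshold rest once their M-current has decayed — the
resulting slow drift is what paces bursting, and the M-current load
deposited by each burst (one increment per axonal spike) sets the
interburst interval.  The dendritic h-current collapses during spikes
(its time constant drops below 1 ms and its equilibrium to ~0 at spike
voltages), which is the state reset examined in the diagnostics.

A constraint worth noting: the slow/fast classification (a variable is
"slow" if its time constant exceeds 10 ms throughout V ∈ [-75, -40] mV)
must yield exactly seven slow variables for the IB cell — the two
dendritic h-gates, three M-gates, and the two slow synapses.  This
pins the dendritic h-current tau scale from below (0.10 of the base
kinetics).

The SI cell's inability to fire on consecutive fast-drive pulses is
carried jointly by its post-spike h-current collapse and an inhibitory
autapse.  The multiplexing description states the autapse explicitly
and identifies its SI cells with those of the earlier reductions, so
the autapse is present in every configuration here.  In the
configurations where the FS cell is removed (`si_only`, `multiplex3`)
the autapse is stronger and slower, standing in for the per-pulse FS
inhibition that is otherwise present.

## Integration

Classical fixed-step RK4 (default dt = 0.02 ms), compiled with numba,
segmented at drive pulse times so the V_ext reset is applied exactly.
Spikes are detected on the fly as upward crossings of 0 mV with linear
interpolation and a 1.5 ms guard.  Dimensionless states are clamped to
[0, 1] against round-off overshoot.  |V| > 200 mV raises an
integration fault carrying the failure time.  Runs are bit-for-bit
reproducible for identical inputs; halving dt moves spike times by
< 0.01 ms in the tested configurations (the suite asserts < 0.1 ms).
A pure-Python term-by-term implementation of the full right-hand side
(`simulate.reference_rhs`) serves as the oracle for the compiled
kernel; the two agree to machine precision.

Initial conditions (not specified by the source): V = -70 mV
everywhere, gating at its -70 mV equilibrium, synapses at 0.  All
statistics discard an initial transient of
max(1000 ms, K × mean slow period), with K from the transient bound
below when defined, else K = 3.

## The abstract pulse-gating model

Input-1 pulses arrive every T1 ms; input-2 pulses at increasing times
t_n.  The cell fires at an input-1 pulse iff at least m input-1 periods
have passed since its last firing and the time since the last input-2
pulse (its *phase*) is at least c.  Phase ties are closed at c (fire
when phase = c) and a coincident input-2 pulse gives phase 0.

Under the gap condition inf(t_{n+1}-t_n) > max(m T1, c+T1) and
sup(t_{n+1}-t_n) ≤ m T1 + c, the model fires exactly once per input-2
period; after at most

    K = ceil[(sup_gap - (c + T1)) / (inf_gap - m T1)] + 1

periods every firing phase lies in [c, c+T1), and a pulse past the
transient fires iff its phase is in that window.  `verify_theorem41`
checks all three statements on any simulated record; the test suite
does so for 1000 random admissible jittered sequences.  In frequency
terms the admissible input-2 band is
[f1/(f1 c + m), min(f1/m, f1/(f1 c + 1))) with c in seconds.  For
m = 1 (no refractory gating) and periodic input-2 the long-run rate is
(1/T1)(1 - c/T2), within 1/(q T1) when T1/T2 = p/q is rational.

The simulator steps directly from firing to firing (integer arithmetic
on the pulse grid); a literal per-pulse brute-force scan in the test
suite is its oracle, and the two are output-identical on all tested
inputs.

The parameters m and c are not primitives of the conductance-based
model; `estimate_m_c` recovers them from event data as, respectively,
the minimum number of input-1 intervals between firings and the length
of the zero-firing prefix of the input-2 phase histogram (1 ms bins).

One printed formula conflicts with its derivation upstream: the
fixed-point map is stated once as f(x) = x - T_SI - T_IB(x), which is
inconsistent with the iteration phi' = phi + T_SI - T_IB(phi) from
which it is derived.  `phase_map_iterate` follows the iteration form;
with 0 < dT_IB/dphi < 1 the error contracts by (1 - dT_IB/dphi) per
cycle toward the phase solving T_IB(phi*) = T_SI.

## The integrate-and-fire reduction

A single LIF unit (rest 0, threshold 1) with a brief excitatory kick
per input-1 pulse, a conductance-based inhibitory autapse, and
conductance-based input-2 inhibition reproduces the gated firing
pattern.  The published constants for this demonstration are not
available; the defaults here are chosen by construction: a lone kick
from rest crosses threshold in < 1 ms, the autapse blocks a second kick
for between one and two input-1 periods, and input-2 inhibition blocks
kicks for ≈ 16 ms.  At 40 Hz / 16.357 Hz the unit fires at 16.357 Hz,
in phase with input-1, and its spike train passes the entrainment
checks through the fitted (m, c).

## Analysis conventions

Spike threshold 0 mV, 2 ms minimum separation (a -10 mV threshold finds
identical spikes on these traces; asserted).  Bursts are grouped with a
15 ms intra-burst gap; any gap in (10, 50) ms gives identical grouping
for the IB axon train (asserted).  "Immediately after a pulse" means
within 5 ms.  Histograms default to 1 ms bins.  Mode-locking p:q is
detected only if every full window of q input cycles (anchored at the
first post-transient pulse, at least 20 windows) contains exactly p
events; phase-locking is judged separately by the circular standard
deviation of event times modulo the input period, threshold 2 ms.
These thresholds separate the observed regimes cleanly: the 51 Hz
drive gives 1:3 locking with ~0.15 ms dispersion, the 60 Hz drive
gives exact 2:7 locking with ~5 ms dispersion.

## What the generators do and do not emulate

Pulse trains are exactly periodic or have i.i.d. normal interpulse
intervals (s.d. = sigma × mean, non-positive draws resampled; at the
5–10 % levels used the resampling probability is negligible).  There
are no rate-modulated or non-Gaussian jitter processes, no synaptic
failures, and single cells per type — a green test establishes the
mechanism under the stated drive statistics, not robustness to
arbitrary input structure or population heterogeneity.

## Known limitations

* All conductance constants are reconstructed, not transcribed;
  quantities tied to exact constants (plateau positions on the
  frequency axis, the free beta1 rate, absolute gating levels) carry
  a few-percent to ~10 % uncertainty.  Mechanism-level claims (ratios,
  alternation, windows, resets) are the reliable surface.
* The SI→IB synaptic state at burst onset spans ≈ [0.13, 0.34] here
  versus the reported [0.1, 0.2]; the reconstruction's SI cell fires at
  somewhat later interburst phases than the original, so some bursts
  follow an SI spike more closely.  The corresponding acceptance test
  is left failing rather than re-scoped.
* Exact p:q locking can slip over very long horizons (tens of seconds)
  at some drive frequencies; windows of ~8 s post-transient are used,
  matching the horizon at which the locking statements are made.
* The FS cell fires ~3 events per beta1 cycle in the free-running
  network (it responds to individual spikes of each IB burst) where
  the source reports double the principal rate.
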