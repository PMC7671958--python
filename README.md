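# pulsegate

Simulation and analysis toolkit for multi-rhythm interaction in a small
biophysical cortical network: a four-cell Hodgkin–Huxley model of the
parietal beta1 (~15 Hz) rhythm, its successive reductions, and the
abstract pulse-gating model that explains the central phenomenon — a
cell that fires *in phase* with a fast excitatory pulse train while its
*rate* is set by an independent, slower, effectively inhibitory one.

It is written for computational neuroscientists studying entrainment,
mode-locking and phase-response descriptions of bursting cells.

## The science in brief

A slow-inhibitory (SI) cell receives a fast drive (period `T1`, e.g.
gamma at 40 Hz) and a slow one (pulses at times `t_n`, e.g. beta1 at
16.357 Hz). Three properties of the cell suffice to pin its behaviour:
it fires only immediately after a fast pulse; it cannot fire on `m`
consecutive fast cycles (here `m = 2`, from its post-spike h-current
collapse and self-inhibition); and it cannot fire within `c` ms of a
slow pulse (feed-forward inhibition). If the slow interpulse gaps
satisfy

    max(m·T1, c + T1) < t_{n+1} − t_n ≤ m·T1 + c ,

then the cell fires **exactly once per slow period**; after at most
`K = ceil[(sup gap − (c+T1)) / (inf gap − m·T1)] + 1` periods every
firing falls at slow-input phase in `[c, c + T1)`, and a fast pulse
triggers a spike if and only if its phase lies in that window. In
frequency terms the admissible slow band is
`[f1/(f1·c + m), min(f1/m, f1/(f1·c + 1)))` (with `c` in seconds); for
`m = 1` the rate is instead `(1/T1)(1 − c/T2)`.

In the three-cell FS-SI-IB network the role of the slow input is played
by an intrinsically bursting (IB) cell. Its high-dimensional state is
approximately *reset* at each burst (the dendritic h-current collapses
to 0; the M-current steps up by a fixed amount per spike), so the next
interburst interval is nearly a function `T_IB(φ)` of the last SI spike
time alone — a phase-response-like map whose slope in `(0, 1)` yields
stable p:q mode-locking of the whole loop to the drive, including the
striking regime of exact mode-locking *without* phase-locking.

## Worked example

```python
import numpy as np
from pulsegate import (AbstractParams, simulate_abstract, verify_theorem41,
                       f2_range, build_network, simulate,
                       generate_pulse_times, group_bursts, mode_lock_ratio,
                       exclude_transient)

# abstract pulse-gating model at 40 Hz vs 16.357 Hz, c = 17 ms, m = 2
params = AbstractParams.periodic(T1=25.0, T2=61.14, c=17.0, m=2,
                                 n_periods=500)
record = simulate_abstract(params)
report = verify_theorem41(record)
print(f"firings per slow period: {record.period_counts.min()}-"
      f"{record.period_counts.max()}")
print(f"firing phases in [{record.phases[report.K:].min():.2f}, "
      f"{record.phases[report.K:].max():.2f}] ms")
print(f"entrainment guarantees (K={report.K}): "
      f"{'all pass' if report.all_pass else 'violated'}")
lo, hi = f2_range(40.0, m=2, c=0.016)
print(f"admissible slow-input band at 40 Hz: [{lo:.2f}, {hi:.2f}) Hz")

# conductance-based FS-SI-IB network driven at 60 Hz
spec = build_network("fs_si_ib")
train = generate_pulse_times(60.0, 0.0, 10_000.0)
res = simulate(spec, {"input1": train}, duration=10_000.0)
bursts = group_bursts(exclude_transient(res.spikes["IB_a"], 2000.0))
stats = mode_lock_ratio(bursts.onsets, train.times[train.times > 2000.0])
rate = 1000.0 * (len(bursts) - 1) / (bursts.onsets[-1] - bursts.onsets[0])
print(f"IB burst rate at 60 Hz drive: {rate:.2f} Hz, "
      f"locking {stats.ratio}, phase-locked: {stats.phase_locked}")
```

prints

```
firings per slow period: 1-1
firing phases in [17.08, 41.98] ms
entrainment guarantees (K=3): all pass
admissible slow-input band at 40 Hz: [15.15, 20.00) Hz
IB burst rate at 60 Hz drive: 17.14 Hz, locking (2, 7), phase-locked: False
```

The abstract cell fires exactly once per slow period inside a 25 ms
phase window starting at `c = 17` ms, as the theory guarantees. The
conductance-based loop, driven at 60 Hz, bursts exactly twice every
seven input cycles (17.14 Hz = 60·2/7) while its burst phases keep
drifting relative to the drive — mode-locking without phase-locking.

## Scenarios and CLI

Figure-level experiments are registered by name and runnable from the
shell:

```
pulsegate list                 # available scenarios
pulsegate run fig4 --seed 0 --out-dir results
pulsegate sweep fig6 --out-dir results
pulsegate report results
```

Each run writes event tables, statistics, a trace/sweep figure, and a
manifest (config hash, parameter-set version, seed) that makes the
bundle exactly regenerable.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the study's headline quantities from scratch — the
transient bound, the admissible frequency-band endpoints, the
sufficient interpulse bound, the abstract model's firing-window width
and long-run rate over 10,000 slow periods, and the mean IB bursting
rate of the FS-SI-IB network under a 40 Hz drive — and writes them to
the given JSON file.

## Layout

```
src/pulsegate/
  pulses.py       pulse trains and the external-potential trace
  kinetics.py     voltage-dependent gating kinetics
  network.py      compartments, synapses, topologies, shipped parameters
  simulate.py     compiled RK4 integrator + reference dynamics
  abstract.py     pulse-gating model, entrainment theory, frequency bands
  lif.py          integrate-and-fire reduction
  analysis.py     event-time statistics (rates, locking, maps, resets)
  experiments.py  scenario registry and runner
  cli.py          command-line front end
```

The shipped constants (`configs/parietal_beta1.yaml`) are a calibrated
reconstruction of the published parent model; see `docs/methods.md`
for provenance, conventions and limitations.
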