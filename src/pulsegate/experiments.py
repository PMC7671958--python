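"""Scenario registry and end-to-end experiment runner.

Each named scenario reproduces one figure-level experiment: a network
configuration (or the abstract model), its drives, the run length, and
the statistics taken from the result.  Scenarios are data; running them
is one code path.  Every run writes a manifest (config hash, parameter
set version, package version, seed, wall time per stage) so a result
bundle can be regenerated exactly.

Durations here are trimmed to tens of seconds of compute; they are long
enough for every statistic to stabilise past the transient.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import pulsegate
from pulsegate import abstract
from pulsegate import analysis as an
from pulsegate.network import build_network
from pulsegate.pulses import generate_pulse_times
from pulsegate.simulate import simulate

__all__ = ["ExperimentConfig", "SCENARIOS", "run_experiment", "run_sweep"]


# --------------------------------------------------------------------------
# registry — scenario id -> recipe (data, not code)

SCENARIOS: dict[str, dict] = {
    # beta1 oscillation of the full network, no input
    "fig2": dict(kind="hh", config="full4", drives={}, duration=6000.0),
    # full network driven at 40 Hz; SI locks 3:7, IB phase histogram
    "fig3": dict(kind="hh", config="full4",
                 drives={"input1": (40.0, 0.0)}, duration=10000.0),
    # reduced 3-cell network at 40 Hz
    "fig4": dict(kind="hh", config="fs_si_ib",
                 drives={"input1": (40.0, 0.0)}, duration=10000.0),
    # 2-cell network with two periodic inputs
    "fig5": dict(kind="hh", config="fs_si_2inputs",
                 drives={"input1": (40.0, 0.0), "input2": (16.357, 0.0)},
                 duration=8000.0),
    # SI rate vs input-2 frequency (sweep)
    "fig6": dict(kind="sweep", config="fs_si_2inputs", swept="input2",
                 grid=tuple(np.arange(13.0, 22.01, 0.5)),
                 fixed={"input1": 40.0}, duration=5000.0),
    # firing probability vs input-2 phase
    "fig7": dict(kind="hh", config="fs_si_2inputs",
                 drives={"input1": (40.0, 0.0), "input2": (16.357, 0.0)},
                 duration=12000.0),
    # jittered inputs (5 % interval s.d.)
    "fig8": dict(kind="hh", config="fs_si_2inputs",
                 drives={"input1": (40.0, 0.05), "input2": (16.357, 0.05)},
                 duration=12000.0),
    # single SI cell with excitatory and inhibitory inputs
    "fig9": dict(kind="hh", config="si_only",
                 drives={"input1": (40.0, 0.0), "input2": (16.357, 0.0)},
                 duration=8000.0),
    # abstract pulse-gating model, periodic inputs
    "fig10": dict(kind="abstract", T1=25.0, T2=61.14, c=17.0, m=2,
                  n_periods=2000),
    # m = 1 regime (doubled input-1 strength), rate vs input-1 frequency
    "fig13": dict(kind="sweep", config="fs_si_2inputs", swept="input1",
                  grid=tuple(np.arange(30.0, 55.01, 2.5)),
                  fixed={"input2": 16.357}, variants=("strong_input1",),
                  duration=5000.0),
    # FS-SI-IB statistics (interburst histogram, SI phase histogram)
    "fig14": dict(kind="hh", config="fs_si_ib",
                  drives={"input1": (40.0, 0.0)}, duration=10000.0),
    # input frequency / IB rate ratio staircase
    "fig15a": dict(kind="sweep", config="fs_si_ib", swept="input1",
                   grid=tuple(np.arange(40.0, 64.01, 2.0)),
                   fixed={}, duration=8000.0, measure="IB"),
    # 42.5 Hz: mode-locked orbit over five input periods
    "fig15b": dict(kind="hh", config="fs_si_ib",
                   drives={"input1": (42.5, 0.0)}, duration=10000.0),
    # 51 Hz: single-branch interburst map
    "fig16b": dict(kind="hh", config="fs_si_ib",
                   drives={"input1": (51.0, 0.0)}, duration=10000.0),
    # 62 Hz with faster h-current kinetics: multi-branch map
    "fig16c": dict(kind="hh", config="fs_si_ib", variants=("fast_h",),
                   drives={"input1": (62.0, 0.0)}, duration=10000.0),
    # mode-locking without phase-locking
    "fig17": dict(kind="hh", config="fs_si_ib",
                  drives={"input1": (59.0, 0.0)}, duration=10000.0),
    # slow-variable reset diagnostics
    "fig19": dict(kind="hh", config="fs_si_ib",
                  drives={"input1": (40.0, 0.0)}, duration=10000.0),
    # time-division multiplexing demonstration
    "fig24": dict(kind="multiplex", f1=70.0, sigma1=0.10, f2=22.0,
                  duration=6000.0),
}


@dataclass
class ExperimentConfig:
    scenario: str
    seed: int = 0
    out_dir: str | None = None
    duration: float | None = None
    dt: float = 0.02
    overrides: dict = field(default_factory=dict)

    def recipe(self) -> dict:
        if self.scenario not in SCENARIOS:
            raise KeyError(f"unknown scenario {self.scenario!r}; known: "
                           f"{sorted(SCENARIOS)}")
        rec = dict(SCENARIOS[self.scenario])
        rec.update(self.overrides)
        if self.duration is not None:
            rec["duration"] = self.duration
        return rec

    def config_hash(self) -> str:
        blob = json.dumps({"recipe": self.recipe(), "seed": self.seed,
                           "dt": self.dt}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------


def _make_drives(drive_spec: dict, duration: float, seed: int) -> dict:
    out = {}
    for i, (name, (f, sigma)) in enumerate(sorted(drive_spec.items())):
        out[name] = generate_pulse_times(f, sigma, duration,
                                         seed=seed + 31 * i)
    return out


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one scenario end to end; returns the result bundle.

    The bundle holds events, statistics and the manifest; when
    ``config.out_dir`` is set, events and statistics are also written as
    delimited text with a JSON manifest.
    """
    rec = config.recipe()
    stages = {}
    t_start = time.perf_counter()
    bundle: dict = {"scenario": config.scenario}

    if rec["kind"] == "abstract":
        p = abstract.AbstractParams.periodic(rec["T1"], rec["T2"], rec["c"],
                                             rec["m"], rec["n_periods"])
        record = abstract.simulate_abstract(p)
        report = abstract.verify_theorem41(record)
        stages["simulate"] = time.perf_counter() - t_start
        bundle.update(record=record, report=report,
                      rate_hz=record.rate(skip=report.K),
                      events={"firings": record.times})
    elif rec["kind"] == "sweep":
        return run_sweep(config)
    elif rec["kind"] == "multiplex":
        dur = rec["duration"]
        T2 = 1000.0 / rec["f2"]
        drives = {}
        for i in (1, 2, 3):
            drives[f"input1_{i}"] = generate_pulse_times(
                rec["f1"], rec["sigma1"], dur, seed=config.seed + i)
            drives[f"input2_{i}"] = generate_pulse_times(
                rec["f2"], 0.0, dur, offset=(i - 1) * T2 / 3)
        spec = build_network("multiplex3")
        res = simulate(spec, drives, dur, dt=config.dt, seed=config.seed)
        stages["simulate"] = time.perf_counter() - t_start
        cutoff = an.transient_cutoff(None, T2)
        events = {c: an.exclude_transient(res.spikes[c], cutoff)
                  for c in res.spikes}
        bundle.update(result=res, events=events, drives=drives)
    else:  # plain HH scenario
        dur = rec["duration"]
        spec = build_network(rec["config"], tuple(rec.get("variants", ())))
        drives = _make_drives(rec.get("drives", {}), dur, config.seed)
        res = simulate(spec, drives, dur, dt=config.dt, seed=config.seed)
        stages["simulate"] = time.perf_counter() - t_start
        t1 = time.perf_counter()
        periods = [1000.0 / f for f, _ in rec.get("drives", {}).values()]
        cutoff = an.transient_cutoff(None, max(periods) if periods else 0.0)
        events = {}
        for comp, spk in res.spikes.items():
            try:
                events[comp] = an.exclude_transient(spk, cutoff)
            except ValueError:
                events[comp] = np.array([])
        stats = {}
        span = (cutoff, dur)
        for comp, ev in events.items():
            stats[f"rate_{comp}"] = an.firing_rate(ev, span)
        if "IB_a" in events and len(events["IB_a"]):
            bursts = an.group_bursts(events["IB_a"])
            stats["ib_burst_rate"] = an.firing_rate(bursts.onsets, span)
            if len(bursts) > 3:
                stats["ibi_min"] = float(bursts.intervals.min())
                stats["ibi_max"] = float(bursts.intervals.max())
            bundle["ib_bursts"] = bursts
        stages["analyze"] = time.perf_counter() - t1
        bundle.update(result=res, events=events, drives=drives, stats=stats)

    bundle["manifest"] = {
        "scenario": config.scenario,
        "config_hash": config.config_hash(),
        "package_version": pulsegate.__version__,
        "params_version": 1,
        "seed": config.seed,
        "dt": config.dt,
        "stage_seconds": stages,
    }
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir) / config.scenario)
    return bundle


def run_sweep(config: ExperimentConfig) -> dict:
    """Run a frequency sweep scenario; returns table + manifest."""
    rec = config.recipe()
    if rec["kind"] != "sweep":
        raise ValueError(f"scenario {config.scenario!r} is not a sweep")
    t0 = time.perf_counter()
    table = an.rate_vs_frequency_sweep(
        rec["config"], rec["swept"], rec["grid"], rec.get("fixed"),
        duration=rec.get("duration", 5000.0),
        measure=rec.get("measure", "SI"),
        variants=tuple(rec.get("variants", ())), seed=config.seed)
    if rec.get("measure") == "IB":
        # staircase: convert the measured burst rate to input/rate ratio
        table["ratio"] = table["frequency"] / table["rate"]
    bundle = {
        "scenario": config.scenario,
        "table": table,
        "manifest": {
            "scenario": config.scenario,
            "config_hash": config.config_hash(),
            "package_version": pulsegate.__version__,
            "params_version": 1,
            "seed": config.seed,
            "stage_seconds": {"sweep": time.perf_counter() - t0},
        },
    }
    if config.out_dir:
        out = Path(config.out_dir) / config.scenario
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=2))
        _plot_sweep(table, out / "sweep.png")
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name, ev in bundle.get("events", {}).items():
        lines = "".join(f"{i}\t{t:.6f}\n" for i, t in enumerate(ev))
        (out / f"events_{name}.tsv").write_text(lines)
    if "stats" in bundle:
        (out / "stats.tsv").write_text(
            "".join(f"{k}\t{v}\n" for k, v in bundle["stats"].items()))
    if "report" in bundle:
        (out / "theorem_report.txt").write_text(bundle["report"].to_text())
    (out / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2))
    if "result" in bundle:
        _plot_traces(bundle["result"], out / "traces.png")


def _plot_traces(res, path: Path, t_max: float = 1000.0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(res.spec.compartments)
    sel = res.time <= t_max
    fig, axes = plt.subplots(len(comps), 1, sharex=True,
                             figsize=(8, 1.2 * len(comps)))
    axes = np.atleast_1d(axes)
    for ax, c in zip(axes, comps):
        ax.plot(res.time[sel], res.V(c)[sel], lw=0.5)
        ax.set_ylabel(c, fontsize=7)
    axes[-1].set_xlabel("time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_sweep(table, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ycol = "ratio" if "ratio" in table else "rate"
    ax.plot(table["frequency"], table[ycol], "o-", ms=3)
    if ycol == "rate":
        lim = [table["frequency"].min(), table["frequency"].max()]
        ax.plot(lim, lim, "--", color="gray", lw=0.8)
    ax.set_xlabel("swept frequency (Hz)")
    ax.set_ylabel("input/rate ratio" if ycol == "ratio"
                  else "firing rate (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
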