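"""Event-time statistics for simulated traces.

Everything the figures of the study need: spike and burst detection,
rates, firing-probability-versus-phase curves, rate-versus-frequency
sweeps, p:q mode-locking detection with a separate phase-locking
verdict, interburst-interval (phase-response-like) maps and their
fixed-point iteration, and the post-burst state-reset diagnostics of the
bursting cell.  All analysis is in the event-time domain; there is no
spectral machinery here.

Default conventions (all configurable): spike threshold 0 mV with 2 ms
minimum separation; bursts grouped with a 15 ms intra-burst gap;
phase histograms at 1 ms resolution; "immediately after a pulse" means
within 5 ms; phase-locked means circular s.d. below 2 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from pulsegate.abstract import phase_of

__all__ = [
    "SpikeTrain",
    "BurstTrain",
    "InterburstMap",
    "ModeLockStats",
    "detect_spikes",
    "group_bursts",
    "firing_rate",
    "firing_probability_vs_phase",
    "rate_vs_frequency_sweep",
    "mode_lock_ratio",
    "interburst_map",
    "phase_map_iterate",
    "reset_alignment",
    "exclude_transient",
    "transient_cutoff",
    "circular_sd_ms",
]

DEFAULT_THRESHOLD = 0.0  # mV
DEFAULT_MIN_SEPARATION = 2.0  # ms
DEFAULT_INTRA_GAP = 15.0  # ms
DEFAULT_BIN = 1.0  # ms
DEFAULT_AFTER_WINDOW = 5.0  # ms
PHASE_LOCK_SD = 2.0  # ms


@dataclass(frozen=True)
class SpikeTrain:
    times: np.ndarray
    source: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)


@dataclass(frozen=True)
class BurstTrain:
    onsets: np.ndarray  # first-spike-of-burst times
    counts: np.ndarray  # spikes per burst

    def __post_init__(self):
        on = np.asarray(self.onsets, dtype=float)
        ct = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "onsets", on)
        object.__setattr__(self, "counts", ct)
        if on.size and np.any(np.diff(on) <= 0):
            raise ValueError("burst onsets must be strictly increasing")
        if np.any(ct < 1):
            raise ValueError("burst spike counts must be >= 1")

    def __len__(self):
        return len(self.onsets)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.onsets)


@dataclass(frozen=True)
class InterburstMap:
    """(IB-SI, IB-IB) pairs with spike counts of the flanking bursts.

    IB-SI is the lag from a burst onset to the unique SI spike in that
    interburst interval; IB-IB is the full interval.  Intervals with
    zero or multiple SI spikes are excluded (and counted).
    """

    ib_si: np.ndarray
    ib_ib: np.ndarray
    count_open: np.ndarray  # spikes in the burst opening the interval
    count_next: np.ndarray  # spikes in the burst closing it
    n_excluded: int = 0

    def __len__(self):
        return len(self.ib_si)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ib_si": self.ib_si, "ib_ib": self.ib_ib,
                             "count_open": self.count_open,
                             "count_next": self.count_next})

    def slope(self) -> float:
        """Least-squares slope of IB-IB against IB-SI."""
        return float(np.polyfit(self.ib_si, self.ib_ib, 1)[0])


@dataclass(frozen=True)
class ModeLockStats:
    ratio: tuple[int, int] | None  # (p, q) coprime, or None
    phase_sd: float  # circular s.d. of events mod input period, ms
    phase_locked: bool
    n_windows: int = 0

    @property
    def locked(self) -> bool:
        return self.ratio is not None


# --------------------------------------------------------------------------
# detection


def detect_spikes(v: np.ndarray, time: np.ndarray,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_separation: float = DEFAULT_MIN_SEPARATION,
                  source: str = "") -> SpikeTrain:
    """Upward threshold crossings with linear-interpolated times."""
    v = np.asarray(v, dtype=float)
    time = np.asarray(time, dtype=float)
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0]
    times = []
    last = -np.inf
    for i in up:
        tc = time[i] + (time[i + 1] - time[i]) * (threshold - v[i]) \
            / (v[i + 1] - v[i])
        if tc - last >= min_separation:
            times.append(tc)
            last = tc
    return SpikeTrain(np.array(times), source)


def group_bursts(spikes: SpikeTrain | np.ndarray,
                 intra_gap: float = DEFAULT_INTRA_GAP) -> BurstTrain:
    """Group spikes separated by <= intra_gap into bursts."""
    t = spikes.times if isinstance(spikes, SpikeTrain) else \
        np.asarray(spikes, dtype=float)
    if t.size == 0:
        return BurstTrain(np.array([]), np.array([], dtype=int))
    brk = np.nonzero(np.diff(t) > intra_gap)[0]
    starts = np.concatenate([[0], brk + 1])
    onsets = t[starts]
    counts = np.diff(np.concatenate([starts, [len(t)]]))
    return BurstTrain(onsets, counts)


# --------------------------------------------------------------------------
# rates and phase statistics


def firing_rate(events, window: tuple[float, float]) -> float:
    """Event count inside [t0, t1) divided by the window length, in Hz."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    ev = np.asarray(events, dtype=float)
    n = int(np.sum((ev >= t0) & (ev < t1)))
    return 1000.0 * n / (t1 - t0)


def firing_probability_vs_phase(events, trigger, reference,
                                bin_ms: float = DEFAULT_BIN,
                                window: float = DEFAULT_AFTER_WINDOW
                                ) -> pd.DataFrame:
    """P(event shortly after a trigger pulse | reference phase of pulse).

    For each trigger pulse, its phase relative to the reference train is
    computed; the pulse counts as "followed" if an event occurs within
    ``window`` ms after it.  Returns a frame with bin left edges,
    per-bin trigger counts and probabilities (NaN for empty bins).
    """
    ev = np.asarray(events, dtype=float)
    trig = np.asarray(trigger, dtype=float)
    ref = np.asarray(reference, dtype=float)
    trig = trig[trig >= ref[0]]
    phases = phase_of(trig, ref)
    followed = np.array([np.any((ev >= t) & (ev < t + window))
                         for t in trig])
    edges = np.arange(0.0, phases.max() + bin_ms, bin_ms)
    idx = np.clip(np.digitize(phases, edges) - 1, 0, len(edges) - 2)
    n = np.zeros(len(edges) - 1)
    k = np.zeros(len(edges) - 1)
    np.add.at(n, idx, 1)
    np.add.at(k, idx, followed.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        prob = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"phase": edges[:-1], "n_pulses": n.astype(int),
                         "probability": prob})


def firing_window(events, reference, bin_ms: float = DEFAULT_BIN):
    """Left edge and width of the contiguous phase support of firing."""
    ev = np.asarray(events, dtype=float)
    ref = np.asarray(reference, dtype=float)
    ph = phase_of(ev[ev >= ref[0]], ref)
    return float(ph.min()), float(ph.max() - ph.min())


# --------------------------------------------------------------------------
# sweeps


def rate_vs_frequency_sweep(config_id: str, swept_drive: str,
                            grid, fixed: dict | None = None,
                            duration: float = 5000.0,
                            transient: float = 1500.0,
                            measure: str = "SI",
                            variants: tuple[str, ...] = (),
                            sigma: float = 0.0,
                            seed: int | None = None) -> pd.DataFrame:
    """Firing rate of ``measure`` versus the frequency of one drive.

    One simulation per grid point; the other drives keep the
    frequencies given in ``fixed`` (name -> Hz).  Integration faults are
    recorded per point (rate = NaN), not raised.
    """
    from pulsegate.network import build_network
    from pulsegate.pulses import generate_pulse_times
    from pulsegate.simulate import IntegrationFault, simulate

    fixed = dict(fixed or {})
    spec = build_network(config_id, variants)
    rows = []
    for i, f in enumerate(np.asarray(grid, dtype=float)):
        freqs = {**fixed, swept_drive: f}
        drives = {name: generate_pulse_times(
            fq, sigma, duration,
            seed=None if seed is None else seed + 977 * i + hash(name) % 101)
            for name, fq in freqs.items()}
        try:
            res = simulate(spec, drives, duration, seed=seed)
            ev = res.spikes[measure]
            ev = ev[ev > transient]
            rate = 1000.0 * (len(ev) - 1) / (ev[-1] - ev[0]) \
                if len(ev) > 2 else 0.0
            rows.append({"frequency": f, "rate": rate, "fault": False})
        except IntegrationFault:
            rows.append({"frequency": f, "rate": np.nan, "fault": True})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mode-locking


def circular_sd_ms(events, period: float) -> float:
    """Circular standard deviation of event times modulo ``period``."""
    ev = np.asarray(events, dtype=float)
    if len(ev) < 2:
        return 0.0
    ang = 2 * np.pi * (ev % period) / period
    R = abs(np.mean(np.exp(1j * ang)))
    R = min(R, 1.0 - 1e-15)
    return float(np.sqrt(-2.0 * np.log(R)) * period / (2 * np.pi))


def mode_lock_ratio(events, input_times, max_q: int = 9,
                    min_windows: int = 20,
                    phase_sd_threshold: float = PHASE_LOCK_SD
                    ) -> ModeLockStats:
    """Detect exact p:q locking of events to a periodic input.

    A candidate ratio is taken from the mean rate; it is accepted only
    if every full window of q input cycles (anchored at the first input
    pulse) contains exactly p events, over at least ``min_windows``
    windows.  The phase-locked verdict is independent: circular s.d. of
    event times modulo the input period below the threshold.
    """
    ev = np.asarray(events, dtype=float)
    pt = np.asarray(input_times, dtype=float)
    period = float(np.mean(np.diff(pt)))
    sd = circular_sd_ms(ev, period)
    locked_phase = sd < phase_sd_threshold
    if len(ev) < 3 or len(pt) < 3:
        return ModeLockStats(None, sd, locked_phase, 0)
    rate_ratio = (1000.0 * (len(ev) - 1) / (ev[-1] - ev[0])) \
        / (1000.0 / period)
    frac = Fraction(rate_ratio).limit_denominator(max_q)
    p, q = frac.numerator, frac.denominator
    if p == 0:
        return ModeLockStats(None, sd, locked_phase, 0)
    edges = pt[::q]
    counts = np.histogram(ev, bins=edges)[0]
    n_windows = len(counts)
    if n_windows < min_windows or not np.all(counts == p):
        return ModeLockStats(None, sd, locked_phase, n_windows)
    return ModeLockStats((p, q), sd, locked_phase, n_windows)


# --------------------------------------------------------------------------
# interburst maps and phase-map iteration


def interburst_map(ib_bursts: BurstTrain, si_spikes) -> InterburstMap:
    """Pair each interburst interval with its unique SI spike.

    Intervals containing zero or more than one SI spike violate the
    alternation assumption; they are dropped and counted.
    """
    si = si_spikes.times if isinstance(si_spikes, SpikeTrain) else \
        np.asarray(si_spikes, dtype=float)
    on = ib_bursts.onsets
    cnt = ib_bursts.counts
    rows = []
    excluded = 0
    for i in range(len(on) - 1):
        inside = si[(si > on[i]) & (si < on[i + 1])]
        if len(inside) != 1:
            excluded += 1
            continue
        rows.append((inside[0] - on[i], on[i + 1] - on[i],
                     cnt[i], cnt[i + 1]))
    if excluded:
        warnings.warn(f"{excluded} interburst intervals without a unique "
                      "SI spike were excluded", stacklevel=2)
    if not rows:
        return InterburstMap(np.array([]), np.array([]),
                             np.array([], dtype=int),
                             np.array([], dtype=int), excluded)
    a = np.array(rows)
    return InterburstMap(a[:, 0], a[:, 1], a[:, 2].astype(int),
                         a[:, 3].astype(int), excluded)


@dataclass(frozen=True)
class PhaseMapResult:
    phis: np.ndarray  # iterated phases, phis[0] = phi0
    fixed_point: float | None
    slope: float | None  # dT_IB/dphi at the fixed point
    stable: bool
    diverged_at: int | None  # iteration index leaving the domain, if any


def phase_map_iterate(T_IB, T_SI: float, phi0: float, n: int,
                      domain: tuple[float, float] | None = None
                      ) -> PhaseMapResult:
    """Iterate the interburst phase map phi' = phi + T_SI - T_IB(phi).

    ``T_IB`` maps the SI-spike phase (time after burst onset) to the
    resulting interburst interval; it may be a callable or an
    :class:`InterburstMap`, in which case a least-squares line is used.
    The fixed point solves T_IB(phi*) = T_SI; with 0 < dT_IB/dphi < 1
    the iteration contracts towards it geometrically.
    """
    if isinstance(T_IB, InterburstMap):
        b, a = np.polyfit(T_IB.ib_si, T_IB.ib_ib, 1)
        lo, hi = float(T_IB.ib_si.min()), float(T_IB.ib_si.max())
        fn = lambda x: a + b * x
        if domain is None:
            domain = (lo - 2.0, hi + 2.0)
    else:
        fn = T_IB
        if domain is None:
            domain = (-np.inf, np.inf)

    phis = [float(phi0)]
    diverged = None
    for i in range(n):
        phi = phis[-1]
        if not (domain[0] <= phi <= domain[1]):
            diverged = i
            break
        phis.append(phi + T_SI - fn(phi))
    phis = np.array(phis)

    # fixed point: solve T_IB(phi*) = T_SI on the domain
    fixed = slope = None
    stable = False
    lo = domain[0] if np.isfinite(domain[0]) else phi0 - 100.0
    hi = domain[1] if np.isfinite(domain[1]) else phi0 + 100.0
    xs = np.linspace(lo, hi, 2001)
    resid = np.array([fn(x) - T_SI for x in xs])
    sign = np.sign(resid)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips):
        i0 = flips[0]
        x0, x1 = xs[i0], xs[i0 + 1]
        r0, r1 = resid[i0], resid[i0 + 1]
        fixed = float(x0 - r0 * (x1 - x0) / (r1 - r0))
        eps = (hi - lo) * 1e-4
        slope = float((fn(fixed + eps) - fn(fixed - eps)) / (2 * eps))
        stable = 0.0 < slope < 1.0
    return PhaseMapResult(phis, fixed, slope, stable, diverged)


# --------------------------------------------------------------------------
# state-reset diagnostics


def reset_alignment(result, onsets, labels=None, t0: float = 20.0,
                    pre_window: float = 10.0, post_window: float = 50.0
                    ) -> pd.DataFrame:
    """Values of slow variables at burst onset and ``t0`` ms after it.

    ``result`` is a :class:`~pulsegate.simulate.SimulationResult`;
    ``onsets`` a BurstTrain or array of burst-onset times.  Bursts whose
    successor starts within ``post_window`` are excluded so the t0
    sample is not contaminated by the next burst.  Returns one row per
    (variable, burst) with the spike count of the burst when available.
    """
    if isinstance(onsets, BurstTrain):
        on, cnt = onsets.onsets, onsets.counts
    else:
        on = np.asarray(onsets, dtype=float)
        cnt = np.full(len(on), -1)
    if labels is None:
        labels = result.gating_labels + result.synapse_labels
    time = result.time
    rows = []
    for i, t_on in enumerate(on):
        if i + 1 < len(on) and on[i + 1] - t_on < post_window:
            continue
        if t_on - pre_window < time[0] or t_on + t0 > time[-1]:
            continue
        i_on = np.searchsorted(time, t_on)
        i_t0 = np.searchsorted(time, t_on + t0)
        for lbl in labels:
            tr = result[lbl]
            rows.append({"variable": lbl, "onset_time": t_on,
                         "spikes_in_burst": int(cnt[i]),
                         "value_at_onset": float(tr[i_on]),
                         "value_at_t0": float(tr[i_t0])})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# transients


def transient_cutoff(K: int | None, mean_input2_period: float,
                     floor: float = 1000.0) -> float:
    """Discard max(floor, K periods) from the start of every run."""
    k = 3 if K is None else K
    return max(floor, k * mean_input2_period)


def exclude_transient(events, cutoff: float):
    """Drop all events before ``cutoff`` ms."""
    ev = np.asarray(events, dtype=float)
    out = ev[ev >= cutoff]
    if ev.size and out.size == 0:
        raise ValueError("transient cutoff removed every event")
    return out
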