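"""Pulsatile external drives.

Every network configuration in this package is driven by trains of brief
pulses.  A pulse train is a strictly increasing sequence of pulse times
with nominal frequency ``f`` (Hz); the interpulse intervals are either
exactly ``1000/f`` ms (``sigma = 0``) or i.i.d. normal with mean ``1000/f``
ms and standard deviation ``sigma * 1000/f`` ms, truncated to be positive.

Each train induces a continuous external potential V_ext(t): between
pulses V_ext relaxes exponentially toward -70 mV with a 1 ms time
constant, and at each pulse time it is reset to 25 mV (the idealised
effect of a delta-function drive term pulling V_ext to the excitatory
ceiling).  Downstream synapses read V_ext through the same sigmoidal
activation as they would a presynaptic membrane potential.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseTrain",
    "ExternalPotentialTrace",
    "generate_pulse_times",
    "external_potential",
]

V_REST = -70.0  # mV, resting level of the external potential
V_PULSE = 25.0  # mV, value V_ext is reset to at a pulse
TAU_EXT = 1.0  # ms, relaxation time constant of V_ext


@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing pulse times (ms) plus generation metadata."""

    times: np.ndarray
    nominal_frequency: float  # Hz
    jitter_sigma: float = 0.0  # fraction of the mean interval
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if times.size and times[0] < 0:
            raise ValueError("pulse times must be non-negative")

    @property
    def period(self) -> float:
        """Nominal interpulse interval in ms."""
        return 1000.0 / self.nominal_frequency

    def shifted(self, delta: float) -> "PulseTrain":
        """Return a copy with all pulse times shifted by ``delta`` ms."""
        return PulseTrain(self.times + delta, self.nominal_frequency,
                          self.jitter_sigma, self.seed)

    def to_text(self) -> str:
        """Two-column (index, time_ms) delimited serialisation."""
        buf = io.StringIO()
        for i, t in enumerate(self.times):
            buf.write(f"{i}\t{t:.6f}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str, nominal_frequency: float = float("nan"),
                  jitter_sigma: float = 0.0) -> "PulseTrain":
        rows = [line.split() for line in text.splitlines() if line.strip()]
        times = np.array([float(r[1]) for r in rows])
        return cls(times, nominal_frequency, jitter_sigma)


@dataclass(frozen=True)
class ExternalPotentialTrace:
    """V_ext sampled on a time grid, with the train that produced it."""

    time: np.ndarray  # ms
    v_ext: np.ndarray  # mV
    source: PulseTrain = field(repr=False, default=None)

    def to_text(self) -> str:
        buf = io.StringIO()
        for t, v in zip(self.time, self.v_ext):
            buf.write(f"{t:.6f}\t{v:.6f}\n")
        return buf.getvalue()


def generate_pulse_times(f: float, sigma: float, duration: float,
                         seed: int | None = None, *,
                         offset: float = 0.0) -> PulseTrain:
    """Generate a pulse train covering ``[0, duration]`` ms.

    Parameters
    ----------
    f : float
        Nominal frequency in Hz.  The mean interpulse interval is
        ``1000 / f`` ms.
    sigma : float
        Interval standard deviation as a fraction of the mean.  With
        ``sigma = 0`` the train is exactly periodic and independent of
        the seed.
    duration : float
        Length of the covered window in ms.  The last pulse is the first
        one at or beyond ``duration`` is *not* included; pulses are
        generated while they fall at or before ``duration``.
    seed : int, optional
        Seed for the interval draws (ignored when ``sigma = 0``).
    offset : float
        Time of the first pulse (default 0; used by the multiplexing
        configuration where the slow drives are phase-shifted copies).

    Non-positive normal draws are resampled so that the times stay
    strictly increasing; at the jitter levels used here (<= 10 %) the
    resampling probability is negligible.
    """
    if f <= 0:
        raise ValueError(f"pulse frequency must be positive, got {f}")
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if sigma < 0:
        raise ValueError(f"jitter sigma must be non-negative, got {sigma}")
    mean = 1000.0 / f
    if sigma == 0.0:
        n = int(np.floor((duration - offset) / mean + 1e-9)) + 1
        times = offset + mean * np.arange(max(n, 1))
        return PulseTrain(times, f, 0.0, seed)

    rng = np.random.default_rng(seed)
    sd = sigma * mean
    times = [offset]
    t = offset
    while t <= duration:
        gap = rng.normal(mean, sd)
        while gap <= 0.0:  # truncate: resample non-positive intervals
            gap = rng.normal(mean, sd)
        t += gap
        times.append(t)
    times.pop()  # last appended time exceeds duration
    return PulseTrain(np.array(times), f, sigma, seed)


def external_potential(train: PulseTrain, grid: np.ndarray,
                       *, warn_coarse: bool = True) -> ExternalPotentialTrace:
    """Evaluate the external potential induced by ``train`` on ``grid``.

    Between pulses V_ext obeys dV/dt = -(V - (-70)) / 1 ms; at every pulse
    time V_ext is reset to 25 mV.  The trace is evaluated in closed form
    (piecewise exponential), so it is exact regardless of grid spacing.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a 1-d increasing array")
    if warn_coarse and grid.size > 1 and np.max(np.diff(grid)) > 1.0 + 1e-12:
        import warnings

        warnings.warn("grid coarser than 1 ms undersamples V_ext",
                      stacklevel=2)
    times = train.times if train is not None else np.array([])
    # index of last pulse at or before each grid point (-1 if none)
    idx = np.searchsorted(times, grid, side="right") - 1
    v = np.full(grid.shape, V_REST)
    has = idx >= 0
    dt_since = grid[has] - times[idx[has]]
    v[has] = V_REST + (V_PULSE - V_REST) * np.exp(-dt_since / TAU_EXT)
    return ExternalPotentialTrace(grid, v, train)
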