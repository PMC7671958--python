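"""Leaky integrate-and-fire reduction of the gated cell.

A single LIF unit with an inhibitory autapse and two pulse inputs is
enough to reproduce the pulse-gated firing pattern: it fires only
immediately after an input-1 pulse (the excitatory kick is the only
thing that can reach threshold), it cannot fire on two consecutive
input-1 pulses (the autapse conductance outlasts one input-1 period but
not two), and it cannot fire for an interval ``c`` after an input-2
pulse (the input-2 inhibition).  The once-per-slow-period entrainment
then follows from the gating theory alone.

Voltages are dimensionless: rest 0, threshold 1.  The input-1 kick is a
brief exponential current (1 ms); inhibition is conductance-based with
single-exponential decay, reversal below rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["LIFParams", "simulate_lif"]


@dataclass(frozen=True)
class LIFParams:
    """Constants of the reduced cell.

    Defaults are chosen by construction: a lone input-1 kick from rest
    crosses threshold within ~1 ms; the autapse blocks a second kick for
    between one and two input-1 periods (T1 = 25 ms); input-2 inhibition
    blocks kicks for about 16-17 ms.
    """

    tau_m: float = 10.0  # membrane time constant, ms
    threshold: float = 1.0
    reset: float = 0.0
    v_rest: float = 0.0
    e_inh: float = -0.5  # inhibitory reversal (dimensionless)
    kick: float = 4.0  # input-1 charge (integral of the kick current)
    tau_kick: float = 0.5  # kick current decay, ms
    w_autapse: float = 14.0  # autapse conductance increment, 1/ms
    tau_autapse: float = 13.0  # autapse decay, ms
    w_inh2: float = 18.0  # input-2 conductance increment, 1/ms
    tau_inh2: float = 7.0  # input-2 decay, ms
    refractory: float = 2.0  # ms

    def __post_init__(self):
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        for name in ("tau_m", "tau_kick", "tau_autapse", "tau_inh2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@njit(cache=True)
def _lif_loop(t1, t2, duration, dt, tau_m, thr, reset, v_rest, e_inh,
              kick, tau_k, w_a, tau_a, w_2, tau_2, refr):
    n = int(duration / dt)
    v = v_rest
    ga = 0.0
    g2 = 0.0
    ik = 0.0
    i1 = 0
    i2 = 0
    last = -1e9
    spikes = np.empty(int(duration / 10) + 16)
    ns = 0
    for step in range(n):
        t = step * dt
        while i1 < t1.shape[0] and t1[i1] <= t:
            ik += kick / tau_k
            i1 += 1
        while i2 < t2.shape[0] and t2[i2] <= t:
            g2 += w_2
            i2 += 1
        dv = (-(v - v_rest) / tau_m - (ga + g2) * (v - e_inh) + ik)
        v += dt * dv
        ga -= dt * ga / tau_a
        g2 -= dt * g2 / tau_2
        ik -= dt * ik / tau_k
        if v >= thr and t - last >= refr:
            if ns < spikes.shape[0]:
                spikes[ns] = t
                ns += 1
            last = t
            v = reset
            ga += w_a
    return spikes[:ns]


def simulate_lif(params: LIFParams, input1, input2,
                 duration: float, dt: float = 0.02) -> np.ndarray:
    """Simulate the reduced cell; returns spike times in ms.

    ``input1`` and ``input2`` may be pulse-train objects or arrays of
    pulse times; ``input2`` may be empty.
    """
    t1 = np.asarray(getattr(input1, "times", input1), dtype=float)
    t2 = np.asarray(getattr(input2, "times", input2), dtype=float) \
        if input2 is not None else np.empty(0)
    return _lif_loop(t1, t2, float(duration), float(dt),
                     params.tau_m, params.threshold, params.reset,
                     params.v_rest, params.e_inh, params.kick,
                     params.tau_kick, params.w_autapse,
                     params.tau_autapse, params.w_inh2, params.tau_inh2,
                     params.refractory)
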