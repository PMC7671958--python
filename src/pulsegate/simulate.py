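"""Fixed-step integrator for the conductance-based networks.

The full system state is a flat vector ``[V (per compartment), gating
variables, synaptic states, external potentials (per drive)]``.
Integration is classical fourth-order Runge--Kutta with a fixed step
(default 0.02 ms), segmented at the pulse times of the external drives
so that the reset of V_ext to 25 mV is applied exactly (the drive term
is a delta function; integrating across it would depend on step
placement).  Spikes are detected on the fly as upward crossings of 0 mV
with a 1.5 ms refractory guard, with linear interpolation of the
crossing time.

The inner loop is compiled with numba; the gating formulas it inlines
are pinned to :mod:`pulsegate.kinetics` by a unit test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from pulsegate.kinetics import GATE_KINDS, x_inf
from pulsegate.network import NetworkSpec
from pulsegate.pulses import PulseTrain

__all__ = ["SimulationResult", "IntegrationFault", "simulate"]

SPIKE_THRESHOLD = 0.0  # mV
SPIKE_REFRACTORY = 1.5  # ms
DIVERGENCE_LIMIT = 200.0  # mV


class IntegrationFault(RuntimeError):
    """Raised when a membrane potential diverges during integration."""

    def __init__(self, time: float):
        super().__init__(f"membrane potential diverged at t = {time:.3f} ms")
        self.time = time


@dataclass
class SimulationResult:
    """Stored traces, detected spikes and integrator metadata."""

    time: np.ndarray  # store grid, ms
    states: np.ndarray  # (n_store, n_state)
    labels: list[str]  # one per state column
    spikes: dict[str, np.ndarray]  # compartment -> spike times, ms
    drives: dict[str, PulseTrain]
    spec: NetworkSpec = field(repr=False, default=None)
    dt: float = 0.02
    seed: int | None = None

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def V(self, compartment: str) -> np.ndarray:
        return self[compartment]

    def to_text(self, labels: list[str] | None = None,
                every: int = 1) -> str:
        """Delimited columnar export: time_ms plus the chosen traces."""
        labels = labels or self.labels
        cols = [self.time[::every]] + [self[l][::every] for l in labels]
        lines = ["time_ms\t" + "\t".join(labels)]
        for row in zip(*cols):
            lines.append("\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    @property
    def gating_labels(self) -> list[str]:
        return [l for l in self.labels
                if any(l.endswith("." + k) for k in GATE_KINDS)]

    @property
    def synapse_labels(self) -> list[str]:
        return [l for l in self.labels if l.startswith("syn:")]


# --------------------------------------------------------------------------
# reference (pure python) dynamics — the single-term building blocks.
# The compiled core below inlines the same expressions; a unit test pins
# the two implementations together to machine precision.


def membrane_derivative(V: float, gating: dict, params,
                        I_syn: float = 0.0, I_el: float = 0.0,
                        I_ext: float = 0.0) -> float:
    """dV/dt (mV/ms) of one compartment given its instantaneous currents.

    ``gating`` maps gating-variable kinds (see kinetics.GATE_KINDS) to
    their current values; only the kinds the compartment carries are
    read.  Raises if a gating value leaves [0, 1].
    """
    from pulsegate.kinetics import m0_na

    for kind, val in gating.items():
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"gating variable {kind} = {val} outside [0,1]")
    g, E = params.g, params.E
    ion = g["L"] * (V - E["L"])
    if g["Na"] > 0:
        ion += g["Na"] * m0_na(V) ** 3 * gating["h_Na"] * (V - E["Na"])
    if g["K"] > 0:
        ion += g["K"] * gating["m_K"] ** 4 * (V - E["K"])
    if g["AR"] > 0:
        ion += g["AR"] * gating["m_AR"] * (V - E["AR"])
    if g["KM"] > 0:
        ion += g["KM"] * gating["m_KM"] * (V - E["KM"])
    if g["CaH"] > 0:
        ion += g["CaH"] * gating["m_CaH"] ** 2 * (V - E["CaH"])
    return (-params.J - I_syn - I_el - I_ext - ion) / params.C


def synapse_derivative(s: float, V_pre: float, tau_d: float,
                       tau_r: float) -> float:
    """ds/dt of a first-order synaptic state variable."""
    return -s / tau_d + (1.0 - s) / tau_r * (1.0 + math.tanh(V_pre / 10.0))


def electrical_current(V: float, V_other: float, g: float) -> float:
    """Gap-junction current g (V - V'); antisymmetric in the pair."""
    return g * (V - V_other)


def reference_rhs(spec: NetworkSpec, y: np.ndarray) -> np.ndarray:
    """Full state derivative computed term by term in pure python.

    Independent of the compiled kernel; used as its oracle.  The state
    layout matches :func:`simulate` (V, gating, synapses, V_ext).
    """
    from pulsegate.kinetics import tau_x, x_inf

    packed, labels, comps = _pack(spec)
    nc, ng, ns = packed["nc"], packed["ng"], packed["ns"]
    dy = np.zeros_like(y)
    syn_I = np.zeros(nc)
    for k in range(ns):
        src = packed["syn_src"][k]
        vpre = y[src] if src >= 0 else y[nc + ng + ns + (-src - 1)]
        s = y[nc + ng + k]
        tgt = packed["syn_tgt"][k]
        syn_I[tgt] += s * packed["syn_g"][k] * (y[tgt] - packed["syn_V0"][k])
        dy[nc + ng + k] = synapse_derivative(s, vpre, packed["syn_td"][k],
                                             packed["syn_tr"][k])
    el_I = np.zeros(nc)
    for k in range(len(packed["el_g"])):
        a, b = packed["el_a"][k], packed["el_b"][k]
        cur = electrical_current(y[a], y[b], packed["el_g"][k])
        el_I[a] += cur
        el_I[b] -= cur
    for i, name in enumerate(comps):
        comp = spec.compartments[name]
        gating = {GATE_KINDS[packed["gate_kind"][g]]: y[nc + g]
                  for g in range(ng) if packed["gate_comp"][g] == i}
        dy[i] = membrane_derivative(y[i], gating, comp,
                                    I_syn=syn_I[i], I_el=el_I[i])
    for g in range(ng):
        kind = GATE_KINDS[packed["gate_kind"][g]]
        V = y[packed["gate_comp"][g]]
        x = y[nc + g]
        dy[nc + g] = (x_inf(V, kind) - x) \
            / tau_x(V, kind, packed["gate_tsc"][g])
    for d in range(packed["nd"]):
        v = y[nc + ng + ns + d]
        dy[nc + ng + ns + d] = -70.0 - v
    return dy


# --------------------------------------------------------------------------
# compiled core


@njit(cache=True)
def _rhs(y, dy, iacc, nc, ng, ns, nd,
         C, J, gL, VL, gNa, VNa, gK, VK, gAR, VAR, gKM, VKM, gCaH, VCaH,
         comp_gate, gate_comp, gate_kind, gate_tsc,
         syn_src, syn_tgt, syn_g, syn_V0, syn_td, syn_tr,
         el_a, el_b, el_g):
    for i in range(nc):
        iacc[i] = J[i]
    for k in range(ns):
        src = syn_src[k]
        if src >= 0:
            vpre = y[src]
        else:
            vpre = y[nc + ng + ns + (-src - 1)]
        s = y[nc + ng + k]
        tgt = syn_tgt[k]
        iacc[tgt] += s * syn_g[k] * (y[tgt] - syn_V0[k])
        dy[nc + ng + k] = (-s / syn_td[k]
                           + (1.0 - s) / syn_tr[k]
                           * (1.0 + math.tanh(vpre / 10.0)))
    for k in range(el_g.shape[0]):
        a, b = el_a[k], el_b[k]
        cur = el_g[k] * (y[a] - y[b])
        iacc[a] += cur
        iacc[b] -= cur
    for i in range(nc):
        V = y[i]
        ion = gL[i] * (V - VL[i])
        if gNa[i] > 0.0:
            m0 = 1.0 / (1.0 + math.exp((-V - 34.5) / 10.0))
            h = y[nc + comp_gate[i, 1]]
            ion += gNa[i] * m0 * m0 * m0 * h * (V - VNa[i])
        if gK[i] > 0.0:
            m = y[nc + comp_gate[i, 0]]
            ion += gK[i] * m * m * m * m * (V - VK[i])
        if gAR[i] > 0.0:
            ion += gAR[i] * y[nc + comp_gate[i, 2]] * (V - VAR[i])
        if gKM[i] > 0.0:
            ion += gKM[i] * y[nc + comp_gate[i, 3]] * (V - VKM[i])
        if gCaH[i] > 0.0:
            mc = y[nc + comp_gate[i, 4]]
            ion += gCaH[i] * mc * mc * (V - VCaH[i])
        dy[i] = (-iacc[i] - ion) / C[i]
    for g in range(ng):
        V = y[gate_comp[g]]
        x = y[nc + g]
        kind = gate_kind[g]
        if kind == 0:  # m_K
            inf = 1.0 / (1.0 + math.exp((-V - 29.5) / 10.0))
            tau = 0.25 + 4.35 * math.exp(-abs(V + 10.0) / 10.0)
        elif kind == 1:  # h_Na
            inf = 1.0 / (1.0 + math.exp((V + 59.4) / 10.7))
            tau = 0.15 + 1.15 / (1.0 + math.exp((V + 33.5) / 15.0))
        elif kind == 2:  # m_AR
            inf = 1.0 / (1.0 + math.exp((V + 87.5) / 5.5))
            tau = 1.0 / (math.exp(-14.59 - 0.086 * V)
                         + math.exp(-1.87 + 0.0701 * V))
        elif kind == 3:  # m_KM
            alpha = 0.02 / (1.0 + math.exp((-20.0 - V) / 5.0))
            beta = 0.01 * math.exp((-43.0 - V) / 18.0)
            inf = alpha / (alpha + beta)
            tau = 1.0 / (alpha + beta)
        else:  # m_CaH
            inf = 1.0 / (1.0 + math.exp((-V - 24.6) / 11.3))
            tau = 1.25 / math.cosh(0.031 * (V + 37.1))
        dy[nc + g] = (inf - x) / (tau * gate_tsc[g])
    for d in range(nd):
        v = y[nc + ng + ns + d]
        dy[nc + ng + ns + d] = -70.0 - v


@njit(cache=True)
def _integrate(y0, nc, ng, ns, nd,
               C, J, gL, VL, gNa, VNa, gK, VK, gAR, VAR, gKM, VKM, gCaH, VCaH,
               comp_gate, gate_comp, gate_kind, gate_tsc,
               syn_src, syn_tgt, syn_g, syn_V0, syn_td, syn_tr,
               el_a, el_b, el_g,
               ev_t, ev_d, duration, dt, store_dt):
    nstate = y0.shape[0]
    y = y0.copy()
    k1 = np.empty(nstate)
    k2 = np.empty(nstate)
    k3 = np.empty(nstate)
    k4 = np.empty(nstate)
    yt = np.empty(nstate)
    iacc = np.empty(nc)

    n_store = int(math.floor(duration / store_dt + 1e-9)) + 1
    Y = np.empty((n_store, nstate))
    Y[0] = y
    store_ptr = 1

    max_spk = int(duration / 1.2) + 16
    spk = np.empty((nc, max_spk))
    nspk = np.zeros(nc, dtype=np.int64)
    vprev = y[:nc].copy()
    last_spk = np.full(nc, -1e9)

    fault_t = -1.0
    t = 0.0
    iev = 0
    # apply any events at t = 0
    while iev < ev_t.shape[0] and ev_t[iev] <= 1e-12:
        y[nc + ng + ns + ev_d[iev]] = 25.0
        iev += 1
    Y[0] = y

    while t < duration - 1e-9:
        t_end = duration
        next_ev = iev < ev_t.shape[0] and ev_t[iev] < duration - 1e-9
        if next_ev:
            t_end = ev_t[iev]
        seg = t_end - t
        nsteps = max(1, int(math.ceil(seg / dt - 1e-9)))
        h = seg / nsteps
        for _ in range(nsteps):
            _rhs(y, k1, iacc, nc, ng, ns, nd, C, J, gL, VL, gNa, VNa, gK, VK,
                 gAR, VAR, gKM, VKM, gCaH, VCaH, comp_gate, gate_comp,
                 gate_kind, gate_tsc, syn_src, syn_tgt, syn_g, syn_V0,
                 syn_td, syn_tr, el_a, el_b, el_g)
            for i in range(nstate):
                yt[i] = y[i] + 0.5 * h * k1[i]
            _rhs(yt, k2, iacc, nc, ng, ns, nd, C, J, gL, VL, gNa, VNa, gK, VK,
                 gAR, VAR, gKM, VKM, gCaH, VCaH, comp_gate, gate_comp,
                 gate_kind, gate_tsc, syn_src, syn_tgt, syn_g, syn_V0,
                 syn_td, syn_tr, el_a, el_b, el_g)
            for i in range(nstate):
                yt[i] = y[i] + 0.5 * h * k2[i]
            _rhs(yt, k3, iacc, nc, ng, ns, nd, C, J, gL, VL, gNa, VNa, gK, VK,
                 gAR, VAR, gKM, VKM, gCaH, VCaH, comp_gate, gate_comp,
                 gate_kind, gate_tsc, syn_src, syn_tgt, syn_g, syn_V0,
                 syn_td, syn_tr, el_a, el_b, el_g)
            for i in range(nstate):
                yt[i] = y[i] + h * k3[i]
            _rhs(yt, k4, iacc, nc, ng, ns, nd, C, J, gL, VL, gNa, VNa, gK, VK,
                 gAR, VAR, gKM, VKM, gCaH, VCaH, comp_gate, gate_comp,
                 gate_kind, gate_tsc, syn_src, syn_tgt, syn_g, syn_V0,
                 syn_td, syn_tr, el_a, el_b, el_g)
            for i in range(nstate):
                y[i] += (h / 6.0) * (k1[i] + 2.0 * k2[i]
                                     + 2.0 * k3[i] + k4[i])
            # clamp dimensionless states against round-off overshoot
            for i in range(nc, nc + ng + ns):
                if y[i] < 0.0:
                    y[i] = 0.0
                elif y[i] > 1.0:
                    y[i] = 1.0
            t += h
            for i in range(nc):
                v = y[i]
                if abs(v) > DIVERGENCE_LIMIT:
                    fault_t = t
                    break
                if vprev[i] < SPIKE_THRESHOLD <= v:
                    tc = t - h + h * (SPIKE_THRESHOLD - vprev[i]) \
                        / (v - vprev[i])
                    if tc - last_spk[i] >= SPIKE_REFRACTORY \
                            and nspk[i] < max_spk:
                        spk[i, nspk[i]] = tc
                        nspk[i] += 1
                        last_spk[i] = tc
                vprev[i] = v
            if fault_t >= 0.0:
                break
            while store_ptr < n_store \
                    and store_ptr * store_dt <= t + 1e-9:
                Y[store_ptr] = y
                store_ptr += 1
        if fault_t >= 0.0:
            break
        t = t_end
        if next_ev:
            while iev < ev_t.shape[0] and ev_t[iev] <= t + 1e-12:
                y[nc + ng + ns + ev_d[iev]] = 25.0
                iev += 1
    while store_ptr < n_store:
        Y[store_ptr] = y
        store_ptr += 1
    return Y, spk, nspk, fault_t


# --------------------------------------------------------------------------
# python wrapper


def _pack(spec: NetworkSpec):
    comps = list(spec.compartments)
    nc = len(comps)
    cidx = {n: i for i, n in enumerate(comps)}

    def arr(fn):
        return np.array([fn(spec.compartments[n]) for n in comps])

    C = arr(lambda c: c.C)
    J = arr(lambda c: c.J)
    cur = {}
    for name in ("L", "Na", "K", "AR", "KM", "CaH"):
        cur["g" + name] = arr(lambda c, n=name: c.g[n])
        cur["V" + name] = arr(lambda c, n=name: c.E[n])

    gate_comp, gate_kind, gate_tsc, gate_labels = [], [], [], []
    comp_gate = -np.ones((nc, 5), dtype=np.int64)
    for i, n in enumerate(comps):
        comp = spec.compartments[n]
        for kind in comp.gate_kinds:
            ki = GATE_KINDS.index(kind)
            comp_gate[i, ki] = len(gate_comp)
            gate_comp.append(i)
            gate_kind.append(ki)
            gate_tsc.append(comp.kinetics.tau_scale[kind])
            gate_labels.append(f"{n}.{kind}")

    didx = {d: i for i, d in enumerate(spec.drives)}
    syn_src, syn_tgt = [], []
    syn_g, syn_V0, syn_td, syn_tr, syn_labels = [], [], [], [], []
    for syn in spec.synapses:
        if syn.is_external:
            syn_src.append(-didx[syn.source[6:]] - 1)
        else:
            syn_src.append(cidx[syn.source])
        syn_tgt.append(cidx[syn.target])
        syn_g.append(syn.g)
        syn_V0.append(syn.V0)
        syn_td.append(syn.tau_d)
        syn_tr.append(syn.tau_r)
        syn_labels.append(f"syn:{syn.label}")

    el_a = np.array([cidx[c.a] for c in spec.couplings], dtype=np.int64)
    el_b = np.array([cidx[c.b] for c in spec.couplings], dtype=np.int64)
    el_g = np.array([c.g for c in spec.couplings], dtype=float)

    labels = (comps + gate_labels + syn_labels
              + [f"Vext:{d}" for d in spec.drives])
    packed = dict(
        nc=nc, ng=len(gate_comp), ns=len(syn_src), nd=len(spec.drives),
        C=C, J=J,
        gL=cur["gL"], VL=cur["VL"], gNa=cur["gNa"], VNa=cur["VNa"],
        gK=cur["gK"], VK=cur["VK"], gAR=cur["gAR"], VAR=cur["VAR"],
        gKM=cur["gKM"], VKM=cur["VKM"], gCaH=cur["gCaH"], VCaH=cur["VCaH"],
        comp_gate=comp_gate,
        gate_comp=np.array(gate_comp, dtype=np.int64),
        gate_kind=np.array(gate_kind, dtype=np.int64),
        gate_tsc=np.array(gate_tsc, dtype=float),
        syn_src=np.array(syn_src, dtype=np.int64),
        syn_tgt=np.array(syn_tgt, dtype=np.int64),
        syn_g=np.array(syn_g, dtype=float),
        syn_V0=np.array(syn_V0, dtype=float),
        syn_td=np.array(syn_td, dtype=float),
        syn_tr=np.array(syn_tr, dtype=float),
        el_a=el_a, el_b=el_b, el_g=el_g,
    )
    return packed, labels, comps


def default_initial_state(spec: NetworkSpec) -> np.ndarray:
    """Rest-like start: V = -70 mV, gating at equilibrium, synapses 0."""
    packed, _, comps = _pack(spec)
    nstate = packed["nc"] + packed["ng"] + packed["ns"] + packed["nd"]
    y0 = np.empty(nstate)
    y0[:packed["nc"]] = -70.0
    for g in range(packed["ng"]):
        kind = GATE_KINDS[packed["gate_kind"][g]]
        y0[packed["nc"] + g] = x_inf(-70.0, kind)
    y0[packed["nc"] + packed["ng"]:] = 0.0
    y0[packed["nc"] + packed["ng"] + packed["ns"]:] = -70.0
    return y0


def simulate(spec: NetworkSpec, drives: dict[str, PulseTrain] | None,
             duration: float, dt: float = 0.02,
             initial: np.ndarray | None = None, seed: int | None = None,
             store_dt: float = 0.05) -> SimulationResult:
    """Integrate ``spec`` for ``duration`` ms under the given drives.

    ``drives`` maps drive names declared by the spec to pulse trains;
    missing drives are treated as silent (V_ext stays at rest).  The
    result is bit-for-bit reproducible for identical inputs.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms for reliable spike shapes")
    drives = drives or {}
    unknown = set(drives) - set(spec.drives)
    if unknown:
        raise ValueError(f"drives not declared by this network: {unknown}")
    packed, labels, comps = _pack(spec)

    events = []
    for name, train in drives.items():
        d = spec.drives.index(name)
        for tt in train.times:
            if 0 <= tt <= duration:
                events.append((float(tt), d))
    events.sort()
    ev_t = np.array([e[0] for e in events], dtype=float)
    ev_d = np.array([e[1] for e in events], dtype=np.int64)

    y0 = default_initial_state(spec) if initial is None \
        else np.asarray(initial, dtype=float)

    Y, spk, nspk, fault_t = _integrate(
        y0, packed["nc"], packed["ng"], packed["ns"], packed["nd"],
        packed["C"], packed["J"], packed["gL"], packed["VL"],
        packed["gNa"], packed["VNa"], packed["gK"], packed["VK"],
        packed["gAR"], packed["VAR"], packed["gKM"], packed["VKM"],
        packed["gCaH"], packed["VCaH"],
        packed["comp_gate"], packed["gate_comp"], packed["gate_kind"],
        packed["gate_tsc"], packed["syn_src"], packed["syn_tgt"],
        packed["syn_g"], packed["syn_V0"], packed["syn_td"],
        packed["syn_tr"], packed["el_a"], packed["el_b"], packed["el_g"],
        ev_t, ev_d, float(duration), float(dt), float(store_dt))
    if fault_t >= 0:
        raise IntegrationFault(fault_t)

    spikes = {name: spk[i, :nspk[i]].copy() for i, name in enumerate(comps)}
    time = store_dt * np.arange(Y.shape[0])
    return SimulationResult(time, Y, labels, spikes, dict(drives), spec,
                            dt, seed)
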