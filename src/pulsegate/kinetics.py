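"""Voltage-dependent gating kinetics.

Traub-lineage first-order kinetics for the five gating variables of the
membrane model: the delayed-rectifier activation ``m_K`` (fourth power),
the transient-sodium inactivation ``h_Na`` (activation ``m0`` is
instantaneous), the h-current / anomalous-rectifier activation ``m_AR``,
the M-current activation ``m_KM``, and the high-threshold calcium
activation ``m_CaH`` (squared).  Each variable x relaxes as

    dx/dt = (x_inf(V) - x) / tau_x(V)

with the equilibria and time constants below.  A per-compartment
``tau_scale`` multiplies ``tau_x``; this is how the model expresses e.g.
the faster M-current of the bursting cell's axon or the faster h-current
variant used in some runs.

Functions accept scalars or numpy arrays (V in mV, tau in ms).
"""

from __future__ import annotations

import numpy as np

__all__ = ["GATE_KINDS", "m0_na", "x_inf", "tau_x", "GatingKinetics"]

# order matters: it is the layout used by the compiled simulator core
GATE_KINDS = ("m_K", "h_Na", "m_AR", "m_KM", "m_CaH")


def m0_na(V):
    """Instantaneous sodium activation (cubed in the current)."""
    return 1.0 / (1.0 + np.exp((-V - 34.5) / 10.0))


def _km_rates(V):
    alpha = 0.02 / (1.0 + np.exp((-20.0 - V) / 5.0))
    beta = 0.01 * np.exp((-43.0 - V) / 18.0)
    return alpha, beta


def x_inf(V, kind: str):
    """Equilibrium value of gating variable ``kind`` at potential V."""
    if kind == "m_K":
        return 1.0 / (1.0 + np.exp((-V - 29.5) / 10.0))
    if kind == "h_Na":
        return 1.0 / (1.0 + np.exp((V + 59.4) / 10.7))
    if kind == "m_AR":
        return 1.0 / (1.0 + np.exp((V + 87.5) / 5.5))
    if kind == "m_KM":
        alpha, beta = _km_rates(V)
        return alpha / (alpha + beta)
    if kind == "m_CaH":
        return 1.0 / (1.0 + np.exp((-V - 24.6) / 11.3))
    raise KeyError(kind)


def tau_x(V, kind: str, scale: float = 1.0):
    """Time constant (ms) of gating variable ``kind`` at potential V."""
    if kind == "m_K":
        tau = 0.25 + 4.35 * np.exp(-np.abs(V + 10.0) / 10.0)
    elif kind == "h_Na":
        tau = 0.15 + 1.15 / (1.0 + np.exp((V + 33.5) / 15.0))
    elif kind == "m_AR":
        tau = 1.0 / (np.exp(-14.59 - 0.086 * V) + np.exp(-1.87 + 0.0701 * V))
    elif kind == "m_KM":
        alpha, beta = _km_rates(V)
        tau = 1.0 / (alpha + beta)
    elif kind == "m_CaH":
        tau = 1.25 / np.cosh(0.031 * (V + 37.1))
    else:
        raise KeyError(kind)
    return scale * tau


class GatingKinetics:
    """Bundle of tau/inf functions with per-variable tau scales."""

    def __init__(self, tau_scale: dict[str, float] | None = None):
        self.tau_scale = {k: 1.0 for k in GATE_KINDS}
        if tau_scale:
            for k, v in tau_scale.items():
                if k not in GATE_KINDS:
                    raise KeyError(f"unknown gating variable {k!r}")
                self.tau_scale[k] = float(v)

    def x_inf(self, V, kind: str):
        return x_inf(V, kind)

    def tau(self, V, kind: str):
        return tau_x(V, kind, self.tau_scale[kind])

    def derivative(self, x, V, kind: str):
        """dx/dt = (x_inf - x)/tau for this variable."""
        return (x_inf(V, kind) - x) / self.tau(V, kind)

    def is_slow(self, kind: str, v_lo: float = -75.0, v_hi: float = -40.0,
                threshold: float = 10.0) -> bool:
        """Slow iff tau > threshold ms throughout the subthreshold range."""
        V = np.linspace(v_lo, v_hi, 141)
        return bool(np.min(self.tau(V, kind)) > threshold)
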