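"""Discrete pulse-gating model of the SI cell and its analytic theory.

The model strips the conductance-based network down to a firing rule.
Input-1 pulses arrive periodically with period ``T1`` (ms); input-2
pulses arrive at times ``t_n`` (not necessarily periodic).  The cell
"fires" at an input-1 pulse iff

* at least ``m`` input-1 periods have elapsed since its previous firing
  (``m = 2`` encodes "cannot fire on two consecutive pulses"), and
* the time since the last input-2 pulse (the input-2 *phase*) is at
  least ``c`` ms, the effective inhibition time.

Under the gap condition

    inf_n (t_{n+1} - t_n) > max(m*T1, c + T1)   and
    sup_n (t_{n+1} - t_n) <= m*T1 + c

the cell fires exactly once per input-2 period, and after a short
transient of at most ``K`` periods every firing phase lies in the
half-open window ``[c, c + T1)``; moreover an input-1 pulse past the
transient triggers a firing iff its phase lies in that window.  For
``m = 1`` (no refractory gating) the long-run rate is instead
``(1/T1) * (1 - c/T2)`` when input-2 is periodic with period ``T2``.

All times are in milliseconds; frequencies returned by the range
helpers are in Hz with ``c`` given in seconds, matching the convention
of the frequency-domain inequalities.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "AbstractParams",
    "FiringRecord",
    "TheoremReport",
    "simulate_abstract",
    "phase_of",
    "check_conditions",
    "transient_bound_K",
    "remark42_bound",
    "verify_theorem41",
    "f2_range",
    "f1_range",
    "asymptotic_rate_m1",
    "estimate_m_c",
    "random_admissible_train",
    "reanchor",
]


# --------------------------------------------------------------------------
# parameters and records


@dataclass(frozen=True)
class AbstractParams:
    """Parameters of the gating rule.

    ``t`` is the input-2 pulse sequence with ``t[0] = 0``; ``s1`` is the
    time of the first firing (which by convention coincides with an
    input-1 pulse) and must lie in ``[c, t[1])``.
    """

    T1: float
    c: float
    m: int
    t: np.ndarray
    s1: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if self.T1 <= 0:
            raise ValueError("T1 must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if t.size < 2 or abs(t[0]) > 1e-12 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing with t[0] = 0")
        s1 = self.c if self.s1 is None else self.s1
        object.__setattr__(self, "s1", float(s1))
        if not (self.c <= self.s1 < t[1]):
            raise ValueError(f"s1 must lie in [c, t_2) = [{self.c}, {t[1]})")

    @classmethod
    def periodic(cls, T1: float, T2: float, c: float, m: int,
                 n_periods: int, s1: float | None = None) -> "AbstractParams":
        """Convenience constructor with periodic input-2 of period ``T2``."""
        t = T2 * np.arange(n_periods + 1, dtype=float)
        return cls(T1, c, m, t, s1)

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.t)


@dataclass(frozen=True)
class FiringRecord:
    """Firing times of the gated cell together with their input-2 phases."""

    times: np.ndarray  # u_n, ms
    phases: np.ndarray  # time since last input-2 pulse at each firing, ms
    period_counts: np.ndarray  # firings per complete input-2 period
    params: AbstractParams = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.times)

    def rate(self, skip: int = 0) -> float:
        """Mean firing rate in Hz over firings ``skip`` onward."""
        u = self.times[skip:]
        if len(u) < 2:
            raise ValueError("need at least two firings to compute a rate")
        return 1000.0 * (len(u) - 1) / (u[-1] - u[0])

    def to_text(self) -> str:
        buf = io.StringIO()
        for u, p in zip(self.times, self.phases):
            buf.write(f"{u:.6f}\t{p:.6f}\n")
        return buf.getvalue()


@dataclass(frozen=True)
class TheoremReport:
    """Outcome of checking the once-per-period entrainment guarantees."""

    K: int
    part_a: bool
    part_b: bool
    part_c: bool
    violations_a: np.ndarray
    violations_b: np.ndarray
    violations_c: np.ndarray

    @property
    def all_pass(self) -> bool:
        return self.part_a and self.part_b and self.part_c

    def to_text(self) -> str:
        lines = [f"K\t{self.K}"]
        for name in ("a", "b", "c"):
            ok = getattr(self, f"part_{name}")
            bad = getattr(self, f"violations_{name}")
            lines.append(f"part_{name}\t{'pass' if ok else 'FAIL'}"
                         + ("" if ok else "\tindices " + ",".join(map(str, bad))))
        return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# core operations


def phase_of(x, t_seq) -> np.ndarray | float:
    """Time since the last input-2 pulse: x - max{t_n : t_n <= x}.

    For a periodic sequence of period T2 this is ``x mod T2``.  Raises
    for query points before the first pulse.
    """
    t_seq = np.asarray(t_seq, dtype=float)
    arr = np.asarray(x, dtype=float)
    if np.any(arr < t_seq[0]):
        raise ValueError("phase undefined before the first input-2 pulse")
    idx = np.searchsorted(t_seq, arr, side="right") - 1
    out = arr - t_seq[idx]
    return out if arr.ndim else float(out)


def simulate_abstract(params: AbstractParams,
                      horizon: float | None = None) -> FiringRecord:
    """Run the gating rule up to ``horizon`` (default: last input-2 pulse).

    The firing sequence starts at ``u_1 = s1``; subsequent firings are
    the earliest input-1 pulses at least ``m * T1`` after the previous
    firing whose input-2 phase is >= ``c`` (phase test closed at ``c``;
    a pulse coinciding with an input-2 pulse has phase exactly 0).
    """
    t = params.t
    if horizon is None:
        horizon = float(t[-1])
    if horizon < t[1]:
        raise ValueError("horizon shorter than the second input-2 pulse")
    T1, c, m, s1 = params.T1, params.c, params.m, params.s1

    fired = [s1]
    u_prev = s1
    # index l of the next candidate input-1 pulse s_l = s1 + l*T1
    while True:
        l = math.ceil((u_prev + m * T1 - s1) / T1 - 1e-12)
        s = s1 + l * T1
        while s <= horizon and s <= t[-1]:
            k = np.searchsorted(t, s + 1e-12) - 1
            if s - t[k] >= c - 1e-12:
                break
            l += 1
            s = s1 + l * T1
        else:
            break
        if s > horizon or s > t[-1]:
            break
        fired.append(s)
        u_prev = s

    u = np.array(fired)
    phases = phase_of(u, t)
    last_full = np.searchsorted(t, horizon, side="right") - 1
    counts = np.histogram(u, bins=t[:last_full + 1])[0] if last_full >= 1 \
        else np.array([], dtype=int)
    return FiringRecord(u, phases, counts, params)


def check_conditions(params: AbstractParams):
    """Test the sufficient gap condition for once-per-period entrainment.

    Returns ``(ok, left_margin, right_margin)`` where ``left_margin =
    inf_gap - max(m*T1, c+T1)`` (must be > 0) and ``right_margin =
    m*T1 + c - sup_gap`` (must be >= 0).
    """
    gaps = params.gaps
    inf_gap, sup_gap = float(gaps.min()), float(gaps.max())
    left = inf_gap - max(params.m * params.T1, params.c + params.T1)
    right = params.m * params.T1 + params.c - sup_gap
    return left > 0 and right >= 0, left, right


def transient_bound_K(T1: float, c: float, m: int,
                      inf_gap: float, sup_gap: float) -> int:
    """Transient bound: firings settle into [c, c+T1) within K periods.

    K = ceil((sup_gap - (c + T1)) / (inf_gap - m*T1)) + 1.
    """
    denom = inf_gap - m * T1
    if denom <= 0:
        raise ValueError("requires inf_gap > m * T1")
    num = sup_gap - (c + T1)
    return int(math.ceil(num / denom - 1e-12)) + 1


def remark42_bound(T1: float, m: int, inf_gap: float) -> int:
    """Coarser a-priori bound ceil(2 / (1 - m*T1/inf_gap)) on K."""
    ratio = m * T1 / inf_gap
    if ratio >= 1:
        raise ValueError("requires inf_gap > m * T1")
    return int(math.ceil(2.0 / (1.0 - ratio) - 1e-12))


def verify_theorem41(record: FiringRecord,
                     params: AbstractParams | None = None) -> TheoremReport:
    """Check the three entrainment guarantees on a simulated record.

    (a) the n-th firing lies in [t_n + c, t_{n+1});
    (b) firings from period K onward have phase in [c, c + T1);
    (c) input-1 pulses at or after t_K fire iff their phase is in
        [c, c + T1).
    """
    if params is None:
        params = record.params
    t, T1, c, m = params.t, params.T1, params.c, params.m
    gaps = params.gaps
    K = transient_bound_K(T1, c, m, float(gaps.min()), float(gaps.max()))
    u = record.times
    eps = 1e-9

    n_chk = min(len(u), len(t) - 1)
    lo = t[:n_chk] + c
    hi = t[1:n_chk + 1]
    bad_a = np.nonzero(~((u[:n_chk] >= lo - eps) & (u[:n_chk] < hi)))[0]

    # firings are 1-indexed in the theorem; u[K-1] is the K-th firing,
    # which lies in the K-th period by part (a)
    sel = np.arange(min(K - 1, len(u)), len(u))
    ph = record.phases[sel]
    bad_b = sel[~((ph >= c - eps) & (ph < c + T1))]

    # part (c): enumerate input-1 pulses from t_K to the last firing
    tK = t[min(K - 1, len(t) - 1)]
    s1 = params.s1
    l0 = max(0, math.ceil((tK - s1) / T1 - eps))
    s_all = s1 + T1 * np.arange(l0, int((u[-1] - s1) / T1 + 1) + 1)
    s_all = s_all[(s_all >= tK) & (s_all <= u[-1]) & (s_all <= t[-1])]
    if s_all.size:
        ph_s = phase_of(s_all, t)
        in_window = (ph_s >= c - eps) & (ph_s < c + T1)
        fired = np.isclose(s_all[:, None], u[None, :], atol=1e-6).any(axis=1)
        bad_c = np.nonzero(in_window != fired)[0]
    else:
        bad_c = np.array([], dtype=int)

    return TheoremReport(K, bad_a.size == 0, bad_b.size == 0,
                         bad_c.size == 0, bad_a, bad_b, bad_c)


# --------------------------------------------------------------------------
# frequency ranges and the m = 1 rate


def f2_range(f1: float, m: int, c: float) -> tuple[float, float]:
    """Admissible input-2 frequencies [lower, upper) in Hz (``c`` in s)."""
    if f1 <= 0 or c < 0:
        raise ValueError("f1 must be positive and c non-negative")
    lower = f1 / (f1 * c + m)
    upper = min(f1 / m, f1 / (f1 * c + 1))
    return lower, upper


def f1_range(f2: float, m: int, c: float) -> tuple[float, float]:
    """Admissible input-1 frequencies (lower, upper] in Hz (``c`` in s)."""
    if c * f2 >= 1:
        raise ValueError("requires c * f2 < 1")
    lower = max(m * f2, f2 / (1 - c * f2))
    upper = m * f2 / (1 - c * f2)
    return lower, upper


@dataclass(frozen=True)
class AsymptoticRate:
    rate_hz: float
    bound_hz: float | None  # |empirical limit - rate| bound, rational ratio
    ratio: tuple[int, int] | None  # (p, q) with T1/T2 = p/q if rational


def asymptotic_rate_m1(T1: float, T2: float, c: float,
                       max_q: int = 10 ** 6) -> AsymptoticRate:
    """Long-run rate (1/T1)(1 - c/T2) of the ungated (m=1) model, in Hz.

    If ``T1/T2`` is (numerically) rational with denominator q <= max_q,
    the empirical limit is only guaranteed within ``1/(q*T1)`` of the
    formula; that bound is attached, converted to Hz.
    """
    if not (0 <= c < T2 and 0 < T1 < T2):
        raise ValueError("requires 0 <= c < T2 and 0 < T1 < T2")
    rate = (1000.0 / T1) * (1.0 - c / T2)
    frac = Fraction(T1 / T2).limit_denominator(max_q)
    if abs(float(frac) - T1 / T2) < 1e-12:
        p, q = frac.numerator, frac.denominator
        return AsymptoticRate(rate, 1000.0 / (q * T1), (p, q))
    return AsymptoticRate(rate, None, None)


# --------------------------------------------------------------------------
# parameter recovery and helpers


def estimate_m_c(firing_times, input1_times, input2_times,
                 bin_ms: float = 1.0, min_firings: int = 50):
    """Recover the gating parameters (m, c) from event times.

    ``m`` is the minimum number of input-1 intervals separating
    successive firings; ``c`` is the left edge of the first occupied bin
    of the firing-phase histogram relative to input-2 (the length of the
    zero-probability prefix), at resolution ``bin_ms``.
    """
    u = np.asarray(firing_times, dtype=float)
    s = np.asarray(input1_times, dtype=float)
    t = np.asarray(input2_times, dtype=float)
    if len(u) < min_firings:
        raise ValueError(f"need at least {min_firings} firings, got {len(u)}")
    # count input-1 pulses strictly between successive firings (+1)
    pos = np.searchsorted(s, u + 1e-6)
    m_hat = int(np.min(np.diff(pos)))
    phases = phase_of(u[u >= t[0]], t)
    edges = np.arange(0.0, phases.max() + 2 * bin_ms, bin_ms)
    hist = np.histogram(phases, bins=edges)[0]
    first = int(np.argmax(hist > 0))
    c_hat = edges[first]
    return m_hat, float(c_hat)


def random_admissible_train(T1: float, c: float, m: int, n_gaps: int,
                            rng: np.random.Generator,
                            eps: float = 1e-6) -> np.ndarray:
    """Random input-2 times whose gaps satisfy the entrainment condition.

    Gaps are uniform on (max(m*T1, c+T1) + eps, m*T1 + c]; the condition
    requires a strict lower inequality, hence the eps.
    """
    lo = max(m * T1, c + T1) + eps
    hi = m * T1 + c
    if hi <= lo:
        raise ValueError("no admissible gap interval for these parameters")
    gaps = rng.uniform(lo, hi, size=n_gaps)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def reanchor(firing_times, input2_times, which: int = 0):
    """Re-label a firing sequence so that u_1 is the ``which``-th firing
    after the first input-2 pulse and times are measured from the start
    of the input-2 period containing it.

    Returns ``(u, t)`` with ``t[0] = 0`` and ``u[0] in [t[0], t[1])``.
    """
    u = np.asarray(firing_times, dtype=float)
    t = np.asarray(input2_times, dtype=float)
    u = u[u >= t[0]]
    if len(u) <= which:
        raise ValueError("not enough firings to re-anchor")
    u = u[which:]
    k = np.searchsorted(t, u[0] + 1e-12) - 1
    return u - t[k], t[k:] - t[k]
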