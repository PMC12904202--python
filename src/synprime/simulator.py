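"""Sequential two-step (loose/tight) vesicle-priming simulator.

Release sites cycle through empty (ES), loosely docked (LS) and tightly
docked (TS) states::

    ES  <--k1(Ca)/b1-->  LS  <--k2(Ca)/b2-->  TS  --AP: p_fusion-->  fused

Only TS vesicles are fusion competent.  An action potential (AP)
releases ``p_fusion * TS`` vesicles and returns the sites to ES (or to
a labile empty state ERS when the labile extension is enabled, which
also adds an activity-generated labile tight state TSL).  The forward
rates k1 and k2 increase linearly with global residual calcium above
rest, with sensitivities sigma1 and sigma2 (1/s per uM); p_fusion
facilitates linearly with residual calcium up to a cap.  The brief
local calcium transient of each AP additionally tightens a fixed
fraction of the loosely docked pool (``ap_conversion``), taking
effect after that AP's release so newly tightened vesicles first
fuse at the following stimulus.

Global calcium is a linear superposition of per-AP exponentially
decaying transients on top of a resting level; the local calcium
domain driving fusion itself is not simulated explicitly (its effect
is folded into p_fusion), but its nominal peak is kept for
power-law cooperativity arithmetic.

Mean-field occupancies evolve by fixed-step RK4 between APs; a
stochastic mode replaces expectations with binomial/multinomial
sampling at the same time resolution.

Units: time s, calcium nM (sensitivities per uM), rates 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .plasticity import recovery_fraction

__all__ = [
    "PrimingModelParams",
    "CaTransientParams",
    "SimState",
    "Protocol",
    "TrainResult",
    "WT_PARAMS",
    "HK_PARAMS",
    "DEFAULT_CA_PARAMS",
    "global_ca",
    "rate_constants",
    "simulate_train",
    "simulate_recovery",
    "simulate_train_stochastic",
]


@dataclass(frozen=True)
class PrimingModelParams:
    """Rate constants and fusion parameters of the two-step scheme.

    ``sigma1``/``sigma2`` are the calcium sensitivities of the ES->LS
    and LS->TS transitions (1/s per uM of global Ca above rest);
    ``facilitation_gain`` scales p_fusion per uM residual Ca.
    """

    N_total: float = 3600.0
    k1_rest: float = 0.36
    sigma1: float = 1.5
    b1: float = 0.5
    k2_rest: float = 0.7
    sigma2: float = 3.0
    b2: float = 1.8
    p_fusion_0: float = 0.34
    ap_conversion: float = 0.1
    facilitation_gain: float = 8.0
    p_fusion_max: float = 0.6
    labile_enabled: bool = False
    tsl_decay: float = 2.0
    ers_decay: float = 2.0
    rate_cap: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("k1_rest", "sigma1", "b1", "k2_rest", "sigma2", "b2",
                     "tsl_decay", "ers_decay", "rate_cap", "facilitation_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ap_conversion < 1:
            raise ValueError("ap_conversion must lie in [0, 1)")
        if not 0 < self.p_fusion_0 <= self.p_fusion_max <= 1:
            raise ValueError("need 0 < p_fusion_0 <= p_fusion_max <= 1")
        if self.N_total < 1:
            raise ValueError("N_total must be >= 1")
        # degenerate rate sets (all-zero limits) are allowed for
        # analytic checks; resting_state() validates on use

    @property
    def resting_f_ts(self) -> float:
        """Resting TS fraction of the FRP: k2_rest / (k2_rest + b2)."""
        denom = self.k2_rest + self.b2
        if denom == 0:
            raise ZeroDivisionError("k2_rest + b2 is zero; f_TS undefined")
        return self.k2_rest / denom

    def resting_state(self) -> "SimState":
        """Analytic resting steady state of the three-state core.

        Detailed balance along the chain gives LS/ES = k1_rest/b1 and
        TS/LS = k2_rest/b2; labile states are empty at rest.
        """
        if self.b1 == 0 or self.b2 == 0:
            raise ZeroDivisionError(
                "resting state undefined with b1 == 0 or b2 == 0; "
                "pass an explicit initial_state instead")
        es = 1.0
        ls = es * self.k1_rest / self.b1
        ts = ls * self.k2_rest / self.b2
        scale = self.N_total / (es + ls + ts)
        return SimState(t=0.0, ES=es * scale, LS=ls * scale, TS=ts * scale,
                        TSL=0.0, ERS=0.0, p_fusion_now=self.p_fusion_0,
                        ca_now=float("nan"))

    @property
    def resting_frp(self) -> float:
        """Resting fast-releasing pool LS + TS (SV counts)."""
        s = self.resting_state()
        return s.LS + s.TS

    def with_frp(self, frp: float) -> "PrimingModelParams":
        """Rescale N_total so the resting FRP equals ``frp``."""
        return replace(self, N_total=self.N_total * frp / self.resting_frp)

    def with_f_ts(self, f_ts: float) -> "PrimingModelParams":
        """Adjust k2_rest so the resting f_TS equals ``f_ts``."""
        if not 0 < f_ts < 1:
            raise ValueError("f_ts must lie in (0, 1)")
        return replace(self, k2_rest=self.b2 * f_ts / (1.0 - f_ts))


@dataclass(frozen=True)
class CaTransientParams:
    """Global residual-calcium dynamics (nM) plus nominal local peak (uM)."""

    ca_rest: float = 50.0
    ca_increment_per_ap: float = 30.0
    tau_global: float = 0.15
    ca_local_peak: float = 56.0

    def __post_init__(self) -> None:
        if self.ca_rest <= 0:
            raise ValueError("ca_rest must be positive (nM)")
        if self.tau_global <= 0:
            raise ValueError("tau_global must be positive (s)")
        if self.ca_increment_per_ap < 0:
            raise ValueError("ca_increment_per_ap must be >= 0")


@dataclass
class SimState:
    """Instantaneous occupancies (site counts) and fusion state."""

    t: float
    ES: float
    LS: float
    TS: float
    TSL: float
    ERS: float
    p_fusion_now: float
    ca_now: float

    @property
    def total(self) -> float:
        return self.ES + self.LS + self.TS + self.TSL + self.ERS

    @property
    def frp(self) -> float:
        return self.LS + self.TS + self.TSL

    def as_vector(self) -> list:
        return [self.ES, self.LS, self.TS, self.TSL, self.ERS]


@dataclass(frozen=True)
class Protocol:
    """AP times of a stimulation protocol (s, strictly increasing)."""

    ap_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ap_times",
                           np.asarray(self.ap_times, dtype=float))
        t = self.ap_times
        if t.ndim != 1 or t.size < 1:
            raise ValueError("need at least one AP time")
        if np.any(np.diff(t) <= 0):
            raise ValueError("ap_times must be strictly increasing")

    @classmethod
    def regular_train(cls, f_hz: float, n_ap: int, start: float = 0.0) -> "Protocol":
        if f_hz <= 0 or n_ap < 1:
            raise ValueError("need f_hz > 0 and n_ap >= 1")
        return cls(start + np.arange(n_ap) / f_hz)

    def __len__(self) -> int:
        return int(self.ap_times.size)


@dataclass
class TrainResult:
    """Per-AP release and (optionally) continuous occupancy traces."""

    protocol: Protocol
    m: np.ndarray                 # quanta released per AP (expected counts)
    p_fusion: np.ndarray          # p_fusion applied at each AP
    ca_at_ap: np.ndarray          # global Ca (nM) just before each AP
    final_state: SimState
    trace_t: Optional[np.ndarray] = None
    trace: Optional[np.ndarray] = None   # columns ES, LS, TS, TSL, ERS

    @property
    def m1(self) -> float:
        return float(self.m[0])


WT_PARAMS = PrimingModelParams()
"""wt/- style defaults: f_TS = 0.7/(0.7+1.8) = 0.28, p_fusion = 0.34."""

HK_PARAMS = replace(WT_PARAMS, k2_rest=WT_PARAMS.k2_rest * 2.15,
                    sigma1=WT_PARAMS.sigma1 * 0.15, p_fusion_0=0.39)
"""HK/- style: k2_rest x2.15 (f_TS ~ 0.46), sigma1 strongly reduced."""

DEFAULT_CA_PARAMS = CaTransientParams()


def global_ca(params: CaTransientParams, ap_times: Sequence[float],
              t) -> np.ndarray | float:
    """Global [Ca2+] (nM) at time(s) ``t``: resting level plus linearly
    summating exponential transients from all APs at ``t_i <= t``."""
    t_arr = np.asarray(t, dtype=float)
    ap = np.asarray(ap_times, dtype=float)
    dt = t_arr[..., None] - ap
    contrib = np.where(dt >= 0, np.exp(-np.maximum(dt, 0.0) / params.tau_global), 0.0)
    ca = params.ca_rest + params.ca_increment_per_ap * contrib.sum(axis=-1)
    return float(ca) if np.isscalar(t) or t_arr.ndim == 0 else ca


def rate_constants(params: PrimingModelParams, ca: float,
                   ca_rest: float = 50.0) -> Tuple[float, float]:
    """Forward rates (k1, k2) in 1/s at global Ca ``ca`` (nM).

    Linear in supra-resting Ca (converted nM -> uM), capped at
    ``rate_cap``; monotone nondecreasing in ca.
    """
    if ca < 0:
        raise ValueError("ca must be >= 0")
    d = max(0.0, ca - ca_rest) / 1000.0   # uM above rest
    k1 = min(params.rate_cap, params.k1_rest + params.sigma1 * d)
    k2 = min(params.rate_cap, params.k2_rest + params.sigma2 * d)
    return k1, k2


def _p_fusion(params: PrimingModelParams, ca: float, ca_rest: float) -> float:
    d = max(0.0, ca - ca_rest) / 1000.0
    return min(params.p_fusion_max,
               params.p_fusion_0 * (1.0 + params.facilitation_gain * d))


def _deriv(p: PrimingModelParams, ca: float, ca_rest: float, y):
    es, ls, ts, tsl, ers = y
    d = max(0.0, ca - ca_rest) * 0.001
    k1 = p.k1_rest + p.sigma1 * d
    if k1 > p.rate_cap:
        k1 = p.rate_cap
    k2 = p.k2_rest + p.sigma2 * d
    if k2 > p.rate_cap:
        k2 = p.rate_cap
    rel_tsl = p.tsl_decay * tsl
    rel_ers = p.ers_decay * ers
    a = k1 * es - p.b1 * ls          # net ES -> LS
    c = k2 * ls - p.b2 * ts          # net LS -> TS
    return (-a + rel_ers, a - c + rel_tsl, c, -rel_tsl, -rel_ers)


def _rate_matrix(p: PrimingModelParams, ca: float, ca_rest: float) -> np.ndarray:
    """Generator matrix M with dy/dt = M @ y at fixed calcium."""
    k1, k2 = rate_constants(p, ca, ca_rest)
    M = np.zeros((5, 5))
    M[0, 0] = -k1;        M[0, 1] = p.b1;                M[0, 4] = p.ers_decay
    M[1, 0] = k1;         M[1, 1] = -(p.b1 + k2);        M[1, 2] = p.b2
    M[1, 3] = p.tsl_decay
    M[2, 1] = k2;         M[2, 2] = -p.b2
    M[3, 3] = -p.tsl_decay
    M[4, 4] = -p.ers_decay
    return M

# Residual Ca below this fraction of one AP increment is treated as
# fully decayed, allowing an exact matrix-exponential jump over long
# quiet stretches (recovery intervals of many seconds).
_CA_SETTLED_FRACTION = 1e-6


def _evolve(p: PrimingModelParams, cap: CaTransientParams, y, resid: float,
            duration: float, dt: float, trace=None, t0: float = 0.0):
    """RK4-integrate occupancies over ``duration`` starting with residual
    calcium ``resid`` (nM above rest) decaying exponentially.

    Once the residual transient has decayed to a negligible level the
    remaining stretch is advanced in one exact matrix-exponential step
    (the system is then linear and time-invariant).
    """
    if duration <= 0:
        return y, resid
    rest = cap.ca_rest
    tau = cap.tau_global
    settle = _CA_SETTLED_FRACTION * max(cap.ca_increment_per_ap, 1.0)
    # time until residual Ca is negligible
    t_settle = 0.0 if resid <= settle else tau * math.log(resid / settle)
    t_rk = min(duration, t_settle)
    n = int(math.ceil(t_rk / dt)) if t_rk > 0 else 0
    h = t_rk / n if n else 0.0
    fh = math.exp(-0.5 * h / tau) if n else 1.0
    f1 = fh * fh
    r = resid
    t = 0.0
    for _ in range(n):
        ca0 = rest + r
        cah = rest + r * fh
        ca1 = rest + r * f1
        k1v = _deriv(p, ca0, rest, y)
        y2 = [y[i] + 0.5 * h * k1v[i] for i in range(5)]
        k2v = _deriv(p, cah, rest, y2)
        y3 = [y[i] + 0.5 * h * k2v[i] for i in range(5)]
        k3v = _deriv(p, cah, rest, y3)
        y4 = [y[i] + h * k3v[i] for i in range(5)]
        k4v = _deriv(p, ca1, rest, y4)
        y = [y[i] + h / 6.0 * (k1v[i] + 2 * k2v[i] + 2 * k3v[i] + k4v[i])
             for i in range(5)]
        r *= f1
        t += h
        if trace is not None:
            trace.append((t0 + t, *y))
    if duration > t_rk:
        # calcium settled: exact propagation at resting rates
        M = _rate_matrix(p, rest, rest)
        y = list(expm(M * (duration - t_rk)) @ np.asarray(y))
        r = 0.0
        if trace is not None:
            trace.append((t0 + duration, *y))
    return y, r


def simulate_train(params: PrimingModelParams,
                   ca_params: CaTransientParams = DEFAULT_CA_PARAMS,
                   protocol: Protocol | None = None,
                   *,
                   dt: float = 1e-4,
                   initial_state: Optional[SimState] = None,
                   record_trace: bool = False,
                   check_accuracy: bool = False) -> TrainResult:
    """Mean-field simulation of evoked release for a protocol.

    Between APs the occupancies follow the linear kinetic scheme at
    calcium-dependent rates; at each AP, ``p_fusion_now * (TS + TSL)``
    quanta are released and the sites return to the empty pool (ERS
    when the labile extension is on, else ES); afterwards a fraction
    ``ap_conversion`` of LS tightens to TS (the AP's local calcium
    transient).  p_fusion is evaluated on the residual calcium just
    before the AP, so the first response of a resting synapse is
    exactly ``p_fusion_0 * TS_rest``.

    ``check_accuracy=True`` reruns at dt/2 and raises if any per-AP
    release changes by more than 0.1%.
    """
    if protocol is None:
        protocol = Protocol.regular_train(100.0, 40)
    if dt > 5e-4:
        raise ValueError("integration step dt must be <= 0.5 ms")
    if check_accuracy:
        a = simulate_train(params, ca_params, protocol, dt=dt)
        b = simulate_train(params, ca_params, protocol, dt=dt / 2)
        rel = np.max(np.abs(a.m - b.m) / np.maximum(np.abs(b.m), 1e-30))
        if rel > 1e-3:
            raise RuntimeError(
                f"step-size nonconvergence: halving dt changes m_j by {rel:.2e}")
        return b

    state = initial_state or params.resting_state()
    y = state.as_vector()
    resid = max(0.0, state.ca_now - ca_params.ca_rest) \
        if math.isfinite(state.ca_now) else 0.0
    trace = [] if record_trace else None
    t_now = state.t
    if trace is not None:
        trace.append((t_now, *y))
    ap_times = protocol.ap_times
    m_out = np.empty(len(protocol))
    p_out = np.empty(len(protocol))
    ca_out = np.empty(len(protocol))
    for i, t_ap in enumerate(ap_times):
        y, resid = _evolve(params, ca_params, y, resid, t_ap - t_now, dt,
                           trace, t_now)
        t_now = t_ap
        ca_now = ca_params.ca_rest + resid
        p_now = _p_fusion(params, ca_now, ca_params.ca_rest)
        released = p_now * (y[2] + y[3])
        y[2] -= p_now * y[2]
        y[3] -= p_now * y[3]
        if params.labile_enabled:
            y[4] += released
        else:
            y[0] += released
        conv = params.ap_conversion * y[1]   # local-Ca LS -> TS tightening
        y[1] -= conv
        y[2] += conv
        resid += ca_params.ca_increment_per_ap
        m_out[i] = released
        p_out[i] = p_now
        ca_out[i] = ca_now
        if trace is not None:
            trace.append((t_now, *y))
    final = SimState(t=t_now, ES=y[0], LS=y[1], TS=y[2], TSL=y[3], ERS=y[4],
                     p_fusion_now=p_out[-1], ca_now=ca_params.ca_rest + resid)
    res = TrainResult(protocol=protocol, m=m_out, p_fusion=p_out,
                      ca_at_ap=ca_out, final_state=final)
    if trace is not None:
        arr = np.asarray(trace)
        res.trace_t = arr[:, 0]
        res.trace = arr[:, 1:]
    return res


def simulate_recovery(params: PrimingModelParams,
                      ca_params: CaTransientParams = DEFAULT_CA_PARAMS,
                      conditioning: Protocol | None = None,
                      intervals: Sequence[float] = (0.125, 0.25, 0.5, 1, 2, 4, 8, 16),
                      *,
                      dt: float = 1e-4,
                      ss_window: int = 5) -> Tuple[np.ndarray, dict]:
    """Recovered release fraction after a conditioning train.

    For each interval the post-train state evolves under the decaying
    residual calcium, one test AP is delivered, and the recovered
    fraction (m_test - m_ss) / (m_1 - m_ss) is computed with m_1 and
    m_ss (mean of the last ``ss_window`` responses) taken from the
    conditioning train.  Returns (fractions, details).
    """
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0) or np.any(np.diff(intervals) < 0):
        raise ValueError("intervals must be positive and ascending")
    if conditioning is None:
        conditioning = Protocol.regular_train(200.0, 25)
    cond = simulate_train(params, ca_params, conditioning, dt=dt)
    m1 = cond.m1
    m_ss = float(np.mean(cond.m[-ss_window:]))
    fracs = np.empty(intervals.size)
    m_tests = np.empty(intervals.size)
    for i, iv in enumerate(intervals):
        t_test = conditioning.ap_times[-1] + iv
        test = simulate_train(params, ca_params, Protocol([t_test]), dt=dt,
                              initial_state=cond.final_state)
        m_tests[i] = test.m1
        fracs[i] = recovery_fraction(test.m1, m1, m_ss)
    return fracs, {"m1": m1, "m_ss": m_ss, "m_test": m_tests,
                   "intervals": intervals}


def simulate_train_stochastic(params: PrimingModelParams,
                              ca_params: CaTransientParams = DEFAULT_CA_PARAMS,
                              protocol: Protocol | None = None,
                              *,
                              seed: int | np.random.Generator,
                              dt: float = 2e-4,
                              initial_state: Optional[SimState] = None) -> TrainResult:
    """Stochastic (sampled) counterpart of :func:`simulate_train`.

    Site counts are integers; per-AP release is Binomial(TS, p_fusion)
    (plus Binomial(TSL, p_fusion) when labile states are enabled) and
    state transitions use tau-leaping with exact per-step exponential
    jump probabilities, so the expectation over replicates matches the
    mean-field trajectory.  Fully reproducible given the seed.
    """
    if protocol is None:
        protocol = Protocol.regular_train(100.0, 40)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    p = params
    rest = ca_params.ca_rest
    tau = ca_params.tau_global
    state0 = initial_state or p.resting_state()
    n_round = int(round(state0.total))
    # integer occupancies, largest-remainder rounding
    frac = np.array(state0.as_vector())
    y = np.floor(frac).astype(int)
    rem = n_round - y.sum()
    order = np.argsort(frac - np.floor(frac))[::-1]
    y[order[:rem]] += 1
    y = y.tolist()

    resid = 0.0
    t_now = 0.0
    m_out = np.empty(len(protocol))
    p_out = np.empty(len(protocol))
    ca_out = np.empty(len(protocol))
    decay = math.exp(-dt / tau)

    def leap(duration: float) -> None:
        nonlocal resid
        n = int(math.ceil(duration / dt))
        if n == 0:
            return
        h = duration / n
        fac = math.exp(-h / tau) if abs(h - dt) > 1e-15 else decay
        for _ in range(n):
            ca = rest + resid
            k1, k2 = rate_constants(p, ca, rest)
            # competing exits from LS: -> ES (b1) and -> TS (k2)
            tot_ls = p.b1 + k2
            p_leave = -math.expm1(-tot_ls * h)
            n_ls_out = rng.binomial(y[1], p_leave) if y[1] else 0
            n_ls_to_ts = rng.binomial(n_ls_out, k2 / tot_ls) if n_ls_out else 0
            n_ls_to_es = n_ls_out - n_ls_to_ts
            n_es_to_ls = rng.binomial(y[0], -math.expm1(-k1 * h)) if y[0] else 0
            n_ts_to_ls = rng.binomial(y[2], -math.expm1(-p.b2 * h)) if y[2] else 0
            n_tsl_to_ls = rng.binomial(y[3], -math.expm1(-p.tsl_decay * h)) if y[3] else 0
            n_ers_to_es = rng.binomial(y[4], -math.expm1(-p.ers_decay * h)) if y[4] else 0
            y[0] += n_ls_to_es + n_ers_to_es - n_es_to_ls
            y[1] += n_es_to_ls + n_ts_to_ls + n_tsl_to_ls - n_ls_out
            y[2] += n_ls_to_ts - n_ts_to_ls
            y[3] -= n_tsl_to_ls
            y[4] -= n_ers_to_es
            resid *= fac

    for i, t_ap in enumerate(protocol.ap_times):
        leap(t_ap - t_now)
        t_now = t_ap
        ca_now = rest + resid
        p_now = _p_fusion(p, ca_now, rest)
        rel_ts = rng.binomial(y[2], p_now) if y[2] else 0
        rel_tsl = rng.binomial(y[3], p_now) if (p.labile_enabled and y[3]) else 0
        y[2] -= rel_ts
        y[3] -= rel_tsl
        released = rel_ts + rel_tsl
        if p.labile_enabled:
            y[4] += released
        else:
            y[0] += released
        conv = rng.binomial(y[1], p.ap_conversion) if (p.ap_conversion and y[1]) else 0
        y[1] -= conv
        y[2] += conv
        resid += ca_params.ca_increment_per_ap
        m_out[i] = released
        p_out[i] = p_now
        ca_out[i] = ca_now
    final = SimState(t=t_now, ES=y[0], LS=y[1], TS=y[2], TSL=y[3], ERS=y[4],
                     p_fusion_now=p_out[-1], ca_now=rest + resid)
    return TrainResult(protocol=protocol, m=m_out, p_fusion=p_out,
                       ca_at_ap=ca_out, final_state=final)
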