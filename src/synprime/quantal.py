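"""Quantal analysis of evoked and spontaneous release records.

Evoked EPSC amplitudes (negative, pA) are converted to quantal contents
``m = amplitude / q*`` with an effective quantal size ``q*`` (default
-6.6 pA).  Train metrics (paired-pulse ratio, steady-state depression),
regressions through the origin for paired measurements, and binned
event rates for miniature-EPSC streams live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

DEFAULT_Q_STAR = -6.6
"""Effective quantal size in pA (negative inward current)."""

GENOTYPES = ("wt/wt", "wt/-", "HK/-", "DN/DN", "HK/DN", "KW/KW", "synthetic")

__all__ = [
    "DEFAULT_Q_STAR",
    "GENOTYPES",
    "QuantalTrain",
    "STPMetrics",
    "PairedMeasurements",
    "MiniEventStream",
    "epsc_to_quanta",
    "stp_metrics",
    "regression_through_origin",
    "binned_event_rate",
]


def epsc_to_quanta(
    amplitudes: Sequence[float],
    q_star: float = DEFAULT_Q_STAR,
    *,
    tolerance: float = 1e-9,
) -> np.ndarray:
    """Convert EPSC peak amplitudes (pA) to quantal contents.

    Both amplitudes and ``q_star`` follow the inward-current sign
    convention (negative), so the elementwise ratio is nonnegative.
    Tiny negative ratios (|m| < ``tolerance``), as can arise from
    baseline noise around zero, are clamped to 0 with a warning;
    larger sign mismatches raise.
    """
    if q_star == 0:
        raise ValueError("q_star must be nonzero")
    amps = np.asarray(amplitudes, dtype=float)
    m = amps / q_star
    neg = m < 0
    if np.any(neg):
        if np.all(np.abs(m[neg]) < tolerance):
            warnings.warn(
                "clamping tiny negative quantal contents to zero",
                RuntimeWarning,
                stacklevel=2,
            )
            m = np.where(neg, 0.0, m)
        else:
            raise ValueError(
                "amplitudes and q_star disagree in sign: negative quantal content"
            )
    return m


@dataclass
class QuantalTrain:
    """One evoked train: amplitudes and their quantal contents.

    Stimulus indexing is 1-based throughout (``m_j`` for stimulus j),
    so ``train.m_at(1)`` is the first response.
    """

    synapse_id: str
    f_stim: float
    amplitudes: np.ndarray
    genotype: str = "synthetic"
    q_star: float = DEFAULT_Q_STAR
    preconditioning: Optional[dict] = None
    m: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise ValueError("amplitudes must be a nonempty 1-D sequence")
        if self.f_stim <= 0:
            raise ValueError("f_stim must be positive (Hz)")
        self.m = epsc_to_quanta(self.amplitudes, self.q_star)

    def __len__(self) -> int:
        return int(self.m.size)

    def m_at(self, j: int) -> float:
        """Quantal content at 1-based stimulus index ``j``."""
        if not 1 <= j <= len(self):
            raise IndexError(f"stimulus index {j} outside 1..{len(self)}")
        return float(self.m[j - 1])

    @classmethod
    def from_quanta(
        cls,
        synapse_id: str,
        f_stim: float,
        m: Sequence[float],
        genotype: str = "synthetic",
        q_star: float = DEFAULT_Q_STAR,
        preconditioning: Optional[dict] = None,
    ) -> "QuantalTrain":
        """Build a train from quantal contents (amplitudes = q* · m)."""
        amps = np.asarray(m, dtype=float) * q_star
        return cls(synapse_id, f_stim, amps, genotype, q_star, preconditioning)


@dataclass(frozen=True)
class STPMetrics:
    """Short-term plasticity summary of one train."""

    ppr: float
    depression_ratio_10Hz: Optional[float]
    m1: float
    m_ss: float


def stp_metrics(
    train: QuantalTrain,
    ss_window: Optional[Tuple[int, int]] = None,
) -> STPMetrics:
    """Paired-pulse ratio, 5th/1st depression ratio and steady state.

    ``ss_window`` is an inclusive 1-based (start, end) stimulus range;
    default (35, 40) for trains of >= 40 stimuli, else the last five.
    """
    n = len(train)
    if ss_window is None:
        ss_window = (35, 40) if n >= 40 else (max(1, n - 4), n)
    lo, hi = ss_window
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"ss_window {ss_window} outside train of length {n}")
    m1 = train.m_at(1)
    if m1 == 0:
        raise ZeroDivisionError("m_1 is zero; PPR undefined")
    if n < 2:
        raise ValueError("need >= 2 stimuli for a paired-pulse ratio")
    ppr = train.m_at(2) / m1
    dep5 = train.m_at(5) / m1 if n >= 5 else None
    m_ss = float(np.mean(train.m[lo - 1 : hi]))
    return STPMetrics(ppr=ppr, depression_ratio_10Hz=dep5, m1=m1, m_ss=m_ss)


@dataclass
class PairedMeasurements:
    """Paired (x, y) observations for a regression through the origin."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D sequences")
        if self.x.size < 1:
            raise ValueError("need at least one point")


def regression_through_origin(
    pairs: PairedMeasurements,
) -> Tuple[float, Optional[float]]:
    """Least-squares slope of ``y = slope * x`` (intercept fixed at 0).

    Returns ``(slope, se)``; the closed form is slope = Σxy / Σx².
    The standard error uses the residual variance with n-1 degrees of
    freedom and is ``None`` for a single point (undefined).
    """
    x, y = pairs.x, pairs.y
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("degenerate design: all x are zero")
    slope = float(np.dot(x, y)) / sxx
    n = x.size
    if n < 2:
        return slope, None
    resid = y - slope * x
    s2 = float(np.dot(resid, resid)) / (n - 1)
    return slope, math.sqrt(s2 / sxx)


@dataclass
class MiniEventStream:
    """Timestamped spontaneous (miniature) events in one recording."""

    event_times: np.ndarray
    duration: float
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive (s)")
        t = self.event_times
        if t.size:
            if np.any(np.diff(t) < 0):
                raise ValueError("event times must be ascending")
            if t[0] < 0 or t[-1] > self.duration:
                raise ValueError("event times outside [0, duration]")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.shape != t.shape:
                raise ValueError("amplitudes must match event_times")


def binned_event_rate(stream: MiniEventStream, bin_width: float = 2.0) -> np.ndarray:
    """Mean event rate (Hz) in consecutive nonoverlapping bins.

    The trailing partial bin is dropped, not rescaled.  An empty
    stream yields all-zero rates.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive (s)")
    n_bins = int(stream.duration / bin_width + 1e-12)
    if n_bins == 0:
        return np.zeros(0)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(stream.event_times, bins=edges)
    return counts / bin_width
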