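"""Vesicle-pool and fusion-probability estimators.

The fast-releasing pool (FRP) is estimated per stimulation frequency
by back-extrapolating a line through the late cumulative quantal
release of a depressing train to stimulus 0 (FRP'), then corrected
for incomplete pool depletion by extrapolating 1/FRP' against 1/f_stim
to infinite frequency.  The release fraction F = m_1 / FRP is
corrected the same way.  A geometric series m_j = m_1 (1-p)^(j-1)
fitted to a differential release trace yields an independent fusion
probability, and the identities f_TS = k2/(k2+b2), F = f_TS * p_fusion
tie the estimators to the two-step scheme.  Errors use a balanced
bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .quantal import QuantalTrain

__all__ = [
    "PoolEstimates",
    "GeometricFit",
    "frp_prime",
    "correct_pool_across_frequencies",
    "release_fraction",
    "pool_estimates",
    "geometric_difference_fit",
    "fts_identity",
    "compound_release_fraction",
    "balanced_bootstrap",
]

logger = logging.getLogger(__name__)


def frp_prime(train: QuantalTrain,
              ss_window: Optional[Tuple[int, int]] = None) -> float:
    """Single-frequency pool estimate FRP' by back-extrapolation.

    An ordinary least-squares line is fitted to the cumulative quantal
    release C_j over the late (steady-state) stimuli and read out at
    j = 0; under ongoing replenishment at a constant rate, the
    intercept is the initially releasable pool.  ``ss_window`` is an
    inclusive 1-based range, default the last 10 stimuli.
    """
    n = len(train)
    if ss_window is None:
        ss_window = (max(1, n - 9), n)
    lo, hi = ss_window
    if not (1 <= lo < hi <= n):
        raise ValueError(f"ss_window {ss_window} invalid for train of length {n}")
    if np.any(train.m < 0):
        raise ValueError("negative quantal content; cumulative release not ascending")
    cum = np.cumsum(train.m)
    j = np.arange(lo, hi + 1, dtype=float)
    fit = linregress(j, cum[lo - 1: hi])
    if fit.slope < 0:
        warnings.warn("negative steady-state slope in FRP' fit", RuntimeWarning,
                      stacklevel=2)
    return float(fit.intercept)


def _line(x: np.ndarray, y: np.ndarray):
    fit = linregress(x, y)
    return fit.slope, fit.intercept, fit.rvalue ** 2


def correct_pool_across_frequencies(freqs: Sequence[float],
                                    frp_prime_values: Sequence[float],
                                    ) -> Tuple[float, dict]:
    """Depletion-corrected pool: 1/FRP' regressed on 1/f_stim, FRP =
    1/intercept at infinite frequency.  Returns (FRP, diagnostics)."""
    f = np.asarray(freqs, dtype=float)
    v = np.asarray(frp_prime_values, dtype=float)
    if f.size != v.size or f.size < 2:
        raise ValueError("need FRP' at >= 2 frequencies")
    if np.any(v <= 0) or np.any(f <= 0):
        raise ValueError("frequencies and FRP' values must be positive")
    slope, intercept, r2 = _line(1.0 / f, 1.0 / v)
    if intercept <= 0:
        raise ValueError("pool correction failed: nonpositive 1/FRP intercept")
    return 1.0 / intercept, {"slope": slope, "intercept": intercept, "r2": r2}


def release_fraction(m1: float, freqs: Sequence[float],
                     frp_prime_values: Sequence[float]) -> Tuple[float, dict]:
    """Depletion-corrected release fraction: F' = m1/FRP' regressed on
    1/f_stim, F = intercept at infinite frequency."""
    f = np.asarray(freqs, dtype=float)
    v = np.asarray(frp_prime_values, dtype=float)
    if f.size != v.size or f.size < 2:
        raise ValueError("need FRP' at >= 2 frequencies")
    if np.any(v <= 0) or np.any(f <= 0):
        raise ValueError("frequencies and FRP' values must be positive")
    if m1 == 0:
        warnings.warn("m1 is zero; release fraction degenerate at 0",
                      RuntimeWarning, stacklevel=2)
    fp = m1 / v
    slope, intercept, r2 = _line(1.0 / f, fp)
    return float(intercept), {"slope": slope, "intercept": intercept, "r2": r2}


@dataclass
class PoolEstimates:
    """Per-frequency and depletion-corrected pool/fraction estimates."""

    freqs: np.ndarray
    frp_prime: np.ndarray
    f_prime: np.ndarray
    frp: float
    F: float
    p_fusion: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def f_ts_implied(self) -> Optional[float]:
        """f_TS implied by F = f_TS * p_fusion, if p_fusion is known."""
        if not self.p_fusion:
            return None
        return self.F / self.p_fusion


def pool_estimates(trains_by_freq: dict,
                   ss_window: Optional[Tuple[int, int]] = None,
                   p_fusion: Optional[float] = None) -> PoolEstimates:
    """Full pool analysis from one synapse's trains keyed by frequency.

    m_1 is averaged over the supplied trains (it should not depend on
    frequency in a resting synapse).
    """
    freqs = np.array(sorted(trains_by_freq), dtype=float)
    fps = np.array([frp_prime(trains_by_freq[f], ss_window) for f in freqs])
    m1 = float(np.mean([trains_by_freq[f].m_at(1) for f in freqs]))
    frp, d1 = correct_pool_across_frequencies(freqs, fps)
    F, d2 = release_fraction(m1, freqs, fps)
    return PoolEstimates(freqs=freqs, frp_prime=fps, f_prime=m1 / fps,
                         frp=frp, F=F, p_fusion=p_fusion,
                         diagnostics={"pool_fit": d1, "fraction_fit": d2,
                                      "m1": m1})


@dataclass(frozen=True)
class GeometricFit:
    """Two-parameter geometric-series fit m_j = m1 (1-p)^(j-1)."""

    m1_hat: float
    p_fusion_hat: float
    rss: float


def geometric_difference_fit(delta_m: Sequence[float],
                             max_stimuli: int = 15) -> GeometricFit:
    """Fit a geometric series to a (differential) release trace.

    Bounded nonlinear least squares in the linear domain over stimuli
    1..``max_stimuli`` (or the full trace if shorter), so noisy zero or
    negative points need not be excluded; p is constrained to [0, 1].
    """
    y = np.asarray(delta_m, dtype=float)[:max_stimuli]
    if y.size < 3:
        raise ValueError("need >= 3 points for a geometric fit")
    if np.all(y <= 0):
        raise ValueError("all values nonpositive; geometric fit impossible")
    j = np.arange(1, y.size + 1, dtype=float)

    def model(jj, m1, p):
        return m1 * (1.0 - p) ** (jj - 1)

    p0_decay = 0.5
    if y[0] > 0 and y.size > 1 and 0 < y[1] < y[0]:
        p0_decay = min(0.95, max(0.05, 1.0 - y[1] / y[0]))
    theta, _ = curve_fit(model, j, y, p0=[max(y[0], 1e-6), p0_decay],
                         bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=20000)
    rss = float(np.sum((model(j, *theta) - y) ** 2))
    return GeometricFit(m1_hat=float(theta[0]), p_fusion_hat=float(theta[1]),
                        rss=rss)


def fts_identity(k2_rest: float, b2: float) -> float:
    """Resting tight-state fraction f_TS = k2_rest / (k2_rest + b2)."""
    if k2_rest < 0 or b2 < 0:
        raise ValueError("rates must be >= 0")
    denom = k2_rest + b2
    if denom == 0:
        raise ZeroDivisionError("k2_rest + b2 is zero; f_TS undefined")
    return k2_rest / denom


def compound_release_fraction(f_ts: float, p_fusion: float) -> float:
    """Release fraction as the product of two independent events:
    being tightly docked at AP arrival and fusing, F = f_TS * p_fusion."""
    if not 0 <= f_ts <= 1 or not 0 <= p_fusion <= 1:
        raise ValueError("f_ts and p_fusion must lie in [0, 1]")
    return f_ts * p_fusion


def balanced_bootstrap(statistic: Callable[[np.ndarray], float],
                       sample: Sequence[float], B: int = 1000, *,
                       seed: int | np.random.Generator = 0,
                       ci: float = 0.95,
                       return_resamples: bool = False):
    """Balanced-bootstrap percentile confidence interval.

    The ``B`` resamples are drawn by permuting ``B`` concatenated
    copies of the sample and cutting it into blocks of size n, so each
    observation appears exactly ``B`` times in aggregate.  Resamples on
    which the statistic raises are dropped (with a log message).
    Returns ``(lo, hi)`` or ``(lo, hi, values)``.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need a sample of size >= 2")
    if B < 100:
        raise ValueError("need B >= 100 resamples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.permutation(np.tile(np.arange(n), B)).reshape(B, n)
    values = []
    failures = 0
    for row in idx:
        try:
            values.append(float(statistic(x[row])))
        except Exception:
            failures += 1
    if failures:
        logger.warning("balanced_bootstrap: statistic failed on %d/%d resamples",
                       failures, B)
    if not values:
        raise ValueError("statistic failed on every resample")
    values = np.asarray(values)
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    if return_resamples:
        return float(lo), float(hi), values
    return float(lo), float(hi)
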