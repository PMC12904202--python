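"""Recovery-from-depression, posttetanic potentiation and cooperativity.

Recovery after a depleting train is expressed as the recovered
fraction (m_test - m_ss) / (m_1 - m_ss) and fitted with mono- or
bi-exponential time courses.  Posttetanic potentiation (PTP) is
quantified as the peak normalized response after tetanic stimulation
and the time for the potentiation to decay to half of its peak.
Power-law calcium cooperativity converts a change in calcium into a
predicted fold change of release.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RecoveryCurve",
    "PTPResult",
    "recovery_fraction",
    "fit_recovery",
    "ptp_quantify",
    "cooperativity_prediction",
]

DEFAULT_RECOVERY_INTERVALS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


def recovery_fraction(m_test: float, m1: float, m_ss: float) -> float:
    """Recovered release fraction (m_test - m_ss) / (m_1 - m_ss).

    0 when the test response is still at steady-state depression,
    1 when it has returned to the initial response.
    """
    if m1 == m_ss:
        raise ZeroDivisionError("m1 equals m_ss; recovered fraction undefined")
    return (m_test - m_ss) / (m1 - m_ss)


@dataclass
class RecoveryCurve:
    """Recovery time course and (after fitting) its exponential fit.

    ``amplitudes``/``tau`` hold the fitted components of
    ``f(t) = 1 - sum_i A_i * exp(-t / tau_i)``.
    """

    intervals: np.ndarray
    fractions: np.ndarray
    model: Optional[str] = None          # "mono" | "bi"
    amplitudes: Optional[np.ndarray] = None
    tau: Optional[np.ndarray] = None
    rss: Optional[float] = None
    converged: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.intervals.shape != self.fractions.shape:
            raise ValueError("intervals and fractions must have equal length")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def predict(self, t) -> np.ndarray:
        if self.amplitudes is None:
            raise ValueError("curve has not been fitted")
        t = np.asarray(t, dtype=float)
        return 1.0 - sum(a * np.exp(-t / tau)
                         for a, tau in zip(self.amplitudes, self.tau))


def _fit_exp(t: np.ndarray, f: np.ndarray, n_comp: int,
             amp_sum_max: float) -> Tuple[np.ndarray, np.ndarray, float]:
    # the total amplitude is bounded (sum A_i <= amp_sum_max), so the
    # two-component model is parameterized as (A_total, weight, taus)
    span = float(t.max())

    if n_comp == 1:
        def model(tt, a, tau):
            return 1.0 - a * np.exp(-tt / tau)

        p0 = [max(1e-3, 1.0 - f.min()), np.median(t)]
        lo = [0.0, 1e-6]
        hi = [amp_sum_max, 100 * span]
        theta, _ = curve_fit(model, t, f, p0=p0, bounds=(lo, hi),
                             maxfev=20000)
        amps = np.array([theta[0]])
        taus = np.array([theta[1]])
        resid = model(t, *theta) - f
    else:
        def model(tt, a_tot, w, tau1, tau2):
            return 1.0 - a_tot * (w * np.exp(-tt / tau1)
                                  + (1.0 - w) * np.exp(-tt / tau2))

        a_tot0 = min(amp_sum_max, max(1e-2, 1.0 - f.min()))
        lo = [0.0, 0.0, 1e-6, 1e-6]
        hi = [amp_sum_max, 1.0, 100 * span, 100 * span]
        med = float(np.median(t))
        best = None
        # deterministic multistart: time constants a decade apart in
        # several positions guard against the local minima of the
        # strongly correlated (w, tau) surface
        for tau1_0, tau2_0, w0 in ((t.min(), 4 * med, 0.5),
                                   (0.1 * med, 2 * med, 0.4),
                                   (0.3 * med, 8 * med, 0.6)):
            try:
                theta, _ = curve_fit(model, t, f,
                                     p0=[a_tot0, w0, tau1_0, tau2_0],
                                     bounds=(lo, hi), maxfev=20000)
            except RuntimeError:
                continue
            rss_c = float(np.sum((model(t, *theta) - f) ** 2))
            if best is None or rss_c < best[0]:
                best = (rss_c, theta)
        if best is None:
            raise RuntimeError("bi-exponential fit failed to converge")
        a_tot, w, tau1, tau2 = best[1]
        amps = np.array([a_tot * w, a_tot * (1.0 - w)])
        taus = np.array([tau1, tau2])
        resid = model(t, *theta) - f
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    rss = float(np.sum(resid ** 2))
    return amps, taus, rss


def fit_recovery(curve: RecoveryCurve, model: str = "mono", *,
                 amp_sum_max: float = 1.05,
                 f_ratio: float = 6.0) -> RecoveryCurve:
    """Fit ``1 - sum A_i exp(-t/tau_i)`` to a recovery time course.

    ``model``: "mono" (one component), "bi" (two), or "auto", which
    keeps the bi-exponential only when it lowers the residual sum of
    squares by the F-ratio criterion
    ``((rss_mono - rss_bi)/2) / (rss_bi/(n - 4)) > f_ratio``.
    The total fitted amplitude is bounded by ``amp_sum_max``.
    """
    t, f = curve.intervals, curve.fractions
    if model not in ("mono", "bi", "auto"):
        raise ValueError("model must be 'mono', 'bi' or 'auto'")
    n = t.size
    if model in ("mono", "auto") and n < 3:
        raise ValueError("need >= 3 points for a mono-exponential fit")
    if model == "bi" and n < 5:
        raise ValueError("need >= 5 points for a bi-exponential fit")
    out = RecoveryCurve(t, f)
    try:
        if model == "auto":
            a1, tau1, rss1 = _fit_exp(t, f, 1, amp_sum_max)
            chosen = ("mono", a1, tau1, rss1)
            if n >= 5:
                try:
                    a2, tau2, rss2 = _fit_exp(t, f, 2, amp_sum_max)
                    dof = n - 4
                    if dof > 0 and rss2 > 0:
                        F = ((rss1 - rss2) / 2.0) / (rss2 / dof)
                        if F > f_ratio:
                            chosen = ("bi", a2, tau2, rss2)
                    elif rss2 == 0 and rss1 > 0:
                        chosen = ("bi", a2, tau2, rss2)
                except RuntimeError:
                    pass
            out.model, out.amplitudes, out.tau, out.rss = chosen
        else:
            n_comp = 1 if model == "mono" else 2
            amps, taus, rss = _fit_exp(t, f, n_comp, amp_sum_max)
            out.model, out.amplitudes, out.tau, out.rss = model, amps, taus, rss
        out.converged = True
    except RuntimeError:
        out.model = model
        out.converged = False
    return out


@dataclass(frozen=True)
class PTPResult:
    """Posttetanic potentiation magnitude and decay half-time."""

    fold: float
    t_half: Optional[float]
    baseline_mean: float
    fold_at_first_point: float


def ptp_quantify(times: Sequence[float], amplitudes: Sequence[float], *,
                 peak_window: float = 60.0,
                 smooth: bool = False) -> PTPResult:
    """Quantify posttetanic potentiation from an amplitude time series.

    ``times`` are seconds relative to tetanus end (pre-tetanus points
    at t < 0, post-tetanus at t >= 0, typically 15-s spacing).
    Amplitudes are renormalized to the mean of the pre-tetanus points,
    so the result is invariant to baseline scaling.  ``fold`` is the
    maximum normalized amplitude within ``peak_window`` s after the
    tetanus (optionally 3-point smoothed); ``t_half`` is the first
    time, by linear interpolation, at which the potentiation
    (value - 1) decays to half its peak, or None when fold <= 1.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(amplitudes, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("times and amplitudes must be equal-length 1-D")
    pre = t < 0
    if pre.sum() == 0:
        baseline = 1.0   # series supplied already normalized
    elif pre.sum() < 3:
        raise ValueError("need >= 3 pre-tetanus points for the baseline")
    else:
        baseline = float(a[pre].mean())
    if baseline <= 0:
        raise ValueError("nonpositive baseline")
    norm = a / baseline
    post = t >= 0
    tp, vp = t[post], norm[post]
    if tp.size < 2:
        raise ValueError("need >= 2 post-tetanus points")
    v_eval = vp.copy()
    if smooth and vp.size >= 3:
        v_eval[1:-1] = (vp[:-2] + vp[1:-1] + vp[2:]) / 3.0
    in_win = tp <= peak_window
    if not np.any(in_win):
        in_win = np.zeros_like(tp, bool)
        in_win[0] = True
    i_peak = int(np.argmax(np.where(in_win, v_eval, -np.inf)))
    fold = float(v_eval[i_peak])
    if fold <= 1.0:
        return PTPResult(fold=fold, t_half=None, baseline_mean=baseline,
                         fold_at_first_point=float(vp[0]))
    target = 1.0 + (fold - 1.0) / 2.0
    t_half = None
    for k in range(i_peak, tp.size - 1):
        v0, v1 = v_eval[k], v_eval[k + 1]
        if v0 >= target >= v1:
            if v0 == v1:
                t_half = float(tp[k])
            else:
                t_half = float(tp[k] + (v0 - target) / (v0 - v1)
                               * (tp[k + 1] - tp[k]))
            break
    return PTPResult(fold=fold, t_half=t_half, baseline_mean=baseline,
                     fold_at_first_point=float(vp[0]))


def cooperativity_prediction(ca_pre: float, ca_post: float,
                             slope: float) -> float:
    """Predicted fold change of release for a calcium change, assuming
    a power law with exponent ``slope`` on the log-log relationship:
    (ca_post / ca_pre) ** slope."""
    if ca_pre <= 0 or ca_post <= 0:
        raise ValueError("calcium concentrations must be positive")
    return (ca_post / ca_pre) ** slope
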