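"""Scalar indices and fits extracted from BO signal traces.

Two timing indices summarize a trace: the *decay time* (first time after a
stimulus switch at which the smoothed signal loses the sign it held before
the switch — the moment the two BO populations reach similar activity) and
the *response time* (first time the smoothed signal exceeds a 10 Hz
detection level).  Exponential fits over the post-switch window give the
slope of the signal change.  Trial populations are compared with Welch's
t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import BOTrace

__all__ = [
    "smooth_trace",
    "decay_time",
    "response_time",
    "fit_exponential",
    "compare_conditions",
    "summarize",
    "ConditionSummary",
    "ExpFit",
]

log = logging.getLogger(__name__)


def smooth_trace(trace: BOTrace, window_ms: float = 5.0) -> np.ndarray:
    """Centered moving average of the BO signal.

    The +-0.25 current noise leaves ripple on nu whose zero-mean excursions
    would otherwise trigger spurious threshold crossings; a short moving
    average (default 5 ms, half the membrane time constant) suppresses the
    ripple without shifting crossing times materially.
    """
    if window_ms <= 0:
        return trace.nu.copy()
    n = max(1, int(round(window_ms / trace.dt)))
    if n % 2 == 0:
        n += 1
    kernel = np.full(n, 1.0 / n)
    padded = np.pad(trace.nu, n // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def decay_time(
    trace: BOTrace, switch_time: float, window_ms: float = 5.0
) -> float | None:
    """First time >= switch_time at which nu loses its pre-switch sign.

    The sign is taken from the mean smoothed signal over the 50 ms leading
    up to the switch.  Returns None when the trace never reaches zero (the
    caller excludes such trials from averages with a logged count).
    """
    if switch_time >= trace.times[-1]:
        raise ValueError("trace ends before the switch time")
    nu = smooth_trace(trace, window_ms)
    i_switch = int(np.searchsorted(trace.times, switch_time))
    i_pre = max(0, i_switch - int(round(50.0 / trace.dt)))
    pre = float(np.mean(nu[i_pre:i_switch])) if i_switch > i_pre else nu[i_switch]
    sign = 1.0 if pre >= 0 else -1.0
    post = sign * nu[i_switch:]
    hit = np.flatnonzero(post <= 0.0)
    if hit.size == 0:
        return None
    return float(trace.times[i_switch + hit[0]])


def response_time(
    trace: BOTrace,
    threshold_hz: float = 10.0,
    window_ms: float = 5.0,
    after: float = 0.0,
) -> float | None:
    """First time the smoothed signal exceeds the detection threshold."""
    if threshold_hz <= 0:
        raise ValueError("threshold must be positive")
    nu = smooth_trace(trace, window_ms)
    i0 = int(np.searchsorted(trace.times, after))
    hit = np.flatnonzero(nu[i0:] > threshold_hz)
    if hit.size == 0:
        return None
    return float(trace.times[i0 + hit[0]])


@dataclass
class ExpFit:
    """Exponential decay fit ``a * exp(-(t - t0)/tau_fit) + c`` over a window."""

    amplitude: float        #: a, Hz
    tau_fit: float          #: ms
    offset: float           #: c, Hz
    window: tuple[float, float]
    converged: bool

    @property
    def slope_at_start(self) -> float:
        """Initial signal change in Hz per second (negative for decay)."""
        return -self.amplitude / self.tau_fit * 1000.0

    def derivative(self, t_rel: np.ndarray) -> np.ndarray:
        """|d nu/dt| in Hz/s at times relative to the window start."""
        return np.abs(
            self.amplitude / self.tau_fit * np.exp(-t_rel / self.tau_fit) * 1000.0
        )


def fit_exponential(
    trace: BOTrace, window: tuple[float, float] = (500.0, 1000.0)
) -> ExpFit:
    """Least-squares exponential fit of the smoothed signal over a window."""
    t0, t1 = window
    if not (trace.times[0] <= t0 < t1 <= trace.times[-1] + 1e-9):
        raise ValueError("fit window outside trace")
    sel = (trace.times >= t0) & (trace.times <= t1)
    t_rel = trace.times[sel] - t0
    # least squares absorbs the noise ripple itself; smoothing first would
    # leak pre-window samples into the fit
    y = trace.nu[sel]
    a0 = y[0] - y[-1]
    c0 = y[-1]
    tau0 = max((t1 - t0) / 4.0, 1.0)

    def f(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    try:
        popt, _ = optimize.curve_fit(
            f, t_rel, y, p0=(a0, tau0, c0), maxfev=20000,
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e7, np.inf]),
        )
        converged = True
    except RuntimeError:
        popt = (a0, tau0, c0)
        converged = False
        log.warning("exponential fit did not converge; window %s", window)
    return ExpFit(float(popt[0]), float(popt[1]), float(popt[2]), window, converged)


def compare_conditions(a, b) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between two scalar populations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with distinct means")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


@dataclass
class ConditionSummary:
    """Per-condition trial statistics for one scalar index."""

    condition: str
    values: np.ndarray              #: per-trial scalars (crossings found)
    n_missing: int = 0              #: trials without a crossing, excluded
    tests: dict = field(default_factory=dict)  #: other condition -> (t, p)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def se(self) -> float:
        return float(np.std(self.values, ddof=1) / math.sqrt(len(self.values)))


def summarize(condition: str, raw_values) -> ConditionSummary:
    """Collect per-trial scalars, dropping and counting missing crossings."""
    vals = [v for v in raw_values if v is not None]
    missing = len(raw_values) - len(vals)
    if missing:
        log.warning("%s: %d trial(s) without crossing excluded", condition, missing)
    if not vals:
        raise ValueError(f"no usable trials for condition {condition!r}")
    return ConditionSummary(condition, np.asarray(vals, dtype=float), missing)
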