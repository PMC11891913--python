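"""Peptide adsorption/insertion into Langmuir lipid monolayers.

A peptide injected beneath a lipid monolayer at initial surface pressure
``pi0`` raises the pressure by ``delta_pi = pi_end - pi0`` as it adsorbs and
inserts.  ``pi_end`` is evaluated as a window mean around 35 min after
injection; plotting ``delta_pi`` against ``pi0`` over a series of monolayers
and extrapolating the (usually negative) linear trend to ``delta_pi = 0``
yields the maximal insertion pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .containers import MonolayerTrace
from .meta import ValidationError

#: Baseline is "constant" if its sd over the pre-injection window stays below
#: this (mN/m).
BASELINE_SD_LIMIT = 0.2


@dataclass
class MonolayerResult:
    """Surface-pressure change for one trace."""

    pi0: float
    pi_end: float
    delta_pi: float
    baseline_sd: float
    qc_flags: frozenset[str] = frozenset()


@dataclass
class InsertionRegression:
    """OLS of delta_pi on pi0; x-intercept is the maximal insertion pressure."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    x_intercept: float | None
    qc_flags: frozenset[str] = frozenset()


def initial_pressure(trace: MonolayerTrace, window_s: float = 600.0
                     ) -> tuple[float, float, frozenset[str]]:
    """Mean surface pressure over the pre-injection baseline window.

    Returns ``(pi0, baseline_sd, qc_flags)``; a baseline sd above
    ``BASELINE_SD_LIMIT`` flags ``unstable_baseline``.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    t0 = trace.injection_time - window_s
    if t0 < trace.time[0]:
        raise ValidationError(
            f"baseline window of {window_s} s exceeds the "
            f"{trace.injection_time - trace.time[0]:.0f} s pre-injection span")
    mask = (trace.time >= t0) & (trace.time <= trace.injection_time)
    window = trace.pressure[mask]
    pi0 = float(np.mean(window))
    sd = float(np.std(window, ddof=0))
    flags = frozenset({"unstable_baseline"}) if sd > BASELINE_SD_LIMIT else frozenset()
    return pi0, sd, flags


def delta_pi(trace: MonolayerTrace, t_eval_min: float = 35.0,
             avg_window_s: float = 120.0,
             baseline_window_s: float = 600.0) -> MonolayerResult:
    """Surface-pressure change ``pi_end - pi0`` at ``t_eval_min`` after injection.

    ``pi_end`` is the mean pressure over the ``avg_window_s`` window ending
    ``t_eval_min`` minutes after the injection; may be negative.
    """
    t_eval = trace.injection_time + t_eval_min * 60.0
    if trace.time[-1] < t_eval:
        raise ValidationError(
            f"trace ends {trace.time[-1]:.0f} s but pi_end evaluation needs "
            f"{t_eval:.0f} s ({t_eval_min} min after injection)")
    pi0, sd, flags = initial_pressure(trace, baseline_window_s)
    mask = (trace.time >= t_eval - avg_window_s) & (trace.time <= t_eval)
    pi_end = float(np.mean(trace.pressure[mask]))
    return MonolayerResult(pi0=pi0, pi_end=pi_end, delta_pi=pi_end - pi0,
                           baseline_sd=sd, qc_flags=flags)


def insertion_regression(points: list[tuple[float, float]]) -> InsertionRegression:
    """OLS fit of delta_pi versus pi0 across a monolayer series.

    Requires >= 3 points spanning >= 10 mN/m in pi0.  The x-intercept
    ``-intercept/slope`` (maximal insertion pressure) is reported only for a
    negative slope; otherwise it is ``None`` and flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 (pi0, delta_pi) points")
    pi0, dpi = pts[:, 0], pts[:, 1]
    if np.ptp(pi0) < 10.0:
        raise ValidationError(
            f"pi0 spread {np.ptp(pi0):.2f} mN/m is degenerate (need >= 10)")
    model = sm.OLS(dpi, sm.add_constant(pi0))
    fit = model.fit()
    intercept, slope = fit.params
    intercept_se, slope_se = fit.bse
    flags: set[str] = set()
    if slope < 0:
        x_int = float(-intercept / slope)
    else:
        x_int = None
        flags.add("nonnegative_slope")
    return InsertionRegression(slope=float(slope), intercept=float(intercept),
                               slope_se=float(slope_se),
                               intercept_se=float(intercept_se),
                               x_intercept=x_int, qc_flags=frozenset(flags))
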