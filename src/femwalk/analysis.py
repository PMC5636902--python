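"""Trial-averaged correlation analysis pipeline.

Bundles the per-trial MSD/DACF estimation, trial averaging, scaling
fits over the canonical short (2-12 ms) and long (120-1200 ms) windows,
and DACF oscillation metrics into one report, computed for the 2-D
trajectory and for each movement component.  Curves are always computed
per trial and then averaged; trials are never concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrialSet, Trajectory
from .correlation import (
    DEFAULT_K,
    LONG_RANGE_MS,
    SHORT_RANGE_MS,
    CorrelationCurve,
    OscillationMetrics,
    ScalingFit,
    average_curves,
    dacf,
    fit_scaling_exponent,
    msd,
    oscillation_metrics,
)

__all__ = ["ComponentReport", "AnalysisReport", "analyze_trials", "report_dict"]


@dataclass
class ComponentReport:
    """Averaged curves and summaries for one component (or the 2-D walk)."""

    msd: CorrelationCurve
    dacf: CorrelationCurve
    alpha_short: ScalingFit
    alpha_long: ScalingFit
    oscillation: OscillationMetrics


@dataclass
class AnalysisReport:
    full: ComponentReport  # 2-D (components summed in the MSD sense)
    horizontal: ComponentReport | None
    vertical: ComponentReport | None
    n_trials: int


def _component_report(
    trials: list[Trajectory],
    component: int | None,
    k: int,
    msd_max_lag: int,
    dacf_max_lag: int,
    short_range: tuple[float, float],
    long_range: tuple[float, float],
) -> ComponentReport:
    msd_avg = average_curves([msd(t, msd_max_lag, component=component) for t in trials])
    dacf_avg = average_curves(
        [dacf(t, k=k, max_lag=dacf_max_lag, component=component) for t in trials]
    )
    return ComponentReport(
        msd=msd_avg,
        dacf=dacf_avg,
        alpha_short=fit_scaling_exponent(msd_avg, short_range),
        alpha_long=fit_scaling_exponent(msd_avg, long_range),
        oscillation=oscillation_metrics(dacf_avg),
    )


def analyze_trials(
    trials: TrialSet | list[Trajectory],
    k: int = DEFAULT_K,
    msd_max_lag: int = 650,
    dacf_max_lag: int = 300,
    short_range: tuple[float, float] = SHORT_RANGE_MS,
    long_range: tuple[float, float] = LONG_RANGE_MS,
    components: bool = True,
) -> AnalysisReport:
    """Full correlation characterisation of a set of trials."""
    tl = list(trials.trials) if isinstance(trials, TrialSet) else list(trials)
    if not tl:
        raise ValueError("no trials to analyse")
    full = _component_report(
        tl, None, k, msd_max_lag, dacf_max_lag, short_range, long_range
    )
    hor = ver = None
    if components and tl[0].n_dim == 2:
        hor = _component_report(tl, 0, k, msd_max_lag, dacf_max_lag, short_range, long_range)
        ver = _component_report(tl, 1, k, msd_max_lag, dacf_max_lag, short_range, long_range)
    return AnalysisReport(full=full, horizontal=hor, vertical=ver, n_trials=len(tl))


def _comp_dict(c: ComponentReport) -> dict:
    osc = c.oscillation
    return {
        "alpha_short": c.alpha_short.alpha,
        "alpha_long": c.alpha_long.alpha,
        "oscillation_detected": osc.detected,
        "first_max_lag_ms": osc.first_max_lag_ms,
        "period_ms": osc.period_ms,
        "delay_bounds_ms": list(osc.delay_bounds_ms) if osc.delay_bounds_ms else None,
        "peak_value": osc.peak_value,
    }


def report_dict(rep: AnalysisReport) -> dict:
    """JSON-ready summary (the `fem analyze` fit report)."""
    out = {"n_trials": rep.n_trials, "full": _comp_dict(rep.full)}
    if rep.horizontal is not None:
        out["horizontal"] = _comp_dict(rep.horizontal)
        out["vertical"] = _comp_dict(rep.vertical)
    return out
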