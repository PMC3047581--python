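"""Kinetic-anomaly diagnostics.

Three pathologies make amplification kinetics deviate from the linear
efficiency model, and each biases E_max — hence the quantity — if its
cycles leak into the LRE window:

plateau drift
    Fluorescence keeps rising beyond the predicted plateau; late points
    drift progressively *above* the LRE line (E_max underestimated,
    quantity overestimated).
profile collapse
    Amplification falters late (primer or enzyme limitation); late points
    drift progressively *below* the line (E_max overestimated, quantity
    underestimated).
profile arcing
    The whole efficiency-vs-fluorescence relation is smoothly curved
    rather than linear (some enzyme formulations); the model simply does
    not hold and quantification is unreliable.

The window selector — not this module — is what excludes aberrant cycles;
classification only annotates the profile.  Drift and collapse are judged
from the trend of efficiency residuals over the cycles just above the
final window; arcing from poor window linearity, significant within-window
curvature, or systematically positive residuals *below* the window (drift
and collapse act only above the window, arcing bends both sides away from
it).  All thresholds are configurable; the defaults are package choices —
the pathologies are defined in the literature only pictorially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .core import BaselinedProfile, LreFit, LreWindow

__all__ = [
    "Kinetics",
    "DiagnosticsConfig",
    "KineticsReport",
    "post_window_residual_trend",
    "classify_kinetics",
]


class Kinetics(str, Enum):
    CONFORMING = "conforming"
    PLATEAU_DRIFT = "plateau_drift"
    PROFILE_COLLAPSE = "profile_collapse"
    ARCING = "arcing"
    NON_AMPLIFYING = "non_amplifying"


@dataclass(frozen=True)
class DiagnosticsConfig:
    """Thresholds for kinetic classification.

    drift_threshold
        |drift score| (residual-slope per cycle, in units of E_max) beyond
        which drift/collapse is called.
    r2_min
        Window r-squared below which the profile is called arcing.
    curvature_t
        |t| of the quadratic term of within-window residuals beyond which
        arcing is called; only tested on windows of at least
        ``curvature_min_window`` cycles (a quadratic t-test needs degrees
        of freedom to mean anything).
    below_threshold
        Mean below-window residual (units of E_max) beyond which arcing is
        called.
    lookahead
        Maximum number of post-window cycles entering the residual-trend
        score; the score is the steepest trend over spans of 3 up to this
        many cycles, so a long stalled plateau cannot dilute an abrupt
        deviation and a late-starting ramp is still reached.
    """

    drift_threshold: float = 0.05
    r2_min: float = 0.90
    curvature_t: float = 3.0
    curvature_min_window: int = 8
    # statistical significance alone is not enough: the quadratic term must
    # also bend the window by a material fraction of E_max.
    curvature_min_effect: float = 0.02
    below_threshold: float = 0.05
    below_floor_fraction: float = 0.01  # of fitted fmax
    min_below_cycles: int = 3
    lookahead: int = 6
    min_trend_cycles: int = 3
    # r-squared of 3-4 noisy points is too unstable to call arcing on.
    r2_min_window: int = 5


@dataclass
class KineticsReport:
    """Classification of one profile's amplification kinetics."""

    classification: Kinetics
    drift_score: float | None
    window_r2: float | None
    below_window_mean: float | None = None
    curvature_t_stat: float | None = None
    notes: str = ""


def _residual(profile: BaselinedProfile, fit: LreFit, cycle: int) -> float:
    return profile.ec_at(cycle) - (fit.emax + fit.delta_e * profile.fc_at(cycle))


def post_window_residual_trend(
    profile: BaselinedProfile,
    fit: LreFit,
    window: LreWindow,
    config: DiagnosticsConfig | None = None,
) -> float | None:
    """Signed trend of efficiency residuals above the LRE window.

    Residuals r_C = E_C - (E_max + dE * F_C) are taken for the cycles
    immediately above the window (wherever E_C is defined).  The score is
    the steepest slope of r_C versus cycle over the leading 3 to
    ``lookahead`` residuals, divided by E_max so it is dimensionless per
    cycle.  Scanning several spans matters because the deviation onset
    sits an unknown 0-3 cycles above wherever expansion stopped: a short
    span catches an abrupt stall (collapse) before the flat stalled tail
    dilutes it, a long one reaches a ramp that starts beyond the first
    clean post-window cycles (drift).  Positive means points drifting
    above the LRE line (plateau drift), negative means collapse.  ``None``
    when fewer than three eligible cycles exist.
    """
    config = config or DiagnosticsConfig()
    cycles, resid = [], []
    for c in range(window.end_cycle + 1, profile.n_cycles + 1):
        r = _residual(profile, fit, c)
        if math.isfinite(r):
            cycles.append(c)
            resid.append(r)
        if len(cycles) >= config.lookahead:
            break
    if len(cycles) < config.min_trend_cycles:
        return None
    best = 0.0
    for span in range(config.min_trend_cycles, len(cycles) + 1):
        slope = stats.linregress(cycles[:span], resid[:span]).slope
        if abs(slope) > abs(best):
            best = float(slope)
    return best / fit.emax


def _below_window_mean(
    profile: BaselinedProfile,
    fit: LreFit,
    window: LreWindow,
    config: DiagnosticsConfig,
) -> float | None:
    """Mean efficiency residual of the rise cycles below the window."""
    floor = config.below_floor_fraction * fit.fmax
    resid = []
    for c in range(2, window.start_cycle):
        if profile.fc_at(c) < floor:
            continue
        r = _residual(profile, fit, c)
        if math.isfinite(r):
            resid.append(r)
    if len(resid) < config.min_below_cycles:
        return None
    return float(np.mean(resid) / fit.emax)


def _window_curvature(
    profile: BaselinedProfile, fit: LreFit, window: LreWindow
) -> tuple[float, float] | None:
    """(t statistic, effect size) of the quadratic term of E_C vs F_C
    inside the window; effect = peak bend across the window in units of
    E_max."""
    n = window.size
    x = np.array([profile.fc_at(c) for c in window.cycles])
    y = np.array([profile.ec_at(c) for c in window.cycles])
    x = x - x.mean()  # center to decorrelate the quadratic term
    X = np.column_stack([np.ones(n), x, x * x])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = n - 3
    if dof < 1 or rank < 3:
        return None
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[2, 2])
    if se == 0:
        return None
    effect = abs(beta[2]) * float(np.max(x * x)) / fit.emax
    return float(beta[2] / se), effect


def classify_kinetics(
    profile: BaselinedProfile,
    fit: LreFit | None,
    window: LreWindow | None,
    trace: object | None = None,
    config: DiagnosticsConfig | None = None,
) -> KineticsReport:
    """Classify one profile's kinetics.  Annotation only — quantities are
    never altered here."""
    config = config or DiagnosticsConfig()
    if fit is None or window is None or not fit.valid:
        return KineticsReport(
            classification=Kinetics.NON_AMPLIFYING,
            drift_score=None,
            window_r2=None if fit is None else fit.r2,
            notes="no valid LRE fit",
        )
    score = post_window_residual_trend(profile, fit, window, config)
    below = _below_window_mean(profile, fit, window, config)
    curv_t = curv_effect = None
    if window.size >= config.curvature_min_window:
        curv = _window_curvature(profile, fit, window)
        if curv is not None:
            curv_t, curv_effect = curv

    curved = (
        curv_t is not None
        and abs(curv_t) > config.curvature_t
        and curv_effect > config.curvature_min_effect
    )
    if window.size >= config.r2_min_window and fit.r2 < config.r2_min:
        cls, notes = Kinetics.ARCING, f"window r2 {fit.r2:.3f} < {config.r2_min}"
    elif curved:
        cls, notes = (
            Kinetics.ARCING,
            f"window curvature |t| {abs(curv_t):.1f}, "
            f"bend {curv_effect:.3f} of E_max",
        )
    elif below is not None and below > config.below_threshold:
        cls, notes = (
            Kinetics.ARCING,
            f"below-window residuals +{below:.3f} of E_max",
        )
    elif score is not None and score > config.drift_threshold:
        cls, notes = Kinetics.PLATEAU_DRIFT, f"residual trend +{score:.3f}/cycle"
    elif score is not None and score < -config.drift_threshold:
        cls, notes = Kinetics.PROFILE_COLLAPSE, f"residual trend {score:.3f}/cycle"
    else:
        cls, notes = Kinetics.CONFORMING, ""
    return KineticsReport(
        classification=cls,
        drift_score=score,
        window_r2=fit.r2,
        below_window_mean=below,
        curvature_t_stat=curv_t,
        notes=notes,
    )
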