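"""Automated LRE window selection.

The window's bottom (the "start cycle") is chosen either by the default
rule — the first integer cycle strictly below the provisional half-maximum
cycle — or, when read precision at low fluorescence is limiting, by a
user-supplied minimum F_C: the start cycle is the cycle after the first
reading above that minimum, so the start cycle's efficiency denominator is
itself above the minimum.

The top of the window is found recursively.  Starting from a three-cycle
window, the window is fitted, the F_0 of the cycle immediately above the
window is back-calculated with the current fit and compared with the
window-average F_0; if the fractional difference is within the F_0
threshold (default 6%) the cycle joins the window and the fit is repeated,
otherwise expansion stops.  This excludes late cycles whose kinetics have
drifted away from the LRE model, the dominant source of quantitative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from .core import (
    BaselinedProfile,
    FluorescenceProfile,
    LreFit,
    LreWindow,
    WindowParams,
    back_calculate_f0,
    fit_lre,
    observed_half_max_cycle,
    subtract_baseline,
)
from .errors import (
    AberrantProfileError,
    BaselineError,
    NonAmplifyingError,
    WindowError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import Run

__all__ = [
    "CandidateRecord",
    "WindowTrace",
    "AnalyzedProfile",
    "MinFcScan",
    "select_start_cycle_default",
    "select_start_cycle_min_fc",
    "expand_window",
    "analyze_profile",
    "optimize_min_fc",
]

# Expansion halts when a candidate reading reaches this fraction of the
# fitted plateau: F_0 back-calculation has a pole at F_C = F_max.
_FMAX_GUARD = 0.999


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate cycle evaluated during window expansion."""

    cycle: int
    fc: float
    ec: float
    f0: float
    pct_diff: float  # |candidate F0 - window avg F0| / window avg F0
    accepted: bool


@dataclass
class WindowTrace:
    """Full record of the expansion loop for one profile."""

    records: list[CandidateRecord]
    stop_reason: str  # threshold_exceeded | end_of_profile | near_fmax | fit_invalid
    window: LreWindow

    @property
    def terminating(self) -> CandidateRecord | None:
        """The rejected candidate that stopped expansion, if any."""
        if self.records and not self.records[-1].accepted:
            return self.records[-1]
        return None


@dataclass
class AnalyzedProfile:
    """A profile with its analysis artifacts (or the flags explaining
    why it has none)."""

    profile: FluorescenceProfile
    params: WindowParams
    baselined: BaselinedProfile | None = None
    start_cycle: int | None = None
    window: LreWindow | None = None
    fit: LreFit | None = None
    trace: WindowTrace | None = None
    kinetics: "object | None" = None  # diagnostics.KineticsReport
    flags: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return self.fit is not None and self.fit.valid and not self.flags


def select_start_cycle_default(profile: BaselinedProfile) -> int:
    """Largest integer cycle strictly below the observed half-max cycle.

    Clamped to cycle 2, the first cycle with a defined efficiency.
    """
    half = observed_half_max_cycle(profile)
    start = math.floor(half)
    if start == half:
        start -= 1
    return max(start, 2)


def select_start_cycle_min_fc(profile: BaselinedProfile, min_fc: float) -> int:
    """Cycle following the first cycle whose reading exceeds ``min_fc``.

    The efficiency denominator of the returned start cycle is therefore
    the first reading above the minimum.
    """
    above = np.nonzero(profile.fc > min_fc)[0]
    if above.size == 0:
        raise WindowError(f"no cycle exceeds minimum F_C {min_fc}")
    first = int(above[0]) + 1  # 1-based cycle
    if first >= profile.n_cycles:
        raise WindowError(
            f"first cycle above minimum F_C {min_fc} is the final cycle"
        )
    return max(first + 1, 2)


def expand_window(
    profile: BaselinedProfile,
    start_cycle: int,
    params: WindowParams,
) -> tuple[LreWindow, LreFit, WindowTrace]:
    """Grow the LRE window upward until the F_0 threshold is exceeded.

    The candidate cycle's F_0 is always computed with the *current*
    window's fit, and the fit (hence the window-average F_0) is recomputed
    after every accepted cycle.  Expansion also stops at the end of the
    profile and when the candidate reading approaches the fitted plateau,
    where F_0 is undefined.

    Raises
    ------
    WindowError
        If fewer than ``initial_window_size`` cycles remain at/above the
        start cycle.
    AberrantProfileError
        If the initial window's fit is invalid (delta_e >= 0 or
        emax <= 0).
    """
    n = profile.n_cycles
    size = params.initial_window_size
    if start_cycle < 2:
        raise WindowError("start cycle must be >= 2")
    if start_cycle + size - 1 > n:
        raise WindowError(
            f"only {n - start_cycle + 1} cycles at/above start cycle "
            f"{start_cycle}; window needs {size}"
        )
    # A 3-point slope at low fluorescence is fragile against read noise;
    # before declaring the profile aberrant, retry with a slightly larger
    # initial window, which pins the slope down.
    window = fit = None
    for trial_size in range(size, min(size + 4, n - start_cycle + 2)):
        trial = LreWindow(start_cycle=start_cycle, size=trial_size)
        try:
            trial_fit = fit_lre(profile, trial)
        except ValueError:  # efficiency undefined inside the trial window
            continue
        if trial_fit.valid:
            window, fit = trial, trial_fit
            break
    if window is None:
        raise AberrantProfileError(
            f"no valid initial window fit at start cycle {start_cycle} "
            "(non-negative slope or non-positive intercept)"
        )
    records: list[CandidateRecord] = []
    stop_reason = "end_of_profile"
    while window.end_cycle < n:
        cand = window.end_cycle + 1
        fc_c = profile.fc_at(cand)
        ec_c = profile.ec_at(cand)
        if fc_c >= _FMAX_GUARD * fit.fmax:
            stop_reason = "near_fmax"
            break
        f0_c = back_calculate_f0(fc_c, cand, fit.emax, fit.fmax)
        pct = abs(f0_c - fit.avg_f0) / fit.avg_f0
        ok = pct <= params.f0_threshold
        records.append(
            CandidateRecord(
                cycle=cand, fc=fc_c, ec=ec_c, f0=f0_c, pct_diff=pct, accepted=ok
            )
        )
        if not ok:
            stop_reason = "threshold_exceeded"
            break
        grown = LreWindow(start_cycle=window.start_cycle, size=window.size + 1)
        new_fit = fit_lre(profile, grown)
        if not new_fit.valid:
            # revert: keep the last window whose fit made physical sense
            records[-1] = replace(records[-1], accepted=False)
            stop_reason = "fit_invalid"
            break
        window, fit = grown, new_fit
    trace = WindowTrace(records=records, stop_reason=stop_reason, window=window)
    return window, fit, trace


def analyze_profile(
    profile: FluorescenceProfile, params: WindowParams | None = None
) -> AnalyzedProfile:
    """Full single-profile pipeline: baseline, start cycle, window, fit.

    Deterministic for fixed input and parameters.  Pathological profiles
    are returned flagged (``non_amplifying``, ``aberrant_fit``,
    ``baseline_overlap``, ``window_too_short``) and carry no fit and no
    quantity; no exception escapes.
    """
    from .diagnostics import classify_kinetics  # local: avoid import cycle

    params = params if params is not None else WindowParams()
    out = AnalyzedProfile(profile=profile, params=params)
    try:
        bp = subtract_baseline(profile, params.baseline_cycles)
    except BaselineError as exc:
        out.flags.append("baseline_overlap")
        out.flags.append(str(exc))
        return out
    out.baselined = bp
    try:
        if params.min_fc is not None:
            start = select_start_cycle_min_fc(bp, params.min_fc)
        else:
            start = select_start_cycle_default(bp)
    except NonAmplifyingError:
        out.flags.append("non_amplifying")
        out.kinetics = classify_kinetics(bp, None, None)
        return out
    except WindowError:
        out.flags.append("no_window")
        return out
    out.start_cycle = start
    try:
        window, fit, trace = expand_window(bp, start, params)
    except AberrantProfileError:
        out.flags.append("aberrant_fit")
        out.kinetics = classify_kinetics(bp, None, None)
        return out
    except (WindowError, ValueError):
        out.flags.append("window_too_short")
        return out
    out.window, out.fit, out.trace = window, fit, trace
    out.kinetics = classify_kinetics(bp, fit, window, trace)
    return out


@dataclass
class MinFcScan:
    """Result of a minimum-F_C grid search."""

    best_min_fc: float
    table: list[tuple[float, float]]  # (candidate, Av Repl-F0 CV)


@dataclass
class ParamScan:
    """Result of a joint (min F_C, F_0 threshold) grid search."""

    best: WindowParams
    table: list[tuple[float, float, float]]  # (min_fc, threshold, CV)


def _set_cvs(run: "Run", params: WindowParams) -> list[float]:
    """Per-set replicate F_0 CVs of a run re-analyzed under `params`
    (sets retaining fewer than two valid replicates are dropped)."""
    cvs = []
    for s in run.replicate_sets:
        if len(s.profiles) < 2:
            continue
        f0s = []
        for prof in s.profiles:
            ap = analyze_profile(prof, params)
            if ap.fit is not None and ap.fit.valid and not ap.flags:
                f0s.append(ap.fit.avg_f0)
        if len(f0s) >= 2:
            arr = np.asarray(f0s)
            cvs.append(float(np.std(arr, ddof=1) / np.mean(arr)))
    return cvs


def optimize_window_params(
    run: "Run",
    min_fc_grid: list[float],
    threshold_grid: list[float],
    params: WindowParams | None = None,
) -> ParamScan:
    """Tune minimum F_C and F_0 threshold jointly on replicate precision.

    On instruments with poor optical read precision the default window
    parameters leave short windows and noisy F_0 estimates; the remedy is
    the same as for the minimum F_C alone — scan the settings and keep
    the combination that minimizes the run's Av Repl-F_0 CV, a statistic
    computed purely from replicate agreement.  A setting that invalidates
    profiles (dropping replicate sets) is never preferred over one that
    keeps more sets usable, regardless of its CV; ties break toward the
    lower minimum F_C, then the lower threshold.
    """
    if not min_fc_grid or not threshold_grid:
        raise ValueError("grids must be non-empty")
    params = params if params is not None else WindowParams()
    if not any(len(s.profiles) >= 2 for s in run.replicate_sets):
        raise ValueError("run has no replicate set with >= 2 replicates")
    table: list[tuple[float, float, float]] = []
    best_key: tuple[int, float] | None = None
    best_setting: tuple[float, float] | None = None
    for mfc in sorted(min_fc_grid):
        for thr in sorted(threshold_grid):
            trial = replace(params, min_fc=mfc, f0_threshold=thr)
            cvs = _set_cvs(run, trial)
            cv = float(np.mean(cvs)) if cvs else math.inf
            table.append((float(mfc), float(thr), cv))
            key = (-len(cvs), cv)
            if best_key is None or key < best_key:
                best_key = key
                best_setting = (float(mfc), float(thr))
    best_params = replace(
        params, min_fc=best_setting[0], f0_threshold=best_setting[1]
    )
    return ParamScan(best=best_params, table=table)


def optimize_min_fc(
    run: "Run",
    candidate_grid: list[float],
    params: WindowParams | None = None,
) -> MinFcScan:
    """Choose the minimum F_C that minimizes the run's Av Repl-F_0 CV.

    Every profile in every replicate set is re-analyzed at each candidate;
    the run-level average replicate F_0 CV is recomputed each time.  Ties
    break toward the lower minimum F_C.  Candidates under which no set
    retains two valid replicates score infinity.
    """
    if not candidate_grid:
        raise ValueError("candidate grid is empty")
    params = params if params is not None else WindowParams()
    sets = [s for s in run.replicate_sets if len(s.profiles) >= 2]
    if not sets:
        raise ValueError("run has no replicate set with >= 2 replicates")
    table: list[tuple[float, float]] = []
    for cand in sorted(candidate_grid):
        cvs = _set_cvs(run, replace(params, min_fc=cand))
        cv = float(np.mean(cvs)) if cvs else math.inf
        table.append((float(cand), cv))
    best = min(table, key=lambda t: t[1])[0]  # sorted grid => ties -> lower
    return MinFcScan(best_min_fc=best, table=table)
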