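"""Core LRE (linear regression of efficiency) mathematics.

Real-time qPCR amplification follows a sigmoidal trajectory: the per-cycle
amplification efficiency

    E_C = F_C / F_{C-1} - 1

declines linearly with the accumulated fluorescence F_C,

    E_C = E_max + dE * F_C,        dE < 0,

so ordinary least squares on the (F_C, E_C) pairs inside a contiguous
"LRE window" of cycles yields E_max (intercept) and dE (slope).  The plateau
fluorescence is F_max = -E_max/dE, and the discrete dynamics implied by the
linear efficiency model,

    F_C = F_{C-1} (1 + E_max) / (1 + E_max * F_{C-1} / F_max),

are solved exactly by the logistic curve

    F_C = F_max / (1 + ((F_max - F_0)/F_0) (1 + E_max)^{-C}),

whose algebraic inverse back-calculates the initial target fluorescence F_0
from any single in-range cycle reading.  F_0, converted to mass through an
optical calibration factor, is what makes quantification absolute.

Efficiency convention: E_C here is the consecutive-reading ratio minus one,
so E_max = 1.0 means perfect doubling.  Fluorescence units are the
instrument's arbitrary units throughout; only the optical calibration factor
carries units of fluorescence per ng of DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import BaselineError, NonAmplifyingError

__all__ = [
    "Strandedness",
    "FluorescenceProfile",
    "BaselinedProfile",
    "LreWindow",
    "LreFit",
    "WindowParams",
    "subtract_baseline",
    "cycle_efficiency",
    "fit_lre",
    "predict_fc",
    "back_calculate_f0",
    "c_half_from_fit",
    "observed_half_max_cycle",
]


class Strandedness(str, Enum):
    """Strandedness of the target at cycle 0 (cDNA is single-stranded)."""

    DOUBLE = "double"
    SINGLE = "single"

    @classmethod
    def parse(cls, text: str) -> "Strandedness":
        t = str(text).strip().lower()
        if t in ("double", "ds", "double-stranded", "dsdna"):
            return cls.DOUBLE
        if t in ("single", "ss", "single-stranded", "ssdna"):
            return cls.SINGLE
        raise ValueError(f"unrecognized strandedness: {text!r}")


def _as_float_array(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("fluorescence readings must be one-dimensional")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


@dataclass(eq=False)
class FluorescenceProfile:
    """One well's annotated raw per-cycle fluorescence trace.

    Cycles are 1-based and consecutive; ``raw_fc[i]`` is the reading of
    cycle ``i + 1``.
    """

    well_label: str
    sample_name: str
    amplicon_name: str
    amplicon_size: int
    strandedness: Strandedness
    raw_fc: np.ndarray
    is_calibration: bool = False
    run_id: str = ""

    def __post_init__(self) -> None:
        self.raw_fc = _as_float_array(self.raw_fc)
        if len(self.raw_fc) < 10:
            raise ValueError("a profile needs at least 10 cycles")
        if not np.all(np.isfinite(self.raw_fc)):
            raise ValueError("all fluorescence readings must be finite")
        self.amplicon_size = int(self.amplicon_size)
        if self.amplicon_size < 1:
            raise ValueError("amplicon size must be >= 1 bp")
        self.strandedness = Strandedness(self.strandedness)

    @property
    def n_cycles(self) -> int:
        return len(self.raw_fc)

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.n_cycles + 1)

    @property
    def label(self) -> str:
        """Display label, ``amplicon @ sample``; analysis appends E_max/No."""
        return f"{self.amplicon_name} @ {self.sample_name}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FluorescenceProfile):
            return NotImplemented
        return (
            self.well_label == other.well_label
            and self.sample_name == other.sample_name
            and self.amplicon_name == other.amplicon_name
            and self.amplicon_size == other.amplicon_size
            and self.strandedness == other.strandedness
            and self.is_calibration == other.is_calibration
            and self.run_id == other.run_id
            and np.array_equal(self.raw_fc, other.raw_fc)
        )


@dataclass(eq=False)
class BaselinedProfile:
    """Background-subtracted profile with per-cycle efficiencies.

    ``fc[i]`` is the baseline-subtracted reading of cycle ``i + 1``;
    ``ec[j]`` is the efficiency of cycle ``j + 2`` (cycle 1 has no
    predecessor).  Efficiencies whose denominator is non-positive are NaN.
    """

    source: FluorescenceProfile
    baseline: float
    fc: np.ndarray
    ec: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.fc)

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.n_cycles + 1)

    def fc_at(self, cycle: int) -> float:
        return float(self.fc[cycle - 1])

    def ec_at(self, cycle: int) -> float:
        """Efficiency of `cycle` (NaN for cycle 1 or undefined ratios)."""
        if cycle < 2 or cycle > self.n_cycles:
            return math.nan
        return float(self.ec[cycle - 2])


@dataclass(frozen=True)
class LreWindow:
    """Contiguous cycle range [start_cycle, start_cycle + size - 1] used
    for the efficiency regression."""

    start_cycle: int
    size: int

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("LRE window needs at least 3 cycles")
        if self.start_cycle < 2:
            raise ValueError("LRE window cannot start before cycle 2")

    @property
    def end_cycle(self) -> int:
        return self.start_cycle + self.size - 1

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(self.start_cycle, self.end_cycle + 1)


@dataclass
class LreFit:
    """Result of the efficiency-vs-fluorescence regression on one window.

    emax
        Maximal amplification efficiency (Y-intercept); 1.0 = doubling.
    delta_e
        Efficiency loss per fluorescence unit (slope); negative for a
        well-behaved profile.
    fmax
        Plateau fluorescence, -emax/delta_e.
    f0_per_cycle
        F_0 back-calculated from each window cycle; for model-conforming
        data these agree across cycles.
    c_half
        Fractional cycle at which fluorescence reaches F_max/2 (a
        Cq-like but assay-independent position statistic).
    """

    emax: float
    delta_e: float
    fmax: float
    r2: float
    f0_per_cycle: np.ndarray
    avg_f0: float
    c_half: float

    @property
    def valid(self) -> bool:
        return (
            self.delta_e < 0
            and self.emax > 0
            and math.isfinite(self.avg_f0)
            and self.avg_f0 > 0
        )


@dataclass
class WindowParams:
    """Tunables of automated window selection.

    min_fc
        Optional minimum fluorescence for the start-cycle override rule;
        ``None`` selects the default first-cycle-below-C_1/2 rule.
    f0_threshold
        Maximum fractional difference between a candidate cycle's F_0 and
        the window-average F_0 before expansion stops (default 6%).
    baseline_cycles
        Inclusive cycle range averaged for background estimation; ``None``
        disables subtraction (pre-baselined data).
    """

    min_fc: float | None = None
    f0_threshold: float = 0.06
    initial_window_size: int = 3
    baseline_cycles: tuple[int, int] | None = (4, 9)

    def __post_init__(self) -> None:
        if self.f0_threshold <= 0:
            raise ValueError("f0_threshold must be positive")
        if self.initial_window_size < 3:
            raise ValueError("initial window size must be >= 3")


# Fraction of the profile maximum above which a reading is considered part
# of the amplification rise (baseline-range guard).
_RISE_FRACTION = 0.10
# Trailing readings within this fraction of the maximum count as plateau.
_PLATEAU_TOLERANCE = 0.05


def subtract_baseline(
    profile: FluorescenceProfile,
    baseline_cycles: tuple[int, int] | None = (4, 9),
) -> BaselinedProfile:
    """Estimate and remove background fluorescence.

    The baseline is the mean raw reading over ``baseline_cycles``
    (inclusive, 1-based).  ``None`` applies a zero baseline for data that
    the instrument has already background-corrected.

    Raises
    ------
    BaselineError
        If any reading in the range exceeds 10% of the profile maximum,
        i.e. the range overlaps the amplification rise.
    """
    raw = profile.raw_fc
    if baseline_cycles is None:
        baseline = 0.0
    else:
        lo, hi = baseline_cycles
        if not (1 <= lo <= hi <= profile.n_cycles):
            raise BaselineError(
                f"baseline cycle range {baseline_cycles} outside profile "
                f"cycles 1..{profile.n_cycles}"
            )
        segment = raw[lo - 1 : hi]
        # Rise-overlap guard: a reading counts as "rise" only if it sits
        # above the segment's typical level by 10% of the profile's dynamic
        # range AND above the segment's noise (flat no-template wells must
        # not trip the guard on noise alone).  Median/MAD, not mean/std:
        # the contamination being guarded against would inflate both.
        level = float(np.median(segment))
        rise = _RISE_FRACTION * (float(np.max(raw)) - level)
        mad = float(np.median(np.abs(segment - level)))
        noise = 5.0 * 1.4826 * mad
        if np.any(segment > level + max(rise, noise)) and rise > 0:
            raise BaselineError(
                f"baseline cycles {lo}-{hi} overlap the amplification rise "
                f"(reading above {_RISE_FRACTION:.0%} of the dynamic range)"
            )
        baseline = float(np.mean(segment))
    fc = raw - baseline
    prev = fc[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ec = np.where(prev > 0, fc[1:] / prev - 1.0, np.nan)
    return BaselinedProfile(source=profile, baseline=baseline, fc=fc, ec=ec)


def cycle_efficiency(fc_prev: float, fc: float) -> float:
    """Amplification efficiency of one cycle from consecutive readings.

    Returns ``fc / fc_prev - 1`` (perfect doubling gives 1.0), or NaN when
    the denominator is non-positive and the ratio is meaningless.
    """
    if fc_prev <= 0:
        return math.nan
    return fc / fc_prev - 1.0


def predict_fc(f0: float, emax: float, fmax: float, cycle: float) -> float:
    """Forward model: fluorescence after `cycle` rounds of amplification.

    The logistic solution of the linear-efficiency dynamics; monotone
    increasing in `cycle` and asymptotic to `fmax`.
    """
    if not (f0 > 0 and fmax > f0 and emax > 0):
        raise ValueError("predict_fc requires 0 < f0 < fmax and emax > 0")
    return fmax / (1.0 + ((fmax - f0) / f0) * (1.0 + emax) ** (-cycle))


def back_calculate_f0(fc: float, cycle: float, emax: float, fmax: float) -> float:
    """Initial target fluorescence implied by a single cycle reading.

    Exact algebraic inverse of :func:`predict_fc`.  Returns NaN when
    ``fc`` is outside ``(0, fmax)`` (past the usable range) or the fit
    parameters are unusable.
    """
    if not (emax > 0 and fmax > 0) or not (0 < fc < fmax):
        return math.nan
    return fmax / (1.0 + ((fmax - fc) / fc) * (1.0 + emax) ** cycle)


def c_half_from_fit(f0: float, emax: float, fmax: float) -> float:
    """Fractional cycle at which predicted fluorescence reaches fmax/2."""
    if not (f0 > 0 and fmax > f0 and emax > 0):
        raise ValueError("c_half requires 0 < f0 < fmax and emax > 0")
    return math.log((fmax - f0) / f0) / math.log1p(emax)


def fit_lre(profile: BaselinedProfile, window: LreWindow) -> LreFit:
    """Ordinary least squares of (F_C, E_C) pairs over the window cycles.

    The intercept is E_max, the slope is dE, and F_max = -E_max/dE.  F_0 is
    back-calculated from every window cycle and averaged.  A fit with
    non-negative slope or non-positive intercept is returned with
    ``valid == False`` (non-amplifying or aberrant profile); it carries no
    usable F_0.
    """
    if window.end_cycle > profile.n_cycles:
        raise ValueError("window extends past the profile")
    cycs = window.cycles
    x = np.array([profile.fc_at(c) for c in cycs])
    y = np.array([profile.ec_at(c) for c in cycs])
    if not np.all(np.isfinite(y)):
        bad = [int(c) for c, v in zip(cycs, y) if not math.isfinite(v)]
        raise ValueError(f"efficiency undefined for window cycles {bad}")
    try:
        res = stats.linregress(x, y)
    except ValueError:  # all fc identical: no regression, not amplifying
        return LreFit(
            emax=0.0,
            delta_e=0.0,
            fmax=math.nan,
            r2=0.0,
            f0_per_cycle=np.full(len(cycs), math.nan),
            avg_f0=math.nan,
            c_half=math.nan,
        )
    emax = float(res.intercept)
    delta_e = float(res.slope)
    fmax = -emax / delta_e if delta_e != 0 else math.nan
    f0s = np.array([back_calculate_f0(fx, c, emax, fmax) for fx, c in zip(x, cycs)])
    defined = f0s[np.isfinite(f0s)]
    avg_f0 = float(np.mean(defined)) if defined.size else math.nan
    if delta_e < 0 and emax > 0 and avg_f0 > 0 and avg_f0 < fmax:
        c_half = c_half_from_fit(avg_f0, emax, fmax)
    else:
        c_half = math.nan
    return LreFit(
        emax=emax,
        delta_e=delta_e,
        fmax=fmax,
        r2=float(res.rvalue) ** 2,
        f0_per_cycle=f0s,
        avg_f0=avg_f0,
        c_half=c_half,
    )


def observed_half_max_cycle(profile: BaselinedProfile) -> float:
    """Fit-free half-maximum crossing, by linear interpolation.

    The end of the amplification rise is located from the per-cycle
    increments: after the increment peaks, the first cycle where the
    increment has decayed to 5% of its peak — or has stopped shrinking in
    the lower half of its decline, as happens when late-cycle drift keeps
    fluorescence creeping upward — marks the plateau, whose level is the
    mean of the next few readings.  (Locating the plateau where the rise
    *ends*, rather than at the trailing maximum, keeps the estimate from
    being dragged upward by post-plateau drift.)  The returned fractional
    cycle is where the baselined fluorescence first crosses half of that
    plateau.  This provisional statistic seeds the default start-cycle
    rule without depending on a window or fit.

    Raises
    ------
    NonAmplifyingError
        If the profile never rises, never levels off, or its apparent
        plateau is indistinguishable from pre-rise noise.
    """
    fc = profile.fc
    n = len(fc)
    if float(np.max(fc)) <= 0:
        raise NonAmplifyingError("profile never rises above baseline")
    df = np.diff(fc)
    ipeak = int(np.argmax(df))
    peak = float(df[ipeak])
    if peak <= 0:
        raise NonAmplifyingError("profile never rises above baseline")
    level_idx = None
    for i in range(ipeak + 1, len(df)):
        if df[i] <= _PLATEAU_TOLERANCE * peak:
            level_idx = i + 1
            break
        if df[i] >= df[i - 1] and df[i - 1] < 0.8 * peak:
            level_idx = i + 1
            break
    if level_idx is None:
        raise NonAmplifyingError("profile has not plateaued")
    plateau = float(np.mean(fc[level_idx : min(level_idx + 3, n)]))
    if plateau <= 0:
        raise NonAmplifyingError("profile has not plateaued")
    # Amplitude guard: an amplifying profile's plateau towers over its
    # typical per-cycle increment (most cycles are flat); a noise-only
    # trace has a "plateau" only a couple of increments tall.
    scale = float(np.median(np.abs(df)))
    if scale > 0 and plateau < 8.0 * scale:
        raise NonAmplifyingError("apparent plateau is within read noise")
    half = plateau / 2.0
    idx = int(np.argmax(fc >= half))
    if fc[idx] < half:
        raise NonAmplifyingError("profile never reaches half of plateau")
    if idx == 0:
        return 1.0
    f_prev, f_here = float(fc[idx - 1]), float(fc[idx])
    if f_here <= f_prev:
        return float(idx + 1)
    return idx + (half - f_prev) / (f_here - f_prev)
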