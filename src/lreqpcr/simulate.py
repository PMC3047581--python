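"""Synthetic amplification profiles and runs with known ground truth.

The generator runs the quantification equations in reverse: a true
molecule count N* becomes an amplicon mass, a true optical calibration
factor turns that mass into an initial fluorescence F_0*, and the discrete
LRE recurrence

    F_C = F_{C-1} (1 + E_max) / (1 + E_max * F_{C-1} / F_max)

(the dynamics whose per-cycle efficiency is *exactly* E_max + dE * F_C)
propagates F_0* to a full trace.  Because the generator satisfies the
analyzer's model identically, any deviation recovered downstream is
attributable to the effects injected here: instrument background
(additive baseline), read noise (multiplicative, with an additive floor so
early cycles are noise-limited, as real optics are), Poisson sampling of
template molecules in the low-copy regime, and the three kinetic
distortions — plateau drift, profile collapse and profile arcing.

Distortions are localized: cycles before the rise midpoint are untouched
by drift and collapse, baseline-estimation cycles by all modes.  Every
stochastic output requires a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import FluorescenceProfile, Strandedness
from .quantify import (
    CONV_BP_MOLECULES_PER_NG,
    ReplicateSet,
    Run,
)

__all__ = [
    "SimSpec",
    "ProfileTruth",
    "SimulatedRun",
    "DEFAULT_STRENGTH",
    "f0_from_molecules",
    "simulate_profile",
    "simulate_replicate_set",
    "simulate_run",
]

#: Default distortion strengths: chosen to reproduce clearly visible
#: pathologies (points obviously leaving the LRE line) at moderate
#: severity.  drift: fraction of F_max added per cycle past plateau onset
#: (0.97 F_max); collapse: fractional efficiency deficit per cycle once
#: past ~0.6 F_max, so amplification dies within a few cycles and the
#: profile stalls visibly short of F_max; arcing: peak fractional E_max
#: suppression at mid-rise.
DEFAULT_STRENGTH = {"none": 0.0, "drift": 0.10, "collapse": 0.50, "arcing": 0.30}

# Distortion onsets, as fractions of F_max reached by the clean trajectory.
_DRIFT_ONSET = 0.97
_COLLAPSE_ONSET = 0.60


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth parameters for one simulated reaction.

    Defaults emulate a SYBR Green I assay on a 96-well instrument run for
    50 cycles: E_max 0.95, plateau 7e6 fluorescence units, background
    5e4 units, 0.2% multiplicative read noise, a 200 bp double-stranded
    target at 1e4 molecules per reaction, and an optical calibration
    factor of 1e5 units/ng.
    """

    n_star: float = 1e4  # true molecules per reaction
    ocf: float = 1e5  # true fluorescence units per ng dsDNA
    amplicon_size: int = 200
    strandedness: Strandedness = Strandedness.DOUBLE
    emax: float = 0.95
    fmax: float = 7e6
    baseline: float = 5e4
    # Multiplicative read-noise SD per reading.  The default emulates a
    # high-precision optical bench (per-cycle F_0 scatter in the low
    # single percents, as a well-tuned 96-well instrument delivers);
    # 0.01 represents a mediocre instrument.
    noise_sd: float = 0.002
    noise_floor: float | None = None  # additive sd; default noise_sd*baseline
    n_cycles: int = 50
    distortion: str = "none"  # none | drift | collapse | arcing
    strength: float | None = None  # None -> DEFAULT_STRENGTH[distortion]
    poisson: bool | None = None  # None -> auto (n_star < 10)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.distortion not in DEFAULT_STRENGTH:
            raise ValueError(f"unknown distortion {self.distortion!r}")
        for name in ("ocf", "amplicon_size", "emax", "fmax", "n_cycles"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_star < 0 or self.noise_sd < 0 or self.baseline < 0:
            raise ValueError("n_star, noise_sd and baseline must be >= 0")

    @property
    def effective_strength(self) -> float:
        if self.strength is not None:
            return self.strength
        return DEFAULT_STRENGTH[self.distortion]

    @property
    def is_stochastic(self) -> bool:
        use_poisson = self.poisson if self.poisson is not None else self.n_star < 10
        return self.noise_sd > 0 or bool(use_poisson)


@dataclass
class ProfileTruth:
    """Everything the generator knew about one profile."""

    spec: SimSpec
    template_count: float  # molecules actually seeded (Poisson draw or N*)
    f0: float  # true initial fluorescence of this reaction
    c_half: float | None  # true half-max cycle (None if no template)


@dataclass
class SimulatedRun:
    """A full synthetic project fixture with ground truth."""

    run: Run
    calibration_profiles: list[FluorescenceProfile]
    calibration_truths: list[ProfileTruth]
    known_ng: float
    truth: dict[tuple[str, str], list[ProfileTruth]]  # (amplicon, sample)


def f0_from_molecules(
    n: float,
    amplicon_size: int,
    strandedness: Strandedness,
    ocf: float,
    conv: float = CONV_BP_MOLECULES_PER_NG,
) -> float:
    """True initial fluorescence of ``n`` molecules under a known OCF."""
    per_ng = conv / amplicon_size
    if Strandedness(strandedness) is Strandedness.SINGLE:
        per_ng *= 2.0
    mass_ng = n / per_ng
    return mass_ng * ocf


def _recurrence(
    f0: float, emax_per_cycle: np.ndarray, fmax: float
) -> np.ndarray:
    """Propagate F_0 through the discrete LRE dynamics (cycles 1..n)."""
    out = np.empty(len(emax_per_cycle))
    f = f0
    for i, e in enumerate(emax_per_cycle):
        f = f * (1.0 + e) / (1.0 + e * f / fmax)
        out[i] = f
    return out


def _clean_trajectory(spec: SimSpec, f0: float) -> np.ndarray:
    n = spec.n_cycles
    if f0 <= 0:
        return np.zeros(n)
    return _recurrence(f0, np.full(n, spec.emax), spec.fmax)


def _first_cycle_at(traj: np.ndarray, level: float) -> int | None:
    """1-based first cycle at/above `level`, or None."""
    idx = np.nonzero(traj >= level)[0]
    return int(idx[0]) + 1 if idx.size else None


def _distorted_trajectory(spec: SimSpec, f0: float) -> np.ndarray:
    clean = _clean_trajectory(spec, f0)
    s = spec.effective_strength
    if spec.distortion == "none" or s == 0 or f0 <= 0:
        return clean
    n = spec.n_cycles
    cycles = np.arange(1, n + 1)
    if spec.distortion == "drift":
        onset = _first_cycle_at(clean, _DRIFT_ONSET * spec.fmax)
        if onset is None:
            return clean
        ramp = np.maximum(0, cycles - onset + 1) * s * spec.fmax
        return clean + ramp
    if spec.distortion == "collapse":
        onset = _first_cycle_at(clean, _COLLAPSE_ONSET * spec.fmax)
        if onset is None:
            return clean
        deficit = np.clip(1.0 - s * np.maximum(0, cycles - onset), 0.0, 1.0)
        return _recurrence(f0, spec.emax * deficit, spec.fmax)
    if spec.distortion == "arcing":
        lo = _first_cycle_at(clean, 0.01 * spec.fmax)
        hi = _first_cycle_at(clean, 0.99 * spec.fmax)
        if lo is None:
            return clean
        if hi is None:
            hi = n
        lo = lo - 1  # modulation spans the open interval (lo, hi)
        span = max(hi - lo, 1)
        phase = np.clip((cycles - lo) / span, 0.0, 1.0)
        modulation = 1.0 - s * np.sin(np.pi * phase)
        return _recurrence(f0, spec.emax * modulation, spec.fmax)
    raise AssertionError("unreachable")


def simulate_profile(
    spec: SimSpec,
    rng: np.random.Generator | None = None,
    *,
    well_label: str = "A1",
    sample_name: str = "sample",
    amplicon_name: str = "amp",
    run_id: str = "run1",
    is_calibration: bool = False,
) -> tuple[FluorescenceProfile, ProfileTruth]:
    """One simulated well plus its truth record."""
    if rng is None:
        if spec.is_stochastic and spec.seed is None:
            raise ValueError("stochastic simulation requires a seed or rng")
        rng = np.random.default_rng(spec.seed)
    use_poisson = spec.poisson if spec.poisson is not None else spec.n_star < 10
    if use_poisson:
        count = float(rng.poisson(spec.n_star))
    else:
        count = float(spec.n_star)
    f0 = f0_from_molecules(
        count, spec.amplicon_size, spec.strandedness, spec.ocf
    )
    signal = _distorted_trajectory(spec, f0)
    reading = signal + spec.baseline
    if spec.noise_sd > 0:
        floor = (
            spec.noise_floor
            if spec.noise_floor is not None
            else spec.noise_sd * spec.baseline
        )
        reading = reading * (1.0 + rng.normal(0.0, spec.noise_sd, len(reading)))
        reading = reading + rng.normal(0.0, floor, len(reading))
    profile = FluorescenceProfile(
        well_label=well_label,
        sample_name=sample_name,
        amplicon_name=amplicon_name,
        amplicon_size=spec.amplicon_size,
        strandedness=spec.strandedness,
        raw_fc=reading,
        is_calibration=is_calibration,
        run_id=run_id,
    )
    if f0 > 0:
        c_half = math.log((spec.fmax - f0) / f0) / math.log1p(spec.emax)
    else:
        c_half = None
    truth = ProfileTruth(spec=spec, template_count=count, f0=f0, c_half=c_half)
    return profile, truth


def simulate_replicate_set(
    spec: SimSpec,
    n_replicates: int,
    rng: np.random.Generator,
    *,
    sample_name: str,
    amplicon_name: str,
    run_id: str = "run1",
    well_prefix: str = "W",
) -> tuple[ReplicateSet, list[ProfileTruth]]:
    """Technical replicates with independent noise (and template draws)."""
    profiles, truths = [], []
    for i in range(n_replicates):
        p, t = simulate_profile(
            spec,
            rng,
            well_label=f"{well_prefix}{i + 1}",
            sample_name=sample_name,
            amplicon_name=amplicon_name,
            run_id=run_id,
        )
        profiles.append(p)
        truths.append(t)
    rset = ReplicateSet(
        sample_name=sample_name, amplicon_name=amplicon_name, profiles=profiles
    )
    return rset, truths


def simulate_run(
    n_amplicons: int = 3,
    n_samples: int = 3,
    n_replicates: int = 3,
    *,
    seed: int,
    base_spec: SimSpec | None = None,
    n_star: float | dict[tuple[str, str], float] = 1e4,
    n_calibration: int = 3,
    known_ng: float = 1e-5,
    run_id: str = "run1",
) -> SimulatedRun:
    """A full run fixture: amplicons x samples x replicates, plus
    calibration profiles amplified from a known DNA mass.

    The default 3x3x3 design mirrors a reference-gene expression study:
    three amplicons quantified in three replicate sample preparations
    with three technical PCR replicates each.  ``n_star`` may be a single
    count or a ``{(amplicon, sample): count}`` map.
    """
    rng = np.random.default_rng(seed)
    base = base_spec if base_spec is not None else SimSpec()
    amplicons = [f"AMP{i + 1}" for i in range(n_amplicons)]
    sizes = [150 + 50 * (i % 3) for i in range(n_amplicons)]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    sets: list[ReplicateSet] = []
    truth: dict[tuple[str, str], list[ProfileTruth]] = {}
    well = 0
    for amp, size in zip(amplicons, sizes):
        for sample in samples:
            if isinstance(n_star, dict):
                n = n_star[(amp, sample)]
            else:
                n = n_star
            spec = replace(base, n_star=n, amplicon_size=size)
            rset, truths = simulate_replicate_set(
                spec,
                n_replicates,
                rng,
                sample_name=sample,
                amplicon_name=amp,
                run_id=run_id,
                well_prefix=f"W{well}_",
            )
            well += 1
            sets.append(rset)
            truth[(amp, sample)] = truths
    run = Run(run_id=run_id, replicate_sets=sets)
    # Calibration seeds a known amplicon-equivalent mass of lambda gDNA:
    # its molecule count follows from that mass (double-stranded genomic).
    cal_spec = replace(
        base,
        n_star=known_ng * CONV_BP_MOLECULES_PER_NG / base.amplicon_size,
        strandedness=Strandedness.DOUBLE,
        distortion="none",
        strength=None,
        poisson=False,
    )
    cal_profiles, cal_truths = [], []
    for i in range(n_calibration):
        p, t = simulate_profile(
            cal_spec,
            rng,
            well_label=f"CAL{i + 1}",
            sample_name="lambda_gDNA",
            amplicon_name="lambda_cal",
            run_id=run_id,
            is_calibration=True,
        )
        cal_profiles.append(p)
        cal_truths.append(t)
    return SimulatedRun(
        run=run,
        calibration_profiles=cal_profiles,
        calibration_truths=cal_truths,
        known_ng=known_ng,
        truth=truth,
    )
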