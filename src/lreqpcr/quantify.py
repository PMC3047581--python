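"""Absolute quantification and replicate statistics.

F_0 (initial target fluorescence) becomes an absolute molecule count in two
steps: an optical calibration factor (OCF, fluorescence units per ng of
double-stranded DNA, measured by amplifying a known mass of lambda gDNA
under the same reaction setup) converts F_0 to target mass, and the
amplicon's molar mass converts mass to molecules:

    mass_ng   = F_0 / OCF
    molecules = mass_ng * 9.1e11 / amplicon_size_bp      (double-stranded)

where 9.1e11 bp*molecules/ng follows from Avogadro's number and
660 g/mol per base pair (the LRE literature's rounding).  Single-stranded
targets (cDNA before cycle 1) weigh half as much per base, hence twice the
molecules per ng.

Technical replicates are averaged per cycle into an average profile — the
primary working unit — except below ~10 molecules per reaction, where
Poisson scatter of template counts makes the replicates genuinely
different: there the per-replicate quantities are averaged instead.  The
run-level mean of replicate-F_0 coefficients of variation ("Av Repl-F_0
CV") is the intra-run precision statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import FluorescenceProfile, Strandedness, WindowParams
from .errors import LreError
from .windows import AnalyzedProfile, analyze_profile

__all__ = [
    "CONV_BP_MOLECULES_PER_NG",
    "LOW_COPY_THRESHOLD",
    "Ocf",
    "ReplicateSet",
    "Run",
    "make_average_profile",
    "compute_ocf",
    "molecules_from_f0",
    "analyze_replicate_set",
    "quantify_replicate_set",
    "replicate_f0_cv",
    "average_replicate_f0_cv",
]

#: bp * molecules per ng of double-stranded DNA (660 g/mol/bp).
CONV_BP_MOLECULES_PER_NG = 9.1e11

#: Below this many molecules per reaction, Poisson scatter of template
#: counts dominates and per-replicate averaging replaces the average
#: profile.
LOW_COPY_THRESHOLD = 10.0

#: Replicate C_1/2 spread (cycles) beyond which the set is flagged as not
#: tightly clustered.
C_HALF_SCATTER_WARN = 1.0


@dataclass
class Ocf:
    """Optical calibration factor for one reaction setup."""

    value: float  # fluorescence units per ng dsDNA
    sd: float = 0.0
    source_reaction_setup: str = ""
    calibration_profile_ids: list[str] = field(default_factory=list)
    per_profile: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("OCF must be positive")


@dataclass
class ReplicateSet:
    """Technical replicates of one (sample, amplicon) pair."""

    sample_name: str
    amplicon_name: str
    profiles: list[FluorescenceProfile]
    analyzed: list[AnalyzedProfile] | None = None
    average_profile: FluorescenceProfile | None = None
    average_analyzed: AnalyzedProfile | None = None
    quantity: float | None = None  # molecules per reaction
    quantification_path: str | None = None  # average_profile | replicate_mean
    f0_cv: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class Run:
    """One instrument run: a group of replicate sets analyzed together."""

    run_id: str
    replicate_sets: list[ReplicateSet]
    run_date: str = ""
    ocf: Ocf | None = None
    av_repl_f0_cv: float | None = None


def make_average_profile(
    replicates: list[FluorescenceProfile],
) -> FluorescenceProfile:
    """Per-cycle arithmetic mean of replicate raw readings.

    All replicates must share cycle count, sample, amplicon, size and
    strandedness; annotations are inherited.
    """
    if len(replicates) < 2:
        raise ValueError("averaging needs at least 2 replicates")
    first = replicates[0]
    for r in replicates[1:]:
        if r.n_cycles != first.n_cycles:
            raise ValueError("replicates have mismatched cycle counts")
        if (
            r.sample_name != first.sample_name
            or r.amplicon_name != first.amplicon_name
            or r.amplicon_size != first.amplicon_size
            or r.strandedness != first.strandedness
        ):
            raise ValueError("replicates have mismatched annotations")
    mean_fc = np.mean([r.raw_fc for r in replicates], axis=0)
    return FluorescenceProfile(
        well_label="avg(" + ",".join(r.well_label for r in replicates) + ")",
        sample_name=first.sample_name,
        amplicon_name=first.amplicon_name,
        amplicon_size=first.amplicon_size,
        strandedness=first.strandedness,
        raw_fc=mean_fc,
        is_calibration=first.is_calibration,
        run_id=first.run_id,
    )


def compute_ocf(
    cal_profiles: list[AnalyzedProfile],
    known_quantity_ng: float,
    reaction_setup: str = "",
) -> Ocf:
    """Optical calibration factor from analyzed calibration profiles.

    Each valid calibration profile contributes ``avg_F0 / known_ng``;
    the OCF is their mean, with the standard deviation reported as
    dispersion.  Flagged profiles are excluded.
    """
    if not known_quantity_ng > 0:
        raise ValueError("known calibration quantity must be positive ng")
    values, ids = [], []
    for ap in cal_profiles:
        if ap.fit is not None and ap.fit.valid and not ap.flags:
            values.append(ap.fit.avg_f0 / known_quantity_ng)
            ids.append(ap.profile.well_label)
    if not values:
        raise LreError("no valid calibration profile; cannot compute OCF")
    arr = np.asarray(values)
    return Ocf(
        value=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
        source_reaction_setup=reaction_setup,
        calibration_profile_ids=ids,
        per_profile=[float(v) for v in values],
    )


def molecules_from_f0(
    f0: float,
    ocf: Ocf | float,
    amplicon_size: int,
    strandedness: Strandedness = Strandedness.DOUBLE,
    conv: float = CONV_BP_MOLECULES_PER_NG,
) -> float:
    """Absolute molecule count per reaction from an F_0 value."""
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    if amplicon_size < 1:
        raise ValueError("amplicon size must be >= 1 bp")
    ocf_value = ocf.value if isinstance(ocf, Ocf) else float(ocf)
    mass_ng = f0 / ocf_value
    per_ng = conv / amplicon_size
    if Strandedness(strandedness) is Strandedness.SINGLE:
        per_ng *= 2.0  # 330 g/mol per base: half the mass per molecule
    return mass_ng * per_ng


def analyze_replicate_set(
    rset: ReplicateSet, params: WindowParams | None = None
) -> ReplicateSet:
    """Analyze every replicate and the set's average profile in place."""
    params = params if params is not None else WindowParams()
    rset.analyzed = [analyze_profile(p, params) for p in rset.profiles]
    if len(rset.profiles) >= 2:
        rset.average_profile = make_average_profile(rset.profiles)
    else:
        rset.average_profile = rset.profiles[0]
    rset.average_analyzed = analyze_profile(rset.average_profile, params)
    rset.f0_cv = replicate_f0_cv(rset)
    return rset


def _replicate_molecules(rset: ReplicateSet, ocf: Ocf | float) -> list[float]:
    """Per-replicate molecule counts for the low-copy averaging path.

    A non-amplifying replicate is a true zero-template reaction at
    limiting dilution and counts as 0 molecules — but only when at least
    one sibling replicate amplified, which shows the assay itself worked.
    Replicates flagged for other reasons (aberrant kinetics, baseline
    problems) are excluded.  A set with no valid fit at all returns no
    counts: it is indistinguishable from assay failure.
    """
    counts: list[float] = []
    any_valid = False
    for ap in rset.analyzed or []:
        if ap.fit is not None and ap.fit.valid and not ap.flags:
            any_valid = True
            counts.append(
                molecules_from_f0(
                    ap.fit.avg_f0,
                    ocf,
                    ap.profile.amplicon_size,
                    ap.profile.strandedness,
                )
            )
        elif "non_amplifying" in ap.flags:
            counts.append(0.0)
    return counts if any_valid else []


def quantify_replicate_set(
    rset: ReplicateSet,
    ocf: Ocf | float,
    params: WindowParams | None = None,
) -> float | None:
    """Molecules per reaction for one replicate set.

    Default path: quantify the average profile.  Below
    :data:`LOW_COPY_THRESHOLD` molecules — the Poisson regime, where
    replicate template counts genuinely differ — the mean of the
    per-replicate quantities is reported instead and the set is flagged
    ``poisson_regime``.  The regime gate checks the average-profile
    quantity *and* the per-replicate mean: Poisson scatter desynchronizes
    the replicate sigmoids, which flattens the average profile's apparent
    efficiency and inflates its back-calculated quantity — the very
    artifact the low-copy rule exists to avoid — so near the threshold
    only the per-replicate mean can be trusted to see it.  The path taken
    is recorded.  Returns ``None`` (with flags) when no usable profile
    exists.
    """
    if rset.analyzed is None or rset.average_analyzed is None:
        analyze_replicate_set(rset, params)
    avg_ap = rset.average_analyzed
    q_avg: float | None = None
    if avg_ap.fit is not None and avg_ap.fit.valid and not avg_ap.flags:
        q_avg = molecules_from_f0(
            avg_ap.fit.avg_f0,
            ocf,
            avg_ap.profile.amplicon_size,
            avg_ap.profile.strandedness,
        )
    c_halves = [
        ap.fit.c_half
        for ap in rset.analyzed
        if ap.fit is not None and ap.fit.valid and not ap.flags
    ]
    # The average profile is only meaningful for tightly clustered
    # replicates: desynchronized sigmoids average into a flattened curve
    # with a biased efficiency.  Scattered sets fall back to per-replicate
    # quantification.
    scattered = (
        len(c_halves) >= 2
        and (max(c_halves) - min(c_halves)) > C_HALF_SCATTER_WARN
    )
    if scattered and "replicate_scatter" not in rset.flags:
        rset.flags.append("replicate_scatter")
    counts = _replicate_molecules(rset, ocf)
    replicate_mean = float(np.mean(counts)) if counts else None
    low_copy = (q_avg is not None and q_avg < LOW_COPY_THRESHOLD) or (
        replicate_mean is not None and replicate_mean < LOW_COPY_THRESHOLD
    )
    if q_avg is not None and not low_copy and not scattered:
        rset.quantity = q_avg
        rset.quantification_path = "average_profile"
        return q_avg
    # Low-copy branch, or the average profile was unusable/untrustworthy.
    if not counts:
        rset.quantity = None
        rset.quantification_path = None
        if "no_valid_profile" not in rset.flags:
            rset.flags.append("no_valid_profile")
        return None
    if q_avg is None:
        if "average_profile_flagged" not in rset.flags:
            rset.flags.append("average_profile_flagged")
    elif low_copy:
        if "poisson_regime" not in rset.flags:
            rset.flags.append("poisson_regime")
    rset.quantity = float(np.mean(counts))
    rset.quantification_path = "replicate_mean"
    return rset.quantity


def replicate_f0_cv(rset: ReplicateSet) -> float | None:
    """Sample CV (sd/mean, ddof=1) of the replicates' average F_0 values.

    Undefined (``None``) with fewer than two valid replicates; such sets
    are excluded from the run average.
    """
    if rset.analyzed is None:
        raise ValueError("replicate set has not been analyzed")
    f0s = [
        ap.fit.avg_f0
        for ap in rset.analyzed
        if ap.fit is not None and ap.fit.valid and not ap.flags
    ]
    if len(f0s) < 2:
        return None
    arr = np.asarray(f0s)
    return float(np.std(arr, ddof=1) / np.mean(arr))


def average_replicate_f0_cv(run: Run) -> float:
    """Run-level "Av Repl-F_0 CV": mean of the defined set-level CVs."""
    cvs = [s.f0_cv for s in run.replicate_sets if s.f0_cv is not None]
    if not cvs:
        raise LreError("no replicate set with a defined F0 CV")
    return float(np.mean(cvs))


def analyze_run(
    run: Run,
    ocf: Ocf | float | None = None,
    params: WindowParams | None = None,
) -> Run:
    """Analyze and (if an OCF is given) quantify every set in a run."""
    for rset in run.replicate_sets:
        analyze_replicate_set(rset, params)
        if ocf is not None:
            quantify_replicate_set(rset, ocf, params)
    try:
        run.av_repl_f0_cv = average_replicate_f0_cv(run)
    except LreError:
        run.av_repl_f0_cv = None
    if isinstance(ocf, Ocf):
        run.ocf = ocf
    return run
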