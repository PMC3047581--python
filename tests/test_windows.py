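"""Automated window selection: start-cycle rules, recursive expansion
gated by the F_0 threshold, and the precision-driven parameter scans."""

import math
from dataclasses import replace

import numpy as np
import pytest

from lreqpcr import (
    SimSpec,
    WindowParams,
    analyze_profile,
    expand_window,
    select_start_cycle_default,
    select_start_cycle_min_fc,
    simulate_profile,
    simulate_run,
    subtract_baseline,
)
from lreqpcr.errors import AberrantProfileError, WindowError
from lreqpcr.windows import optimize_min_fc, optimize_window_params

from oracles import oracle_analyze


def mixed_profiles(n, seed):
    """Randomized synthetic profiles cycling through all kinetic modes."""
    rng = np.random.default_rng(seed)
    modes = ["none", "drift", "collapse", "arcing"]
    out = []
    for i in range(n):
        spec = SimSpec(
            n_star=float(rng.choice([1e2, 1e3, 1e4, 1e5])),
            distortion=modes[i % 4],
            noise_sd=float(rng.choice([0.0, 0.002, 0.005])),
        )
        p, t = simulate_profile(spec, rng)
        out.append((p, t))
    return out


class TestStartCycleDefault:
    def test_floor_of_fractional_half_max(self):
        from lreqpcr.core import BaselinedProfile

        # half-max crossing at 4.6 -> start cycle 4
        fc = np.array([0, 4, 10, 30, 80, 120, 125, 125, 125, 125], dtype=float)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(9, np.nan))
        from lreqpcr.core import observed_half_max_cycle

        h = observed_half_max_cycle(bp)
        assert 4 < h < 5
        assert select_start_cycle_default(bp) == math.floor(h)

    def test_integer_boundary_is_strictly_below(self):
        from lreqpcr.core import BaselinedProfile

        # plateau 120, half 60 hit exactly at cycle 5
        fc = np.array([0, 5, 15, 30, 60, 115, 120, 120, 120, 120], dtype=float)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(9, np.nan))
        from lreqpcr.core import observed_half_max_cycle

        assert observed_half_max_cycle(bp) == pytest.approx(5.0)
        assert select_start_cycle_default(bp) == 4


class TestStartCycleMinFc:
    def test_cycle_after_first_reading_above_minimum(self):
        # mirrors the documented manual setting of 225,000 units: readings
        # of 150k at cycle 21 and 260k at cycle 22 place the start at 23
        from lreqpcr.core import BaselinedProfile

        fc = np.zeros(40)
        fc[:20] = np.geomspace(10, 1.5e5, 20)
        fc[20] = 1.5e5
        fc[21] = 2.6e5
        fc[22:] = np.linspace(4e5, 7e6, 18)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(39, np.nan))
        assert select_start_cycle_min_fc(bp, 225_000.0) == 23

    def test_zero_minimum_degenerates_to_first_positive_cycle(self):
        from lreqpcr.core import BaselinedProfile

        fc = np.array([0, 0, 3, 9, 27, 81, 150, 180, 190, 195], dtype=float)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(9, np.nan))
        assert select_start_cycle_min_fc(bp, 0.0) == 4  # first fc>0 is cycle 3

    def test_no_cycle_above_minimum_flagged(self):
        from lreqpcr.core import BaselinedProfile

        fc = np.linspace(0, 100, 12)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(11, np.nan))
        with pytest.raises(WindowError):
            select_start_cycle_min_fc(bp, 1e6)

    def test_matches_linear_scan_oracle(self, rng):
        for p, _ in mixed_profiles(30, 1234):
            bp = subtract_baseline(p, (4, 9))
            for min_fc in (1e4, 1e5, 1e6):
                try:
                    got = select_start_cycle_min_fc(bp, min_fc)
                except WindowError:
                    got = None
                res = oracle_analyze(p.raw_fc, min_fc=min_fc)
                want = res["start"] if res["flag"] != "no_window" else None
                assert got == want


class TestExpandWindow:
    def test_model_conforming_profile_expands_to_plateau(self):
        p, truth = simulate_profile(SimSpec(noise_sd=0.0, baseline=0.0, seed=2))
        bp = subtract_baseline(p, None)
        start = select_start_cycle_default(bp)
        window, fit, trace = expand_window(bp, start, WindowParams())
        # every accepted candidate conformed; expansion ran into the pole
        assert trace.stop_reason == "near_fmax"
        assert all(r.pct_diff < 1e-6 for r in trace.records)
        assert bp.fc_at(window.end_cycle) > 0.95 * fit.fmax

    def test_trace_invariants_on_mixed_profiles(self):
        params = WindowParams()
        for p, _ in mixed_profiles(40, 77):
            ap = analyze_profile(p, params)
            if ap.trace is None:
                continue
            for rec in ap.trace.records:
                if rec.accepted:
                    assert rec.pct_diff <= params.f0_threshold
            term = ap.trace.terminating
            if ap.trace.stop_reason == "threshold_exceeded":
                assert term is not None and term.pct_diff > params.f0_threshold
            else:
                assert ap.trace.stop_reason in (
                    "end_of_profile",
                    "near_fmax",
                    "fit_invalid",
                )

    def test_drift_cycles_stay_out_of_the_window(self):
        # expansion must stop at or before the first drifted cycle
        from lreqpcr.simulate import _DRIFT_ONSET, _clean_trajectory, _first_cycle_at

        for seed in range(5):
            spec = SimSpec(distortion="drift", noise_sd=0.0, seed=seed)
            p, truth = simulate_profile(spec)
            onset = _first_cycle_at(
                _clean_trajectory(spec, truth.f0), _DRIFT_ONSET * spec.fmax
            )
            ap = analyze_profile(p)
            assert ap.window is not None
            assert ap.window.end_cycle < onset

    def test_lower_threshold_never_enlarges_window(self):
        for p, _ in mixed_profiles(24, 55):
            sizes = []
            for thr in (0.12, 0.06, 0.03, 0.01):
                ap = analyze_profile(p, WindowParams(f0_threshold=thr))
                sizes.append(None if ap.window is None else ap.window.size)
            defined = [s for s in sizes if s is not None]
            assert defined == sorted(defined, reverse=True)

    def test_aberrant_initial_fit_flagged(self):
        # decreasing "amplification" has positive-slope efficiency: aberrant
        from lreqpcr.core import BaselinedProfile

        fc = np.array([100, 90, 70, 40, 30, 25, 22, 21, 20, 20], dtype=float)
        ec = np.array(
            [fc[i + 1] / fc[i] - 1 for i in range(9)], dtype=float
        )
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=ec)
        with pytest.raises(AberrantProfileError):
            expand_window(bp, 2, WindowParams())


class TestAnalyzeProfile:
    def test_deterministic(self):
        p, _ = simulate_profile(SimSpec(seed=3))
        a, b = analyze_profile(p), analyze_profile(p)
        assert a.window == b.window
        assert a.fit.emax == b.fit.emax
        assert a.fit.avg_f0 == b.fit.avg_f0
        np.testing.assert_array_equal(a.fit.f0_per_cycle, b.fit.f0_per_cycle)

    def test_noiseless_recovery_of_true_f0(self, noiseless_bare_profile):
        p, truth = noiseless_bare_profile
        ap = analyze_profile(p, WindowParams(baseline_cycles=None))
        assert ap.is_valid
        assert ap.fit.avg_f0 == pytest.approx(truth.f0, rel=1e-6)
        assert ap.fit.emax == pytest.approx(truth.spec.emax, rel=1e-6)

    def test_all_zero_profile_flagged_not_raised(self):
        from lreqpcr import FluorescenceProfile, Strandedness

        p = FluorescenceProfile(
            well_label="A1",
            sample_name="s",
            amplicon_name="a",
            amplicon_size=100,
            strandedness=Strandedness.DOUBLE,
            raw_fc=np.zeros(40),
        )
        ap = analyze_profile(p)
        assert "non_amplifying" in ap.flags
        assert ap.fit is None


class TestOracleEquivalence:
    def test_start_and_window_match_rule_transcription(self):
        profiles = mixed_profiles(200, 2026)
        agree = 0
        for p, _ in profiles:
            ap = analyze_profile(p, WindowParams())
            want = oracle_analyze(p.raw_fc)
            if ap.window is None:
                assert want["window"] is None or want["flag"] is not None
            else:
                assert want["flag"] is None
                assert ap.start_cycle == want["start"]
                assert (ap.window.start_cycle, ap.window.size) == want["window"]
            agree += 1
        assert agree == 200


class TestOptimizeMinFc:
    def test_single_candidate_returned(self, small_run):
        sim, _ = small_run
        scan = optimize_min_fc(sim.run, [1e5])
        assert scan.best_min_fc == 1e5
        assert len(scan.table) == 1

    def test_returns_argmin_of_reported_table(self, small_run):
        sim, _ = small_run
        grid = [3e4, 1e5, 3e5, 1e6]
        scan = optimize_min_fc(sim.run, grid)
        best_cv = min(cv for _, cv in scan.table)
        assert scan.best_min_fc == min(
            c for c, cv in scan.table if cv == best_cv
        )
        # table CVs match an independent recomputation
        from lreqpcr.windows import _set_cvs

        for cand, cv in scan.table:
            cvs = _set_cvs(sim.run, WindowParams(min_fc=cand))
            expect = float(np.mean(cvs)) if cvs else math.inf
            assert cv == pytest.approx(expect)

    def test_tie_breaks_toward_lower_candidate(self, small_run):
        sim, _ = small_run
        scan = optimize_min_fc(sim.run, [1e5, 1e5 + 0.0])  # duplicate = tie
        assert scan.best_min_fc == 1e5

    def test_empty_grid_rejected(self, small_run):
        sim, _ = small_run
        with pytest.raises(ValueError):
            optimize_min_fc(sim.run, [])


class TestOptimizeWindowParams:
    def test_best_setting_minimizes_cv_over_grid(self, small_run):
        sim, _ = small_run
        scan = optimize_window_params(sim.run, [3e4, 2e5], [0.06, 0.2])
        finite = [row for row in scan.table if math.isfinite(row[2])]
        assert finite
        best_cv = min(row[2] for row in finite)
        assert any(
            row[0] == scan.best.min_fc
            and row[1] == scan.best.f0_threshold
            and row[2] == best_cv
            for row in scan.table
        )
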