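"""Core LRE mathematics: baselines, efficiencies, the regression, and the
logistic forward/inverse model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lreqpcr import (
    FluorescenceProfile,
    LreWindow,
    SimSpec,
    Strandedness,
    back_calculate_f0,
    c_half_from_fit,
    cycle_efficiency,
    fit_lre,
    observed_half_max_cycle,
    predict_fc,
    simulate_profile,
    subtract_baseline,
)
from lreqpcr.errors import BaselineError, NonAmplifyingError

from oracles import ols_normal_equations


def profile_from(readings, **kw):
    defaults = dict(
        well_label="A1",
        sample_name="s",
        amplicon_name="a",
        amplicon_size=200,
        strandedness=Strandedness.DOUBLE,
    )
    defaults.update(kw)
    return FluorescenceProfile(raw_fc=np.asarray(readings, dtype=float), **defaults)


class TestSubtractBaseline:
    def test_constant_background(self):
        p = profile_from([100, 100, 100, 100, 200, 400, 800, 900, 950, 980])
        bp = subtract_baseline(p, (1, 4))
        assert bp.baseline == 100
        np.testing.assert_allclose(bp.fc[:7], [0, 0, 0, 0, 100, 300, 700])

    def test_none_means_zero_baseline(self):
        p = profile_from(np.linspace(1, 10, 12))
        bp = subtract_baseline(p, None)
        assert bp.baseline == 0.0
        np.testing.assert_array_equal(bp.fc, p.raw_fc)

    def test_range_overlapping_rise_rejected(self):
        p = profile_from([10, 10, 10, 10, 10, 500, 5e3, 5e4, 9e4, 1e5])
        with pytest.raises(BaselineError):
            subtract_baseline(p, (4, 8))

    def test_recovers_generator_baseline_within_noise(self):
        # known background b, plateau >> b: estimate within 3*sigma/sqrt(n)
        spec = SimSpec(baseline=5e4, noise_sd=0.01, seed=42)
        p, _ = simulate_profile(spec)
        bp = subtract_baseline(p, (4, 9))
        sigma = spec.noise_sd * spec.baseline * math.sqrt(2)  # mult + floor
        assert abs(bp.baseline - spec.baseline) < 3 * sigma / math.sqrt(6)

    def test_efficiency_undefined_where_denominator_nonpositive(self):
        p = profile_from([100, 100, 100, 100, 90, 400, 800, 900, 950, 980])
        bp = subtract_baseline(p, (1, 4))
        # cycle 5 has fc=-10; efficiency of cycle 6 has denominator <= 0
        assert math.isnan(bp.ec_at(6))
        assert bp.ec_at(7) == pytest.approx(700 / 300 - 1)


class TestCycleEfficiency:
    @pytest.mark.parametrize(
        "prev,cur,expected",
        [(200, 400, 1.0), (400, 400, 0.0), (100, 150, 0.5)],
    )
    def test_ratio_minus_one(self, prev, cur, expected):
        assert cycle_efficiency(prev, cur) == pytest.approx(expected)

    @pytest.mark.parametrize("prev", [0.0, -5.0])
    def test_nonpositive_denominator_flagged_nan(self, prev):
        assert math.isnan(cycle_efficiency(prev, 100.0))

    def test_recurrence_profile_efficiency_is_linear_in_fc(self):
        # update rule of the generator is the oracle: E_C = emax*(1 - fc/fmax)
        spec = SimSpec(
            n_star=1e4, emax=0.9, fmax=1e6, baseline=0.0, noise_sd=0.0, seed=0
        )
        p, _ = simulate_profile(spec)
        bp = subtract_baseline(p, None)
        for c in range(2, p.n_cycles + 1):
            ec = bp.ec_at(c)
            expected = 0.9 * (1 - bp.fc_at(c) / 1e6)
            assert ec == pytest.approx(expected, abs=1e-9)


class TestFitLre:
    def test_exact_points_on_a_line(self):
        # ec = 1.0 - 2e-7 * fc at three fluorescence values
        fc = np.array([1e5, 2e5, 3e5])
        raw = np.concatenate([np.zeros(7), fc])
        # build a profile whose cycles 8..10 carry these fc values and whose
        # ec values at those cycles equal the line exactly
        # Simpler: drive fit_lre directly through a hand-made BaselinedProfile
        from lreqpcr.core import BaselinedProfile

        n = 10
        full_fc = np.zeros(n)
        full_fc[7:] = fc
        ec = np.full(n - 1, np.nan)
        for c, v in zip((8, 9, 10), fc):
            ec[c - 2] = 1.0 - 2e-7 * v
        bp = BaselinedProfile(source=None, baseline=0.0, fc=full_fc, ec=ec)
        fit = fit_lre(bp, LreWindow(start_cycle=8, size=3))
        assert fit.emax == pytest.approx(1.0, rel=1e-12)
        assert fit.delta_e == pytest.approx(-2e-7, rel=1e-12)
        assert fit.fmax == pytest.approx(5e6, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_parameters_to_machine_precision(
        self, noiseless_bare_profile
    ):
        p, truth = noiseless_bare_profile
        spec = truth.spec
        bp = subtract_baseline(p, None)
        # any >=3-cycle window inside the rise
        for start, size in [(20, 3), (22, 5), (18, 8)]:
            fit = fit_lre(bp, LreWindow(start_cycle=start, size=size))
            assert fit.emax == pytest.approx(spec.emax, rel=1e-10)
            assert fit.delta_e == pytest.approx(-spec.emax / spec.fmax, rel=1e-10)

    def test_agrees_with_normal_equations_oracle(self, rng):
        from lreqpcr.core import BaselinedProfile

        for _ in range(20):
            n = 12
            fc = np.sort(rng.uniform(1e4, 5e6, n))
            full = np.concatenate([np.zeros(2), fc])
            noise = rng.normal(0, 0.02, n)
            ec_vals = 0.9 - 1.5e-7 * fc + noise
            ec = np.full(len(full) - 1, np.nan)
            ec[1 : 1 + n] = ec_vals
            bp = BaselinedProfile(source=None, baseline=0.0, fc=full, ec=ec)
            fit = fit_lre(bp, LreWindow(start_cycle=3, size=n))
            intercept, slope, r2 = ols_normal_equations(fc, ec_vals)
            assert fit.emax == pytest.approx(intercept, rel=1e-9)
            assert fit.delta_e == pytest.approx(slope, rel=1e-9)
            assert fit.r2 == pytest.approx(r2, rel=1e-9)

    def test_flat_profile_fit_flagged_invalid(self):
        from lreqpcr.core import BaselinedProfile

        fc = np.full(12, 500.0)
        ec = np.zeros(11)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=ec)
        fit = fit_lre(bp, LreWindow(start_cycle=4, size=4))
        assert not fit.valid


class TestForwardInverseModel:
    def test_zero_cycle_identity(self):
        assert predict_fc(1e-3, 0.95, 5e6, 0) == pytest.approx(1e-3, rel=1e-12)
        assert back_calculate_f0(1e-3, 0, 0.95, 5e6) == pytest.approx(
            1e-3, rel=1e-12
        )

    def test_asymptote(self):
        assert predict_fc(1e-3, 0.95, 5e6, 1000) == pytest.approx(5e6, rel=1e-6)

    def test_round_trip_inversion(self):
        fc = predict_fc(1e-3, 0.95, 5e6, 25)
        assert back_calculate_f0(fc, 25, 0.95, 5e6) == pytest.approx(
            1e-3, rel=1e-9
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        f0=st.floats(1e-6, 1e3),
        emax=st.floats(0.3, 1.0),
        log_ratio=st.floats(1.0, 12.0),
        cycle=st.floats(0.0, 60.0),
    )
    def test_round_trip_inversion_property(self, f0, emax, log_ratio, cycle):
        fmax = f0 * 10**log_ratio
        fc = predict_fc(f0, emax, fmax, cycle)
        # the analysis never back-calculates within 0.1% of the plateau
        # (pole of the inversion), so neither does the property
        if 0 < fc <= 0.999 * fmax:
            assert back_calculate_f0(fc, cycle, emax, fmax) == pytest.approx(
                f0, rel=1e-9
            )

    def test_f0_past_plateau_flagged(self):
        assert math.isnan(back_calculate_f0(5e6, 30, 0.95, 5e6))

    def test_f0_identical_across_cycles_on_closed_form_profile(self):
        f0, emax, fmax = 2e-3, 0.9, 6e6
        for c in range(1, 60):
            fc = predict_fc(f0, emax, fmax, c)
            if 1.0 < fc < 0.99 * fmax:
                assert back_calculate_f0(fc, c, emax, fmax) == pytest.approx(
                    f0, rel=1e-9
                )


class TestCHalf:
    def test_closed_form_value(self):
        # f0 = fmax/3 leaves (fmax-f0)/f0 = 2; with emax 1 -> ln2/ln2 = 1
        assert c_half_from_fit(1e6, 1.0, 3e6) == pytest.approx(1.0, rel=1e-12)

    def test_defining_property(self):
        c = c_half_from_fit(1e-3, 0.87, 4e6)
        assert predict_fc(1e-3, 0.87, 4e6, c) == pytest.approx(2e6, rel=1e-9)

    def test_strictly_decreasing_in_f0(self):
        f0s = np.logspace(-6, 3, 40)
        cs = [c_half_from_fit(f, 0.95, 1e4 + 1e6) for f in f0s]
        assert all(a > b for a, b in zip(cs, cs[1:]))


class TestObservedHalfMax:
    def test_hand_computable_crossing(self):
        from lreqpcr.core import BaselinedProfile

        fc = np.array([0, 10, 50, 90, 100, 100], dtype=float)
        bp = BaselinedProfile(source=None, baseline=0.0, fc=fc, ec=np.full(5, np.nan))
        # plateau 100, half 50 reached exactly at cycle 3
        assert observed_half_max_cycle(bp) == pytest.approx(3.0)

    def test_flat_profile_flagged_non_amplifying(self):
        from lreqpcr.core import BaselinedProfile

        bp = BaselinedProfile(
            source=None, baseline=0.0, fc=np.zeros(12), ec=np.full(11, np.nan)
        )
        with pytest.raises(NonAmplifyingError):
            observed_half_max_cycle(bp)

    def test_agrees_with_fit_based_c_half_on_clean_profiles(self):
        for seed, n_star in [(1, 1e3), (2, 1e4), (3, 1e5)]:
            p, truth = simulate_profile(
                SimSpec(n_star=n_star, noise_sd=0.0, baseline=0.0, seed=seed)
            )
            bp = subtract_baseline(p, None)
            assert observed_half_max_cycle(bp) == pytest.approx(
                truth.c_half, abs=0.5
            )


class TestScaleEquivariance:
    def test_scaling_fc_preserves_ec_and_scales_f0(self, noiseless_bare_profile):
        from lreqpcr.core import BaselinedProfile

        p, _ = noiseless_bare_profile
        bp = subtract_baseline(p, None)
        k = 1e3
        scaled = BaselinedProfile(
            source=p, baseline=0.0, fc=bp.fc * k, ec=bp.ec.copy()
        )
        w = LreWindow(start_cycle=22, size=4)
        fit = fit_lre(bp, w)
        fit_k = fit_lre(scaled, w)
        assert fit_k.emax == pytest.approx(fit.emax, rel=1e-9)
        assert fit_k.fmax == pytest.approx(k * fit.fmax, rel=1e-9)
        assert fit_k.avg_f0 == pytest.approx(k * fit.avg_f0, rel=1e-9)


class TestProfileInvariants:
    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValueError):
            profile_from(np.ones(9))

    def test_non_finite_reading_rejected(self):
        with pytest.raises(ValueError):
            profile_from([1, 2, 3, 4, 5, 6, 7, 8, 9, np.nan])

    def test_bad_amplicon_size_rejected(self):
        with pytest.raises(ValueError):
            profile_from(np.ones(12), amplicon_size=0)
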