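"""First-contact detection, MFCT estimation, viscosity correction,
sink-radius optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretloop.data import ETA_D2O_MPAS, ETA_SPC_MPAS, KINETIC_REFERENCE
from fretloop.kinetics import (ContactEventList, detect_contacts, mfct,
                               mfct_uncertainty, optimize_sink_radius,
                               smooth_trace, viscosity_correct)
from fretloop.synthetic import gen_ou_trace
from fretloop.trajectory import DistanceTrace


def events_from_intervals(intervals):
    intervals = np.asarray(intervals, dtype=float)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    return ContactEventList(times, intervals, 0.45)


class TestSmoothTrace:
    def test_reproduces_cubic_polynomial(self):
        t = np.arange(200.0)
        values = 1e-6 * t ** 3 - 1e-4 * t ** 2 + 0.01 * t + 1.0
        trace = DistanceTrace(t, values)
        out = smooth_trace(trace, window=21, polyorder=3)
        np.testing.assert_allclose(out.values[10:-10], values[10:-10], atol=1e-10)

    def test_constant_unchanged(self):
        trace = DistanceTrace(np.arange(100.0), np.full(100, 0.9))
        out = smooth_trace(trace, window=11, polyorder=2)
        np.testing.assert_allclose(out.values, 0.9)

    def test_reduces_noise_about_signal(self, rng):
        t = np.arange(2000.0)
        sine = 0.9 + 0.2 * np.sin(2 * np.pi * t / 500)
        noisy = sine + 0.05 * rng.standard_normal(t.size)
        out = smooth_trace(DistanceTrace(t, noisy), window=31, polyorder=3)
        assert np.var(out.values - sine) < np.var(noisy - sine)

    @pytest.mark.parametrize("window,polyorder", [(10, 3), (5, 5), (501, 3)])
    def test_parameter_violations(self, window, polyorder):
        trace = DistanceTrace(np.arange(100.0), np.full(100, 0.9))
        with pytest.raises(ValueError):
            smooth_trace(trace, window, polyorder)


class TestDetectContacts:
    def test_hand_trace(self):
        trace = DistanceTrace(np.arange(7.0),
                              [0.6, 0.5, 0.43, 0.50, 0.60, 0.44, 0.60])
        ev = detect_contacts(trace, 0.45)
        np.testing.assert_allclose(ev.contact_times, [2.0, 5.0])
        np.testing.assert_allclose(ev.intervals, [3.0])

    def test_trace_above_r_gives_no_events(self):
        trace = DistanceTrace(np.arange(10.0), np.linspace(0.9, 1.0, 10))
        ev = detect_contacts(trace, 0.45)
        assert ev.contact_times.size == 0 and ev.n_int == 0

    def test_single_monotone_crossing(self):
        trace = DistanceTrace(np.arange(10.0), np.linspace(1.0, 0.1, 10))
        ev = detect_contacts(trace, 0.45)
        assert ev.contact_times.size == 1 and ev.n_int == 0

    def test_programmed_telegraph_crossings(self):
        # Square-wave-like trace with known downward-crossing indices.
        values = np.tile(np.r_[np.full(5, 0.8), np.full(5, 0.3)], 4)
        trace = DistanceTrace(np.arange(values.size, dtype=float), values)
        ev = detect_contacts(trace, 0.45)
        np.testing.assert_allclose(ev.contact_times, [5.0, 15.0, 25.0, 35.0])
        np.testing.assert_allclose(ev.intervals, [10.0, 10.0, 10.0])

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-0.5, 0.5), st.integers(0, 2 ** 31 - 1))
    def test_joint_shift_invariance(self, shift, seed):
        trace = gen_ou_trace(n=2000, seed=seed)
        shifted = DistanceTrace(trace.times, trace.values + shift)
        ev0 = detect_contacts(trace, 0.9)
        ev1 = detect_contacts(shifted, 0.9 + shift)
        np.testing.assert_allclose(ev0.contact_times, ev1.contact_times)


class TestMFCT:
    def test_constant_intervals_give_half(self):
        ev = events_from_intervals(np.full(50, 6000.0))
        assert mfct(ev) == pytest.approx(3.0)  # c/2 in ns

    def test_hand_arithmetic(self):
        ev = events_from_intervals([2.0, 4.0])
        # <d^2> = 10, <d> = 3 -> 10/6 ps
        assert mfct(ev) * 1000 == pytest.approx(10.0 / 6.0)

    def test_exponential_intervals_recover_mean(self, rng):
        mu_ns = 8.0
        intervals = rng.exponential(mu_ns * 1000, 100_000)
        ev = events_from_intervals(intervals)
        assert mfct(ev) == pytest.approx(mu_ns, rel=0.02)

    def test_cauchy_schwarz_lower_bound(self, rng):
        for seed in range(5):
            d = np.random.default_rng(seed).lognormal(6, 1, 500)
            ev = events_from_intervals(d)
            assert mfct(ev) * 1000 >= d.mean() / 2 - 1e-9

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError):
            mfct(events_from_intervals([5.0]))


class TestMFCTUncertainty:
    def test_identical_intervals_zero(self):
        ev = events_from_intervals(np.full(30, 1000.0))
        assert mfct_uncertainty(ev) == 0.0

    def test_matches_bootstrap_for_exponential(self, rng):
        intervals = rng.exponential(5000.0, 10_000)
        ev = events_from_intervals(intervals)
        analytic = mfct_uncertainty(ev)
        boot_idx = rng.integers(0, intervals.size, (1000, intervals.size))
        resampled = intervals[boot_idx]
        t_boot = (np.mean(resampled ** 2, axis=1)
                  / (2 * np.mean(resampled, axis=1))) / 1000.0
        assert analytic == pytest.approx(t_boot.std(ddof=1), rel=0.25)

    def test_scales_with_viscosity_factor(self):
        sigma = 0.84
        _, f = viscosity_correct(1.0, ETA_D2O_MPAS, ETA_SPC_MPAS)
        assert sigma * f == pytest.approx(2.08, abs=0.005)


class TestViscosityCorrection:
    def test_equal_viscosities_identity(self):
        T, f = viscosity_correct(5.0, 0.9, 0.9)
        assert T == 5.0 and f == 1.0

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(ValueError):
            viscosity_correct(5.0, -1.0, 0.445)

    def test_reference_table_arithmetic(self):
        """Corrected times, propagated errors, and percent deviations all
        follow from the uncorrected values and the viscosity pair."""
        printed_corr = {"trpDbo": (21.36, 2.08, 2.9), "(GS)": (12.64, 1.20, 2.8),
                        "(GS)2": (17.60, 2.11, 3.5), "(GS)3": (22.13, 3.32, 7.8)}
        for row in KINETIC_REFERENCE:
            T_corr, f = viscosity_correct(row.T_md, ETA_D2O_MPAS, ETA_SPC_MPAS)
            sigma_corr = row.sigma_md * f
            pct = 100.0 * abs(T_corr - row.T_exp) / row.T_exp
            exp_T, exp_sigma, exp_pct = printed_corr[row.peptide]
            # published corrected columns carry rounding of unrounded inputs
            assert T_corr == pytest.approx(exp_T, abs=0.02)
            assert sigma_corr == pytest.approx(exp_sigma, abs=0.02)
            assert round(pct, 1) == exp_pct
        # the factor itself, from the viscosities, to 3 d.p.
        _, f = viscosity_correct(1.0, ETA_D2O_MPAS, ETA_SPC_MPAS)
        assert round(f, 3) == 2.472


class TestSinkOptimization:
    @pytest.fixture(scope="class")
    def ou_trace(self):
        return gen_ou_trace(mean=0.9, relaxation_time=100.0, stationary_std=0.2,
                            n=200_000, dt=1.0, seed=3)

    def test_recovers_calibrated_radius_exactly(self, ou_trace):
        f = ETA_D2O_MPAS / ETA_SPC_MPAS
        target = mfct(detect_contacts(ou_trace, 0.47)) * f
        res = optimize_sink_radius(ou_trace, target, f)
        assert res.r_opt == pytest.approx(0.47, abs=1e-9)
        assert res.percent_error == pytest.approx(0.0, abs=1e-9)

    def test_unreachable_target_hits_boundary(self):
        # Telegraph trace: every radius in the band sees identical crossings,
        # so T(r) is constant and an unreachable target ties across the grid;
        # the tie-break returns the smallest radius, which is flagged as a
        # boundary solution.
        values = np.tile(np.r_[np.full(10, 0.8), np.full(10, 0.3)], 50)
        trace = DistanceTrace(np.arange(values.size, dtype=float), values)
        res = optimize_sink_radius(trace, T_exp=1e6, f=2.472)
        assert res.at_boundary
        assert res.r_opt == res.grid[0][0]

    def test_objective_minimal_on_returned_grid(self, ou_trace):
        f = 2.472
        target = 3.0
        res = optimize_sink_radius(ou_trace, target, f)
        errs = [abs(T - target) / target for _, T in res.grid]
        best = dict(res.grid)[res.r_opt]
        assert abs(best - target) / target == pytest.approx(min(errs), abs=1e-12)

    def test_mfct_increases_as_radius_shrinks(self, ou_trace):
        times = []
        for r in (0.55, 0.50, 0.45, 0.40):
            times.append(mfct(detect_contacts(ou_trace, r)))
        assert times == sorted(times)

    def test_no_intervals_in_range_rejected(self):
        trace = DistanceTrace(np.arange(100.0), np.full(100, 2.0))
        with pytest.raises(ValueError, match="sink radius"):
            optimize_sink_radius(trace, 1.0, 2.472)
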