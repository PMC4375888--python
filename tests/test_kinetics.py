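"""Tests of velocity smoothing, pause classification, and rate-constant fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filakin import kinetics, synthetic
from filakin.kymo import FilamentTrace


def linear_trace(slope, n=100, dt=1.0):
    t = np.arange(n) * dt
    return FilamentTrace(t, slope * t)


class TestSmoothVelocity:
    def test_linear_trace_gives_constant_slope(self):
        v = kinetics.smooth_velocity(linear_trace(9.0), window=10)
        assert np.allclose(v, 9.0)

    def test_window_one_returns_raw_finite_differences(self):
        tr = linear_trace(2.0, n=20)
        tr.delta_length[10] += 5.0  # a kink the running mean would blur
        v = kinetics.smooth_velocity(tr, window=1)
        assert v[9] == pytest.approx((tr.delta_length[10] - tr.delta_length[8]) / 2.0)

    def test_noisy_linear_trace_mean_velocity(self):
        rng = np.random.default_rng(0)
        t = np.arange(400.0)
        tr = FilamentTrace(t, 9.0 * t + rng.normal(0, 2.0, t.size))
        v = kinetics.smooth_velocity(tr, window=10)
        se = np.std(v, ddof=1) / np.sqrt(v.size)
        assert abs(np.mean(v) - 9.0) < max(2 * se, 0.1)

    def test_non_uniform_sampling_rejected(self):
        tr = FilamentTrace(np.array([0.0, 1.0, 3.0, 4.0]), np.zeros(4))
        with pytest.raises(ValueError, match="uniform"):
            kinetics.smooth_velocity(tr, window=1)


class TestClassifyPhases:
    def test_all_fast_is_fully_active(self):
        s = kinetics.classify_phases(np.full(50, 9.0))
        assert s.pausing_probability == 0.0
        assert s.labels.all()

    def test_all_stopped_is_fully_paused(self):
        s = kinetics.classify_phases(np.zeros(50))
        assert s.pausing_probability == 1.0
        assert not s.labels.any()

    def test_counting_two_long_pause_runs(self):
        v = np.full(100, 9.0)
        v[10:25] = 0.0
        v[60:70] = 0.0
        s = kinetics.classify_phases(v, min_run=1)
        assert s.pausing_probability == pytest.approx(0.25)

    def test_short_blips_are_debounced(self):
        v = np.full(60, 9.0)
        v[30] = 0.0  # single-sample dropout
        s = kinetics.classify_phases(v, min_run=3)
        assert s.pausing_probability == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_pause_probability_ignores_length_units_of_the_image(self, scale):
        # P_p depends only on velocities (already in subunits/s), not on any
        # multiplicative intensity calibration of the source image
        v = np.array([0.0] * 25 + [9.0] * 75)
        s = kinetics.classify_phases(v, min_run=1)
        assert s.pausing_probability == pytest.approx(0.25)
        assert scale > 0  # the rescaling never enters the classification


class TestPauseFreeVelocity:
    def test_pure_linear_trace(self):
        pf = kinetics.pause_free_velocity(linear_trace(9.0))
        assert pf.velocity == pytest.approx(9.0, abs=1e-9)

    def test_growth_pause_trace_excludes_paused_half(self):
        t = np.arange(200.0)
        y = np.where(t < 100, 10.0 * t, 10.0 * 99.0 + 10.0)
        tr = FilamentTrace(t, y)
        pf = kinetics.pause_free_velocity(tr)
        v = kinetics.smooth_velocity(tr, window=10)
        s = kinetics.classify_phases(v)
        assert pf.velocity == pytest.approx(10.0, rel=0.02)
        assert s.pausing_probability == pytest.approx(0.5, abs=0.05)

    def test_simulated_trace_recovers_net_rate(self):
        es = []
        for seed in range(20):
            tr = synthetic.simulate_growth_trace(
                synthetic.GrowthParams(kon=11, conc=1, koff=2, duration=500, dt=1, seed=seed)
            )
            es.append(kinetics.pause_free_velocity(tr).velocity)
        se = np.std(es, ddof=1) / np.sqrt(len(es))
        assert abs(np.mean(es) - 9.0) < 3 * se + 1e-6

    def test_fully_paused_trace_errors(self):
        with pytest.raises(ValueError, match="paused"):
            kinetics.pause_free_velocity(linear_trace(0.0))


class TestRateConstants:
    def test_exact_table_line_for_surface_myosin(self):
        # E = 11 c - 1.6 at the measured concentrations
        conc = [0.3, 0.5, 1.0, 2.0]
        pts = [(c, 11.0 * c - 1.6) for c in conc]
        r = kinetics.fit_rate_constants(pts)
        assert r.kon == pytest.approx(11.0, abs=1e-9)
        assert r.koff == pytest.approx(1.6, abs=1e-9)
        assert r.cc == pytest.approx(0.1454545, abs=1e-6)
        assert round(r.cc, 2) == 0.15

    def test_line_through_origin_gives_zero_critical_concentration(self):
        pts = [(c, 8.0 * c) for c in (0.5, 1.0, 1.5)]
        r = kinetics.fit_rate_constants(pts)
        assert r.koff == pytest.approx(0.0, abs=1e-9)
        assert r.cc == pytest.approx(0.0, abs=1e-9)

    def test_collinear_points_reproduced_to_machine_precision(self):
        pts = [(c, 7.7 * c - 0.7) for c in (0.3, 0.7, 1.2, 1.9)]
        r = kinetics.fit_rate_constants(pts)
        np.testing.assert_allclose([r.kon, r.koff], [7.7, 0.7], rtol=1e-12, atol=1e-12)

    def test_ci_coverage_is_nominal(self):
        # 500 replicates of a noisy 4-concentration experiment: the 95% CI
        # should cover the generating kon in 95% +/- 3% of replicates
        rng = np.random.default_rng(12345)
        conc = np.array([0.3, 0.5, 1.0, 2.0])
        kon_true, koff_true, sigma = 11.0, 1.6, 0.5
        hits = 0
        for _ in range(500):
            e = kon_true * conc - koff_true + rng.normal(0, sigma, conc.size)
            r = kinetics.fit_rate_constants(list(zip(conc, e, [sigma] * 4)))
            if r.ci95_kon[0] <= kon_true <= r.ci95_kon[1]:
                hits += 1
        assert abs(hits / 500 - 0.95) <= 0.03

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            kinetics.fit_rate_constants([(1.0, 9.0), (1.0, 9.5)])


class TestCriticalConcentration:
    @pytest.mark.parametrize(
        "kon,koff,printed",
        [
            (11.0, 1.6, 0.15),  # surface NEM-myosin, barbed
            (0.8, 0.4, 0.5),  # surface NEM-myosin, pointed
            (8.5, 0.1, 0.012),  # filamin, barbed
            (5.3, 2.6, 0.5),  # filamin, pointed (printed at one decimal)
        ],
    )
    def test_published_rate_pairs(self, kon, koff, printed):
        cc = kinetics.critical_concentration(kon, koff)
        decimals = len(str(printed).split(".")[1])
        assert round(cc, decimals) == pytest.approx(printed)

    def test_zero_koff_gives_zero(self):
        assert kinetics.critical_concentration(5.0, 0.0) == 0.0

    def test_zero_kon_undefined(self):
        with pytest.raises(ValueError):
            kinetics.critical_concentration(0.0, 1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_invariant_under_common_rate_rescaling(self, scale):
        base = kinetics.critical_concentration(11.0, 1.6)
        assert kinetics.critical_concentration(11.0 * scale, 1.6 * scale) == pytest.approx(base, rel=1e-9)


class TestDensityConversions:
    def test_one_nanomolar_on_flow_cell_surfaces(self):
        # 6.022e9 molecules spread over 2e8 um^2
        d = kinetics.surface_density_from_concentration(1.0, volume_uL=10, area_mm2=100, both_surfaces=True)
        assert d == pytest.approx(30.1, abs=0.1)

    def test_zero_concentration_and_linearity(self):
        assert kinetics.surface_density_from_concentration(0.0) == 0.0
        d1 = kinetics.surface_density_from_concentration(3.0)
        d2 = kinetics.surface_density_from_concentration(6.0)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    @pytest.mark.parametrize("density,printed", [(5900.0, 35), (16700.0, 100)])
    def test_footprint_conversion_matches_printed_values(self, density, printed):
        per_um = kinetics.tethers_per_micron(density)
        assert round(per_um) == printed

    def test_occupancy_saturates_at_one_tether_per_subunit(self):
        assert kinetics.fractional_occupancy(0.0) == 0.0
        assert kinetics.fractional_occupancy(35.4) == pytest.approx(0.0957, abs=2e-4)
        assert kinetics.fractional_occupancy(370.0) == 1.0
        assert kinetics.fractional_occupancy(1000.0) == 1.0
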