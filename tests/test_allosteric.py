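"""Tests of the allosteric lattice Monte Carlo model and its chi-square fit."""

import numpy as np
import pytest

from filakin import allosteric, synthetic
from filakin.allosteric import DensityResponse, LocalConcModel, MCConfig


def brute_force_velocity(n, tethers, alpha, lc, kon0=11.0, conc=1.0, koff=2.0):
    """Independent per-site oracle: explicit max over all tethers behind i."""
    tethers = np.asarray(tethers)
    total = 0.0
    for i in range(n):
        factor = 1.0
        for j in tethers:
            if j <= i and (i - j) < lc:
                factor = max(factor, 1.0 + (alpha - 1.0) * (1.0 - (i - j) / lc))
        total += factor * kon0 * conc - koff
    return total / n


class TestPlaceTethers:
    def test_zero_occupancy_is_empty(self):
        assert allosteric.place_tethers(1000, 0.0, 0).size == 0

    def test_full_occupancy_is_every_site(self):
        t = allosteric.place_tethers(1000, 1.0, 0)
        assert np.array_equal(t, np.arange(1000))

    def test_binomial_count_statistics(self):
        n, occ = 100_000, 0.01
        counts = [allosteric.place_tethers(n, occ, seed).size for seed in range(100)]
        se = np.sqrt(n * occ * (1 - occ)) / np.sqrt(100)
        assert abs(np.mean(counts) - n * occ) < 3 * se

    def test_sorted_and_reproducible(self):
        a = allosteric.place_tethers(5000, 0.05, 7)
        b = allosteric.place_tethers(5000, 0.05, 7)
        assert np.array_equal(a, b)
        assert np.all(np.diff(a) > 0)


class TestEffectiveKon:
    def test_no_tethers_gives_basal_rate(self):
        assert allosteric.effective_kon(50, [], 5.0, 76.0) == pytest.approx(11.0)

    def test_at_tether_site_rate_is_alpha_fold(self):
        assert allosteric.effective_kon(20, [20], 5.0, 76.0) == pytest.approx(5.0 * 11.0)

    def test_linear_decay_at_half_propagation_length(self):
        # alpha=9, L_C=160, nearest tether 80 behind: 1 + 8*(1 - 80/160) = 5
        assert allosteric.effective_kon(100, [20], 9.0, 160.0) == pytest.approx(5.0 * 11.0)

    def test_beyond_propagation_length_rate_is_basal(self):
        assert allosteric.effective_kon(200, [20, 30], 9.0, 160.0, kon0=11.0) == pytest.approx(11.0)

    def test_tethers_ahead_of_tip_do_not_act(self):
        assert allosteric.effective_kon(10, [50], 9.0, 160.0) == pytest.approx(11.0)

    def test_overlapping_tethers_take_maximum_not_sum(self):
        # several tethers right behind the tip must not exceed alpha*kon0
        v = allosteric.effective_kon(10, [8, 9, 10], 5.0, 76.0)
        assert v == pytest.approx(5.0 * 11.0)

    def test_lc_of_one_acts_only_at_the_tether_site(self):
        assert allosteric.effective_kon(10, [10], 5.0, 1.0) == pytest.approx(55.0)
        assert allosteric.effective_kon(11, [10], 5.0, 1.0) == pytest.approx(11.0)


class TestSimulateElongation:
    def test_baseline_constants_give_nine_subunits_per_second(self):
        cfg = MCConfig(conc=1.0, lattice_size=10_000, seed=0)
        assert allosteric.simulate_elongation(cfg, 1.0, 76.0, 0.05) == pytest.approx(9.0)

    def test_saturated_lattice_closed_form(self):
        cfg = MCConfig(conc=1.0, lattice_size=5000, seed=0)
        for alpha in (0.4, 5.1, 9.0):
            v = allosteric.simulate_elongation(cfg, alpha, 76.0, 1.0)
            assert v == pytest.approx(alpha * 11.0 * 1.0 - 2.0, abs=1e-12)

    def test_empty_lattice_closed_form(self):
        cfg = MCConfig(conc=1.0, lattice_size=5000, seed=0)
        v = allosteric.simulate_elongation(cfg, 5.1, 76.0, 0.0)
        assert v == pytest.approx(9.0, abs=1e-12)

    def test_expected_mode_equals_brute_force_oracle(self):
        n = 1000
        cfg = MCConfig(conc=1.0, lattice_size=n, seed=11)
        v = allosteric.simulate_elongation(cfg, 5.1, 76.0, 0.01)
        tethers = allosteric.place_tethers(n, 0.01, np.random.default_rng(11))
        assert v == pytest.approx(brute_force_velocity(n, tethers, 5.1, 76.0), abs=1e-12)

    def test_stochastic_matches_expected_for_homogeneous_rates(self):
        # with no tethers every site has the same net rate, where traversal
        # velocity and site-averaged rate coincide
        diffs = []
        for seed in range(50):
            ve = allosteric.simulate_elongation(MCConfig(lattice_size=10_000, seed=seed), 1.0, 76.0, 0.0)
            vs = allosteric.simulate_elongation(
                MCConfig(lattice_size=10_000, mode="stochastic", seed=seed), 1.0, 76.0, 0.0
            )
            diffs.append(vs - ve)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_monotone_in_occupancy_alpha_and_lc(self):
        cfg = MCConfig(conc=1.0, lattice_size=4000, seed=3)
        occs = np.linspace(0.0, 0.3, 5)
        alphas = np.linspace(1.5, 9.0, 5)
        lcs = np.linspace(1.0, 200.0, 5)
        for alpha in alphas:
            for lc in lcs:
                vs = [allosteric.simulate_elongation(cfg, alpha, lc, o) for o in occs]
                assert np.all(np.diff(vs) >= -1e-12)
        # alpha < 1: non-increasing in occupancy
        for lc in lcs:
            vs = [allosteric.simulate_elongation(cfg, 0.4, lc, o) for o in occs]
            assert np.all(np.diff(vs) <= 1e-12)
        # monotone in alpha and in lc at fixed occupancy
        for occ in occs[1:]:
            va = [allosteric.simulate_elongation(cfg, a, 76.0, occ) for a in alphas]
            assert np.all(np.diff(va) >= -1e-12)
            vl = [allosteric.simulate_elongation(cfg, 5.1, lc, occ) for lc in lcs]
            assert np.all(np.diff(vl) >= -1e-12)

    def test_invalid_occupancy_rejected(self):
        with pytest.raises(ValueError):
            allosteric.simulate_elongation(MCConfig(lattice_size=1000), 5.1, 76.0, 1.5)


class TestChiSquare:
    def test_perfect_match_is_zero(self):
        v = np.array([9.0, 15.0, 30.0])
        assert allosteric.chi_square(v, v, np.ones(3)) == 0.0

    def test_single_two_sigma_residual_is_four(self):
        v = np.array([10.0])
        assert allosteric.chi_square(v, v - 2.0 * 0.5, np.array([0.5])) == pytest.approx(4.0)

    def test_appending_a_mismatch_never_decreases(self):
        v = np.array([9.0, 15.0])
        sim = np.array([9.1, 14.0])
        base = allosteric.chi_square(v, sim, np.array([0.5, 0.5]))
        grown = allosteric.chi_square(
            np.append(v, 30.0), np.append(sim, 25.0), np.array([0.5, 0.5, 0.5])
        )
        assert grown >= base

    def test_zero_std_rejected_with_floor_guidance(self):
        with pytest.raises(ValueError, match="floor"):
            allosteric.chi_square(np.ones(2), np.ones(2), np.array([1.0, 0.0]))


class TestGridFit:
    @staticmethod
    def _round_trip(alpha, lc, gen_seed=123, fit_seed=999, n=10_000, reps=20):
        cfg = MCConfig(lattice_size=n, seed=gen_seed)
        dens = np.geomspace(5, 18_000, 8)
        data = synthetic.simulate_density_response(alpha, lc, cfg, dens, reps=reps)
        return allosteric.grid_fit(data, MCConfig(lattice_size=n, seed=fit_seed), reps=reps)

    def test_noiseless_round_trip_recovers_generating_parameters(self):
        fit = self._round_trip(5.1, 76.0)
        # refined grid: x5 resolution of the default 30-node coarse grids
        alpha_step = 5.1 * ((20.0 / 0.1) ** (1.0 / 29.0) - 1.0) / 5.0
        lc_step = 2.0 * (400.0 - 1.0) / 29.0 / 10.0
        assert abs(fit.alpha - 5.1) <= alpha_step
        assert abs(fit.lc - 76.0) <= lc_step
        assert not fit.boundary

    def test_optimum_lies_inside_its_own_intervals(self):
        fit = self._round_trip(0.7, 11.0)
        assert fit.chi2_min >= 0.0
        assert fit.ci68_alpha[0] <= fit.alpha <= fit.ci68_alpha[1]
        assert fit.ci68_lc[0] <= fit.lc <= fit.ci68_lc[1]

    def test_intervals_nested(self):
        fit = self._round_trip(5.1, 76.0)
        assert fit.ci95_alpha[0] <= fit.ci68_alpha[0] <= fit.ci68_alpha[1] <= fit.ci95_alpha[1]
        assert fit.ci95_lc[0] <= fit.ci68_lc[0] <= fit.ci68_lc[1] <= fit.ci95_lc[1]

    def test_boundary_solution_flagged(self):
        fit = self._round_trip(0.4, 1.0)
        assert fit.boundary  # L_C at the grid floor of one monomer

    def test_delta_chi2_interval_covers_truth_in_noisy_replicates(self):
        # nominal 68% for delta-chi2 = 1; finite grid and replicate noise
        # erode it, so require >= 60% over 50 noisy replicates
        n, reps = 2000, 8
        dens = np.geomspace(5, 18_000, 6)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = MCConfig(lattice_size=n, seed=10_000 + rep)
            data = synthetic.simulate_density_response(
                5.1, 76.0, cfg, dens, reps=reps, noise_sd=0.5, seed=20_000 + rep
            )
            fit = allosteric.grid_fit(
                data, MCConfig(lattice_size=n, seed=30_000 + rep), reps=reps
            )
            if fit.ci68_alpha[0] <= 5.1 <= fit.ci68_alpha[1]:
                hits += 1
        assert hits / n_rep >= 0.60

    def test_too_few_points_rejected(self):
        dr = DensityResponse([5, 50], [1e-4, 1e-3], [9.1, 9.5], [0.1, 0.1], [5, 5])
        with pytest.raises(ValueError, match="at least 3"):
            allosteric.grid_fit(dr, MCConfig(lattice_size=1000, seed=0), reps=2)


class TestLocalConcentrationModel:
    def test_zero_density_reduces_to_basal_velocity(self):
        m = LocalConcModel(kon=11.0, koff=2.0, c0=1.0, d=0.0)
        assert allosteric.local_concentration_velocity(m) == pytest.approx(9.0)

    def test_worked_value(self):
        m = LocalConcModel(kon=11.6, koff=1.4, c0=1.0, d=0.1)
        assert allosteric.local_concentration_velocity(m) == pytest.approx(14.84)

    def test_exactly_affine_in_density(self):
        vs = [
            allosteric.local_concentration_velocity(LocalConcModel(11.0, 2.0, 1.0, d))
            for d in np.linspace(0, 1, 9)
        ]
        second = np.diff(vs, 2)
        assert np.allclose(second, 0.0, atol=1e-12)
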