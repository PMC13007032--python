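"""Histogramming, window overlap and the WHAM solver.

The WHAM fixed-point iteration is cross-checked against an
algorithmically independent route (direct minimisation of the convex
WHAM likelihood), and against analytic truths on synthetic windows.
"""

import numpy as np
import pytest

from slabpmf import (AnalyticProfileSpec, BiasSpec, FreeEnergyProfile,
                     WindowSamples, build_histograms, combine_replicas,
                     evaluate_profile, generate_window_set, wham_solve,
                     wham_solve_mle, window_overlap, zero_by_plateau)


def _window(samples, center=0.0, k=0.0):
    return WindowSamples(bias=BiasSpec(center, k), samples=np.asarray(samples),
                         temperature=300.0)


class TestBuildHistograms:
    def test_counts_land_in_one_bin(self):
        h = build_histograms([_window([0.5] * 10)], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(h.counts, [[10, 0]])

    def test_interior_edge_goes_right(self):
        h = build_histograms([_window([1.0])], np.array([0.0, 1.0, 2.0]))
        np.testing.assert_array_equal(h.counts, [[0, 1]])

    def test_out_of_range_tracked_not_counted(self):
        h = build_histograms([_window([-5.0, 0.5, 99.0])],
                             np.array([0.0, 1.0]))
        assert h.counts.sum() == 1
        assert h.n_out_of_range[0] == 2

    def test_uniform_samples_within_multinomial_envelope(self, rng):
        x = rng.uniform(0, 1, 10_000)
        h = build_histograms([_window(x)], np.linspace(0, 1, 11))
        expected = 1000
        # 99.9% multinomial envelope
        assert np.all(np.abs(h.counts[0] - expected)
                      < 4 * np.sqrt(expected * 0.9))

    def test_nonmonotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            build_histograms([_window([0.5])], np.array([0.0, 2.0, 1.0]))


class TestWindowOverlap:
    def test_identical_histograms_give_one(self, rng):
        x = rng.normal(0, 1, 5000)
        h = build_histograms([_window(x), _window(x.copy())],
                             np.linspace(-4, 4, 41))
        assert window_overlap(h)["overlap"][0] == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        h = build_histograms([_window([0.1] * 5), _window([0.9] * 5)],
                             np.linspace(0, 1, 11))
        assert window_overlap(h)["overlap"][0] == 0.0

    def test_half_shared_uniform_support(self):
        # uniform over [0, 2) vs [1, 3): normalized min overlaps on [1, 2)
        a = np.repeat(np.arange(0.25, 2.0, 0.5), 10)
        b = np.repeat(np.arange(1.25, 3.0, 0.5), 10)
        h = build_histograms([_window(a), _window(b)], np.linspace(0, 3, 7))
        assert window_overlap(h)["overlap"][0] == pytest.approx(0.5)

    def test_single_window_rejected(self):
        h = build_histograms([_window([0.5])], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            window_overlap(h)

    def test_low_overlap_flagged(self):
        h = build_histograms([_window([0.1] * 5), _window([0.9] * 5)],
                             np.linspace(0, 1, 11))
        assert window_overlap(h, threshold=0.1)["flagged_pairs"] == [(0, 1)]


class TestWhamSolve:
    def test_single_unbiased_window_is_log_histogram(self, rng, kt300):
        """With one window and zero bias WHAM reduces to −kT ln(counts/N)."""
        x = rng.normal(0, 1, 20_000)
        h = build_histograms([_window(x)], np.linspace(-3, 3, 31))
        prof = wham_solve(h, 300.0)
        p = h.counts[0] / h.counts[0].sum()
        ok = p > 0
        expected = -kt300 * np.log(p[ok])
        diff = prof.pmf[ok] - expected
        assert np.ptp(diff) < 1e-10  # equal up to an additive constant

    def test_flat_truth_recovered_flat(self, flat_profile):
        """Flat generating profile: the reconstruction is flat to within
        histogram noise on well-sampled bins (≥1000 counts, where the
        per-bin statistical error is ≲ 0.1 kJ/mol)."""
        wins = generate_window_set(flat_profile, np.linspace(-6, 6, 15),
                                   20.0, 100_000, seed=21)
        h = build_histograms(wins, np.arange(-8, 8.2, 0.2))
        prof = wham_solve(h, 300.0)
        well = prof.defined & (prof.n_total >= 1000)
        assert well.sum() > 40
        assert np.ptp(prof.pmf[well]) < 0.5

    def test_harmonic_truth_recovered(self, kt300):
        spec = AnalyticProfileSpec("harmonic", (-6, 6), {"a": 2.0})
        wins = generate_window_set(spec, np.linspace(-4, 4, 11), 20.0,
                                   20_000, seed=22)
        h = build_histograms(wins, np.arange(-5, 5.2, 0.2))
        prof = wham_solve(h, 300.0)
        ok = prof.defined & (prof.n_total >= 100)
        truth = 0.5 * 2.0 * prof.bin_centers[ok] ** 2
        d = prof.pmf[ok] - truth
        d -= d.mean()
        assert np.sqrt(np.mean(d**2)) < 0.3

    def test_probabilities_normalized_nonnegative(self, flat_profile, kt300):
        wins = generate_window_set(flat_profile, [-2.0, 0.0, 2.0], 10.0,
                                   5000, seed=23)
        h = build_histograms(wins, np.arange(-5, 5.2, 0.2))
        prof = wham_solve(h, 300.0)
        p = np.exp(-prof.pmf[prof.defined] / kt300)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_constant_bias_shift(self, flat_profile):
        """Adding a constant to every bias leaves the PMF unchanged."""
        wins = generate_window_set(flat_profile, [-1.0, 0.0, 1.0], 15.0,
                                   5000, seed=24)
        h = build_histograms(wins, np.arange(-3, 3.2, 0.2))
        base = wham_solve(h, 300.0, tol=1e-9)

        class ShiftedBias(BiasSpec):
            def energy(self, xi):
                return super().energy(xi) + 7.5

        shifted = build_histograms(
            [WindowSamples(bias=ShiftedBias(w.bias.center, w.bias.force_constant),
                           samples=w.samples, temperature=300.0)
             for w in wins], np.arange(-3, 3.2, 0.2))
        prof = wham_solve(shifted, 300.0, tol=1e-9)
        ok = base.defined
        np.testing.assert_allclose(prof.pmf[ok], base.pmf[ok], atol=1e-6)

    def test_agrees_with_likelihood_minimisation(self, double_well, kt300):
        """Fixed-point f_i match the independent convex-optimisation route."""
        wins = generate_window_set(double_well, np.linspace(-6, 6, 5), 3.0,
                                   5000, seed=25)
        h = build_histograms(wins, np.arange(-10, 10.4, 0.4))
        it = wham_solve(h, 300.0, tol=1e-9)
        mle = wham_solve_mle(h, 300.0)
        assert np.max(np.abs(it.window_free_energies
                             - mle.window_free_energies)) < 1e-6 * kt300

    def test_empty_bins_undefined(self, flat_profile):
        wins = generate_window_set(flat_profile, [0.0], 50.0, 2000, seed=26)
        h = build_histograms(wins, np.arange(-10, 10.5, 0.5))
        prof = wham_solve(h, 300.0)
        assert np.any(~prof.defined)
        assert np.all(np.isfinite(prof.pmf[prof.defined]))

    def test_nonconvergence_raises_with_residual(self, flat_profile):
        from slabpmf.wham import ConvergenceError
        wins = generate_window_set(flat_profile, [-2.0, 0.0, 2.0], 5.0, 2000,
                                   seed=27)
        h = build_histograms(wins, np.arange(-6, 6.2, 0.2))
        with pytest.raises(ConvergenceError) as exc:
            wham_solve(h, 300.0, tol=1e-9, max_iter=2)
        assert exc.value.residual > 0


class TestZeroByPlateau:
    def _profile(self, pmf):
        pmf = np.asarray(pmf, dtype=float)
        return FreeEnergyProfile(bin_centers=np.arange(len(pmf), dtype=float),
                                 pmf=pmf)

    def test_constant_profile_shifts_to_zero(self):
        out = zero_by_plateau(self._profile([3.0] * 10), (5.0, 9.0))
        assert np.allclose(out.pmf, 0.0)
        assert out.zero_reference["constant"] == pytest.approx(3.0)

    def test_idempotent(self):
        p = self._profile(np.linspace(2, 0, 10))
        once = zero_by_plateau(p, (6.0, 9.0))
        twice = zero_by_plateau(once, (6.0, 9.0))
        np.testing.assert_allclose(once.pmf, twice.pmf, atol=1e-9)

    def test_subtracts_plateau_mean(self, rng):
        pmf = np.concatenate([rng.normal(5, 1, 5), rng.normal(1, 0.1, 5)])
        out = zero_by_plateau(self._profile(pmf), (5.0, 9.0))
        assert out.zero_reference["constant"] == pytest.approx(pmf[5:].mean())
        assert np.mean(out.pmf[5:]) == pytest.approx(0.0, abs=1e-12)

    def test_default_range_uses_last_defined_fifth(self):
        pmf = np.array([4.0, 3.0, 2.0, 1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        out = zero_by_plateau(self._profile(pmf))
        assert out.zero_reference["constant"] == pytest.approx(0.5)

    def test_empty_plateau_rejected(self):
        with pytest.raises(ValueError):
            zero_by_plateau(self._profile([1.0, 2.0, 3.0]), (10.0, 20.0))


class TestCombineReplicas:
    def _profile(self, pmf):
        return FreeEnergyProfile(bin_centers=np.arange(len(pmf), dtype=float),
                                 pmf=np.asarray(pmf, dtype=float))

    def test_identical_replicas_zero_spread(self):
        reps = [self._profile([1.0, 2.0, 3.0]) for _ in range(4)]
        out = combine_replicas(reps)
        np.testing.assert_allclose(out.stderr, 0.0)

    def test_two_point_sd_formula(self):
        a = self._profile([1.0, 1.0])
        delta = 0.6
        b = self._profile([1.0 + delta, 1.0])
        out = combine_replicas([a, b])
        assert out.pmf[0] == pytest.approx(1.0 + delta / 2)
        assert out.stderr[0] == pytest.approx(delta / np.sqrt(2))

    def test_gaussian_noise_recovers_sigma(self, rng):
        """Mean per-bin SD across 4 replicas ≈ c₄σ (χ-distribution mean)."""
        sigma, n_bins = 1.0, 400
        base = np.zeros(n_bins)
        reps = [self._profile(base + rng.normal(0, sigma, n_bins))
                for _ in range(4)]
        out = combine_replicas(reps)
        from scipy.special import gamma
        c4 = np.sqrt(2.0 / 3.0) * gamma(2.0) / gamma(1.5)
        assert out.stderr.mean() == pytest.approx(sigma * c4, rel=0.1)

    def test_nan_bins_propagate(self):
        a = self._profile([1.0, np.nan])
        b = self._profile([2.0, 3.0])
        out = combine_replicas([a, b])
        assert np.isnan(out.pmf[1]) and np.isfinite(out.pmf[0])

    def test_mismatched_grids_rejected(self):
        a = self._profile([1.0, 2.0])
        b = FreeEnergyProfile(bin_centers=np.array([0.0, 2.0]),
                              pmf=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            combine_replicas([a, b])
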