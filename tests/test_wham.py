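"""Window placement, WHAM reconstruction, bootstrap bands, split-half
convergence and binding free energies, all against analytic PMFs."""

import numpy as np
import pytest

from pfklab.synthetic import double_well_pmf, gen_umbrella_samples
from pfklab.tables import KB_KJ_PER_MOL_K
from pfklab.wham import (FreeEnergyProfile, UmbrellaWindow,
                         WhamConvergenceError, binding_delta_g,
                         bootstrap_profile, place_windows, read_window_file,
                         split_half_convergence, wham_solve,
                         write_window_file)


class TestPlaceWindows:
    def test_tight_spacing_yields_64_windows(self):
        centers = place_windows(0.0, 1.89, 0.03)
        assert len(centers) == 64
        np.testing.assert_allclose(np.diff(centers), 0.03)

    def test_wide_spacing_yields_64_windows(self):
        assert len(place_windows(0.0, 3.15, 0.05)) == 64

    def test_degenerate_single_window(self):
        np.testing.assert_array_equal(place_windows(0, 1, 2), [0.0])

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            place_windows(0, 1, 0.0)


def harmonic_pmf(x):
    return 50.0 * (np.asarray(x) - 1.0) ** 2


class TestWhamSolve:
    def test_single_unbiased_window_matches_direct_histogram(self):
        """Independent oracle: with one unbiased window WHAM reduces to
        -kT log(histogram)."""
        wins = gen_umbrella_samples(harmonic_pmf, [1.0], 0.0, 50_000,
                                    seed=42, x_range=(0.3, 1.7))
        prof = wham_solve(wins, n_bins=40, anchor="min")
        kt = KB_KJ_PER_MOL_K * 300.0
        counts, edges = np.histogram(wins[0].samples,
                                     bins=np.linspace(
                                         wins[0].samples.min(),
                                         wins[0].samples.max(), 41))
        with np.errstate(divide="ignore"):
            direct = -kt * np.log(counts.astype(float))
        direct -= np.nanmin(direct[np.isfinite(direct)])
        ok = prof.counts >= 100
        np.testing.assert_allclose(prof.free_energy[ok], direct[ok],
                                   atol=1e-8)
        # and both recover the analytic harmonic PMF
        x = prof.bin_centers[ok]
        true = harmonic_pmf(x) - harmonic_pmf(x).min()
        assert np.max(np.abs(prof.free_energy[ok] - true)) < 0.5

    def test_flat_pmf_recovered_flat(self):
        wins = gen_umbrella_samples(lambda x: np.zeros_like(x),
                                    np.linspace(0.5, 2.0, 16), 800.0,
                                    4000, seed=7)
        prof = bootstrap_profile(wins, n_bootstrap=50, seed=1, n_bins=40)
        ok = prof.counts >= 100
        spread = np.abs(prof.free_energy[ok]
                        - np.mean(prof.free_energy[ok]))
        assert np.all(spread <= 3 * np.maximum(prof.bootstrap_band[ok], 0.05))

    def test_double_well_features_recovered(self):
        centers = np.linspace(0.6, 1.9, 32)
        wins = gen_umbrella_samples(double_well_pmf, centers, 1500.0,
                                    5000, seed=3)
        prof = wham_solve(wins, n_bins=64, anchor="min")
        x, f = prof.bin_centers, prof.free_energy
        def feat(lo, hi, op):
            m = (x >= lo) & (x <= hi) & np.isfinite(f)
            return op(f[m])
        well1 = feat(0.7, 0.9, np.min)
        well2 = feat(1.5, 1.7, np.min)
        barrier = feat(1.1, 1.3, np.max)
        assert well1 == pytest.approx(0.0, abs=0.5)
        assert well2 == pytest.approx(0.0, abs=0.5)
        assert barrier == pytest.approx(12.0, abs=0.5)

    def test_anchoring_invariant_under_pmf_offset(self):
        centers = np.linspace(0.6, 1.9, 16)
        w1 = gen_umbrella_samples(double_well_pmf, centers, 1200.0, 3000,
                                  seed=5)
        w2 = gen_umbrella_samples(lambda x: double_well_pmf(x) + 37.0,
                                  centers, 1200.0, 3000, seed=5)
        # identical seeds + offset-invariant sampling -> same bin grid
        p1 = wham_solve(w1, n_bins=40)
        p2 = wham_solve(w2, n_bins=40)
        ok = np.isfinite(p1.free_energy) & np.isfinite(p2.free_energy)
        np.testing.assert_allclose(p1.free_energy[ok], p2.free_energy[ok],
                                   atol=1e-6)

    def test_deterministic_bit_for_bit(self):
        wins = gen_umbrella_samples(harmonic_pmf, [0.8, 1.0, 1.2], 500.0,
                                    1000, seed=2)
        p1 = wham_solve(wins, n_bins=30)
        p2 = wham_solve(wins, n_bins=30)
        np.testing.assert_array_equal(p1.free_energy, p2.free_energy)

    def test_disjoint_windows_diagnosed(self):
        rng = np.random.default_rng(0)
        wins = [UmbrellaWindow(0.5, 1000.0, rng.normal(0.5, 0.02, 200)),
                UmbrellaWindow(2.5, 1000.0, rng.normal(2.5, 0.02, 200))]
        with pytest.raises(WhamConvergenceError, match="overlap"):
            wham_solve(wins, n_bins=50)

    def test_iteration_cap_reported(self):
        wins = gen_umbrella_samples(harmonic_pmf,
                                    np.linspace(0.6, 1.4, 8), 800.0,
                                    500, seed=9)
        with pytest.raises(WhamConvergenceError, match="converge"):
            wham_solve(wins, max_iterations=2)

    def test_mixed_temperatures_rejected(self):
        w1 = UmbrellaWindow(1.0, 100.0, np.ones(10), temperature=300.0)
        w2 = UmbrellaWindow(1.0, 100.0, np.ones(10), temperature=298.0)
        with pytest.raises(ValueError, match="temperature"):
            wham_solve([w1, w2])


class TestBootstrap:
    def test_zero_variance_windows_give_zero_band(self):
        # every sample in the window identical: case resampling cannot
        # change anything, so the band vanishes exactly
        wins = [UmbrellaWindow(1.0, 0.0, np.full(200, 1.0))]
        prof = bootstrap_profile(wins, n_bootstrap=20, seed=0, n_bins=5,
                                 bin_range=(0.9, 1.1))
        assert np.nanmax(prof.bootstrap_band) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self):
        wins = gen_umbrella_samples(harmonic_pmf, [0.9, 1.0, 1.1], 800.0,
                                    500, seed=4)
        p1 = bootstrap_profile(wins, n_bootstrap=25, seed=11, n_bins=20)
        p2 = bootstrap_profile(wins, n_bootstrap=25, seed=11, n_bins=20)
        np.testing.assert_array_equal(p1.bootstrap_band, p2.bootstrap_band)

    def test_band_shrinks_like_root_n(self):
        centers = np.linspace(0.7, 1.3, 8)
        small = gen_umbrella_samples(harmonic_pmf, centers, 600.0, 500,
                                     seed=6)
        large = gen_umbrella_samples(harmonic_pmf, centers, 600.0, 2000,
                                     seed=6)
        kw = dict(n_bootstrap=80, seed=3, n_bins=24, bin_range=(0.55, 1.45))
        b_small = bootstrap_profile(small, **kw).bootstrap_band
        b_large = bootstrap_profile(large, **kw).bootstrap_band
        ratio = np.nanmedian(b_small) / np.nanmedian(b_large)
        assert ratio == pytest.approx(2.0, rel=0.3)

    def test_requires_multiple_samples(self):
        with pytest.raises(ValueError):
            bootstrap_profile([UmbrellaWindow(1.0, 0.0, np.array([1.0]))],
                              n_bootstrap=10)


class TestBindingDeltaG:
    def _profile(self, f, x=None):
        x = np.linspace(0.5, 3.0, len(f)) if x is None else x
        return FreeEnergyProfile(bin_centers=x, free_energy=np.asarray(f),
                                 counts=np.ones(len(f)), temperature=300.0)

    def test_depth_25_gives_25(self):
        x = np.linspace(0.5, 3.0, 100)
        f = np.zeros(100)
        f[10] = -25.0
        prof = self._profile(f, x)
        assert binding_delta_g(prof, (0.5, 1.5), (2.5, 3.0)) == 25.0

    def test_flat_profile_gives_zero(self):
        prof = self._profile(np.zeros(50))
        assert binding_delta_g(prof, (0.5, 1.5), (2.5, 3.0)) == 0.0

    def test_noisy_plateau_averages_out(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0.5, 3.0, 200)
        f = rng.normal(0.0, 0.3, 200)
        f[20] = -10.0
        prof = self._profile(f, x)
        dg = binding_delta_g(prof, (0.5, 1.0), (2.0, 3.0))
        assert dg == pytest.approx(10.0, abs=0.3)

    def test_ddg_between_two_profiles(self):
        x = np.linspace(0.5, 3.0, 100)
        native = np.zeros(100); native[10] = -40.0
        mutant = np.zeros(100); mutant[10] = -15.0
        dg_n = binding_delta_g(self._profile(native, x), (0.5, 1.5), (2.5, 3.0))
        dg_m = binding_delta_g(self._profile(mutant, x), (0.5, 1.5), (2.5, 3.0))
        assert dg_n - dg_m == pytest.approx(25.0)

    def test_empty_region_rejected(self):
        prof = self._profile(np.zeros(10))
        with pytest.raises(ValueError):
            binding_delta_g(prof, (10.0, 11.0), (2.5, 3.0))


class TestSplitHalf:
    def test_stationary_halves_agree(self):
        centers = np.linspace(0.6, 1.9, 16)
        wins = gen_umbrella_samples(double_well_pmf, centers, 1200.0,
                                    4000, seed=12)
        first, second, disc = split_half_convergence(wins, n_bins=40)
        band = bootstrap_profile(wins, n_bootstrap=40, seed=1,
                                 n_bins=40).bootstrap_band
        # halves have ~2x the band of the full data
        assert disc <= 3 * 2 * np.nanmax(band) + 0.5

    def test_planted_drift_detected(self):
        centers = np.linspace(0.6, 1.9, 16)
        first_half = gen_umbrella_samples(
            lambda x: double_well_pmf(x, barrier=4.0), centers, 1200.0,
            2000, seed=13)
        second_half = gen_umbrella_samples(double_well_pmf, centers, 1200.0,
                                           2000, seed=14)
        wins = [UmbrellaWindow(a.center, a.spring_constant,
                               np.concatenate([a.samples, b.samples]))
                for a, b in zip(first_half, second_half)]
        _, _, disc = split_half_convergence(wins, n_bins=40)
        assert disc > 3.0  # far beyond statistical noise

    def test_duplicated_halves_have_zero_discrepancy(self):
        x = np.linspace(0.8, 1.2, 400)
        wins = [UmbrellaWindow(1.0, 0.0, np.concatenate([x, x]))]
        _, _, disc = split_half_convergence(wins, n_bins=20)
        assert disc == pytest.approx(0.0, abs=1e-12)


class TestWindowFiles:
    def test_round_trip(self, tmp_path):
        win = UmbrellaWindow(1.23, 850.0,
                             np.random.default_rng(0).normal(1.23, 0.05, 100),
                             temperature=298.0)
        path = tmp_path / "win.dat"
        write_window_file(win, path)
        back = read_window_file(path)
        assert back.center == win.center
        assert back.spring_constant == win.spring_constant
        assert back.temperature == 298.0
        np.testing.assert_allclose(back.samples, win.samples, atol=1e-8)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.0 1.0\n1.0 1.1\n")
        with pytest.raises(ValueError, match="header"):
            read_window_file(path)
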