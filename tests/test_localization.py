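"""Profiles, tail fits, Eq.-2 inversion, hotspots, ring transport (fast paths)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silkbeam import localization
from silkbeam.localization import (
    IntensityProfile,
    NotLocalizedError,
    average_log_profile,
    fit_localization_length,
    forward_xi,
    hotspot_fwhm,
    invert_mean_free_path,
    ring_aperture_mask,
    ring_contrast,
)


def exponential_image(xi=4.6, npix=256, spacing=0.1):
    x = (np.arange(npix) + 0.5) * spacing - npix * spacing / 2
    xx, yy = np.meshgrid(x, x)
    r = np.hypot(xx, yy)
    return np.exp(-2.0 * r / xi)


class TestAverageLogProfile:
    def test_identity_on_radially_symmetric_exponential(self):
        img = exponential_image(xi=4.6)
        prof = average_log_profile([img], 0.1)
        expected = np.exp(-2.0 * prof.r / 4.6)
        sel = prof.r < 10.0
        assert np.allclose(prof.I[sel], expected[sel], rtol=0.05)

    def test_axis_cut_matches_azimuthal_on_symmetric_image(self):
        img = exponential_image(xi=3.0)
        az = average_log_profile([img], 0.1, "azimuthal")
        ax = average_log_profile([img], 0.1, "axis-cut")
        n = min(len(az.r), len(ax.r))
        sel = az.r[:n] < 8.0
        assert np.allclose(az.I[:n][sel], ax.I[:n][sel], rtol=0.01)

    def test_averaging_reduces_noise_variance(self, rng):
        """Pointwise variance of an N-average scales like 1/N."""
        base = exponential_image(xi=4.6)

        def noisy_profiles(n_images, n_trials=30):
            var_acc = []
            for t in range(n_trials):
                imgs = [
                    base * rng.lognormal(0.0, 0.3, size=base.shape)
                    for _ in range(n_images)
                ]
                prof = average_log_profile(imgs, 0.1)
                var_acc.append(prof.I[5])
            return np.var(var_acc)

        v1, v8 = noisy_profiles(1), noisy_profiles(8)
        assert v8 < v1 / 4.0  # ~1/8 expected, allow statistical slack

    def test_zero_image_refused(self):
        with pytest.raises(ValueError, match="zero"):
            average_log_profile([np.zeros((32, 32))], 0.1)


class TestFitLocalizationLength:
    def test_exact_profile_recovers_xi(self):
        r = np.arange(0.05, 20.0, 0.1)
        prof = IntensityProfile(r, np.exp(-2.0 * r / 4.6), "azimuthal", 1)
        fit = fit_localization_length(prof, window=(1.0, 15.0))
        assert fit.xi == pytest.approx(4.6, abs=1e-6)
        assert fit.r_squared > 0.999999

    def test_flat_profile_is_not_localized(self):
        r = np.arange(0.05, 10.0, 0.1)
        prof = IntensityProfile(r, np.ones_like(r), "azimuthal", 1)
        with pytest.raises(NotLocalizedError):
            fit_localization_length(prof, window=(0.1, 9.0))

    def test_scale_invariance(self):
        r = np.arange(0.05, 20.0, 0.1)
        noise = np.random.default_rng(0).lognormal(0.0, 0.1, size=r.shape)
        I = np.exp(-2.0 * r / 2.0) * noise
        f1 = fit_localization_length(IntensityProfile(r, I, "azimuthal", 1))
        f2 = fit_localization_length(IntensityProfile(r, 1e6 * I, "azimuthal", 1))
        assert f1.xi == pytest.approx(f2.xi, rel=1e-9)

    def test_too_few_samples_refused(self):
        r = np.arange(0.05, 20.0, 0.1)
        prof = IntensityProfile(r, np.exp(-r), "azimuthal", 1)
        with pytest.raises(ValueError, match="samples"):
            fit_localization_length(prof, window=(0.0, 0.5))

    @pytest.mark.parametrize("xi", [1.0, 2.0, 4.6, 10.0])
    def test_noisy_recovery_within_five_percent(self, xi):
        """Median recovered xi over 50 noisy replicates within 5%."""
        rng = np.random.default_rng(int(xi * 100))
        r = np.arange(0.05, 5.0 * xi, xi / 40.0)
        clean = np.exp(-2.0 * r / xi)
        fits = []
        for _ in range(50):
            I = clean * rng.lognormal(0.0, 0.1, size=r.shape)
            fit = fit_localization_length(
                IntensityProfile(r, I, "azimuthal", 1), window=(0.2 * xi, 4.0 * xi)
            )
            fits.append(fit.xi)
        assert abs(np.median(fits) - xi) / xi < 0.05


class TestTailShapeDichotomy:
    """Exponential tails appear only with transverse disorder.

    Over the clean decade of decay (10% to 1% of peak) the ensemble-
    averaged exit profile of a disordered fiber is exponential (straight in
    log), while the void-free fiber's profile is not.
    """

    @staticmethod
    def _tail_fit(density, n_seeds, chain):
        from silkbeam import bpm, fibergen

        spacing = min(
            bpm.default_grid_spacing(0.6), fibergen.max_raster_spacing()
        )
        imgs = []
        for s in range(n_seeds):
            seed = int(
                np.random.default_rng([chain, s]).integers(0, 2**31 - 1)
            )
            pop = fibergen.sample_void_population(
                density, fiber_radius=8.0, seed=seed
            )
            cs = fibergen.rasterize_cross_section(
                pop, grid_spacing=spacing, margin=5.0
            )
            beam = bpm.make_gaussian_beam(
                2.0, (0, 0), 0.6, spacing, cs.index_map.shape[0]
            )
            cfg = bpm.PropagationConfig(
                step_dz=0.05, total_length=80.0, boundary_width=3.0,
                reference_index=1.54, single_precision=True,
            )
            out, _ = bpm.propagate(beam, cs, cfg)
            imgs.append(bpm.intensity_image(out))
        prof = average_log_profile(imgs, spacing)
        peak = prof.I.max()
        lo = prof.r[np.argmax(prof.I <= 0.1 * peak)]
        hi = min(prof.r[np.nonzero(prof.I >= 0.01 * peak)[0][-1]], 8.0)
        return fit_localization_length(prof, window=(lo, hi))

    def test_disordered_tail_is_exponential_but_void_free_is_not(self):
        disordered = self._tail_fit(2.2, n_seeds=6, chain=99)
        assert disordered.r_squared > 0.9
        assert 0 < disordered.xi < 8.0
        try:
            void_free = self._tail_fit(0.0, n_seeds=1, chain=99)
        except (NotLocalizedError, ValueError):
            return  # flagged outright: acceptable outcome
        assert void_free.r_squared < 0.9  # poor fit: no exponential tail


class TestMeanFreePathInversion:
    def test_paper_worked_example(self):
        """xi = 4.6 um, omega_0 = 2 um inverts to l* ~ 0.98-0.99 um."""
        est = invert_mean_free_path(4.6, 2.0)
        assert 0.96 <= est.l_star <= 1.00
        assert est.k_perp == pytest.approx(1.0)

    def test_round_trip_identity(self):
        xi = forward_xi(0.5, 2.0)
        assert xi == pytest.approx(0.5 * math.exp(math.pi * 0.25 / 2.0))
        est = invert_mean_free_path(xi, 2.0)
        assert est.l_star == pytest.approx(0.5, rel=1e-9)

    def test_against_dense_grid_scan_oracle(self, rng):
        """Brute-force grid scan agrees with the root-finder to < 1e-6 um."""
        for _ in range(100):
            omega_0 = rng.uniform(0.5, 5.0)
            l_true = rng.uniform(0.05, 1.5)
            xi = forward_xi(l_true, omega_0)
            grid = np.linspace(1e-6, 2.0, 2_000_001)
            fwd = grid * np.exp(math.pi * (2.0 / omega_0) * grid**2 / 2.0)
            l_scan = grid[np.searchsorted(fwd, xi)]
            est = invert_mean_free_path(xi, omega_0)
            assert abs(est.l_star - l_scan) < 1e-6

    @settings(derandomize=True, max_examples=100)
    @given(
        l=st.floats(1e-3, 2.0),
        omega_0=st.floats(0.2, 10.0),
    )
    def test_forward_inverse_bijection(self, l, omega_0):
        xi = forward_xi(l, omega_0)
        est = invert_mean_free_path(xi, omega_0)
        assert est.l_star == pytest.approx(l, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            invert_mean_free_path(-1.0, 2.0)
        with pytest.raises(ValueError):
            invert_mean_free_path(4.6, 0.0)


class TestHotspotFWHM:
    def _gaussian(self, sigma, npix=256, spacing=0.05, center=(0.0, 0.0), amp=1.0):
        x = (np.arange(npix) + 0.5) * spacing - npix * spacing / 2
        xx, yy = np.meshgrid(x, x)
        r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
        return amp * np.exp(-r2 / (2.0 * sigma**2))

    def test_gaussian_closed_form(self):
        for sigma in (0.5, 1.0):
            fwhm, _ = hotspot_fwhm(self._gaussian(sigma), 0.05, smooth_px=0)
            assert fwhm == pytest.approx(2.3548 * sigma, rel=0.01)

    def test_taller_of_two_gaussians_wins(self):
        img = self._gaussian(0.5, center=(-3.0, 0.0), amp=1.0) + self._gaussian(
            0.8, center=(3.0, 0.0), amp=0.4
        )
        fwhm, center = hotspot_fwhm(img, 0.05)
        assert center[0] < 0  # the taller, left-hand hotspot
        assert fwhm == pytest.approx(2.3548 * 0.5, rel=0.05)

    def test_scale_invariance(self):
        img = self._gaussian(0.7)
        f1, _ = hotspot_fwhm(img, 0.05)
        f2, _ = hotspot_fwhm(img * 42.0, 0.05)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_plateau_is_ambiguous(self):
        img = np.zeros((64, 64))
        img[10:40, 10:40] = 1.0
        with pytest.raises(ValueError, match="plateau|ambiguous"):
            hotspot_fwhm(img, 0.1, smooth_px=0)


class TestRingTransport:
    def test_mask_geometry(self):
        mask = ring_aperture_mask(512, 0.1, 1.0, 30.0, 24)
        assert mask.sum() > 0
        x = (np.arange(512) + 0.5) * 0.1 - 25.6
        xx, yy = np.meshgrid(x, x)
        r = np.hypot(xx, yy)
        assert np.all(np.abs(r[mask > 0] - 15.0) < 1.0)

    def test_contrast_bounds_and_zero_length_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(256, 256))
        score = ring_contrast(img, 0.1, 15.0, 1.0, 12.0)
        assert -1.0 <= score <= 1.0
        mask = ring_aperture_mask(256, 0.1, 1.0, 15.0, 16)
        perfect = ring_contrast(mask, 0.1, 15.0, 1.0, 12.0)
        assert perfect > 0.9  # energy only in the ring annulus

    def test_ring_must_fit_in_fiber(self, small_cross_section):
        with pytest.raises(ValueError, match="fit"):
            localization.transport_ring_image(
                1.0, 30.0, 16, small_cross_section, 0.0, 0.6, fiber_radius=8.0
            )
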