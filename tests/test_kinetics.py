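"""Two-channel unmixing and release-kinetics fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodroplet import kinetics as kin, synthetic as syn


def _peptide_scene(beta=1.4, noise=0.0, seed=0, shape=(64, 64)):
    """Peptide-only two-channel pair: green = beta * red everywhere."""
    rng = np.random.default_rng(seed)
    red = np.full(shape, 50.0)
    red[16:48, 16:48] = 200.0
    green = beta * red
    if noise > 0:
        red = red + rng.normal(0, noise * 50.0, shape)
        green = green + rng.normal(0, noise * 50.0, shape)
    fg = np.zeros(shape, bool)
    fg[16:48, 16:48] = True
    return green, red, fg


class TestEstimateBeta:
    def test_exact_ratio(self):
        green, red, fg = _peptide_scene(beta=2.0)
        assert kin.estimate_beta(green, red, fg).beta == pytest.approx(2.0)

    def test_noisy_scene_within_five_percent(self):
        green, red, fg = _peptide_scene(beta=1.4, noise=0.05, seed=3)
        model = kin.estimate_beta(green, red, fg)
        assert model.beta == pytest.approx(1.4, abs=0.05)

    def test_median_robust_to_contamination(self):
        """10 % dsDNA-positive pixels skew the mean but not the median."""
        green, red, fg = _peptide_scene(beta=1.4)
        rng = np.random.default_rng(5)
        contaminated = fg & (rng.uniform(size=fg.shape) < 0.10)
        green = green + np.where(contaminated, 300.0, 0.0)
        model = kin.estimate_beta(green, red, fg)
        mean_ratio = (green[fg] / red[fg]).mean()
        assert model.beta == pytest.approx(1.4, rel=0.05)
        assert abs(mean_ratio - 1.4) > 0.05

    def test_half_image_consistency(self):
        green, red, fg = _peptide_scene(beta=1.4, noise=0.05, seed=7)
        left = fg.copy()
        left[:, 32:] = False
        right = fg & ~left
        b_left = kin.estimate_beta(green, red, left).beta
        b_right = kin.estimate_beta(green, red, right).beta
        assert b_left == pytest.approx(b_right, rel=0.05)

    def test_too_few_foreground_pixels(self):
        green, red, _ = _peptide_scene()
        with pytest.raises(ValueError, match="foreground"):
            kin.estimate_beta(green, red, np.zeros_like(green, bool))


class TestUnmix:
    def test_peptide_only_scene_maps_to_zero(self):
        green, red, fg = _peptide_scene(beta=1.4, noise=0.02, seed=9)
        model = kin.estimate_beta(green, red, fg)
        out = kin.unmix(green, red, model)
        noise_sd = 0.02 * 50.0
        assert np.abs(out[fg]).mean() < 3 * noise_sd

    def test_beta_zero_passthrough_and_linearity(self):
        rng = np.random.default_rng(11)
        green = rng.uniform(10, 100, (32, 32))
        red = rng.uniform(10, 100, (32, 32))
        model = kin.UnmixModel(beta=1.3, ratio_iqr=(1.2, 1.4), n_pixels=100)
        np.testing.assert_allclose(
            kin.unmix(3.0 * green, 3.0 * red, model), 3.0 * kin.unmix(green, red, model)
        )

    def test_known_dna_maps_recovered(self):
        rng = np.random.default_rng(13)
        ds = rng.uniform(0, 80, (32, 32))
        ss = rng.uniform(0, 80, (32, 32))
        pep_red = rng.uniform(10, 40, (32, 32))
        beta = 1.4
        green = ds + beta * pep_red
        red = ss + pep_red
        model = kin.UnmixModel(beta=beta, ratio_iqr=(1.4, 1.4), n_pixels=1000)
        np.testing.assert_allclose(kin.unmix(green, red, model), ds - beta * ss, atol=1e-9)

    def test_negative_values_preserved(self):
        model = kin.UnmixModel(beta=2.0, ratio_iqr=(2.0, 2.0), n_pixels=100)
        out = kin.unmix(np.zeros((4, 4)), np.ones((4, 4)), model)
        np.testing.assert_allclose(out, -2.0)

    def test_shape_mismatch(self):
        model = kin.UnmixModel(beta=1.0, ratio_iqr=(1, 1), n_pixels=100)
        with pytest.raises(ValueError, match="mismatch"):
            kin.unmix(np.ones((4, 4)), np.ones((5, 5)), model)


class TestCortexSeries:
    @staticmethod
    def _shell_series(rates, bleach, n=8, noise=0.0, seed=0):
        truth = syn.KineticsTruth(release_rate=rates, bleach_factor=bleach, i0=100.0, i_inf=10.0)
        times = np.arange(n) * 2.0
        series, _ = syn.gen_release_series(truth, times, noise_sd=noise, seed=seed)
        images = []
        cfg = syn.SceneConfig(
            image_shape=(128, 128), pixel_size=0.2, psf_sigma=0.0,
            background_level=0.0, noise_sd=0.0,
        )
        for level in series:
            img, _ = syn.render_scene(
                cfg, [syn.Shell(center=(12.8, 12.8), radius=10.0, thickness=1.0, intensity=level)]
            )
            images.append(img)
        return images, times, truth

    def test_static_shell_constant_curve(self):
        images, times, _ = self._shell_series(0.0, 1.0)
        out = kin.cortex_intensity_series(
            images, times, (12.8, 12.8), 10.0, band_width=1.0, pixel_size=0.2
        )
        vals = out["intensity_corrected"].to_numpy()
        assert np.ptp(vals) / vals.mean() < 0.01

    def test_bleach_corrected_no_release_is_flat(self):
        images, times, _ = self._shell_series(0.0, 0.93)
        factors = 0.93 ** np.arange(len(times))
        out = kin.cortex_intensity_series(
            images, times, (12.8, 12.8), 10.0, bleach_factors=factors,
            band_width=1.0, pixel_size=0.2,
        )
        vals = out["intensity_corrected"].to_numpy()
        assert np.ptp(vals) / vals.mean() < 0.01

    def test_release_curve_matches_generating_exponential(self):
        images, times, truth = self._shell_series(0.05, 0.93)
        factors = 0.93 ** np.arange(len(times))
        out = kin.cortex_intensity_series(
            images, times, (12.8, 12.8), 10.0, bleach_factors=factors,
            band_width=1.0, pixel_size=0.2,
        )
        expected = truth.i_inf + (truth.i0 - truth.i_inf) * np.exp(-0.05 * times)
        vals = out["intensity_corrected"].to_numpy()
        scale = vals[0] / expected[0]
        np.testing.assert_allclose(vals, expected * scale, rtol=0.02)


class TestFitRelease:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 40, 2.0)
        y = 12.0 + 88.0 * np.exp(-0.05 * t)
        fit = kin.fit_release(t, y, n_bootstrap=50)
        assert fit.k == pytest.approx(0.05, rel=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)
        assert fit.i_inf == pytest.approx(12.0, rel=1e-6)
        assert fit.residual_sd < 1e-8

    def test_constant_curve_flagged_zero_rate(self):
        fit = kin.fit_release(np.arange(10.0), np.full(10, 40.0), n_bootstrap=50)
        assert fit.k == pytest.approx(0.0, abs=1e-6)
        assert fit.flagged

    def test_rate_ordering_preserved_across_seeds(self):
        """k_low < k_high doses keep their fitted order in ≥ 95 % of seeds."""
        t = np.arange(0, 40, 2.0)
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y_low = 10 + 90 * np.exp(-0.03 * t) + rng.normal(0, 2.0, t.size)
            y_high = 10 + 90 * np.exp(-0.08 * t) + rng.normal(0, 2.0, t.size)
            k_low = kin.fit_release(t, y_low, n_bootstrap=0).k
            k_high = kin.fit_release(t, y_high, n_bootstrap=0).k
            wins += k_high > k_low
        assert wins >= 95

    def test_bias_when_bleach_uncorrected(self):
        """Skipping bleach correction inflates the fitted decay constant."""
        truth = syn.KineticsTruth(release_rate=0.05, bleach_factor=0.93, i0=100.0, i_inf=10.0)
        times = np.arange(0, 30, 2.0)
        observed, _ = syn.gen_release_series(truth, times)
        factors = 0.93 ** np.arange(len(times))
        k_corr = kin.fit_release(times, observed / factors, n_bootstrap=0).k
        k_raw = kin.fit_release(times, observed, n_bootstrap=0).k
        assert k_corr == pytest.approx(0.05, rel=0.10)
        assert k_raw > k_corr

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(k=st.floats(0.01, 0.3), i_inf=st.floats(0.0, 30.0))
    def test_noiseless_fit_is_exact(self, k, i_inf):
        t = np.arange(0, 50, 2.5)
        y = i_inf + (100.0 - i_inf) * np.exp(-k * t)
        fit = kin.fit_release(t, y, n_bootstrap=0)
        assert fit.k == pytest.approx(k, rel=1e-5)
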