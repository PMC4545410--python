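"""Periodogram, window smoothing, effective degrees of freedom, peaks."""

import math

import numpy as np
import pytest

import growthspec as gs
from growthspec.spectrum import Spectrum, daniell_weights, modified_daniell_weights


def naive_periodogram(y):
    """Brute-force O(N^2) DFT sum, the definition itself."""
    n = len(y)
    out = []
    for j in range(1, n // 2 + 1):
        lam = 2 * math.pi * j / n
        s = sum(y[t - 1] * np.exp(-1j * lam * t) for t in range(1, n + 1))
        out.append(abs(s) ** 2 / (2 * math.pi * n))
    return np.array(out)


class TestPeriodogram:
    def test_single_fourier_line(self):
        n = 64
        t = np.arange(1, n + 1)
        y = np.cos(2 * np.pi * 8 * t / n)
        std = gs.standardize(y)
        spec = gs.periodogram(std)
        j = np.argmax(spec.periodogram)
        assert spec.freqs[j] == pytest.approx(8 / 64)
        # all power concentrates on that line
        assert spec.periodogram[j] / spec.periodogram.sum() > 0.999

    @pytest.mark.parametrize("n", [255, 256])
    def test_parseval(self, n):
        y = np.random.default_rng(3).normal(size=n)
        std = gs.standardize(y)
        spec = gs.periodogram(std)
        assert gs.total_power(spec) == pytest.approx(
            np.var(std.values), abs=1e-9
        )

    @pytest.mark.parametrize("n", [16, 33, 64])
    def test_matches_naive_dft(self, n):
        y = gs.standardize(np.random.default_rng(n).normal(size=n)).values
        spec = gs.periodogram(y)
        np.testing.assert_allclose(
            spec.periodogram, naive_periodogram(y), atol=1e-10
        )

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            gs.periodogram(np.zeros(5) + np.arange(5))

    def test_non_standardized_warns(self):
        with pytest.warns(UserWarning, match="not standardized"):
            gs.periodogram(np.random.default_rng(0).normal(5.0, 3.0, 64))


def _flat_spectrum(n=64, level=1.0):
    m = n // 2
    return Spectrum(
        freqs=np.arange(1, m + 1) / n,
        periodogram=np.full(m, level),
        n=n,
    )


class TestSmoothing:
    def test_flat_periodogram_is_preserved(self):
        spec = gs.smooth_density(_flat_spectrum(level=2.5), half_width=3)
        np.testing.assert_allclose(spec.density, 2.5, atol=1e-12)

    def test_daniell_interior_is_mean_of_neighbors(self):
        rng = np.random.default_rng(5)
        spec = _flat_spectrum(n=64)
        spec = Spectrum(freqs=spec.freqs, periodogram=rng.uniform(size=32), n=64)
        sm = gs.smooth_density(spec, half_width=2)
        for i in range(2, 30):
            assert sm.density[i] == pytest.approx(
                spec.periodogram[i - 2 : i + 3].mean()
            )

    def test_area_conserved(self, white_spectrum):
        # the plain factor-2 sum is invariant under reflecting-edge smoothing
        assert gs.total_power(
            white_spectrum, "density", fold_nyquist=False
        ) == pytest.approx(
            gs.total_power(white_spectrum, "periodogram", fold_nyquist=False),
            abs=1e-6,
        )

    def test_density_of_standardized_series_integrates_to_one(
        self, white_spectrum
    ):
        # (N-1)/N of the population-variance normalization
        assert gs.total_power(white_spectrum, "density") == pytest.approx(
            1.0, abs=0.01
        )

    def test_ar1_tracks_closed_form(self):
        """AR(1) with phi=0.6: the smoothed estimate tracks
        sigma^2/(2*pi*(1 - 2*phi*cos(lambda) + phi^2))."""
        phi = 0.6
        ratios = []
        for seed in range(20):
            series, _ = gs.generate(
                gs.FixtureSpec(kind="ar1", n=1024, params={"phi": phi}, seed=seed)
            )
            with pytest.warns(UserWarning):
                spec = gs.smooth_density(gs.periodogram(series.values))
            lam = spec.freqs_radians
            f_true = 1.0 / (2 * np.pi * (1 - 2 * phi * np.cos(lam) + phi**2))
            ratios.append(spec.density / f_true)
        mean_ratio = np.mean(ratios, axis=0)[5:-5]
        assert abs(mean_ratio.mean() - 1.0) < 0.05
        assert np.all(np.abs(mean_ratio - 1.0) < 0.3)

    def test_half_width_too_large(self):
        with pytest.raises(ValueError, match="too large"):
            gs.smooth_density(_flat_spectrum(n=20), half_width=5)

    def test_unknown_window(self):
        with pytest.raises(ValueError, match="unknown window"):
            gs.smooth_density(_flat_spectrum(), window="parzen")


class TestEffectiveDf:
    def test_raw_periodogram_has_2_df(self):
        assert gs.effective_df(np.array([1.0])) == pytest.approx(2.0)

    @pytest.mark.parametrize("h", [1, 2, 5, 10])
    def test_daniell_closed_form(self, h):
        assert gs.effective_df(daniell_weights(h)) == pytest.approx(2 * (2 * h + 1))

    def test_tapered_weights(self):
        assert gs.effective_df(np.array([0.25, 0.5, 0.25])) == pytest.approx(16 / 3)

    def test_modified_daniell_sums_to_one(self):
        w = modified_daniell_weights(3)
        assert w.sum() == pytest.approx(1.0)
        assert gs.effective_df(w) == pytest.approx(2 / np.sum(w**2))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            gs.effective_df(np.array([1.0, 1.0]))


class TestPeaks:
    def test_two_tone_peaks_found_at_construction_frequencies(self):
        series, truth = gs.generate(
            gs.FixtureSpec(kind="two_tone", n=512, seed=2)
        )
        res = gs.SpectralModel(series).fit()
        peaks = res.peaks(min_prominence_fraction=0.2)
        found = sorted(f for f, _ in peaks[:2])
        assert found[0] == pytest.approx(truth["freq1"], abs=0.01)
        assert found[1] == pytest.approx(truth["freq2"], abs=0.01)

    def test_monotone_density_has_no_interior_peak(self):
        m = 32
        spec = Spectrum(
            freqs=np.arange(1, m + 1) / 64,
            periodogram=np.linspace(1.0, 0.1, m),
            n=64,
            density=np.linspace(1.0, 0.1, m),
        )
        peaks = gs.find_peaks(spec)
        # only the dominating boundary ordinate may be reported
        assert all(f == spec.freqs[0] for f, _ in peaks)

    def test_white_noise_few_spurious_peaks(self, white_spectrum):
        peaks = gs.find_peaks(white_spectrum, min_prominence_fraction=0.5)
        assert len(peaks) <= 2

    def test_requires_density(self):
        with pytest.raises(ValueError, match="density"):
            gs.find_peaks(_flat_spectrum())


class TestModelObjects:
    def test_model_accepts_raw_series_and_summarizes(self, rng):
        series = gs.ForensicSeries(rng.normal(size=128) + 0.05 * np.arange(128))
        res = gs.SpectralModel(series).fit()
        assert res.edf == pytest.approx(2 * (2 * res.spectrum.half_width + 1))
        txt = res.summary()
        assert "window" in txt and "EDF" in txt
        frame = res.to_frame()
        assert set(frame.columns) >= {"freq_cycles_per_obs", "periodogram", "density"}

    def test_band_power_entrypoint_matches_function(self, rng):
        series = gs.ForensicSeries(rng.normal(size=256))
        res = gs.SpectralModel(series).fit()
        via_results = res.band_power(0.1, 0.3)
        direct = gs.band_power(res.spectrum, gs.FrequencyBand(0.1, 0.3))
        assert via_results.auc == pytest.approx(direct.auc)
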