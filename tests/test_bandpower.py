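"""Band power, chi-square moment matching, CIs, F and t comparisons."""

import numpy as np
import pytest
from scipy import stats

import growthspec as gs
from growthspec.spectrum import Spectrum

# printed worked-example inputs: low-frequency band power of a standardized
# hair-isotope spectrum, and the width-adjusted high-frequency counterpart
LF_AUC, LF_VAR = 0.587, 0.064
HF_AUC, HF_VAR = 0.28, 0.0102


def _bp(auc, var, band=None, standardized=True):
    c, r = gs.moment_match(auc, var)
    return gs.BandPower(
        auc=auc, variance=var, c=c, r_df=r, band=band, standardized=standardized
    )


class TestMomentMatch:
    @pytest.mark.parametrize(
        "auc, var, c, r",
        [
            (LF_AUC, LF_VAR, 0.0545, 10.8),
            (HF_AUC, HF_VAR, 0.0182, 15.4),
            (1.0, 2.0, 1.0, 1.0),
        ],
    )
    def test_printed_pairs(self, auc, var, c, r):
        c_hat, r_hat = gs.moment_match(auc, var)
        assert c_hat == pytest.approx(c, abs=5e-5)
        assert r_hat == pytest.approx(r, abs=0.05)

    def test_round_trip_moments_exact(self, rng):
        for _ in range(20):
            auc = rng.uniform(0.05, 2.0)
            var = rng.uniform(0.001, 0.5)
            c, r = gs.moment_match(auc, var)
            assert c * r == pytest.approx(auc, rel=1e-12)
            assert 2 * c * c * r == pytest.approx(var, rel=1e-12)

    def test_identities_on_bandpower(self, white_spectrum):
        bp = gs.band_power(white_spectrum, gs.FrequencyBand(0.07, 0.27))
        assert bp.c == pytest.approx(0.5 * bp.variance / bp.auc, abs=1e-9)
        assert bp.r_df == pytest.approx(bp.auc / bp.c, abs=1e-9)
        assert bp.se == pytest.approx(np.sqrt(bp.variance))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gs.moment_match(0.0, 1.0)
        with pytest.raises(ValueError):
            gs.moment_match(1.0, 0.0)


class TestBandPower:
    def test_flat_density_full_band_is_one(self):
        n = 512
        m = n // 2
        spec = Spectrum(
            freqs=np.arange(1, m + 1) / n,
            periodogram=np.full(m, 1 / (2 * np.pi)),
            n=n,
            density=np.full(m, 1 / (2 * np.pi)),
        )
        bp = gs.band_power(spec, gs.FrequencyBand(0.0, 0.5))
        assert bp.auc == pytest.approx(1.0, abs=0.01)

    def test_additive_over_disjoint_bands(self, white_spectrum):
        a = gs.band_power(white_spectrum, gs.FrequencyBand(0.05, 0.2)).auc
        b = gs.band_power(white_spectrum, gs.FrequencyBand(0.2, 0.45)).auc
        u = gs.band_power(white_spectrum, gs.FrequencyBand(0.05, 0.45)).auc
        assert a + b == pytest.approx(u, abs=1e-12)

    def test_white_noise_total_near_one(self):
        for seed in range(5):
            std = gs.standardize(np.random.default_rng(seed).normal(size=128))
            spec = gs.smooth_density(gs.periodogram(std))
            bp = gs.band_power(spec, gs.FrequencyBand(0.0, 0.5))
            assert 0.95 < bp.auc < 1.01  # smoothing + N-1 scaling keep it ~1

    def test_empty_band_rejected(self, white_spectrum):
        with pytest.raises(ValueError, match="no grid ordinates"):
            gs.band_power(white_spectrum, gs.FrequencyBand(0.001, 0.002))

    def test_band_validation(self):
        with pytest.raises(ValueError):
            gs.FrequencyBand(0.3, 0.2)
        with pytest.raises(ValueError):
            gs.FrequencyBand(0.0, 0.6)


class TestConfidenceIntervals:
    def test_standardized_switches_to_one_sided(self):
        bp = _bp(LF_AUC, LF_VAR, standardized=True)
        # two-sided chi-square critical values ~3.7 and ~21.6 at R=10.8
        assert stats.chi2.ppf(0.025, bp.r_df) == pytest.approx(3.7, abs=0.02)
        assert stats.chi2.ppf(0.975, bp.r_df) == pytest.approx(21.6, abs=0.02)
        ci = gs.band_power_ci(bp, 0.95)
        assert ci.sided == "one"
        assert ci.upper == 1.0
        assert ci.lower == pytest.approx(0.24, abs=0.005)

    def test_unstandardized_stays_two_sided(self):
        bp = _bp(LF_AUC, LF_VAR, standardized=False)
        ci = gs.band_power_ci(bp, 0.95)
        assert ci.sided == "two"
        assert ci.lower == pytest.approx(bp.c * stats.chi2.ppf(0.025, bp.r_df))
        assert ci.upper == pytest.approx(bp.c * stats.chi2.ppf(0.975, bp.r_df))

    def test_large_df_concentrates_on_auc(self):
        bp = _bp(0.5, 1e-8, standardized=False)
        ci = gs.band_power_ci(bp, 0.95)
        assert ci.lower == pytest.approx(0.5, abs=1e-3)
        assert ci.upper == pytest.approx(0.5, abs=1e-3)

    def test_level_monotonicity(self):
        bp = _bp(LF_AUC, LF_VAR, standardized=False)
        lo = gs.band_power_ci(bp, 0.90)
        hi = gs.band_power_ci(bp, 0.99)
        assert hi.lower <= lo.lower and hi.upper >= lo.upper

    def test_coverage_monte_carlo(self):
        """CIs built from AUC draws c*chi2_R (variance known) cover the
        true mean ~95% of the time."""
        rng = np.random.default_rng(42)
        c0, r0 = 0.05, 20.0
        mean, var = c0 * r0, 2 * c0 * c0 * r0
        cover = 0
        n = 4000
        for _ in range(n):
            auc = c0 * rng.chisquare(r0)
            bp = _bp(auc, var, standardized=False)
            ci = gs.band_power_ci(bp, 0.95)
            cover += ci.lower <= mean <= ci.upper
        assert 0.92 < cover / n < 0.98

    def test_bad_level(self):
        with pytest.raises(ValueError):
            gs.band_power_ci(_bp(1.0, 0.1), level=1.5)


class TestBandwidthAdjust:
    def test_printed_example(self):
        assert gs.bandwidth_adjust(0.322, 0.20, 0.23) == pytest.approx(0.28, abs=5e-3)

    def test_equal_widths_unchanged(self):
        assert gs.bandwidth_adjust(0.322, 0.2, 0.2) == pytest.approx(0.322)

    def test_halved_width_halves_auc(self):
        assert gs.bandwidth_adjust(0.4, 0.1, 0.2) == pytest.approx(0.2)

    def test_bandpower_variant_scales_variance_quadratically(self):
        bp = _bp(0.322, 0.0135, band=gs.FrequencyBand(0.27, 0.5))
        adj = gs.bandwidth_adjust(bp, 0.20)
        k = 0.20 / 0.23
        assert adj.auc == pytest.approx(bp.auc * k)
        assert adj.variance == pytest.approx(bp.variance * k * k)


class TestRatioTest:
    def test_printed_lf_hf_example(self):
        lf = _bp(LF_AUC, LF_VAR, band=gs.FrequencyBand(0.07, 0.27))
        hf = _bp(HF_AUC, HF_VAR, band=gs.FrequencyBand(0.27, 0.5))
        res = gs.lf_hf_ratio_test(lf, hf)
        assert res.ratio == pytest.approx(2.10, abs=0.005)
        assert res.df1 == pytest.approx(10.8, abs=0.05)
        assert res.df2 == pytest.approx(15.4, abs=0.05)
        assert res.p_one == pytest.approx(0.09, abs=0.005)
        assert res.p_two == pytest.approx(0.18, abs=0.01)

    def test_identical_bands_give_ratio_one(self):
        lf = _bp(0.4, 0.02, band=gs.FrequencyBand(0.05, 0.25))
        hf = _bp(0.4, 0.02, band=gs.FrequencyBand(0.3, 0.5))
        res = gs.lf_hf_ratio_test(lf, hf)
        assert res.ratio == pytest.approx(1.0)
        assert res.p_two > 0.8

    def test_overlapping_bands_warn(self):
        lf = _bp(0.4, 0.02, band=gs.FrequencyBand(0.05, 0.3))
        hf = _bp(0.4, 0.02, band=gs.FrequencyBand(0.25, 0.5))
        with pytest.warns(UserWarning, match="overlap"):
            gs.lf_hf_ratio_test(lf, hf)

    def test_null_p_values_uniform(self):
        """White-noise null with disjoint, equal-count bands clear of the
        folding ordinate: one-sided p is uniform (KS)."""
        ps = []
        for seed in range(500):
            std = gs.standardize(
                np.random.default_rng(seed).normal(size=1024)
            )
            spec = gs.smooth_density(gs.periodogram(std))
            lf = gs.band_power(spec, gs.FrequencyBand(0.0703, 0.2578))
            hf = gs.band_power(spec, gs.FrequencyBand(0.3008, 0.4883))
            ps.append(gs.lf_hf_ratio_test(lf, hf).p_one)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTwoSample:
    def test_printed_between_record_comparison(self):
        res = gs.two_sample_auc_test(0.587, 0.253, 0.527, 0.199)
        assert res.t_stat == pytest.approx(0.19, abs=0.005)
        assert res.p_two == pytest.approx(0.85, abs=0.005)

    def test_equal_aucs(self):
        res = gs.two_sample_auc_test(0.5, 0.1, 0.5, 0.1)
        assert res.t_stat == 0.0
        assert res.p_two == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = gs.two_sample_auc_test(0.6, 0.1, 0.4, 0.2)
        b = gs.two_sample_auc_test(0.4, 0.2, 0.6, 0.1)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_two == pytest.approx(b.p_two)

    def test_bad_se(self):
        with pytest.raises(ValueError):
            gs.two_sample_auc_test(0.5, 0.0, 0.4, 0.1)
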