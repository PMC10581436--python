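import numpy as np
import pytest
from scipy import stats as sps

import panobreast as pb
from panobreast.coil_snr import mean_offdiagonal
from panobreast.phantom import MultiCoilImage, draw_noise


class TestNoiseCovariance:
    def test_identity_recovered(self):
        rng = np.random.default_rng(0)
        cov = pb.make_noise_cov(8, 1.0, 0.0)
        samples = draw_noise(cov, 100_000, rng)
        est = pb.noise_covariance(samples)
        assert np.abs(est.matrix - np.eye(8)).max() < 0.05

    def test_constant_samples_give_zero(self):
        samples = np.ones((4, 50), dtype=complex) * (2 + 3j)
        est = pb.noise_covariance(samples)
        np.testing.assert_array_equal(est.matrix, np.zeros((4, 4)))

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="insufficient"):
            pb.noise_covariance(np.zeros((8, 4), dtype=complex))

    def test_roundtrip_with_construction(self):
        cov = pb.make_noise_cov(28, 1.0, 0.065)
        rng = np.random.default_rng(1)
        est = pb.noise_covariance(draw_noise(cov, 100_000, rng))
        assert np.abs(est.matrix - cov.matrix).max() < 0.05


class TestNormalizedCorrelation:
    def test_identity(self):
        corr = pb.normalized_correlation(pb.make_noise_cov(6, 2.0, 0.0))
        np.testing.assert_array_equal(corr, np.eye(6))

    def test_mean_offdiagonal_matches_target(self):
        corr = pb.normalized_correlation(pb.make_noise_cov(28, 1.0, 0.065))
        assert mean_offdiagonal(corr) == pytest.approx(0.065, abs=1e-12)

    def test_scale_invariance(self):
        cov = pb.make_noise_cov(8, 1.0, 0.2)
        scaled = pb.NoiseCovariance(matrix=5.0 * cov.matrix)
        np.testing.assert_allclose(
            pb.normalized_correlation(scaled), pb.normalized_correlation(cov)
        )


def _single_channel_mc(value=10.0, shape=(6, 6, 6)):
    data = np.full((1,) + shape, value, dtype=complex)
    return MultiCoilImage(data=data, affine=np.eye(4))


class TestCombineChannels:
    def test_single_channel_identity(self):
        mc = _single_channel_mc(3 + 4j)
        cov = pb.make_noise_cov(1, 1.0, 0.0)
        res = pb.combine_channels(mc, cov, mode="whitened_rss")
        np.testing.assert_allclose(np.abs(res.combined), 5.0)

    def test_two_equal_channels_sqrt2(self):
        data = np.ones((2, 4, 4, 4), dtype=complex) * 7.0
        mc = MultiCoilImage(data=data, affine=np.eye(4))
        cov = pb.make_noise_cov(2, 1.0, 0.0)
        res = pb.combine_channels(mc, cov, mode="whitened_rss")
        np.testing.assert_allclose(np.abs(res.combined), 7.0 * np.sqrt(2))

    def test_matched_filter_recovers_signal(self):
        rng = np.random.default_rng(2)
        shape = (5, 5, 5)
        sens = rng.standard_normal((3,) + shape) + 1j * rng.standard_normal((3,) + shape)
        signal = rng.random(shape) + 0.5
        mc = MultiCoilImage(data=sens * signal[None], affine=np.eye(4))
        cov = pb.make_noise_cov(3, 1.0, 0.1)
        res = pb.combine_channels(mc, cov, mode="matched_filter", sens=sens)
        np.testing.assert_allclose(res.combined.real, signal, atol=1e-10)

    def test_matched_filter_requires_sens(self):
        with pytest.raises(ValueError, match="requires sensitivity"):
            pb.combine_channels(_single_channel_mc(), pb.make_noise_cov(1, 1.0, 0.0),
                                mode="matched_filter")


class TestSNRMaps:
    def test_single_channel_convention(self):
        """Unit total noise variance: SNR = |signal| * sqrt(2) (per-quadrature sigma)."""
        mc = _single_channel_mc(10.0)
        cov = pb.make_noise_cov(1, 1.0, 0.0)
        analytic = pb.analytic_snr(
            pb.Volume(data=np.full((6, 6, 6), 10.0), affine=np.eye(4)),
            np.ones((1, 6, 6, 6), dtype=complex), cov)
        np.testing.assert_allclose(analytic.data, 10.0 * np.sqrt(2))
        pseudo = pb.pseudo_replica_snr(mc, cov, n_replicas=256, seed=3)
        rel = np.abs(pseudo.data - 10.0 * np.sqrt(2)) / (10.0 * np.sqrt(2))
        assert np.median(rel) < 0.10

    def test_linear_in_signal(self, phantom8, coil8):
        _, ph = phantom8
        doubled = MultiCoilImage(data=2.0 * coil8["mc"].data, affine=coil8["mc"].affine)
        a = pb.pseudo_replica_snr(coil8["mc"], coil8["cov"], n_replicas=64, seed=4)
        b = pb.pseudo_replica_snr(doubled, coil8["cov"], n_replicas=64, seed=4)
        roi = ph.breast_roi.data.astype(bool)
        np.testing.assert_allclose(b.data[roi], 2.0 * a.data[roi], rtol=1e-6)

    def test_quadrupled_cov_halves_snr(self, phantom8, coil8):
        _, ph = phantom8
        cov4 = pb.NoiseCovariance(matrix=4.0 * coil8["cov"].matrix)
        a = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"])
        b = pb.analytic_snr(ph.signal, coil8["sens"], cov4)
        roi = ph.breast_roi.data.astype(bool)
        np.testing.assert_allclose(b.data[roi], 0.5 * a.data[roi], rtol=1e-9)

    @pytest.mark.parametrize("mode", ["whitened_rss", "matched_filter"])
    def test_pseudo_replica_matches_analytic(self, phantom8, coil8, mode):
        _, ph = phantom8
        sens = coil8["sens"] if mode == "matched_filter" else None
        pseudo = pb.pseudo_replica_snr(coil8["mc"], coil8["cov"], mode=mode,
                                       sens=sens, n_replicas=256, seed=5)
        analytic = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"], mode=mode)
        roi = ph.breast_roi.data.astype(bool)
        rel = np.abs(pseudo.data[roi] - analytic.data[roi]) / analytic.data[roi]
        assert np.median(rel) < 0.05

    def test_error_shrinks_with_replicas(self, phantom8, coil8):
        _, ph = phantom8
        analytic = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"])
        roi = ph.breast_roi.data.astype(bool)
        devs = {}
        for n in (64, 256):
            pseudo = pb.pseudo_replica_snr(coil8["mc"], coil8["cov"],
                                           n_replicas=n, seed=6)
            devs[n] = np.median(np.abs(pseudo.data[roi] - analytic.data[roi])
                                / analytic.data[roi])
        assert devs[256] < devs[64]

    def test_matched_filter_at_least_rss(self, phantom8, coil8):
        _, ph = phantom8
        rss = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"], mode="whitened_rss")
        mf = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"], mode="matched_filter")
        assert (mf.data - rss.data >= -1e-9).all()

    def test_zero_noise_model_rejected(self, coil8):
        zero = pb.noise_covariance(np.zeros((coil8["cov"].channels, 64), dtype=complex))
        with pytest.raises(ValueError, match="zero noise"):
            pb.pseudo_replica_snr(coil8["mc"], zero, n_replicas=64, seed=1)

    def test_deterministic_given_seed(self, coil8):
        a = pb.pseudo_replica_snr(coil8["mc"], coil8["cov"], n_replicas=64, seed=8)
        b = pb.pseudo_replica_snr(coil8["mc"], coil8["cov"], n_replicas=64, seed=8)
        np.testing.assert_array_equal(a.data, b.data)


class TestROIStats:
    def _snr(self, data):
        return pb.SNRMap(data=np.asarray(data, dtype=float), affine=np.eye(4))

    def test_constant_map(self):
        roi = pb.Segmentation(data=np.ones((4, 4, 4)), affine=np.eye(4))
        st = pb.roi_snr_stats(self._snr(np.full((4, 4, 4), 7.0)), roi)
        assert st.mean_snr == 7.0 and st.homogeneity == 0.0

    def test_two_point_distribution(self):
        data = np.ones((2, 2, 2))
        data[1] = 3.0
        roi = pb.Segmentation(data=np.ones((2, 2, 2)), affine=np.eye(4))
        st = pb.roi_snr_stats(self._snr(data), roi)
        assert st.mean_snr == pytest.approx(2.0)
        assert st.homogeneity == pytest.approx(st.sd_snr / 2.0)

    def test_grid_mismatch(self):
        roi = pb.Segmentation(data=np.ones((3, 3, 3)), affine=np.eye(4))
        with pytest.raises(ValueError, match="different grids"):
            pb.roi_snr_stats(self._snr(np.ones((4, 4, 4))), roi)

    def test_empty_roi(self):
        roi = pb.Segmentation(data=np.zeros((4, 4, 4)), affine=np.eye(4))
        with pytest.raises(ValueError, match="empty ROI"):
            pb.roi_snr_stats(self._snr(np.ones((4, 4, 4))), roi)

    def test_homogeneity_scale_invariant(self, phantom8, coil8):
        _, ph = phantom8
        snr = pb.analytic_snr(ph.signal, coil8["sens"], coil8["cov"])
        scaled = pb.SNRMap(data=37.0 * snr.data, affine=snr.affine)
        a = pb.roi_snr_stats(snr, ph.breast_roi).homogeneity
        b = pb.roi_snr_stats(scaled, ph.breast_roi).homogeneity
        assert a == pytest.approx(b, rel=1e-12)


class TestSNRGain:
    def _snr(self, data):
        return pb.SNRMap(data=np.asarray(data, dtype=float), affine=np.eye(4))

    def test_self_ratio_is_one(self):
        roi = pb.Segmentation(data=np.ones((3, 3, 3)), affine=np.eye(4))
        m = self._snr(np.random.default_rng(0).random((3, 3, 3)))
        assert pb.snr_gain(m, m, roi) == pytest.approx(1.0)

    def test_triple_map(self):
        roi = pb.Segmentation(data=np.ones((3, 3, 3)), affine=np.eye(4))
        m = self._snr(np.full((3, 3, 3), 2.0))
        m3 = self._snr(np.full((3, 3, 3), 6.0))
        assert pb.snr_gain(m3, m, roi) == pytest.approx(3.0)

    def test_conformal_beats_retracted(self, phantom8, coil28):
        spec, ph = phantom8
        retracted = pb.build_coil_layout(spec, standoff_mm=65.0)
        sens_ret = pb.loop_sensitivity(retracted, ph.signal)
        gain = pb.snr_gain(
            pb.analytic_snr(ph.signal, coil28["sens"], coil28["cov"]),
            pb.analytic_snr(ph.signal, sens_ret, coil28["cov"]),
            ph.breast_roi,
        )
        assert gain > 1.0


class TestPairedTTest:
    def test_symmetric_differences_give_half_p(self):
        # the a == b null has zero difference variance (guarded as an error),
        # so the t = 0, p = 0.5 case is exercised with symmetric differences
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 1.0, 4.0, 3.0]
        t, p = pb.paired_onesided_ttest(a, b)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pb.paired_onesided_ttest([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_hand_computed_example(self):
        b = np.zeros(5)
        a = np.array([2.0, 1.0, 3.0, 2.0, 2.0])
        t, p = pb.paired_onesided_ttest(a, b)
        assert t == pytest.approx(2.0 / (0.7071067811865476 / np.sqrt(5)), rel=1e-3)
        assert t == pytest.approx(6.32, abs=0.01)
        assert p == pytest.approx(0.0016, abs=2e-4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(12)
        a = rng.normal(1.0, 0.5, size=9)
        b = rng.normal(0.5, 0.5, size=9)
        t, p = pb.paired_onesided_ttest(a, b)
        ref = sps.ttest_rel(a, b, alternative="greater")
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


class TestSampleSize:
    def test_study_design_value(self):
        assert pb.required_sample_size(1.0, alpha=0.05, power=0.8, dropout=0.2) == 10

    def test_without_dropout(self):
        assert pb.required_sample_size(1.0, alpha=0.05, power=0.8, dropout=0.0) == 8

    def test_dropout_inflation_arithmetic(self):
        n0 = pb.required_sample_size(1.0, dropout=0.0)
        n_half = pb.required_sample_size(1.0, dropout=0.5)
        assert n_half == int(np.ceil(n0 / 0.5))

    def test_monotone_in_effect_and_power(self):
        sizes = [pb.required_sample_size(d) for d in (0.5, 0.8, 1.0, 1.5)]
        assert sizes == sorted(sizes, reverse=True)
        powers = [pb.required_sample_size(1.0, power=p) for p in (0.7, 0.8, 0.9)]
        assert powers == sorted(powers)

    def test_two_sided_needs_more(self):
        assert (pb.required_sample_size(1.0, sided="two")
                >= pb.required_sample_size(1.0, sided="one"))

    def test_effect_size_arithmetic(self):
        assert pb.standardized_effect_size(1.2, 0.2) == pytest.approx(1.0)
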