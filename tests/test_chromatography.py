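"""EMG peak shape and two-peak chromatogram deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from bphpkit.chromatography import (
    Chromatogram,
    EMGComponent,
    EMGMixture,
    EMGMixtureModel,
    emg_value,
    mixture_value,
)
from bphpkit.simulate import GeneratorSpec, NoiseModel, default_sec_truth, make_chromatogram


class TestEMGValue:
    def test_zero_amplitude_is_zero_everywhere(self):
        c = EMGComponent(amp=0.0, lam=3.0, mu=11.0, sigma=0.3)
        v = np.linspace(5, 25, 50)
        assert np.all(emg_value(c, v) == 0.0)

    def test_matches_convolution_density(self):
        # oracle: Gaussian (*) one-sided exponential, i.e. the exponnorm
        # density with K = 1/(lam*sigma)
        c = EMGComponent(amp=1.0, lam=2.0, mu=12.0, sigma=0.3)
        expected = stats.exponnorm.pdf(12.0, 1.0 / (c.lam * c.sigma),
                                       loc=c.mu, scale=c.sigma)
        assert emg_value(c, 12.0) == pytest.approx(expected, rel=1e-8)

    def test_matches_quadrature_convolution(self):
        c = EMGComponent(amp=1.0, lam=2.0, mu=12.0, sigma=0.3)

        def convolved(x):
            val, _ = quad(
                lambda tau: c.lam * np.exp(-c.lam * tau)
                * stats.norm.pdf(x - tau, loc=c.mu, scale=c.sigma),
                0, 30, limit=200)
            return val

        for x in (11.0, 12.0, 13.5):
            assert emg_value(c, x) == pytest.approx(convolved(x), rel=1e-8)

    def test_area_equals_amp(self):
        c = EMGComponent(amp=2.0, lam=2.0, mu=12.0, sigma=0.3)
        area, _ = quad(lambda v: emg_value(c, v), -np.inf, np.inf, limit=400)
        assert area == pytest.approx(2.0, rel=1e-6)

    def test_stable_far_from_peak(self):
        # the naive exp(...)erfc(...) form overflows here
        c = EMGComponent(amp=1.0, lam=5.0, mu=100.0, sigma=0.5)
        vals = emg_value(c, np.array([0.0, 50.0, 100.0, 200.0, 1000.0]))
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(lam_sigma=st.floats(0.05, 50.0), sigma=st.floats(0.05, 1.0))
    def test_normalization_property(self, lam_sigma, sigma):
        lam = lam_sigma / sigma
        c = EMGComponent(amp=1.0, lam=lam, mu=12.0, sigma=sigma)
        # finite window wide enough that the missed tail mass is < 1e-9;
        # quad over (-inf, inf) can skip a peak this narrow entirely
        lo = c.mu - 10 * sigma
        hi = c.mu + 10 * sigma + 30.0 / lam
        area, _ = quad(lambda v: emg_value(c, v), lo, hi,
                       limit=500, points=[c.mu])
        assert area == pytest.approx(1.0, rel=1e-6)

    def test_gaussian_limit(self):
        # for large lam*sigma the EMG approaches a Gaussian shifted by the
        # exponential mean 1/lam; the residual relative error scales as
        # 1/(lam*sigma)^2, so lam*sigma = 500 gives ~1e-5 agreement
        sigma = 0.2
        c = EMGComponent(amp=1.0, lam=500.0 / sigma, mu=12.0, sigma=sigma)
        v = np.linspace(12 - 3 * sigma, 12 + 3 * sigma, 61)
        gauss = stats.norm.pdf(v, loc=c.mu + 1.0 / c.lam, scale=sigma)
        assert np.allclose(emg_value(c, v), gauss, rtol=1e-4)

    def test_rejects_nonfinite_volume(self):
        c = EMGComponent(amp=1.0, lam=2.0, mu=12.0, sigma=0.3)
        with pytest.raises(ValueError):
            emg_value(c, np.array([1.0, np.nan]))

    @pytest.mark.parametrize("bad", [
        dict(amp=-1.0, lam=2.0, mu=12.0, sigma=0.3),
        dict(amp=1.0, lam=0.0, mu=12.0, sigma=0.3),
        dict(amp=1.0, lam=2.0, mu=12.0, sigma=-0.1),
    ])
    def test_component_invariants(self, bad):
        with pytest.raises(ValueError):
            EMGComponent(**bad)


class TestMixtureValue:
    def test_baseline_only(self):
        m = EMGMixture(EMGComponent(0, 4, 10.6, 0.2), EMGComponent(0, 4, 12.1, 0.25),
                       b=0.01, c=0.0)
        assert mixture_value(m, 15.0) == pytest.approx(0.01)

    def test_linear_drift(self):
        m = EMGMixture(EMGComponent(0, 4, 10.6, 0.2), EMGComponent(0, 4, 12.1, 0.25),
                       b=0.0, c=0.001)
        assert mixture_value(m, 10.0) == pytest.approx(0.01)

    def test_generator_round_trip(self):
        chrom = make_chromatogram(GeneratorSpec(seed=7))
        np.testing.assert_allclose(chrom.absorbance,
                                   mixture_value(chrom.truth, chrom.volume))

    def test_peak_order_enforced(self):
        with pytest.raises(ValueError):
            EMGMixture(EMGComponent(1, 4, 13.0, 0.2), EMGComponent(1, 4, 12.0, 0.25))


class TestChromatogramContainer:
    def test_rejects_decreasing_volume(self):
        with pytest.raises(ValueError):
            Chromatogram(np.linspace(10, 8, 20), np.zeros(20))

    def test_rejects_short_arrays(self):
        with pytest.raises(ValueError):
            Chromatogram(np.linspace(8, 9, 5), np.zeros(5))

    def test_csv_round_trip(self, tmp_path):
        chrom = make_chromatogram(GeneratorSpec(seed=7))
        path = tmp_path / "c.csv"
        chrom.to_csv(path)
        back = Chromatogram.from_csv(path)
        np.testing.assert_allclose(back.volume, chrom.volume)
        np.testing.assert_allclose(back.absorbance, chrom.absorbance)


class TestEMGMixtureFit:
    def test_noiseless_recovery(self):
        chrom = make_chromatogram(GeneratorSpec(seed=7))
        res = EMGMixtureModel(chrom).fit()
        truth = chrom.truth.as_array()
        assert res.converged
        np.testing.assert_allclose(res.params, truth, rtol=1e-4)

    def test_noisy_area_fraction_recovery(self):
        truth = default_sec_truth()
        peak = float(np.max(mixture_value(truth, np.linspace(8, 24, 801))))
        spec = GeneratorSpec(seed=11, noise=NoiseModel("gaussian", 0.005 * peak))
        chrom = make_chromatogram(spec)
        res = EMGMixtureModel(chrom).fit()
        f, se = res.tetramer_fraction()
        truth_f = truth.tetramer.amp / (truth.tetramer.amp + truth.dimer.amp)
        assert f == pytest.approx(truth_f, abs=0.02)

    def test_single_peak_degenerate_mixture(self):
        truth = EMGMixture(EMGComponent(0.0, 4.0, 10.6, 0.22),
                           EMGComponent(0.8, 4.0, 12.1, 0.25), b=0.01, c=5e-4)
        peak = float(np.max(mixture_value(truth, np.linspace(8, 24, 801))))
        chrom = make_chromatogram(GeneratorSpec(
            seed=13, truth=truth, noise=NoiseModel("gaussian", 0.002 * peak)))
        res = EMGMixtureModel(chrom).fit()
        assert res.converged
        # with one physical peak the amplitude split between the two
        # components is unidentifiable, but the well-posed quantities are:
        # the fit reproduces the data at the noise level ...
        resid = mixture_value(res.model, chrom.volume) - chrom.absorbance
        assert np.sqrt(np.mean(resid**2)) < 1.5 * 0.002 * peak
        # ... the total eluted area is conserved ...
        total = res.model.tetramer.amp + res.model.dimer.amp
        assert total == pytest.approx(0.8, rel=0.02)
        # ... and no phantom early-eluting peak is invented
        assert min(res.model.tetramer.mu, res.model.dimer.mu) > 11.5

    def test_insufficient_points_rejected(self):
        chrom = make_chromatogram(GeneratorSpec(seed=7))
        with pytest.raises(ValueError):
            EMGMixtureModel(chrom, window=(8.0, 8.1))

    def test_fraction_se_propagated(self):
        chrom = make_chromatogram(GeneratorSpec(
            seed=17, noise=NoiseModel("gaussian", 0.003)))
        res = EMGMixtureModel(chrom).fit()
        f, se = res.tetramer_fraction()
        assert 0.0 <= f <= 1.0
        assert se > 0.0

    def test_summary_mentions_fraction(self):
        chrom = make_chromatogram(GeneratorSpec(seed=7))
        res = EMGMixtureModel(chrom).fit()
        assert "tetramer area fraction" in res.summary()
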