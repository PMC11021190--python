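import math

import numpy as np
import pytest

import spp
from spp.correlation import (CorrelationCurve, autocorrelate, crosscorrelate,
                             diffusion_coefficient, diffusion_model,
                             fit_diffusion, multiparameter_table)
from spp.io import Trace
from spp.profile import GPStats

from conftest import brute_force_multitau, make_poisson_trace


class TestCorrelator:
    def test_constant_trace_has_zero_correlation(self):
        tr = Trace(["a"], 1e-5, np.full((1, 20_000), 5))
        curve = autocorrelate(tr, "a")
        np.testing.assert_allclose(curve.g, 0.0, atol=1e-12)

    def test_zero_mean_trace_rejected(self):
        tr = Trace(["a"], 1e-5, np.zeros((1, 20_000), dtype=int))
        with pytest.raises(ValueError, match="zero-mean"):
            autocorrelate(tr, "a")

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            autocorrelate(make_poisson_trace(5.0, 5000, seed=1), "a")

    def test_poisson_shot_noise_is_white(self):
        lam, n = 10.0, 100_000
        tr = make_poisson_trace(lam, n, seed=41)
        curve = autocorrelate(tr, "a")
        # shot-noise-limited standard error of G at each lag, given the
        # rebinned mean counts and number of samples entering the estimate
        binsize = np.maximum(1, np.round(curve.lags / (16 * tr.bin_time)))
        binsize = 2 ** np.ceil(np.log2(binsize))
        m = n / binsize
        se = 1.0 / (lam * binsize * np.sqrt(m))
        assert np.all(np.abs(curve.g) < 5 * se)

    def test_multitau_matches_brute_force_oracle(self):
        """Vectorized multi-tau equals a naive-loop reference estimator to
        1e-6 relative on a 1e4-bin trace."""
        rng = np.random.default_rng(42)
        # correlated signal: smoothed Poisson bursts over background
        lam = np.full(10_000, 5.0)
        for c in range(500, 10_000, 700):
            lam += 30.0 * np.exp(-0.5 * ((np.arange(10_000) - c) / 40) ** 2)
        counts = rng.poisson(lam)
        tr = Trace(["a"], 1e-5, counts[np.newaxis])
        curve = autocorrelate(tr, "a")
        lags_bf, g_bf = brute_force_multitau(counts, counts, 1e-5,
                                             tr.duration / 4)
        np.testing.assert_allclose(curve.lags, lags_bf, rtol=1e-12)
        np.testing.assert_allclose(curve.g, g_bf, rtol=1e-6, atol=1e-12)

    def test_cross_equals_auto_for_identical_channels(self):
        counts = np.random.default_rng(43).poisson(8.0, 20_000)
        tr = Trace(["a", "b"], 1e-5, np.vstack([counts, counts]))
        auto = autocorrelate(tr, "a")
        cross = crosscorrelate(tr, "a", "b")
        np.testing.assert_array_equal(auto.g, cross.g)

    def test_cross_is_symmetric_in_channels(self):
        rng = np.random.default_rng(44)
        tr = Trace(["a", "b"], 1e-5, rng.poisson(8.0, size=(2, 20_000)))
        g_ab = crosscorrelate(tr, "a", "b")
        g_ba = crosscorrelate(tr, "b", "a")
        np.testing.assert_array_equal(g_ab.g, g_ba.g)

    def test_independent_channels_have_no_amplitude(self):
        rng = np.random.default_rng(45)
        tr = Trace(["a", "b"], 1e-5, rng.poisson(20.0, size=(2, 100_000)))
        curve = crosscorrelate(tr, "a", "b")
        assert np.all(np.abs(curve.g) < 0.005)

    def test_lags_strictly_increasing(self):
        tr = make_poisson_trace(5.0, 50_000, seed=46)
        curve = autocorrelate(tr, "a")
        assert np.all(np.diff(curve.lags) > 0)
        assert curve.lags[0] == pytest.approx(tr.bin_time)


class TestDiffusionModel:
    def test_half_amplitude_at_tau_d_in_large_ar_limit(self):
        assert diffusion_model(1e-3, N=1.0, tau_D=1e-3, AR=1e9) == \
            pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("omega,tau_d,expected", [
        (0.3, 1e-3, 0.09 / (8 * math.log(2) * 1e-3)),  # ~16.23 µm²/s
        (0.25, 2e-3, 0.0625 / (8 * math.log(2) * 2e-3)),
    ])
    def test_diffusion_coefficient_formula(self, omega, tau_d, expected):
        assert diffusion_coefficient(tau_d, omega) == \
            pytest.approx(expected, rel=1e-12)

    def test_diffusion_coefficient_scalings(self):
        base = diffusion_coefficient(1e-3, 0.3)
        assert base == pytest.approx(16.23, rel=1e-3)
        assert diffusion_coefficient(1e-3, 0.6) == pytest.approx(4 * base)
        assert diffusion_coefficient(1e3, 0.3) < 1e-4  # tau_D -> inf: D -> 0
        with pytest.raises(ValueError):
            diffusion_coefficient(-1e-3, 0.3)


class TestFitDiffusion:
    def _noiseless_curve(self, N=5.0, tau_d=1e-3, ar=5.0):
        lags = np.geomspace(1e-5, 1.0, 120)
        return CorrelationCurve(lags=lags,
                                g=diffusion_model(lags, N, tau_d, ar),
                                kind="auto", channels=("a",))

    def test_noiseless_model_roundtrip(self):
        fit = fit_diffusion(self._noiseless_curve(), omega=0.25, ar=5.0)
        assert fit.converged
        assert fit.N == pytest.approx(5.0, rel=1e-6)
        assert fit.tau_D == pytest.approx(1e-3, rel=1e-6)
        assert fit.D == pytest.approx(
            0.25**2 / (8 * math.log(2) * fit.tau_D), rel=1e-12)

    def test_free_aspect_ratio_recovered_from_noiseless_curve(self):
        fit = fit_diffusion(self._noiseless_curve(ar=3.0), omega=0.25,
                            ar=5.0, ar_mode="free")
        assert fit.AR == pytest.approx(3.0, rel=1e-4)

    def test_fit_scale_invariance(self):
        cfg = spp.SimConfig(
            populations=[spp.Population(concentration=3.75, D=5.0,
                                        brightness={"a": 5.0})],
            seed=47, box=(0.6, 0.6, 2.0), bin_time=1e-5, duration=1.0)
        tr, _ = spp.simulate_trace(cfg, record_transits=False)
        scaled = Trace(["a"], 1e-5, tr.counts * 10)
        fit1 = fit_diffusion(autocorrelate(tr, "a"), omega=0.25)
        fit2 = fit_diffusion(autocorrelate(scaled, "a"), omega=0.25)
        assert fit2.N == pytest.approx(fit1.N, rel=1e-6)
        assert fit2.tau_D == pytest.approx(fit1.tau_D, rel=1e-6)

    def test_nonpositive_amplitude_rejected(self):
        lags = np.geomspace(1e-5, 1e-2, 30)
        curve = CorrelationCurve(lags=lags, g=np.full(30, -0.1),
                                 kind="auto", channels=("a",))
        with pytest.raises(ValueError, match="amplitude"):
            fit_diffusion(curve, omega=0.25)


class TestSpikeSkew:
    def test_single_bright_spike_inflates_cross_correlation(self):
        """One co-occurring bright impurity dominates the cross-correlation
        amplitude while barely moving the per-particle co-occurrence count —
        the failure mode per-particle analysis avoids."""
        rng = np.random.default_rng(48)
        n = 50_000
        a = rng.poisson(5.0, n)
        b = rng.poisson(5.0, n)
        clean = Trace(["a", "b"], 1e-5, np.vstack([a, b]))
        spike = np.round(500.0 * np.exp(
            -0.5 * ((np.arange(n) - 25_000) / 50.0) ** 2)).astype(np.int64)
        spiked = Trace(["a", "b"], 1e-5, np.vstack([a + spike, b + spike]))
        g_clean = crosscorrelate(clean, "a", "b")
        g_spiked = crosscorrelate(spiked, "a", "b")
        assert abs(g_spiked.g[0]) > 10 * abs(g_clean.g[0])


class TestMultiparameterTable:
    def _sample_tables(self, d_mus, gp_mus, n_per_class=20, d_sd=0.5,
                       gp_sd=0.03, seed=0):
        """Constructed per-sample (D, GP) measurements for particle classes."""
        rng = np.random.default_rng(seed)
        gp_stats, fits, labels = {}, {}, []
        i = 0
        for cls, (d_mu, gp_mu) in enumerate(zip(d_mus, gp_mus)):
            for _ in range(n_per_class):
                tau_d = 0.25**2 / (8 * math.log(2)
                                   * max(rng.normal(d_mu, d_sd), 0.1))
                fits[f"s{i:03d}"] = spp.DiffusionFit(
                    N=1.0, tau_D=tau_d, AR=5.0, omega=0.25,
                    residual_rms=0.0, converged=True)
                gp_stats[f"s{i:03d}"] = GPStats(
                    mu=float(rng.normal(gp_mu, gp_sd)), sigma=gp_sd,
                    n_events=200)
                labels.append(cls)
                i += 1
        return gp_stats, fits, np.array(labels)

    def test_unmatched_identifiers_rejected(self):
        gp_stats, fits, _ = self._sample_tables([5.0], [0.2], n_per_class=2)
        del fits["s000"]
        with pytest.raises(ValueError, match="s000"):
            multiparameter_table(gp_stats, fits)

    def test_gp_axis_separates_classes_with_identical_diffusion(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        gp_stats, fits, _ = self._sample_tables([5.0, 5.0], [-0.2, 0.3],
                                                seed=1)
        table = multiparameter_table(gp_stats, fits)
        xy = table[["D", "gp_mean"]].to_numpy()
        z = (xy - xy.mean(0)) / xy.std(0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0)
        labels_joint = km.fit_predict(z)
        labels_d = km.fit_predict(z[:, :1])  # diffusion alone: pure noise
        # both partitions scored in the joint feature space
        s_joint = silhouette_score(z, labels_joint)
        s_d = silhouette_score(z, labels_d)
        assert s_joint > s_d

    def test_joint_separation_recovers_class_labels(self):
        from sklearn.cluster import KMeans

        gp_stats, fits, labels = self._sample_tables(
            [5.0, 6.5], [0.05, 0.17], d_sd=0.6, gp_sd=0.045, seed=2)
        table = multiparameter_table(gp_stats, fits)
        xy = table[["D", "gp_mean"]].to_numpy()
        z = (xy - xy.mean(0)) / xy.std(0)
        pred = KMeans(n_clusters=2, n_init=10,
                      random_state=0).fit_predict(z)
        acc = max((pred == labels).mean(), (pred != labels).mean())
        assert acc >= 0.9

    def test_single_population_does_not_split(self):
        from sklearn.cluster import KMeans
        from sklearn.metrics import silhouette_score

        gp_stats, fits, _ = self._sample_tables([5.0], [0.2],
                                                n_per_class=40, seed=3)
        table = multiparameter_table(gp_stats, fits)
        xy = table[["D", "gp_mean"]].to_numpy()
        z = (xy - xy.mean(0)) / xy.std(0)
        pred = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(z)
        assert silhouette_score(z, pred) < 0.5
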