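import numpy as np
import pytest

import patchkit as pk
from patchkit.idealize import fit_mixture_to_points
from patchkit.models import GaussianComponent, GaussianMixtureFit


def make_trace(samples, fs=10_000.0, v=100.0):
    return pk.Trace(samples=np.asarray(samples, float), sampling_rate_hz=fs,
                    command_voltage_mv=v)


def manual_fit(means, sigma=0.3):
    comps = [GaussianComponent(area=1.0, mu=m, sigma=sigma) for m in means]
    return GaussianMixtureFit(components=comps, offset=0.0, converged=True, redchi=0.0)


class TestAmplitudeHistogram:
    def test_single_value_one_bin(self):
        h = pk.amplitude_histogram(make_trace(np.zeros(1000)), bin_width_pa=0.1)
        assert h.counts.sum() == 1000
        assert np.count_nonzero(h.counts) == 1

    def test_alternating_two_bins(self):
        x = np.tile([0.0, 9.65], 500)
        h = pk.amplitude_histogram(make_trace(x), bin_width_pa=0.1)
        occupied = h.counts[h.counts > 0]
        assert occupied.tolist() == [500, 500]

    def test_count_conservation_and_range(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 0.3, 100_000)
        h = pk.amplitude_histogram(make_trace(x))
        assert h.counts.sum() == x.size
        assert h.bin_edges[0] <= x.min() and h.bin_edges[-1] >= x.max()

    def test_histogram_mean_matches_gaussian(self):
        rng = np.random.default_rng(1)
        n = 100_000
        x = rng.normal(2.0, 0.3, n)
        h = pk.amplitude_histogram(make_trace(x))
        mean = (h.centers * h.counts).sum() / n
        assert abs(mean - 2.0) < 3 * 0.3 / np.sqrt(n) + h.bin_width  # binning bias bound

    def test_rejects_empty_and_bad_width(self):
        with pytest.raises(ValueError):
            pk.amplitude_histogram(make_trace(np.ones(10)), bin_width_pa=-1.0)


class TestGaussianMixtureFit:
    def test_noiseless_two_component_recovery(self):
        # frozen target: f(x) with (A=1000, mu=0, s=0.3) + (A=300, mu=9.65, s=0.3)
        x = np.arange(-2.0, 12.0, 0.05)
        true = [(1000.0, 0.0, 0.3), (300.0, 9.65, 0.3)]
        y = sum(a * np.exp(-((x - m) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))
                for a, m, s in true)
        fit = fit_mixture_to_points(x, y, 2)
        assert fit.converged
        for comp, (a, m, s) in zip(fit.components, true):
            assert comp.area == pytest.approx(a, rel=0.01)
            assert comp.mu == pytest.approx(m, abs=0.01 * max(abs(m), 1.0))
            assert comp.sigma == pytest.approx(s, rel=0.01)

    def test_single_component_mean_is_sample_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(-3.0, 0.5, 50_000)
        h = pk.amplitude_histogram(make_trace(x))
        fit = pk.fit_gaussian_mixture(h, 1)
        assert fit.means[0] == pytest.approx(x.mean(), abs=0.02)

    def test_separation_recovers_unitary_current_1uM_condition(self):
        # simulated patch with G = 57.2 pS at +100 mV: mu2 - mu1 = 5.72 pA
        model = pk.two_state_model(conductance_ps=57.2)
        trace, _ = pk.simulate_patch(model, 100.0, 10.0, pk.AcquisitionSpec(), seed=7)
        h = pk.amplitude_histogram(trace)
        fit = pk.fit_gaussian_mixture(h, 2)
        assert pk.unitary_amplitude(fit) == pytest.approx(5.72, rel=0.01)

    def test_residual_not_worse_with_more_components(self):
        model = pk.two_state_model()
        trace, _ = pk.simulate_patch(model, 100.0, 5.0, pk.AcquisitionSpec(), seed=9)
        h = pk.amplitude_histogram(trace, bin_width_pa=0.1)
        dens = h.density()

        def ssr(fit):
            return float(((fit.evaluate(h.centers) - dens) ** 2).sum())

        ssr1 = ssr(pk.fit_gaussian_mixture(h, 1))
        ssr2 = ssr(pk.fit_gaussian_mixture(h, 2))
        ssr3 = ssr(pk.fit_gaussian_mixture(h, 3))
        assert ssr2 < ssr1
        assert ssr3 <= ssr2 * 1.01

    def test_too_few_bins_rejected(self):
        h = pk.AmplitudeHistogram(bin_edges=np.arange(5.0), counts=[1, 2, 3, 4])
        with pytest.raises(ValueError, match="occupied bins"):
            pk.fit_gaussian_mixture(h, 2)


class TestUnitaryAmplitude:
    def test_positive_and_negative_levels(self):
        assert pk.unitary_amplitude(manual_fit([0.0, 9.65])) == pytest.approx(9.65)
        assert pk.unitary_amplitude(manual_fit([-9.0, 0.0])) == pytest.approx(-9.0)

    def test_single_component_raises_no_opening(self):
        with pytest.raises(pk.NoOpeningDetected):
            pk.unitary_amplitude(manual_fit([0.0]))

    def test_roundtrip_at_both_polarities(self):
        model = pk.two_state_model(conductance_ps=96.5)
        for v, expected in [(100.0, 9.65), (-100.0, -9.65)]:
            trace, _ = pk.simulate_patch(model, v, 10.0, pk.AcquisitionSpec(), seed=3)
            fit = pk.fit_gaussian_mixture(pk.amplitude_histogram(trace), 2)
            assert pk.unitary_amplitude(fit) == pytest.approx(expected, rel=0.02)


class TestIdealizeTrace:
    def test_noiseless_alternating_dwells_recovered(self, quiet_acq):
        levels = np.tile([0, 1], 10)
        ideal_in = pk.IdealizedTrace(levels=levels, durations=np.full(20, 0.01))
        model = pk.two_state_model(conductance_ps=96.5)
        tr = pk.render_current(ideal_in, model, 100.0, quiet_acq)
        out = pk.idealize_trace(tr, manual_fit([0.0, 9.65]))
        assert np.array_equal(out.levels, ideal_in.levels)
        assert out.durations == pytest.approx(ideal_in.durations)

    def test_dead_time_removes_blip(self):
        # 0.05 ms blip inside a closed stretch, dead time 0.1 ms
        fs = 100_000.0
        ideal_in = pk.IdealizedTrace(
            levels=[0, 1, 0, 1, 0],
            durations=[0.010, 0.00005, 0.010, 0.010, 0.010],
        )
        model = pk.two_state_model(conductance_ps=96.5)
        acq = pk.AcquisitionSpec(sampling_rate_hz=fs, filter_cutoff_hz=None, noise_sd_pa=0.0)
        tr = pk.render_current(ideal_in, model, 100.0, acq)
        out = pk.idealize_trace(tr, manual_fit([0.0, 9.65]), dead_time_s=1e-4)
        assert out.levels.tolist() == [0, 1, 0]
        assert out.durations[0] == pytest.approx(0.02005, abs=2 / fs)
        assert out.duration_s == pytest.approx(tr.duration_s)

    def test_idealization_idempotent_on_noiseless_render(self, quiet_acq):
        model = pk.two_state_model()
        truth = pk.simulate_gating(model, 100.0, 2.0, seed=21)
        tr = pk.render_current(truth, model, 100.0, quiet_acq)
        out = pk.idealize_trace(tr, manual_fit([0.0, 9.65]))
        # equality up to sample quantization: compare resampled level paths
        assert np.array_equal(out.sample(quiet_acq.sampling_rate_hz),
                              truth.sample(quiet_acq.sampling_rate_hz))

    def test_popen_close_to_generator_truth(self):
        model = pk.two_state_model(opening_rate=50.0, closing_rate=50.0)
        trace, truth = pk.simulate_patch(model, 100.0, 20.0, pk.AcquisitionSpec(), seed=13)
        fit = pk.fit_gaussian_mixture(pk.amplitude_histogram(trace), 2)
        ideal = pk.idealize_trace(trace, fit, dead_time_s=pk.default_dead_time(5000.0))
        est = pk.popen(ideal, window_s=20.0).popen
        true = trace.meta["true_popen"]
        assert abs(est - true) < 0.02

    def test_unitary_amplitude_converges_with_vanishing_noise(self):
        model = pk.two_state_model(conductance_ps=96.5)
        acq = pk.AcquisitionSpec(noise_sd_pa=0.01)
        trace, _ = pk.simulate_patch(model, 100.0, 5.0, acq, seed=17)
        fit = pk.fit_gaussian_mixture(pk.amplitude_histogram(trace, bin_width_pa=0.02), 2)
        assert pk.unitary_amplitude(fit) == pytest.approx(9.65, rel=0.005)

    def test_baseline_subtraction_removes_linear_drift(self):
        model = pk.two_state_model(conductance_ps=96.5)
        trace, _ = pk.simulate_patch(model, 100.0, 10.0, pk.AcquisitionSpec(), seed=31)
        drift = np.linspace(0.0, 3.0, trace.n_samples)  # 3 pA linear drift
        drifting = pk.Trace(samples=trace.samples + drift,
                            sampling_rate_hz=trace.sampling_rate_hz,
                            command_voltage_mv=100.0)
        corrected = pk.subtract_baseline(drifting, segment_s=1.0)
        fit = pk.fit_gaussian_mixture(pk.amplitude_histogram(corrected), 2)
        assert pk.unitary_amplitude(fit) == pytest.approx(9.65, rel=0.02)
        base = fit.means[np.argmin(np.abs(fit.means))]
        assert abs(base) < 0.3  # closed peak pulled back near 0 pA

    def test_overlap_warning_flag(self):
        tr = make_trace(np.r_[np.zeros(500), np.full(500, 0.5)])
        out = pk.idealize_trace(tr, manual_fit([0.0, 0.5], sigma=0.4))
        assert out.meta["overlap_warning"] is True
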