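"""Synthetic trace/phantom generators and their ground-truth bookkeeping."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from stimlock import GeneratorConfig, IsiPhantomSpec, ParameterError, \
    build_protocol, make_kernel, simulate_fov, simulate_isi_stack, \
    simulate_spontaneous


class TestKernel:
    def test_peak_frame_matches_dense_grid_maximization(self):
        k = make_kernel(rise_tau=0.18, decay_tau=1.5, frame_rate=7.8)
        assert k.samples.max() == 1.0
        # dense-grid numeric maximization of the continuous kernel (oracle)
        res = minimize_scalar(lambda t: -(np.exp(-t / 1.5) - np.exp(-t / 0.18)),
                              bounds=(0, 5), method="bounded")
        assert k.peak_time_s == pytest.approx(res.x, abs=1e-4)
        assert k.peak_lag_frames == round(res.x * 7.8)

    def test_equal_taus_alpha_function_limit(self):
        k = make_kernel(rise_tau=0.5, decay_tau=0.5, frame_rate=20.0)
        assert k.samples.max() == 1.0
        # alpha function peaks at t = tau
        assert k.peak_lag_frames == round(0.5 * 20.0)

    def test_length_covers_five_decay_constants(self):
        k = make_kernel(decay_tau=1.5, frame_rate=7.8)
        assert len(k.samples) >= 5 * 1.5 * 7.8
        assert np.all(k.samples >= 0)

    @pytest.mark.parametrize("bad", [dict(rise_tau=0), dict(decay_tau=-1),
                                     dict(frame_rate=0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_kernel(**bad)


class TestSimulateFov:
    def test_noiseless_responsive_cell_has_exactly_20_transients(self, protocol):
        cfg = GeneratorConfig(frac_responsive=1.0, response_prob=1.0,
                              spont_rate=0.0, noise_sd=0.0)
        traces, truths = simulate_fov(3, protocol, cfg, seed=5)
        for t in truths:
            assert t.is_responsive
            assert len(t.evoked_events) == 20
            assert len(t.spont_events) == 0
        # trace is a pure sum of kernels: nonnegative, nonzero
        assert np.all(traces.dff >= 0) and traces.dff.max() > 0

    def test_event_log_conserves_transients(self, protocol):
        """Every evoked transient maps to exactly one (cell, stimulus) log entry."""
        cfg = GeneratorConfig(frac_responsive=1.0, response_prob=0.5,
                              spont_rate=0.0, noise_sd=0.0, amp_cv=0.0,
                              adaptation_factor=1.0)
        traces, truths = simulate_fov(10, protocol, cfg, seed=7)
        k = make_kernel(cfg.rise_tau, cfg.decay_tau, cfg.frame_rate)
        for i, t in enumerate(truths):
            epochs_hit = [e[0] for e in t.evoked_events]
            assert len(set(epochs_hit)) == len(epochs_hit)  # one per stimulus
            # reconstruct from the log and compare bitwise-free
            impulses = np.zeros(traces.n_frames)
            for _, t_ev, amp in t.evoked_events:
                impulses[int(np.floor(t_ev * cfg.frame_rate))] += amp
            recon = np.convolve(impulses, k.samples)[:traces.n_frames]
            np.testing.assert_allclose(recon, traces.dff[i], atol=1e-12)

    def test_responsive_fraction_converges(self, protocol):
        cfg = GeneratorConfig()
        _, truths = simulate_fov(600, protocol, cfg, seed=13)
        frac = np.mean([t.is_responsive for t in truths])
        # binomial 3-sigma band around 1/3 at n=600
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 600)

    def test_same_seed_bitwise_identical(self, protocol):
        a, _ = simulate_fov(6, protocol, seed=42)
        b, _ = simulate_fov(6, protocol, seed=42)
        assert np.array_equal(a.dff, b.dff)
        c, _ = simulate_fov(6, protocol, seed=43)
        assert not np.array_equal(a.dff, c.dff)

    def test_invalid_cell_count(self, protocol):
        with pytest.raises(ParameterError):
            simulate_fov(0, protocol, seed=1)


class TestSimulateSpontaneous:
    def test_silent_config_gives_zero_traces(self):
        cfg = GeneratorConfig(spont_rate=0.0, noise_sd=0.0)
        traces, _ = simulate_spontaneous(4, 50.0, cfg, seed=3)
        assert np.all(traces.dff == 0)

    def test_event_count_matches_poisson_rate(self):
        cfg = GeneratorConfig(spont_rate=0.05)
        _, truths = simulate_spontaneous(200, 100.0, cfg, seed=9)
        counts = [len(t.spont_events) for t in truths]
        # mean count ~ Poisson(5); SE of the mean over 200 cells ~ 0.158
        assert np.mean(counts) == pytest.approx(5.0, abs=3 * np.sqrt(5 / 200))

    def test_same_seed_reproducible(self):
        a, _ = simulate_spontaneous(5, 30.0, seed=8)
        b, _ = simulate_spontaneous(5, 30.0, seed=8)
        assert np.array_equal(a.dff, b.dff)


class TestIsiPhantom:
    def test_zero_amplitude_means_post_equals_pre_in_expectation(self):
        spec = IsiPhantomSpec(blob_amplitude=0.0, noise_sd=0.001,
                              image_shape=(32, 32), n_trials=20)
        stack = simulate_isi_stack(spec, seed=2)
        pre = stack[:, :spec.pre_frames].mean()
        post = stack[:, spec.pre_frames:].mean()
        assert post == pytest.approx(pre, abs=5e-5)

    def test_noiseless_post_frames_carry_the_blob(self):
        spec = IsiPhantomSpec(blob_amplitude=-0.02, noise_sd=0.0,
                              image_shape=(64, 64), n_trials=2)
        stack = simulate_isi_stack(spec, seed=0)
        drr_true = spec.blob_image()
        post = stack[0, spec.pre_frames:]
        np.testing.assert_allclose(post[0], spec.baseline * (1 + drr_true))

    def test_same_seed_reproducible(self):
        spec = IsiPhantomSpec(image_shape=(16, 16), n_trials=3)
        a = simulate_isi_stack(spec, seed=4)
        b = simulate_isi_stack(spec, seed=4)
        assert np.array_equal(a, b)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            IsiPhantomSpec(blob_sigma=0.0)
        with pytest.raises(ParameterError):
            IsiPhantomSpec(n_trials=0)
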