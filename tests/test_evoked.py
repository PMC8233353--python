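"""Stimulus alignment, AUC, per-stimulus responses, adaptation index."""

import numpy as np
import pytest

from stimlock import GeneratorConfig, InputError, adaptation_index, \
    align_stimuli, auc, build_protocol, evoked_summary, make_kernel, \
    per_stimulus_response, simulate_fov
from stimlock.evoked import EvokedResponseExtractor
from stimlock.zscoring import zscore_matrix

FR = 10.0  # round-number rate so 2 s windows have exact trapezoid sums


class TestAlignStimuli:
    def test_identical_segments_average_to_themselves(self):
        p = build_protocol(n_epochs=20)
        z = np.zeros(int(81 * FR))
        onsets = p.onset_frames(FR)
        pattern = np.sin(np.linspace(0, np.pi, int(2 * FR)))
        for s in onsets:
            z[s:s + len(pattern)] = pattern
        segments, mean_trace = align_stimuli(z, p, FR, window_s=2.0)
        assert segments.shape == (20, 20)
        np.testing.assert_allclose(mean_trace, pattern)

    def test_single_hot_epoch_scales_mean_by_count(self):
        p = build_protocol(n_epochs=20)
        z = np.zeros(int(81 * FR))
        onsets = p.onset_frames(FR)
        z[onsets[4]:onsets[4] + int(2 * FR)] = 20.0
        _, mean_trace = align_stimuli(z, p, FR, window_s=2.0)
        np.testing.assert_allclose(mean_trace, 1.0)

    def test_mean_equals_explicit_loop_on_jittered_responses(self, protocol):
        cfg = GeneratorConfig(frac_responsive=1.0, response_prob=1.0,
                              spont_rate=0.0, noise_sd=0.01)
        traces, _ = simulate_fov(1, protocol, cfg, seed=17)
        z = traces.dff[0]
        segments, mean_trace = align_stimuli(z, protocol, cfg.frame_rate)
        # oracle: direct python loop
        onsets = protocol.onset_frames(cfg.frame_rate)
        wlen = round(2.0 * cfg.frame_rate)
        manual = np.mean([z[s:s + wlen] for s in onsets], axis=0)
        np.testing.assert_allclose(mean_trace, manual)

    def test_window_past_trace_end_names_epoch(self):
        p = build_protocol(n_epochs=20)
        with pytest.raises(InputError, match="epoch 20"):
            align_stimuli(np.zeros(int(77 * FR)), p, FR, window_s=2.0)


class TestAuc:
    def test_rectangle(self):
        seg = np.ones(int(2 * FR) + 1)  # spans exactly 2 s
        assert auc(seg, FR) == pytest.approx(2.0)

    def test_triangle(self):
        up = np.linspace(0, 4, int(FR) + 1)
        seg = np.concatenate([up, up[-2::-1]])  # symmetric, peak 4, base 2 s
        assert auc(seg, FR) == pytest.approx(4.0)

    def test_matches_composite_trapezoid_by_hand(self, rng):
        seg = rng.normal(0, 1, 25)
        manual = sum((seg[i] + seg[i + 1]) / 2 / FR for i in range(24))
        assert auc(seg, FR) == pytest.approx(manual)

    def test_linearity(self, rng):
        x, y = rng.normal(0, 1, (2, 30))
        assert auc(2.5 * x + 0.5 * y, FR) == pytest.approx(
            2.5 * auc(x, FR) + 0.5 * auc(y, FR))

    def test_fubini_mean_trace_auc_equals_mean_of_epoch_aucs(self, rng):
        p = build_protocol(n_epochs=20)
        z = rng.normal(0, 1, int(81 * FR))
        segments, mean_trace = align_stimuli(z, p, FR)
        per_epoch = [auc(s, FR) for s in segments]
        assert auc(mean_trace, FR) == pytest.approx(np.mean(per_epoch))


class TestPerStimulusResponse:
    def _trace_with_events(self, epochs_hit, protocol, amp=8.0):
        kernel = make_kernel(frame_rate=FR)
        z = np.zeros(int(81 * FR))
        impulses = np.zeros_like(z)
        for k in epochs_hit:
            impulses[int(protocol.onsets_s[k] * FR) + 2] = amp
        return np.convolve(impulses, kernel.samples)[:z.size]

    def test_responded_fraction_on_constructed_cell(self):
        p = build_protocol(n_epochs=20)
        hit = sorted(np.random.default_rng(3).choice(20, 12, replace=False))
        z = self._trace_with_events(hit, p)
        table = per_stimulus_response(z, p, FR)
        assert table["responded"].sum() == 12
        assert table["responded"].mean() == pytest.approx(0.6)
        assert sorted(table.loc[table.responded, "epoch"] - 1) == hit

    def test_monotone_decay_is_not_a_response(self):
        p = build_protocol(n_epochs=20)
        z = self._trace_with_events([4], p)
        table = per_stimulus_response(z, p, FR)
        # epoch 6 sees only the residual decay of epoch 5's transient
        assert not table.loc[table.epoch == 6, "responded"].item()
        assert table.loc[table.epoch == 5, "responded"].item()

    def test_latency_measured_from_onset(self):
        p = build_protocol(n_epochs=20)
        z = self._trace_with_events(list(range(20)), p)
        table = per_stimulus_response(z, p, FR)
        kernel_lag = make_kernel(frame_rate=FR).peak_lag_frames
        expected = (2 + kernel_lag) / FR
        assert np.allclose(table["latency_s"], expected)


class TestAdaptationIndex:
    def test_symmetric_blocks_give_zero(self):
        assert adaptation_index(np.ones(20)) == 0.0

    def test_direct_evaluation(self):
        aucs = np.zeros(20)
        aucs[:5] = 0.4    # A = 2
        aucs[15:] = 0.2   # B = 1
        assert adaptation_index(aucs) == pytest.approx(1 / 3)

    def test_boundary_full_adaptation(self):
        aucs = np.zeros(20)
        aucs[:5] = 1.0
        assert adaptation_index(aucs) == 1.0

    def test_antisymmetric_under_block_swap(self, rng):
        aucs = rng.uniform(0.1, 2.0, 20)
        swapped = aucs.copy()
        swapped[:5], swapped[15:] = aucs[15:].copy(), aucs[:5].copy()
        assert adaptation_index(swapped) == pytest.approx(-adaptation_index(aucs))

    def test_undefined_when_sums_cancel(self):
        with pytest.raises(InputError):
            adaptation_index(np.zeros(20))
        with pytest.raises(InputError):
            adaptation_index(np.ones(10))  # too few stimuli


class TestSummaryAndExtractor:
    def test_summary_flags_unresponsive_cell(self):
        p = build_protocol(n_epochs=20)
        z = np.zeros(int(81 * FR))
        rec = evoked_summary(z, p, FR)
        assert rec["pct_stimuli_responded"] == 0.0
        assert np.isnan(rec["mean_peak_amp"])
        assert "no_responded_epochs" in rec["flag"]
        assert "adaptation_undefined" in rec["flag"]

    def test_extractor_matches_per_cell_function(self, small_fov_z, protocol):
        zs, _ = small_fov_z
        ext = EvokedResponseExtractor(protocol=protocol, frame_rate=7.8)
        df = ext.fit(zs.z).transform(zs.z)
        assert len(df) == zs.n_cells
        rec = evoked_summary(zs.z[0], protocol, 7.8)
        assert df.loc[0, "auc_mean_trace"] == pytest.approx(rec["auc_mean_trace"])
        long = ext.per_stimulus(zs.z)
        assert len(long) == zs.n_cells * 20
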