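"""Stimulus protocol rasterization and the scramble-bootstrap classifier."""

import numpy as np
import pytest

from stimlock import DegenerateTraceError, GeneratorConfig, ParameterError, \
    ProtocolError, ScrambleBootstrapClassifier, build_protocol, classify_cell, \
    classify_fov, scramble_z, simulate_fov
from stimlock.classify import null_cutoff_index, split_blocks
from stimlock.events import detect_epochs
from stimlock.zscoring import zscore_matrix


class TestProtocol:
    def test_onset_arithmetic(self):
        p = build_protocol(n_epochs=20, duration_s=1.0, isi_s=3.0, t_start=0.0)
        assert p.onsets_s[-1] == pytest.approx(76.0)
        assert p.n_epochs == 20 and p.end_s == pytest.approx(77.0)

    def test_rasterization_counts_frames_in_window(self):
        p = build_protocol(n_epochs=1, duration_s=1.0, isi_s=3.0, t_start=0.37)
        v = p.rasterize(n_frames=60, frame_rate=7.8)
        # oracle: count frames whose acquisition time lies in [onset, onset+1)
        t = np.arange(60) / 7.8
        expected = ((t >= 0.37) & (t < 1.37)).sum()
        assert v.sum() == expected
        assert expected in (7, 8)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ParameterError):
            build_protocol(n_epochs=0)

    def test_overlapping_epochs_rejected(self):
        from stimlock import StimulusProtocol
        with pytest.raises(ProtocolError):
            StimulusProtocol(onsets_s=np.array([0.0, 0.5]), duration_s=1.0)
        with pytest.raises(ProtocolError):
            StimulusProtocol(onsets_s=np.array([1.0, 1.0]), duration_s=0.5)


class TestScramble:
    def test_single_background_block_is_identity(self, rng):
        z = rng.normal(0, 1, 100)  # no epochs
        assert detect_epochs(z) == []
        out = scramble_z(z, [], rng)
        np.testing.assert_array_equal(out, z)

    def test_conservation_of_length_and_values(self, rng):
        for _ in range(50):
            z = rng.normal(0, 1, 300)
            z[40:60] += 8
            z[200:230] += 6
            epochs = detect_epochs(z)
            out = scramble_z(z, epochs, rng)
            assert out.size == z.size
            np.testing.assert_array_equal(np.sort(out), np.sort(z))

    @pytest.mark.parametrize("mode", ["block", "replace"])
    def test_epochs_survive_contiguously(self, rng, mode):
        z = rng.normal(0, 1, 400)
        z[50:80] += 10
        z[300:320] += 10
        epochs = detect_epochs(z)
        assert len(epochs) == 2
        for _ in range(30):
            out = scramble_z(z, epochs, rng, mode=mode)
            for s, e in epochs:
                segment = z[s:e]
                # substring search: the epoch's sample sequence appears intact
                found = any(np.array_equal(out[i:i + (e - s)], segment)
                            for i in range(out.size - (e - s) + 1))
                assert found

    def test_blocks_partition_the_vector(self, rng):
        z = rng.normal(0, 1, 200)
        z[20:40] += 9
        epochs = detect_epochs(z)
        blocks, is_epoch = split_blocks(z, epochs)
        np.testing.assert_array_equal(np.concatenate(blocks), z)
        assert sum(ep for ep in is_epoch) == len(epochs)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ParameterError):
            scramble_z(np.zeros(10), [], rng, mode="bogus")


class TestCutoffIndex:
    @pytest.mark.parametrize("n,alpha,expected", [
        (10_000, 0.01, 9899),   # ceil(0.99*10000) = 9900 -> 0-based 9899
        (2_000, 0.01, 1979),
        (1_000, 0.05, 949),
        (100, 0.01, 98),
    ])
    def test_top_quantile_order_statistic(self, n, alpha, expected):
        assert null_cutoff_index(n, alpha) == expected


class TestClassifyCell:
    def test_perfect_stimulus_copy_is_locked(self):
        p = build_protocol()
        stim = p.rasterize(640, 7.8).astype(float)
        z = stim * 10.0
        res = classify_cell(z, stim, n_scrambles=500, seed=1)
        assert res.observed_r == pytest.approx(1.0)
        assert res.null_cutoff < 1.0
        assert res.is_locked

    def test_constant_inputs_rejected(self):
        stim = np.zeros(100)
        stim[:10] = 1
        with pytest.raises(DegenerateTraceError):
            classify_cell(np.ones(100), stim, n_scrambles=500, seed=0)
        with pytest.raises(ProtocolError):
            classify_cell(np.random.default_rng(0).normal(size=100),
                          np.ones(100), n_scrambles=500, seed=0)

    def test_seed_determinism(self, rng):
        p = build_protocol()
        z = rng.normal(0, 1, 640)
        z[100:120] += 8
        stim = p.rasterize(640, 7.8)
        a = classify_cell(z, stim, n_scrambles=500, seed=7)
        b = classify_cell(z, stim, n_scrambles=500, seed=7)
        assert np.array_equal(a.null_r, b.null_r)
        assert a.is_locked == b.is_locked


class TestClassifyFov:
    def test_row_per_cell_with_degenerate_flags(self, protocol):
        traces, _ = simulate_fov(6, protocol, seed=21)
        zs = zscore_matrix(traces)
        z = zs.z.copy()
        z[2] = 0.0  # dead cell
        res = classify_fov(z, stim_vector=protocol.rasterize(z.shape[1], 7.8),
                           n_scrambles=200, seed=3)
        assert len(res) == 6
        assert res.loc[2, "flag"] == "degenerate"
        assert not res.loc[2, "is_locked"]
        assert (res.loc[res.flag == "", "observed_r"].notna()).all()

    def test_master_seed_gives_identical_verdicts(self, small_fov_z, protocol):
        zs, _ = small_fov_z
        a = classify_fov(zs, protocol=protocol, n_scrambles=300, seed=5)
        b = classify_fov(zs, protocol=protocol, n_scrambles=300, seed=5)
        assert a["is_locked"].tolist() == b["is_locked"].tolist()
        assert np.allclose(a["null_cutoff"], b["null_cutoff"])

    def test_strong_responders_detected_null_cells_not(self, protocol):
        strong = GeneratorConfig(frac_responsive=1.0, response_prob=0.9,
                                 evoked_amp_mean=0.8, noise_sd=0.05)
        traces, _ = simulate_fov(12, protocol, strong, seed=31)
        zs = zscore_matrix(traces)
        res = classify_fov(zs, protocol=protocol, n_scrambles=1000, seed=1)
        assert res["is_locked"].mean() >= 0.9
        null_cfg = GeneratorConfig(frac_responsive=0.0)
        traces0, _ = simulate_fov(12, protocol, null_cfg, seed=32)
        res0 = classify_fov(zscore_matrix(traces0), protocol=protocol,
                            n_scrambles=1000, seed=2)
        assert res0["is_locked"].sum() <= 1


class TestEstimator:
    def test_fit_attributes_and_predict_consistency(self, protocol):
        traces, _ = simulate_fov(8, protocol, seed=41)
        zs = zscore_matrix(traces)
        stim = protocol.rasterize(zs.n_frames, 7.8)
        clf = ScrambleBootstrapClassifier(stim_vector=stim, n_scrambles=300,
                                          random_state=0)
        labels = clf.fit_predict(zs.z)
        assert labels.dtype == bool and labels.shape == (8,)
        np.testing.assert_array_equal(labels, clf.predict(zs.z))
        assert clf.results_.shape[0] == 8
        assert set(clf.classes_) == {False, True}

    def test_sklearn_param_interface(self):
        clf = ScrambleBootstrapClassifier(n_scrambles=500, alpha=0.05)
        clf.set_params(alpha=0.01)
        assert clf.get_params()["alpha"] == 0.01
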