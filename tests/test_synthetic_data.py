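"""The synthetic pulsatile-video generator: determinism, monotone BP encoding,
signal-plant correctness, and dataset serialization."""

import json

import numpy as np
import pandas as pd
import pytest

from videobp.bpe_net import DBP_EDGES, SBP_EDGES
from videobp.roi_maps import compute_spatiotemporal_map
from videobp.synthetic_data import (
    PULSE_AMP_BASE,
    PULSE_AMP_PER_MMHG,
    SynthConfig,
    _draw_bp,
    generate_dataset,
    generate_pulse_waveform,
    render_subject,
    write_dataset,
)


class TestPulseWaveform:
    def test_equal_pressures_rejected(self):
        with pytest.raises(ValueError, match="sbp > dbp"):
            generate_pulse_waveform(100.0, 100.0, 72.0, 30.0, 15.0, seed=0)

    def test_non_positive_fps_or_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_pulse_waveform(120.0, 80.0, 72.0, 0.0, 15.0, seed=0)
        with pytest.raises(ValueError):
            generate_pulse_waveform(120.0, 80.0, 72.0, 30.0, -1.0, seed=0)

    def test_clip_must_span_two_heartbeats(self):
        with pytest.raises(ValueError, match="two heartbeats"):
            generate_pulse_waveform(120.0, 80.0, 60.0, 30.0, 1.5, seed=0)

    def test_same_seed_identical_series(self):
        a = generate_pulse_waveform(120.0, 80.0, 72.0, 30.0, 15.0, seed=5)
        b = generate_pulse_waveform(120.0, 80.0, 72.0, 30.0, 15.0, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_amplitude_affine_in_pulse_pressure(self):
        # the documented affine map evaluated at both operating points; fine
        # sampling so the discrete peak is the true waveform peak
        hi = generate_pulse_waveform(150.0, 70.0, 60.0, 600.0, 4.0, phase0=0.0)
        lo = generate_pulse_waveform(110.0, 70.0, 60.0, 600.0, 4.0, phase0=0.0)
        amp_hi, amp_lo = hi.max(), lo.max()
        assert amp_hi > amp_lo
        expected_ratio = (PULSE_AMP_BASE + PULSE_AMP_PER_MMHG * 80.0) / (PULSE_AMP_BASE + PULSE_AMP_PER_MMHG * 40.0)
        assert amp_hi / amp_lo == pytest.approx(expected_ratio, rel=1e-3)

    def test_periodic_at_heart_rate(self):
        fps, hr = 100.0, 75.0  # period exactly 80 samples
        w = generate_pulse_waveform(120.0, 80.0, hr, fps, 10.0, phase0=0.25)
        period = int(fps * 60.0 / hr)
        np.testing.assert_allclose(w[:period], w[period : 2 * period], atol=1e-9)

    def test_upstroke_fraction_decreases_with_sbp(self):
        # time from foot to peak, as a fraction of the cycle, at fine sampling
        fps, hr = 1000.0, 60.0
        fractions = []
        for sbp in (95.0, 120.0, 150.0):
            w = generate_pulse_waveform(sbp, 70.0, hr, fps, 4.0, phase0=0.0)
            cycle = w[:1000]
            fractions.append(np.argmax(cycle) / 1000.0)
        assert fractions[0] > fractions[1] > fractions[2]


class TestRenderSubject:
    def test_noise_free_traces_equal_baseline_plus_waveform(self):
        cfg = SynthConfig(n_subjects=1, noise_sd=0.0, illumination_drift_amp=0.0, seed=4, render=True)
        s = render_subject(cfg, 0)
        recomputed = compute_spatiotemporal_map(s.frames, s.roi_masks)
        np.testing.assert_allclose(recomputed.values, s.roi_traces, atol=1e-9)
        # forehead green channel: baseline + perfusion * gain * pulse exactly
        from videobp.synthetic_data import CHANNEL_GAIN, ROI_BASELINE, ROI_PERFUSION

        pulse = (s.roi_traces[0, :, 1] - ROI_BASELINE[0, 1]) / (ROI_PERFUSION[0] * CHANNEL_GAIN[1])
        # same shape up to the per-subject phase: the sampled peak sits within
        # one frame of the true peak, so the amplitude matches to ~1%
        assert pulse.max() == pytest.approx(PULSE_AMP_BASE + PULSE_AMP_PER_MMHG * (s.sbp - s.dbp), rel=0.02)
        assert pulse.min() >= -1e-9

    def test_rendered_and_fast_mode_share_labels(self):
        fast = render_subject(SynthConfig(n_subjects=2, seed=9), 1)
        rendered = render_subject(SynthConfig(n_subjects=2, seed=9, render=True), 1)
        assert fast.sbp == rendered.sbp
        assert fast.dbp == rendered.dbp
        assert fast.heart_rate == rendered.heart_rate

    def test_signal_plant_zero_noise_fast_mode_map_recovery(self):
        cfg = SynthConfig(n_subjects=1, noise_sd=0.0, seed=2)
        s = render_subject(cfg, 0)
        m = s.stmap()
        assert m.values.shape == (4, cfg.n_frames, 3)
        assert m.channel_space == "RGB"

    def test_different_seeds_different_bp(self):
        a = render_subject(SynthConfig(n_subjects=1, seed=1), 0)
        b = render_subject(SynthConfig(n_subjects=1, seed=2), 0)
        assert (a.sbp, a.dbp) != (b.sbp, b.dbp)

    def test_identical_config_bit_identical(self):
        cfg = SynthConfig(n_subjects=1, seed=3, render=True)
        a = render_subject(cfg, 0)
        b = render_subject(cfg, 0)
        np.testing.assert_array_equal(a.frames.pixels, b.frames.pixels)
        np.testing.assert_array_equal(a.roi_traces, b.roi_traces)

    def test_labels_inside_clinical_spans(self):
        for s in generate_dataset(SynthConfig(n_subjects=50, seed=7)):
            assert SBP_EDGES[0] <= s.sbp <= SBP_EDGES[-1]
            assert DBP_EDGES[0] <= s.dbp <= DBP_EDGES[-1]
            assert s.sbp > s.dbp
            assert 60.0 <= s.heart_rate <= 100.0

    def test_frame_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            render_subject(SynthConfig(n_subjects=1, frame_size=(16, 16), seed=0, render=True), 0)

    def test_group_frequencies_match_weights_within_3_binomial_sd(self):
        cfg = SynthConfig(n_subjects=1, seed=123)
        rng = np.random.default_rng(123)
        n = 2000
        sbp_groups = np.zeros(4, dtype=int)
        dbp_groups = np.zeros(4, dtype=int)
        for _ in range(n):
            sbp, dbp = _draw_bp(rng, cfg)
            sbp_groups[np.searchsorted(SBP_EDGES, sbp, side="right") - 1] += 1
            dbp_groups[np.searchsorted(DBP_EDGES, dbp, side="right") - 1] += 1
        for counts, weights in ((sbp_groups, cfg.sbp_group_weights), (dbp_groups, cfg.dbp_group_weights)):
            w = np.asarray(weights) / sum(weights)
            for k in range(4):
                sd = np.sqrt(n * w[k] * (1 - w[k]))
                assert abs(counts[k] - n * w[k]) <= 3 * sd, f"group {k}: {counts[k]} vs {n * w[k]:.0f}"


class TestWriteDataset:
    def test_three_subjects_three_label_rows(self, tmp_path):
        subjects = generate_dataset(SynthConfig(n_subjects=3, seed=0, duration_s=5.0))
        manifest_path = write_dataset(subjects, tmp_path / "ds")
        labels = pd.read_csv(tmp_path / "ds" / "labels.csv")
        assert len(labels) == 3
        assert list(labels.columns) == ["subject_id", "sbp", "dbp"]

    def test_round_trip_of_rendered_frames(self, tmp_path):
        subjects = generate_dataset(SynthConfig(n_subjects=1, seed=1, duration_s=2.0, render=True))
        write_dataset(subjects, tmp_path / "ds")
        with np.load(tmp_path / "ds" / "synth0000_frames.npz") as z:
            np.testing.assert_array_equal(z["pixels"], subjects[0].frames.pixels)

    def test_manifest_paths_exist(self, tmp_path):
        subjects = generate_dataset(SynthConfig(n_subjects=2, seed=2, duration_s=2.0, render=True))
        manifest_path = write_dataset(subjects, tmp_path / "ds")
        manifest = json.loads(manifest_path.read_text())
        assert (tmp_path / "ds" / manifest["labels"]).exists()
        for entry in manifest["subjects"].values():
            for rel in entry.values():
                assert (tmp_path / "ds" / rel).exists()
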