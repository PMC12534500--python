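"""Synthetic-study generator: determinism, calibration, injected effects."""
import dataclasses
import io

import numpy as np
import pytest

import ctbseeg as c
from ctbseeg.errors import ValidationError
from ctbseeg.simulate import DEFAULT_STAGE_GAINS


class TestConfigValidation:
    def test_ramp_must_start_at_one(self):
        with pytest.raises(ValidationError, match="active_effect_ramp"):
            c.SimConfig(active_effect_ramp=(1.1, 1.1, 1.1, 1.1, 1.1, 1.1))

    def test_ramp_must_be_nondecreasing(self):
        with pytest.raises(ValidationError, match="non-decreasing"):
            c.SimConfig(active_effect_ramp=(1.0, 1.2, 1.1, 1.2, 1.2, 1.3))

    def test_coupling_strength_bounds(self):
        with pytest.raises(ValidationError, match="coupling"):
            c.SimConfig(coupling_pairs=(("F4", "O1", "theta", 1.5),))

    def test_band_power_positive(self):
        with pytest.raises(ValidationError, match="positive"):
            c.SimConfig(band_power_baseline={"delta": -1.0})

    def test_sfreq_covers_highest_band(self):
        with pytest.raises(ValidationError, match="sfreq_sleep"):
            c.SimConfig(sfreq_sleep=100.0)

    def test_invalid_arm_and_timepoint_named(self):
        cfg = c.SimConfig(n_subjects=1, wake_duration=5.0)
        with pytest.raises(ValidationError, match="arm"):
            c.simulate_wake_recording(cfg, 0, "placebo", "T1")
        with pytest.raises(ValidationError, match="timepoint"):
            c.simulate_wake_recording(cfg, 0, "active", "T7")


class TestDeterminism:
    def test_wake_bit_identical_and_serialized(self, noisy_cfg, tmp_path):
        r1, g1 = c.simulate_wake_recording(noisy_cfg, 1, "active", "T3")
        r2, g2 = c.simulate_wake_recording(noisy_cfg, 1, "active", "T3")
        np.testing.assert_array_equal(r1.data, r2.data)
        assert g1.artifact_epochs == g2.artifact_epochs
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        c.write_delimited(r1, p1)
        c.write_delimited(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sleep_bit_identical(self, sleep_cfg):
        r1, h1, _ = c.simulate_sleep_night(sleep_cfg, 0, "active")
        r2, h2, _ = c.simulate_sleep_night(sleep_cfg, 0, "active")
        assert h1 == h2
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_substreams_differ_across_context(self, noisy_cfg):
        r1, _ = c.simulate_wake_recording(noisy_cfg, 0, "active", "T1")
        r2, _ = c.simulate_wake_recording(noisy_cfg, 0, "sham", "T1")
        r3, _ = c.simulate_wake_recording(noisy_cfg, 1, "active", "T1")
        assert not np.array_equal(r1.data, r2.data)
        assert not np.array_equal(r1.data, r3.data)


class TestPowerCalibration:
    def test_welch_recovers_configured_band_power(self):
        """Artifact-free, coupling-free, 300 s: measured Welch band power
        matches the configured level within 10 % on every channel."""
        cfg = c.SimConfig(n_subjects=1, wake_duration=300.0,
                          channel_set=("F4", "Cz", "O1"),
                          artifact_rate=0.0, line_noise_amplitude=0.0,
                          coupling_pairs=(), subject_effect_sd=0.0,
                          baseline_power_sd=0.0, seed=17)
        rec, gt = c.simulate_wake_recording(cfg, 0, "sham", "T1")
        es = c.segment_and_reject(rec, 5.0)
        bp = c.band_power_from_epochs(es)
        for ch in cfg.channel_set:
            for band, target in cfg.band_power_baseline.items():
                measured = bp.value(ch, band)
                assert measured == pytest.approx(target, rel=0.10), (ch, band)

    def test_flat_ramp_arms_share_true_band_power(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg,
                                  active_effect_ramp=(1.0,) * 6)
        _, g_active = c.simulate_wake_recording(cfg, 0, "active", "T4")
        _, g_sham = c.simulate_wake_recording(cfg, 0, "sham", "T4")
        assert g_active.band_power == g_sham.band_power

    def test_active_ramp_scales_effect_bands_only(self, clean_cfg):
        _, gt = c.simulate_wake_recording(clean_cfg, 0, "active", "T6")
        base = clean_cfg.band_power_baseline
        assert gt.band_power["F4"]["theta"] == pytest.approx(1.3 * base["theta"])
        assert gt.band_power["F4"]["delta"] == pytest.approx(1.3 * base["delta"])
        assert gt.band_power["F4"]["alpha"] == pytest.approx(base["alpha"])


class TestArtifactsAndLineNoise:
    def test_clean_config_stays_under_threshold(self, clean_cfg):
        rec, gt = c.simulate_wake_recording(clean_cfg, 0, "sham", "T1")
        assert gt.artifact_epochs == []
        es = c.segment_and_reject(rec, 5.0)
        assert es.rejected_indices == []
        # 50 Hz power indistinguishable from broadband background
        f, psd = c.welch_psd(es)
        bin50 = np.argmin(np.abs(f - 50.0))
        neighborhood = psd[:, bin50 - 10:bin50 + 10].mean()
        assert psd[:, bin50].mean() < 3 * neighborhood

    def test_line_noise_visible_then_notched(self, noisy_cfg):
        rec, _ = c.simulate_wake_recording(noisy_cfg, 0, "sham", "T1")
        raw_es = c.segment_and_reject(rec, 5.0, threshold=1e12)
        f, psd_raw = c.welch_psd(raw_es)
        bin50 = np.argmin(np.abs(f - 50.0))
        assert psd_raw[:, bin50].mean() > 10 * psd_raw[:, bin50 - 15].mean()
        filt_es = c.segment_and_reject(c.preprocess_wake(rec), 5.0,
                                       threshold=1e12)
        _, psd_filt = c.welch_psd(filt_es)
        assert psd_filt[:, bin50].mean() < psd_raw[:, bin50].mean() / 100

    def test_ground_truth_artifacts_rejected_after_preprocessing(self, noisy_cfg):
        """Every injected ±150 μV pulse epoch survives the filter chain
        above the ±100 μV rule and is rejected."""
        for subject in range(2):
            rec, gt = c.simulate_wake_recording(noisy_cfg, subject, "sham", "T2")
            assert gt.artifact_epochs  # rate 3/min for 2 min: virtually sure
            es = c.segment_and_reject(c.preprocess_wake(rec), 5.0)
            assert set(gt.artifact_epochs) <= set(es.rejected_indices)


class TestSleepNight:
    def test_forced_hypnogram_used_verbatim(self, sleep_cfg):
        forced = ["W"] * 10 + ["N2"] * 40 + ["R"] * 12
        cfg = dataclasses.replace(sleep_cfg, sleep_duration_minutes=31.0)
        rec, hyp, gt = c.simulate_sleep_night(cfg, 0, "sham", hypnogram=forced)
        assert hyp == forced
        assert gt.hypnogram == forced
        assert rec.n_samples == len(forced) * int(30 * cfg.sfreq_sleep)

    def test_generated_hypnogram_structure(self, sleep_cfg):
        _, hyp, _ = c.simulate_sleep_night(sleep_cfg, 0, "active")
        assert hyp[0] == "W"
        assert set(hyp) <= {"W", "N1", "N2", "N3", "R"}
        # first NREM run spans >= 15 min before the first REM epoch
        first_r = hyp.index("R")
        nrem_before = sum(s in ("N1", "N2", "N3") for s in hyp[:first_r])
        assert nrem_before >= 30

    def test_stage_delta_power_ordering(self, sleep_cfg):
        _, _, gt = c.simulate_sleep_night(sleep_cfg, 0, "sham")
        d = {s: gt.stage_band_power[s]["delta"] for s in gt.stage_band_power}
        assert d["N3"] > d["N2"] > d["N1"] > max(d["R"], d["W"])

    def test_stage_gains_realized_in_signal(self):
        """N3 epochs carry ~10x the wake delta PSD (the default gain)."""
        cfg = c.SimConfig(n_subjects=1, artifact_rate=0.0,
                          line_noise_amplitude=0.0,
                          subject_effect_sd=0.0, baseline_power_sd=0.0,
                          sleep_duration_minutes=40.0, seed=19)
        forced = ["W"] * 20 + ["N3"] * 60
        rec, hyp, gt = c.simulate_sleep_night(cfg, 0, "sham", hypnogram=forced)
        n_per = int(30 * cfg.sfreq_sleep)
        wake = c.Recording(rec.data[:, : 20 * n_per], rec.channel_names,
                           rec.sfreq)
        n3 = c.Recording(rec.data[:, 20 * n_per:], rec.channel_names,
                         rec.sfreq)
        bp_w = c.band_power_from_epochs(c.segment_and_reject(wake, 30.0,
                                                             threshold=1e12))
        bp_n3 = c.band_power_from_epochs(c.segment_and_reject(n3, 30.0,
                                                              threshold=1e12))
        ratio = bp_n3.value("F4", "delta") / bp_w.value("F4", "delta")
        assert ratio == pytest.approx(10.0, rel=0.25)
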