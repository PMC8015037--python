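"""Generator properties: determinism, geometry, injected ground truth."""

import numpy as np
import pytest

from cranioppg import ppg
from cranioppg.synth import (
    ExperimentDesign,
    HemoDynamicsSpec,
    TrialProtocol,
    build_schedule,
    cardiac_template,
    generate_rpeak_times,
    make_tissue,
    simulate_experiment,
    simulate_trial,
    synthesize_ecg,
)
from cranioppg.synth.kinetics import apc_gain_profile, cardiac_phase

from conftest import short_protocol


class TestTissue:
    def test_deterministic_for_fixed_seed(self):
        a = make_tissue(seed=1, height_px=120, width_px=188)
        b = make_tissue(seed=1, height_px=120, width_px=188)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert np.array_equal(a.baseline_intensity, b.baseline_intensity)

    def test_different_seeds_differ(self):
        a = make_tissue(seed=1, height_px=120, width_px=188)
        b = make_tissue(seed=2, height_px=120, width_px=188)
        assert not np.array_equal(a.vessel_mask, b.vessel_mask)

    def test_vessel_construction(self, tissue):
        artery_frac = (tissue.vessel_mask == 1).mean()
        assert 0 < artery_frac < 0.5
        assert (tissue.vessel_mask == 2).any()  # at least one vein
        # electrodes sit adjacent to an artery
        ey, ex = tissue.electrode_center
        ys, xs = np.nonzero(tissue.vessel_mask == 1)
        assert np.hypot(ys - ey, xs - ex).min() < 10

    def test_rejects_small_field(self):
        with pytest.raises(ValueError):
            make_tissue(seed=1, height_px=30, width_px=30)

    def test_baseline_on_ten_bit_scale(self, tissue):
        assert tissue.baseline_intensity.min() >= 0
        assert tissue.baseline_intensity.max() <= 1023


class TestCardiacModel:
    def test_template_normalization(self):
        phi = np.linspace(0, 1, 20001, endpoint=False)
        c = cardiac_template(phi)
        assert np.max(c) - np.min(c) == pytest.approx(1.0, abs=1e-6)
        assert np.mean(c) == pytest.approx(0.0, abs=1e-4)

    def test_rpeak_count_matches_rate(self):
        hemo = HemoDynamicsSpec(hr_variability=0.0, hr_dip_frac=0.0)
        rng = np.random.default_rng(0)
        peaks = generate_rpeak_times(120.0, hemo, TrialProtocol(), rng)
        expected = int(120 * 413 / 60)
        assert abs(peaks.size - expected) <= 1

    def test_rpeaks_strictly_increasing_with_jitter(self):
        hemo = HemoDynamicsSpec(hr_variability=0.05)
        rng = np.random.default_rng(3)
        peaks = generate_rpeak_times(60.0, hemo, TrialProtocol(), rng)
        assert (np.diff(peaks) > 0).all()


class TestTrialVideo:
    def test_deterministic(self, tissue):
        hemo = HemoDynamicsSpec()
        a = simulate_trial(tissue, hemo, short_protocol(), seed=5)
        b = simulate_trial(tissue, hemo, short_protocol(), seed=5)
        assert np.array_equal(a.video.frames, b.video.frames)
        assert np.array_equal(a.ecg.values, b.ecg.values)
        assert np.array_equal(a.rpeaks.times_s, b.rpeaks.times_s)

    def test_null_trial_slow_factor_constant(self, quiet_trial):
        gt = quiet_trial.ground_truth
        assert np.all(gt.volume_factor == 1.0)
        assert np.all(gt.apc_gain == 1.0)
        # frames identical up to cardiac modulation: every frame within
        # baseline * (1 +- artery pulsatility / 2)
        base = quiet_trial.tissue.baseline_intensity
        dev = np.abs(quiet_trial.video.frames - base[None]) / base[None]
        assert dev.max() <= quiet_trial.tissue.artery_pulsatility * 0.5 + 1e-6

    def test_injected_apc_is_a_times_g(self, stim_trial):
        gt = stim_trial.ground_truth
        g = apc_gain_profile(gt.t_s, stim_trial.protocol, stim_trial.hemo)
        a = stim_trial.tissue.artery_pulsatility
        assert np.allclose(gt.injected_apc[1], a * g)

    def test_conservation_over_ten_cycles(self, quiet_trial):
        """Temporal mean over an exact 10-cycle window returns the baseline
        image up to the discrete cardiac-sampling residue."""
        video, rp = quiet_trial.video, quiet_trial.rpeaks.times_s
        fps = video.frame_rate_hz
        i0, i1 = int(np.ceil(rp[5] * fps)), int(np.ceil(rp[15] * fps))
        mean_img = video.frames[i0:i1].mean(axis=0)
        base = quiet_trial.tissue.baseline_intensity
        ac_amp = quiet_trial.tissue.pulsatility_map * base
        tol = 0.05 * ac_amp + 3.0 * quiet_trial.hemo.noise_sd_counts / np.sqrt(i1 - i0)
        assert np.all(np.abs(mean_img - base) <= tol + 1e-6)

    def test_phase_locking(self, quiet_trial):
        """Pixel AC cross-correlates with the injected cardiac waveform at
        zero lag (+- 1 frame)."""
        video = quiet_trial.video
        t = video.times_s
        injected = cardiac_template(cardiac_phase(t, quiet_trial.rpeaks.times_s))
        ys, xs = np.nonzero(quiet_trial.tissue.vessel_mask == 1)
        px = video.frames[:, ys[0], xs[0]].astype(float)
        ac = px - np.mean(px)
        inj = injected - injected.mean()
        lags = np.arange(-5, 6)
        cc = [np.dot(np.roll(inj, k), ac) for k in lags]
        assert abs(lags[int(np.argmax(cc))]) <= 1

    def test_clipping_is_counted(self, tissue):
        hemo = HemoDynamicsSpec(noise_sd_counts=0.0, motion_amplitude_px=0.0)
        bright = make_tissue(seed=1, height_px=96, width_px=96, mean_counts=1021.0)
        rec = simulate_trial(bright, hemo, short_protocol(post_s=2.0, stim_s=2.0, pre_s=2.0), seed=1)
        assert rec.ground_truth.clipped_pixels > 0
        assert rec.video.frames.max() <= 1023

    def test_ecg_video_clock_alignment(self, stim_trial):
        # R-peaks land on the 1 kHz ECG grid: offset to the grid <= 0.5 ms
        rp = stim_trial.rpeaks.times_s
        snapped = np.round(rp * 1000.0) / 1000.0
        assert np.abs(rp - snapped).max() <= 5e-4


class TestECG:
    def test_detection_recovers_ground_truth(self):
        hemo = HemoDynamicsSpec(hr_variability=0.02, hr_dip_frac=0.0)
        rng = np.random.default_rng(11)
        peaks = generate_rpeak_times(60.0, hemo, TrialProtocol(), rng)
        ecg = synthesize_ecg(peaks, 60.0, rng=rng)
        detected = ppg.detect_rpeaks(ecg)
        assert abs(detected.n_peaks - peaks.size) <= 2

    def test_missing_beat_flagged(self):
        hemo = HemoDynamicsSpec(hr_variability=0.0, hr_dip_frac=0.0)
        rng = np.random.default_rng(1)
        peaks = generate_rpeak_times(30.0, hemo, TrialProtocol(), rng)
        gapped = np.delete(peaks, 100)
        ecg = synthesize_ecg(gapped, 30.0, rng=rng)
        detected = ppg.detect_rpeaks(ecg)
        rr = detected.rr_intervals_s
        assert detected.gap_indices.size >= 1
        assert rr[detected.gap_indices[0]] == pytest.approx(2 * np.median(rr), rel=0.2)

    def test_flat_ecg_yields_empty_series(self):
        from cranioppg.datatypes import SampledTrace
        flat = SampledTrace(values=np.zeros(5000), rate_hz=1000.0)
        assert ppg.detect_rpeaks(flat).n_peaks == 0


class TestExperiment:
    def test_printed_design_has_384_trials(self):
        schedule = build_schedule(ExperimentDesign())
        assert len(schedule) == 384
        per_animal = schedule.groupby("animal").size()
        assert (per_animal == 12).all()

    def test_schedule_spacing(self):
        schedule = build_schedule(ExperimentDesign())
        one = schedule[schedule["animal"] == schedule["animal"].iloc[0]]
        trials = one[one["stage"] == 0]["t_start_min"].to_numpy()
        assert np.allclose(np.diff(trials), 10.0)
        firsts = one.groupby("stage")["t_start_min"].min().to_numpy()
        assert np.allclose(np.diff(firsts), 30.0)

    def test_saline_multiplier_is_pure_drift(self):
        design = ExperimentDesign()
        for stage in (1, 2, 3):
            apc_mult, _ = design.stage_multipliers("saline", stage)
            assert apc_mult == pytest.approx(design.drift_per_step ** stage)

    def test_sumatriptan_ground_truth_monotone_decreasing(self):
        design = ExperimentDesign(drift_per_step=1.0)
        ds = simulate_experiment(design, seed=3)
        gt = ds.ground_truth
        suma = gt[gt["group"] == "sumatriptan"]
        means = suma.groupby("stage")["apc_gain_excess"].mean()
        assert (np.diff(means[[1, 2, 3]]) < 0).all()

    def test_experiment_deterministic(self):
        a = simulate_experiment(seed=9)
        b = simulate_experiment(seed=9)
        k = next(iter(a.traces))
        assert np.array_equal(a.traces[k]["APC"].values, b.traces[k]["APC"].values)
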