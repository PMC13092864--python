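"""Generators: closed-form agreement, Monte-Carlo means, determinism."""

import dataclasses

import numpy as np
import pytest

from tpmreg.synthetic import (
    HillTruth,
    ImageTruth,
    TrackTruth,
    WaveEventParams,
    gen_dose_response,
    gen_labeled_image,
    gen_tracks,
    gen_wave_trace,
    rise_profile,
    wave_roi_model,
)
from tpmreg.tracks import summarize_speeds


def quiet_params(**kw):
    base = dict(seed=0, noise_sd=0.0, bleach_rate=0.0)
    base.update(kw)
    return WaveEventParams(**base)


class TestWaveGenerator:
    def test_rise_profile_anchors(self):
        assert rise_profile(0.0) == 0.0
        assert rise_profile(-2.0) == 0.0
        assert rise_profile(3.0) == pytest.approx(0.95, abs=1e-12)

    def test_baseline_exact_before_onset(self):
        p = quiet_params()
        ts = gen_wave_trace(p)
        pre = ts.times < p.t_onset
        assert np.array_equal(ts.roi["actin"][pre],
                              np.full(pre.sum(), p.baseline_actin))

    def test_plateau_value_with_bleach(self):
        # long plateau: midway between rise completion and dispersal onset
        p = quiet_params(bleach_rate=0.002, t_onset=100.0, t_offset=700.0,
                         rise_tau=10.0, duration=900.0)
        ts = gen_wave_trace(p)
        t_mid = 450.0  # >> t_onset + 3 tau, < t_offset
        i = int(np.argmin(np.abs(ts.times - t_mid)))
        expected = (p.baseline_actin + p.plateau_actin) * np.exp(
            -p.bleach_rate * ts.times[i]
        )
        assert ts.roi["actin"][i] == pytest.approx(expected, rel=1e-6)

    def test_monte_carlo_mean_matches_model(self):
        p = WaveEventParams(seed=0, noise_sd=50.0, baseline_actin=1000.0)
        t_probe = 300.0  # on the wave plateau, far from the clip at zero
        vals = []
        for seed in range(200):
            ts = gen_wave_trace(dataclasses.replace(p, seed=seed))
            i = int(np.argmin(np.abs(ts.times - t_probe)))
            vals.append(ts.roi["actin"][i])
        model = wave_roi_model(p, np.array([t_probe]), "actin")[0]
        assert abs(np.mean(vals) - model) < 3 * p.noise_sd / np.sqrt(200)

    def test_same_seed_bitwise_identical(self):
        a = gen_wave_trace(WaveEventParams(seed=7))
        b = gen_wave_trace(WaveEventParams(seed=7))
        assert np.array_equal(a.roi["tpm"], b.roi["tpm"])
        assert np.array_equal(a.field["actin"], b.field["actin"])

    @pytest.mark.parametrize(
        "bad, msg",
        [
            (dict(rise_tau=-1.0), "rise_tau"),
            (dict(noise_sd=-0.1), "noise_sd"),
            (dict(t_onset=500.0, t_offset=400.0), "t_onset < t_offset"),
            (dict(frame_interval=0.0), "frame_interval"),
        ],
    )
    def test_invalid_params_name_the_invariant(self, bad, msg):
        with pytest.raises(ValueError, match=msg):
            gen_wave_trace(WaveEventParams(seed=0, **bad))


class TestDoseGenerator:
    def test_midpoint_and_control(self):
        for h in (0.7, 1.0, 4.0, 9.0):
            truth = HillTruth(seed=0, ic50=1.3, hill_coeff=h, noise_sd=0.0)
            tab = gen_dose_response(truth, [0.0, 1.3], replicates=1)
            by_conc = tab.data.set_index("conc_uM")["response"]
            assert by_conc[0.0] == 1.0  # top exactly at zero concentration
            assert by_conc[1.3] == pytest.approx(0.5, abs=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            gen_dose_response(HillTruth(seed=0, ic50=1.0), [-1.0, 1.0])

    def test_seed_reproducible(self):
        t = HillTruth(seed=5, ic50=2.0)
        a = gen_dose_response(t, [0.5, 1, 2, 4], 3)
        b = gen_dose_response(t, [0.5, 1, 2, 4], 3)
        assert a.data.equals(b.data)


class TestTrackGenerator:
    def test_exact_spacing_without_jitter(self):
        t = TrackTruth(seed=0, speed=500.0, step_jitter_sd=0.0,
                       n_filaments=3, n_frames=5, frame_interval=1.0)
        for track in gen_tracks(t):
            steps = np.hypot(np.diff(track.x), np.diff(track.y))
            assert steps == pytest.approx(np.full(4, 500.0), rel=1e-12)

    def test_stationary_track(self):
        t = TrackTruth(seed=0, speed=0.0, step_jitter_sd=0.0,
                       n_filaments=1, n_frames=4)
        track = gen_tracks(t).tracks[0]
        assert np.ptp(track.x) == 0.0 and np.ptp(track.y) == 0.0

    def test_speed_recovery_within_2se(self):
        t = TrackTruth(seed=11, speed=600.0, step_jitter_sd=15.0,
                       n_filaments=100, n_frames=30)
        summary = summarize_speeds(gen_tracks(t), motile_threshold=50.0)
        se = summary.sd_speed / np.sqrt(summary.n_tracks)
        # path-length speeds carry a small positive jitter bias; the
        # Rice-mean expectation accounts for it exactly
        from helpers import rice_mean

        expected = rice_mean(t.speed * t.frame_interval, t.step_jitter_sd)
        assert abs(summary.mean_speed - expected) < 2 * se


class TestImageGenerator:
    def test_no_enrichment_means_match(self):
        truth = ImageTruth(seed=3, enrichment_factor=1.0, background_sd=5.0)
        img = gen_labeled_image(truth)
        mask = img.ground_truth["blob_mask"]
        inside = img.channels["measure"][mask]
        outside = img.channels["measure"][~mask]
        se = truth.background_sd * np.sqrt(1 / inside.size + 1 / outside.size)
        assert abs(inside.mean() - outside.mean()) < 3 * se

    def test_noise_free_ratio_exact(self):
        truth = ImageTruth(seed=1, enrichment_factor=2.0, background_sd=0.0)
        img = gen_labeled_image(truth)
        mask = img.ground_truth["blob_mask"]
        ratio = img.channels["measure"][mask].mean() / \
            img.channels["measure"][~mask].mean()
        assert ratio == pytest.approx(2.0, abs=1e-12)

    def test_same_seed_bit_identical(self):
        truth = ImageTruth(seed=9, background_sd=8.0,
                           filament_segments=(((10, 10), (10, 100)),))
        a, b = gen_labeled_image(truth), gen_labeled_image(truth)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_out_of_bounds_segment_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gen_labeled_image(ImageTruth(
                seed=0, filament_segments=(((10, 10), (10, 400)),)
            ))
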