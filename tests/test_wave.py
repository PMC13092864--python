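"""Wave-trace pipeline: bleach correction, onset detection, normalization,
ensemble alignment, significance windows."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tpmreg.synthetic import (
    WaveEventParams,
    gen_wave_trace,
    simulate_wave_ensemble,
    wave_roi_model,
)
from tpmreg.wave import (
    AlignedEnsemble,
    GridMismatchError,
    NormalizedTrace,
    WaveDetectionError,
    WaveTraceSet,
    align_ensemble,
    analyze_wave_pair,
    correct_photobleach,
    detect_inflection,
    normalize_trace,
    significance_windows,
)


def make_trace_set(roi_actin, field_actin=None, times=None):
    n = len(roi_actin)
    times = np.arange(n) if times is None else times
    field_actin = np.full(n, 100.0) if field_actin is None else field_actin
    return WaveTraceSet(
        times=times,
        roi={"actin": np.asarray(roi_actin, float), "tpm": np.asarray(roi_actin, float)},
        field={"actin": np.asarray(field_actin, float),
               "tpm": np.asarray(field_actin, float)},
    )


class TestPhotobleachCorrection:
    def test_constant_field_leaves_roi_unchanged(self):
        ts = make_trace_set([5.0, 6.0, 7.0, 8.0])
        out = correct_photobleach(ts)
        assert np.array_equal(out.roi["actin"], ts.roi["actin"])

    def test_shared_exponential_cancels_exactly(self):
        t = np.arange(20.0)
        lam = 0.03
        ts = make_trace_set(40.0 * np.exp(-lam * t), 500.0 * np.exp(-lam * t), t)
        out = correct_photobleach(ts)
        assert out.roi["actin"] == pytest.approx(np.full(20, 40.0), rel=1e-12)

    def test_inverts_generator_bleach_term(self):
        p = WaveEventParams(seed=0, noise_sd=0.0, bleach_rate=0.004)
        corrected = correct_photobleach(gen_wave_trace(p))
        unbleached = wave_roi_model(p, corrected.times, "tpm", bleached=False)
        assert np.max(np.abs(corrected.roi["tpm"] / unbleached - 1.0)) < 1e-9

    def test_nonpositive_field_names_frame(self):
        f = np.full(10, 50.0)
        f[4] = 0.0
        ts = make_trace_set(np.ones(10), f)
        with pytest.raises(ValueError, match="frame 4"):
            correct_photobleach(ts)


class TestInflectionDetection:
    def test_step_series_returns_last_prestep_frame(self):
        assert detect_inflection([1, 1, 1, 5, 5, 5], baseline_window=3) == 2

    def test_flat_series_raises(self):
        with pytest.raises(WaveDetectionError, match="no wave"):
            detect_inflection(np.ones(30), baseline_window=10)

    def test_noise_free_logistic_close_to_onset(self):
        p = WaveEventParams(seed=0, noise_sd=0.0)
        ts = gen_wave_trace(p)
        idx = detect_inflection(ts.roi["actin"])
        onset_frame = p.t_onset / p.frame_interval
        assert abs(idx - onset_frame) <= 2


class TestNormalization:
    def test_anchors_zero_and_one(self):
        p = WaveEventParams(seed=0, noise_sd=0.0)
        ts = gen_wave_trace(p)
        idx = detect_inflection(ts.roi["actin"])
        tr = normalize_trace(ts.roi["actin"], ts.times, idx)
        assert tr.values[tr.inflection_index] == 0.0
        lo, hi = tr.plateau_window
        assert tr.values[lo:hi].mean() == pytest.approx(1.0, abs=1e-9)
        assert tr.times_rel[tr.inflection_index] == 0.0

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_positive_affine_invariance(self, a, b):
        p = WaveEventParams(seed=3, noise_sd=0.0)
        ts = gen_wave_trace(p)
        idx = detect_inflection(ts.roi["actin"])
        base = normalize_trace(ts.roi["actin"], ts.times, idx)
        mapped = normalize_trace(a * ts.roi["actin"] + b, ts.times, idx)
        assert mapped.values == pytest.approx(base.values, abs=1e-9)

    def test_no_amplitude_rejected(self):
        falling = np.linspace(10.0, 1.0, 30)
        with pytest.raises(ValueError, match="amplitude"):
            normalize_trace(falling, np.arange(30.0), 5)


def norm_trace(values, inflection=0, dt=1.0):
    values = np.asarray(values, float)
    return NormalizedTrace(
        times_rel=(np.arange(values.size) - inflection) * dt,
        values=values,
        inflection_index=inflection,
        plateau_value_raw=1.0,
        plateau_window=(0, values.size),
    )


class TestEnsembleAlignment:
    def test_single_trace_convention(self):
        with pytest.warns(UserWarning, match="single-trace"):
            ens = align_ensemble([norm_trace([0.0, 0.5, 1.0])])
        assert np.array_equal(ens.mean, [0.0, 0.5, 1.0])
        assert np.array_equal(ens.sd, np.zeros(3))
        assert np.array_equal(ens.n, [1, 1, 1])

    def test_identical_traces_with_different_onsets_align(self):
        a = norm_trace([0.0, 1.0, 0.5, 0.2], inflection=0)
        b = norm_trace([9.9, 0.0, 1.0, 0.5, 0.2], inflection=1)
        ens = align_ensemble([a, b])
        shared = ens.n == 2
        assert np.allclose(ens.sd[shared], 0.0)

    def test_mixed_frame_intervals_rejected(self):
        with pytest.raises(GridMismatchError):
            align_ensemble([norm_trace([0, 1, 1], dt=1.0),
                            norm_trace([0, 1, 1], dt=2.0)])

    def test_ensemble_mean_tracks_noise_free_model(self):
        # averaging property in isolation: replicates share the true onset
        # and are normalized by the true affine map, so the ensemble mean
        # should approach the noise-free normalized model pointwise
        n_rep = 20
        base = WaveEventParams(seed=0, bleach_rate=0.0)
        k0 = int(base.t_onset / base.frame_interval)
        clean = wave_roi_model(base, gen_wave_trace(base).times, "actin")
        normed = []
        for i in range(n_rep):
            noisy = gen_wave_trace(dataclasses.replace(base, seed=100 + i))
            normed.append(norm_trace(
                (noisy.roi["actin"] - clean[k0]) / base.plateau_actin,
                inflection=k0, dt=base.frame_interval,
            ))
        ens = align_ensemble(normed)
        model = (clean - clean[k0]) / base.plateau_actin
        tol = 3 * (base.noise_sd / base.plateau_actin) / np.sqrt(n_rep)
        assert np.max(np.abs(ens.mean - model)) < tol


class TestSignificanceWindows:
    def test_self_comparison_is_never_significant(self):
        traces = simulate_wave_ensemble(6, seed=2)
        pairs = [analyze_wave_pair(t) for t in traces]
        ens = align_ensemble([q["actin"] for q in pairs])
        prof = significance_windows(ens, ens)
        assert not prof.significant.any()
        assert prof.windows == []

    def test_divergence_after_dispersal_detected(self):
        traces = simulate_wave_ensemble(10, seed=4)
        pairs = [analyze_wave_pair(t) for t in traces]
        ens_a = align_ensemble([q["actin"] for q in pairs])
        ens_t = align_ensemble([q["tpm"] for q in pairs])
        prof = significance_windows(ens_t, ens_a)
        assert len(prof.windows) >= 1
        t_offset_rel = np.median([
            t.truth.t_offset - t.times[q["actin"].inflection_index]
            for t, q in zip(traces, pairs)
        ])
        assert any(start > t_offset_rel for start, _ in prof.windows)

    def test_replicate_floor_truncates_analysis(self):
        # three traces; the third is short, so coverage drops to 2 < n_min
        long, short = 10, 6
        traces = [norm_trace(np.zeros(long)), norm_trace(np.zeros(long)),
                  norm_trace(np.zeros(short))]
        other = [norm_trace(np.ones(long)) for _ in range(3)]
        prof = significance_windows(align_ensemble(traces),
                                    align_ensemble(other), n_min=3)
        assert prof.t_max_analyzed == float(short - 1)
        flagged_late = prof.significant[prof.times_rel > prof.t_max_analyzed]
        assert not flagged_late.any()

    def test_misaligned_grids_rejected(self):
        a = align_ensemble([norm_trace(np.zeros(8), dt=1.0)] * 3)
        b = align_ensemble([norm_trace(np.zeros(8), dt=2.0)] * 3)
        with pytest.raises(GridMismatchError):
            significance_windows(a, b)


class TestFullPair:
    def test_actin_anchor_applies_to_both_channels(self):
        ts = gen_wave_trace(WaveEventParams(seed=0, noise_sd=0.0))
        pair = analyze_wave_pair(ts)
        assert pair["actin"].inflection_index == pair["tpm"].inflection_index
        # the lagged tpm channel is still near baseline at the actin anchor
        assert abs(pair["tpm"].values[pair["tpm"].inflection_index]) < 1e-12
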