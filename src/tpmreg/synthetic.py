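"""Synthetic data generators with known ground truth.

Every generator is a pure function of its parameter record (the seed is an
explicit, mandatory field), emits its ground truth alongside the data, and
in the noise-free limit equals the stated closed-form model exactly.

Generated inputs emulate the study's assays:

* two-channel wave-transit traces — a shared logistic rise with a
  channel lag on the tropomyosin channel, a plateau, channel-specific
  exponential dispersal, mono-exponential photobleaching, and additive
  Gaussian read noise;
* Hill-type inhibition titration tables;
* constant-velocity gliding-filament tracks with isotropic step jitter;
* toy multi-channel images containing blob-like organelles with
  channel-specific enrichment and line-like filaments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import skimage.draw

from .dose import DoseResponseTable, hill_response
from .images import LabeledImage
from .tracks import FilamentTrack, FilamentTrackSet
from .wave import WaveTraceSet

__all__ = [
    "WaveEventParams",
    "HillTruth",
    "TrackTruth",
    "ImageTruth",
    "rise_profile",
    "wave_roi_model",
    "wave_field_model",
    "gen_wave_trace",
    "simulate_wave_ensemble",
    "gen_dose_response",
    "gen_tracks",
    "gen_labeled_image",
]

# Logistic rise, clamped to 0 for t before onset and rescaled so it starts
# at exactly 0 and reaches exactly 0.95 at u = 3 (u in units of rise_tau).
_RISE_K = 2.0 * np.log(20.0) / 3.0
_RISE_MID = 1.5
_RISE_FLOOR = 1.0 / (1.0 + np.exp(_RISE_K * _RISE_MID))


def rise_profile(u) -> np.ndarray:
    """Clamped logistic rise: 0 at u <= 0, 0.95 at u = 3, asymptote 1."""
    u = np.asarray(u, dtype=float)
    s = 1.0 / (1.0 + np.exp(-_RISE_K * (u - _RISE_MID)))
    out = (s - _RISE_FLOOR) / (1.0 - _RISE_FLOOR)
    return np.where(u <= 0.0, 0.0, out)


@dataclass(frozen=True)
class WaveEventParams:
    """Generative parameters for one two-channel wave-transit event.

    Defaults describe a wave recorded at the slower "wave transit" imaging
    cadence (one frame every 15 s): onset three minutes into the recording,
    a ~60 s rise, dispersal with the actin signal decaying faster than the
    tropomyosin signal, and read noise a tenth of the wave amplitude.
    """

    seed: int
    t_onset: float = 180.0          # s
    channel_lag: float = 30.0       # s, tpm rise delayed vs actin
    rise_tau: float = 20.0          # s
    plateau_actin: float = 2000.0   # a.u. above baseline
    plateau_tpm: float = 2000.0
    baseline_actin: float = 500.0   # a.u.
    baseline_tpm: float = 500.0
    t_offset: float = 240.0         # s, start of dispersal
    decay_rate_actin: float = 0.02  # 1/s
    decay_rate_tpm: float = 0.008   # 1/s
    bleach_rate: float = 0.001      # 1/s
    noise_sd: float = 200.0         # a.u.
    frame_interval: float = 15.0    # s
    duration: float = 900.0         # s
    field_level: float = 20000.0    # a.u., whole-field intensity at t = 0

    def validate(self) -> None:
        nonneg = (
            "channel_lag", "plateau_actin", "plateau_tpm", "baseline_actin",
            "baseline_tpm", "decay_rate_actin", "decay_rate_tpm",
            "bleach_rate", "noise_sd",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"invariant violated: {name} must be >= 0")
        if self.rise_tau <= 0:
            raise ValueError("invariant violated: rise_tau must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("invariant violated: frame_interval must be > 0")
        if self.field_level <= 0:
            raise ValueError("invariant violated: field_level must be > 0")
        if not (self.t_onset < self.t_offset < self.duration):
            raise ValueError(
                "invariant violated: require t_onset < t_offset < duration"
            )


@dataclass(frozen=True)
class HillTruth:
    """Ground truth for a dose-response titration."""

    seed: int
    ic50: float                 # uM
    hill_coeff: float = 4.0
    top: float = 1.0
    bottom: float = 0.0
    noise_sd: float = 0.05      # fraction

    def validate(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("invariant violated: ic50 must be > 0")
        if self.hill_coeff <= 0:
            raise ValueError("invariant violated: hill_coeff must be > 0")
        if self.bottom > self.top:
            raise ValueError("invariant violated: bottom must be <= top")
        if self.noise_sd < 0:
            raise ValueError("invariant violated: noise_sd must be >= 0")


@dataclass(frozen=True)
class TrackTruth:
    """Ground truth for constant-velocity gliding-filament tracks."""

    seed: int
    speed: float = 780.0          # nm/s
    step_jitter_sd: float = 20.0  # nm per frame, per coordinate
    n_filaments: int = 100
    n_frames: int = 30
    frame_interval: float = 1.0   # s

    def validate(self) -> None:
        if self.speed < 0:
            raise ValueError("invariant violated: speed must be >= 0")
        if self.step_jitter_sd < 0:
            raise ValueError("invariant violated: step_jitter_sd must be >= 0")
        if self.n_frames < 2:
            raise ValueError("invariant violated: n_frames must be >= 2")
        if self.n_filaments < 1:
            raise ValueError("invariant violated: n_filaments must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("invariant violated: frame_interval must be > 0")


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth for a toy multi-channel image.

    The organelle channel shows bright disks ("blobs") on a dark
    background; the measure channel is flat background multiplied by
    ``enrichment_factor`` inside the blobs; an optional filament channel
    carries bright 1-px line segments of amplitude ``filament_amplitude``
    above background.
    """

    seed: int
    image_shape: tuple[int, int] = (128, 128)
    n_blobs: int = 5
    blob_radius: float = 8.0
    enrichment_factor: float = 2.0
    filament_segments: tuple = ()   # ((r0, c0), (r1, c1)) pairs
    background_mean: float = 100.0
    background_sd: float = 10.0
    blob_contrast: float = 4.0      # organelle-channel multiplier inside blobs
    filament_amplitude: float = 300.0

    def validate(self) -> None:
        h, w = self.image_shape
        if h < 4 or w < 4:
            raise ValueError("invariant violated: image too small")
        if self.enrichment_factor < 0:
            raise ValueError("invariant violated: enrichment_factor must be >= 0")
        if self.background_mean <= 0 or self.background_sd < 0:
            raise ValueError("invariant violated: background parameters")
        if self.n_blobs > 0 and not (
            0 < self.blob_radius <= min(h, w) / 2
        ):
            raise ValueError("invariant violated: blob_radius outside image bounds")
        for seg in self.filament_segments:
            for r, c in seg:
                if not (0 <= r < h and 0 <= c < w):
                    raise ValueError(
                        f"invariant violated: segment endpoint {(r, c)} outside "
                        f"image bounds {self.image_shape}"
                    )


def wave_roi_model(
    params: WaveEventParams, t, channel: str, bleached: bool = True
) -> np.ndarray:
    """Noise-free closed-form ROI trace for one channel.

    ``baseline + plateau * S((t - t_onset - lag) / rise_tau) * D(t)`` with
    the dispersal factor ``D(t) = exp(-decay_rate * (t - t_offset))`` after
    ``t_offset``, all scaled by ``exp(-bleach_rate * t)`` when ``bleached``.
    The channel lag applies only to the tropomyosin channel.
    """
    t = np.asarray(t, dtype=float)
    if channel == "actin":
        lag, base, plat, dec = 0.0, params.baseline_actin, params.plateau_actin, params.decay_rate_actin
    elif channel == "tpm":
        lag = params.channel_lag
        base, plat, dec = params.baseline_tpm, params.plateau_tpm, params.decay_rate_tpm
    else:
        raise ValueError(f"unknown channel {channel!r}")
    s = rise_profile((t - params.t_onset - lag) / params.rise_tau)
    d = np.where(t < params.t_offset, 1.0, np.exp(-dec * (t - params.t_offset)))
    out = base + plat * s * d
    if bleached:
        out = out * np.exp(-params.bleach_rate * t)
    return out


def wave_field_model(params: WaveEventParams, t, bleached: bool = True) -> np.ndarray:
    """Noise-free whole-field trace: constant scaled by the bleach decay."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, params.field_level)
    if bleached:
        out = out * np.exp(-params.bleach_rate * t)
    return out


def gen_wave_trace(params: WaveEventParams) -> WaveTraceSet:
    """Generate one two-channel wave event with additive Gaussian noise.

    Identical seeds give bit-identical output.  Intensities are clipped at
    zero (photon counts cannot be negative); with the default SNR of 10
    the clip is a < 1% tail event on baseline frames.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration / params.frame_interval))
    times = np.arange(n) * params.frame_interval
    roi, fld = {}, {}
    for ch in ("actin", "tpm"):
        roi[ch] = np.clip(
            wave_roi_model(params, times, ch) + rng.normal(0.0, params.noise_sd, n)
            if params.noise_sd > 0 else wave_roi_model(params, times, ch),
            0.0, None,
        )
        f = wave_field_model(params, times)
        if params.noise_sd > 0:
            f = f + rng.normal(0.0, params.noise_sd, n)
        fld[ch] = np.clip(f, 1e-6 * params.field_level, None)
    return WaveTraceSet(times=times, roi=roi, field=fld, truth=params)


def simulate_wave_ensemble(
    n_traces: int,
    seed: int,
    onset_jitter_frames: int = 4,
    **overrides,
) -> list[WaveTraceSet]:
    """Generate replicate wave events with staggered absolute onsets.

    Onsets cycle through ``onset_jitter_frames`` whole-frame shifts (the
    dispersal start shifts with the onset, so all replicates share one
    event shape in wave-relative time); each replicate gets an independent
    child seed derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_traces)
    base = WaveEventParams(seed=0, **overrides)
    out = []
    for i in range(n_traces):
        shift = base.frame_interval * (i % max(onset_jitter_frames, 1))
        p = replace(
            base,
            seed=int(child_seeds[i]),
            t_onset=base.t_onset + shift,
            t_offset=base.t_offset + shift,
        )
        out.append(gen_wave_trace(p))
    return out


def gen_dose_response(
    truth: HillTruth, concentrations, replicates: int = 3
) -> DoseResponseTable:
    """Generate a titration table from a decreasing Hill curve plus noise.

    Zero concentration maps to ``top`` exactly before noise; each
    (concentration, replicate) row receives independent Gaussian noise.
    """
    truth.validate()
    concs = np.asarray(concentrations, dtype=float)
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for rep in range(1, replicates + 1):
        clean = hill_response(concs, truth.ic50, truth.hill_coeff, truth.top, truth.bottom)
        noisy = clean + (rng.normal(0.0, truth.noise_sd, concs.size)
                         if truth.noise_sd > 0 else 0.0)
        rows.append(pd.DataFrame({
            "conc_uM": concs, "response": noisy, "replicate_id": f"rep{rep}",
        }))
    return DoseResponseTable(
        pd.concat(rows, ignore_index=True), truth=truth
    )


def gen_tracks(truth: TrackTruth) -> FilamentTrackSet:
    """Generate constant-heading filament tracks with isotropic step jitter.

    Each filament takes per-frame displacements of length
    ``speed * frame_interval`` along a random fixed heading, plus
    independent N(0, step_jitter_sd^2) jitter on each coordinate.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    tracks = []
    times = np.arange(truth.n_frames) * truth.frame_interval
    step = truth.speed * truth.frame_interval
    for i in range(truth.n_filaments):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        start = rng.uniform(0.0, 50_000.0, size=2)  # nm, 50 um field
        steps = np.tile([step * np.cos(theta), step * np.sin(theta)],
                        (truth.n_frames - 1, 1))
        if truth.step_jitter_sd > 0:
            steps = steps + rng.normal(0.0, truth.step_jitter_sd,
                                       size=steps.shape)
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        tracks.append(FilamentTrack(
            track_id=f"track{i:04d}", times=times, x=pos[:, 0], y=pos[:, 1]
        ))
    return FilamentTrackSet(tracks=tracks, truth=truth)


def gen_labeled_image(truth: ImageTruth) -> LabeledImage:
    """Generate a toy organelle/measure/filament image with ground truth.

    Channels: ``organelle`` (bright disks on dark background, for Otsu
    masking), ``measure`` (flat background scaled by ``enrichment_factor``
    inside the true blob mask), and — when segments are given —
    ``filament`` (1-px bright lines of amplitude ``filament_amplitude``
    above background).  The true blob mask and segments ride along in
    ``ground_truth``.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    h, w = truth.image_shape
    rr, cc = np.mgrid[0:h, 0:w]
    blob_mask = np.zeros((h, w), dtype=bool)
    centers = []
    r = truth.blob_radius
    for _ in range(truth.n_blobs):
        cy = rng.uniform(r, h - 1 - r)
        cx = rng.uniform(r, w - 1 - r)
        centers.append((cy, cx))
        blob_mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2

    def _noise():
        if truth.background_sd > 0:
            return rng.normal(0.0, truth.background_sd, (h, w))
        return 0.0

    organelle = np.full((h, w), truth.background_mean)
    organelle[blob_mask] *= truth.blob_contrast
    organelle = np.clip(organelle + _noise(), 0.0, None)

    measure = np.full((h, w), truth.background_mean)
    measure[blob_mask] *= truth.enrichment_factor
    measure = np.clip(measure + _noise(), 0.0, None)

    channels = {"organelle": organelle, "measure": measure}
    if truth.filament_segments:
        filament = np.full((h, w), truth.background_mean)
        for (r0, c0), (r1, c1) in truth.filament_segments:
            line_r, line_c = skimage.draw.line(int(r0), int(c0), int(r1), int(c1))
            filament[line_r, line_c] += truth.filament_amplitude
        channels["filament"] = np.clip(filament + _noise(), 0.0, None)

    return LabeledImage(
        channels=channels,
        ground_truth={
            "blob_mask": blob_mask,
            "blob_centers": centers,
            "segments": [tuple(map(tuple, s)) for s in truth.filament_segments],
            "truth": truth,
        },
    )
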