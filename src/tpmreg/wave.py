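"""Fluorescence wave-trace pipeline.

Analyses two-channel (actin / tropomyosin) intensity traces recorded while
an actin wave transits a region of interest:

1. photobleaching correction against the whole-field intensity,
2. wave-onset detection (the frame immediately preceding the rise, used as
   the alignment anchor and baseline zero),
3. baseline subtraction and plateau normalization,
4. ensemble alignment of replicate events on a common relative-time grid,
5. per-timepoint Mann-Whitney / Cliff's-delta significance windows between
   the two channel ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import cliffs_delta, mann_whitney_u

__all__ = [
    "WaveTraceSet",
    "NormalizedTrace",
    "AlignedEnsemble",
    "SignificanceProfile",
    "WaveDetectionError",
    "GridMismatchError",
    "correct_photobleach",
    "detect_inflection",
    "normalize_trace",
    "align_ensemble",
    "significance_windows",
    "analyze_wave_pair",
]

CHANNELS = ("actin", "tpm")


class WaveDetectionError(ValueError):
    """No wave-driven intensity rise could be located in a trace."""


class GridMismatchError(ValueError):
    """Two ensembles do not share an aligned relative-time grid."""


@dataclass
class WaveTraceSet:
    """Two-channel ROI and whole-field intensity traces for one wave event.

    ``roi`` and ``field`` map channel name ("actin", "tpm") to intensity
    series in arbitrary units; ``times`` is in seconds, uniformly spaced.
    ``truth`` optionally carries the generating parameters of synthetic data.
    """

    times: np.ndarray
    roi: dict[str, np.ndarray]
    field: dict[str, np.ndarray]
    truth: object | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi = {k: np.asarray(v, dtype=float) for k, v in self.roi.items()}
        self.field = {k: np.asarray(v, dtype=float) for k, v in self.field.items()}
        n = self.times.size
        if n < 3:
            raise ValueError("trace set must have at least 3 frames")
        for name, series in {**{f"roi_{k}": v for k, v in self.roi.items()},
                             **{f"field_{k}": v for k, v in self.field.items()}}.items():
            if series.size != n:
                raise ValueError(f"series {name!r} length {series.size} != {n} time points")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            k = int(np.argmax(dts <= 0)) + 1
            raise ValueError(f"times must be strictly increasing (violated at frame {k})")
        if not np.allclose(dts, dts[0], atol=1e-6, rtol=0):
            raise ValueError("times must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class NormalizedTrace:
    """A baseline-zeroed, plateau-normalized ROI trace.

    ``times_rel`` is time relative to the detected inflection (0 there);
    the value at the inflection is 0 and the mean over the plateau window
    is 1 by construction.
    """

    times_rel: np.ndarray
    values: np.ndarray
    inflection_index: int
    plateau_value_raw: float
    plateau_window: tuple[int, int]  # [start, stop) indices into values

    @property
    def frame_interval(self) -> float:
        return float(self.times_rel[1] - self.times_rel[0])


@dataclass
class AlignedEnsemble:
    """Replicate normalized traces on a common grid anchored at t_rel = 0."""

    times_rel: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    values: np.ndarray  # shape (n_traces, n_timepoints), NaN where uncovered
    frame_interval: float

    def peak_time(self, n_min: int = 1) -> float:
        """Relative time of the ensemble-mean maximum over well-covered points."""
        ok = self.n >= n_min
        if not np.any(ok):
            raise ValueError(f"no timepoint has coverage >= {n_min}")
        means = np.where(ok, self.mean, -np.inf)
        return float(self.times_rel[int(np.nanargmax(means))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_rel_s": self.times_rel, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


@dataclass
class SignificanceProfile:
    """Per-timepoint test results between two aligned ensembles.

    ``significant`` is True where Cliff's delta exceeds ``delta_threshold``
    AND the Mann-Whitney p-value is below ``alpha``; ``windows`` lists the
    maximal runs of consecutive significant timepoints as [t_start, t_end]
    pairs in relative seconds.  No timepoint beyond ``t_max_analyzed`` (the
    last one meeting the replicate floor in both ensembles) is flagged.
    """

    times_rel: np.ndarray
    p_value: np.ndarray
    cliffs_delta: np.ndarray
    significant: np.ndarray
    windows: list[tuple[float, float]]
    t_max_analyzed: float
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_rel_s": self.times_rel,
                "p_value": self.p_value,
                "cliffs_delta": self.cliffs_delta,
                "significant": self.significant,
            }
        )


def correct_photobleach(trace_set: WaveTraceSet) -> WaveTraceSet:
    """Correct ROI traces for photobleaching using the whole-field decay.

    The whole-image trace of each channel is normalized to its initial
    frame and the ROI trace is divided by that fractional decrease:
    ``roi_corr(t) = roi(t) / (field(t) / field(0))``.  The field channels
    are replaced by their self-normalized traces (identically 1 when
    noise-free).
    """
    for ch, f in trace_set.field.items():
        bad = np.flatnonzero(f <= 0)
        if bad.size:
            raise ValueError(
                f"field channel {ch!r} is non-positive at frame {int(bad[0])}; "
                "cannot form the fractional bleaching decrease"
            )
    roi_corr = {}
    field_corr = {}
    for ch in trace_set.roi:
        frac = trace_set.field[ch] / trace_set.field[ch][0]
        roi_corr[ch] = trace_set.roi[ch] / frac
        field_corr[ch] = trace_set.field[ch] / frac  # constant field[0]
    return WaveTraceSet(
        times=trace_set.times.copy(), roi=roi_corr, field=field_corr, truth=trace_set.truth
    )


def detect_inflection(
    values,
    k_sd: float = 3.0,
    baseline_window: int = 10,
    rel_rise: float = 0.05,
) -> int:
    """Locate the frame immediately preceding the wave-driven rise.

    Baseline mean and SD come from the first ``baseline_window`` frames.
    The first subsequent frame exceeding ``mean + k_sd * sd`` marks the
    rise; the returned index is the frame before it (the baseline-zero
    anchor).  If the baseline SD is zero, a relative-rise rule is used
    instead: the first frame exceeding the baseline mean by ``rel_rise``
    (fractionally).

    Raises :class:`WaveDetectionError` when no frame crosses the threshold.
    """
    v = np.asarray(values, dtype=float)
    if v.size <= baseline_window + 2:
        raise ValueError(
            f"series of length {v.size} too short for baseline_window={baseline_window}"
        )
    base = v[:baseline_window]
    mu = float(base.mean())
    sd = float(base.std(ddof=1)) if baseline_window > 1 else 0.0
    if sd > 0:
        threshold = mu + k_sd * sd
    else:
        threshold = mu + rel_rise * abs(mu)
    above = np.flatnonzero(v[baseline_window:] > threshold)
    if above.size == 0:
        raise WaveDetectionError(
            f"no wave detected: no frame exceeds baseline threshold {threshold:.6g}"
        )
    crossing = baseline_window + int(above[0])
    return crossing - 1


def _plateau_window(
    values: np.ndarray,
    inflection_index: int,
    plateau_frames: int,
    smooth_frames: int = 3,
) -> tuple[int, int]:
    """Post-inflection window of ``plateau_frames`` frames centered on the
    maximum of a short moving average (noise-spike resistant)."""
    start = inflection_index + 1
    post = values[start:]
    if post.size == 0:
        raise ValueError("no frames after the inflection point")
    ma = (
        pd.Series(post)
        .rolling(smooth_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    pk = start + int(np.argmax(ma))
    half = plateau_frames // 2
    hi = min(values.size, pk - half + plateau_frames)
    lo = max(start, hi - plateau_frames)
    hi = min(values.size, lo + plateau_frames)
    return lo, hi


def normalize_trace(
    values,
    times,
    inflection_index: int,
    plateau_frames: int = 5,
) -> NormalizedTrace:
    """Baseline-subtract and plateau-normalize one ROI trace.

    The value at the inflection frame becomes 0, the mean over the plateau
    window becomes 1, and times are shifted so the inflection sits at 0.
    The result is invariant under positive affine transforms of the input.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size != t.size:
        raise ValueError("values and times differ in length")
    if not 0 <= inflection_index < v.size - 1:
        raise ValueError(f"inflection_index {inflection_index} out of range")
    lo, hi = _plateau_window(v, inflection_index, plateau_frames)
    plateau_mean = float(v[lo:hi].mean())
    anchor = float(v[inflection_index])
    amplitude = plateau_mean - anchor
    if amplitude <= 0:
        raise ValueError(
            "no resolvable wave amplitude: plateau mean does not exceed the "
            "inflection value"
        )
    return NormalizedTrace(
        times_rel=t - t[inflection_index],
        values=(v - anchor) / amplitude,
        inflection_index=int(inflection_index),
        plateau_value_raw=plateau_mean,
        plateau_window=(lo, hi),
    )


def align_ensemble(traces: Sequence[NormalizedTrace]) -> AlignedEnsemble:
    """Stack normalized traces on a common grid anchored at their inflections.

    All traces must share the frame interval (tolerance 1e-6 s).  Mean,
    sample SD (n-1 denominator) and replicate count are computed per grid
    point over the traces covering it; a single covering trace reports
    SD = 0 (with a warning).
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    dt = traces[0].frame_interval
    for tr in traces:
        if abs(tr.frame_interval - dt) > 1e-6:
            raise GridMismatchError(
                f"mixed frame intervals: {tr.frame_interval} vs {dt}"
            )
    k_start = [-tr.inflection_index for tr in traces]
    k_stop = [tr.values.size - tr.inflection_index for tr in traces]
    kmin, kmax = min(k_start), max(k_stop)
    n_grid = kmax - kmin
    mat = np.full((len(traces), n_grid), np.nan)
    for i, tr in enumerate(traces):
        col = k_start[i] - kmin
        mat[i, col : col + tr.values.size] = tr.values
    n = np.sum(~np.isnan(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
        sd = np.full(n_grid, np.nan)
        multi = n >= 2
        sd[multi] = np.nanstd(mat[:, multi], axis=0, ddof=1)
    if np.any(n == 1):
        sd[n == 1] = 0.0
        if len(traces) == 1:
            warnings.warn(
                "single-trace ensemble: SD reported as 0", stacklevel=2
            )
    return AlignedEnsemble(
        times_rel=np.arange(kmin, kmax) * dt,
        mean=mean,
        sd=sd,
        n=n.astype(int),
        values=mat,
        frame_interval=dt,
    )


def _significant_runs(
    flags: np.ndarray, times: np.ndarray
) -> list[tuple[float, float]]:
    windows: list[tuple[float, float]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            windows.append((float(times[start]), float(times[i - 1])))
            start = None
    if start is not None:
        windows.append((float(times[start]), float(times[-1])))
    return windows


def significance_windows(
    ensemble_a: AlignedEnsemble,
    ensemble_b: AlignedEnsemble,
    alpha: float = 0.05,
    delta_threshold: float = 0.3,
    n_min: int = 3,
    exact_max_n: int = 8,
    absolute_delta: bool = False,
    post_inflection_only: bool = True,
) -> SignificanceProfile:
    """Per-timepoint Mann-Whitney + Cliff's-delta comparison of two ensembles.

    At each shared timepoint where both ensembles have at least ``n_min``
    covering traces, the two sets of per-trace normalized values are
    compared.  A timepoint is significant when Cliff's delta (of ensemble A
    over ensemble B; signed unless ``absolute_delta``) exceeds
    ``delta_threshold`` and the two-sided p-value is below ``alpha``.
    Analysis stops at the last timepoint meeting the replicate floor
    (``t_max_analyzed``), mirroring the truncation of under-replicated
    late timepoints.
    """
    if abs(ensemble_a.frame_interval - ensemble_b.frame_interval) > 1e-6:
        raise GridMismatchError("ensembles have different frame intervals")
    dt = ensemble_a.frame_interval
    ka = np.round(ensemble_a.times_rel / dt).astype(int)
    kb = np.round(ensemble_b.times_rel / dt).astype(int)
    if not (np.allclose(ka * dt, ensemble_a.times_rel, atol=1e-6)
            and np.allclose(kb * dt, ensemble_b.times_rel, atol=1e-6)):
        raise GridMismatchError("ensemble grids are not integer multiples of dt")
    common = np.intersect1d(ka, kb)
    if post_inflection_only:
        common = common[common >= 0]
    if common.size == 0:
        raise GridMismatchError("ensembles share no timepoints")
    times = common * dt
    ia = np.searchsorted(ka, common)
    ib = np.searchsorted(kb, common)

    p = np.full(common.size, np.nan)
    delta = np.full(common.size, np.nan)
    eligible = np.zeros(common.size, dtype=bool)
    for j in range(common.size):
        a_vals = ensemble_a.values[:, ia[j]]
        b_vals = ensemble_b.values[:, ib[j]]
        a_vals = a_vals[~np.isnan(a_vals)]
        b_vals = b_vals[~np.isnan(b_vals)]
        if a_vals.size < n_min or b_vals.size < n_min:
            continue
        eligible[j] = True
        _, p[j] = mann_whitney_u(a_vals, b_vals, exact_max_n=exact_max_n)
        delta[j] = cliffs_delta(a_vals, b_vals)

    if np.any(eligible):
        t_max = float(times[np.flatnonzero(eligible)[-1]])
    else:
        t_max = float("nan")
    crit_delta = np.abs(delta) if absolute_delta else delta
    with np.errstate(invalid="ignore"):
        significant = eligible & (crit_delta > delta_threshold) & (p < alpha)
    return SignificanceProfile(
        times_rel=times,
        p_value=p,
        cliffs_delta=delta,
        significant=significant,
        windows=_significant_runs(significant, times),
        t_max_analyzed=t_max,
        config={
            "alpha": alpha,
            "delta_threshold": delta_threshold,
            "n_min": n_min,
            "exact_max_n": exact_max_n,
            "absolute_delta": absolute_delta,
            "post_inflection_only": post_inflection_only,
        },
    )


def analyze_wave_pair(
    trace_set: WaveTraceSet,
    k_sd: float = 3.0,
    baseline_window: int = 10,
    plateau_frames: int = 5,
) -> dict[str, NormalizedTrace]:
    """Run bleach correction, onset detection and normalization on one event.

    The inflection is detected on the actin channel (the wave is defined by
    actin appearance) and both channels are anchored there; each channel is
    normalized to its own plateau.
    """
    corrected = correct_photobleach(trace_set)
    infl = detect_inflection(
        corrected.roi["actin"], k_sd=k_sd, baseline_window=baseline_window
    )
    return {
        ch: normalize_trace(
            corrected.roi[ch], corrected.times, infl, plateau_frames=plateau_frames
        )
        for ch in CHANNELS
    }
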