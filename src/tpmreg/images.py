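"""Image quantifications: Otsu-mask organelle enrichment and on/off-filament
line-profile background correction.

Two measurements are implemented:

* ``mask_enrichment`` — threshold an organelle channel (e.g. a mitochondrial
  marker) by the Otsu method, apply the mask to a measurement channel
  (e.g. tropomyosin immunofluorescence), and report the mean and
  area-normalized masked signal.
* ``line_profile_coloc`` — sample a line profile directly over a filament
  and a parallel one just off it; the difference of means is the
  background-corrected filament signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "LabeledImage",
    "MaskStats",
    "LineProfilePair",
    "otsu_threshold",
    "mask_enrichment",
    "line_profile_coloc",
]


@dataclass
class LabeledImage:
    """Named co-registered 2D channels, optionally with synthetic ground truth.

    ``ground_truth`` (synthetic images only) may carry the true blob mask
    ("blob_mask") and filament segment endpoints ("segments").
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # nm per pixel
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {sorted(shapes)}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class MaskStats:
    """Masked-signal statistics from one ROI."""

    threshold: float
    mask_area: int
    measure_mean: float
    measure_area_normalized: float
    out_mean: float
    enrichment_ratio: float
    roi_area: int
    condition_label: str = ""

    @property
    def valid(self) -> bool:
        return self.mask_area > 0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "mask_area_px": self.mask_area,
            "measure_mean": self.measure_mean,
            "measure_area_normalized": self.measure_area_normalized,
            "out_mean": self.out_mean,
            "enrichment_ratio": self.enrichment_ratio,
            "roi_area_px": self.roi_area,
            "condition_label": self.condition_label,
        }


@dataclass
class LineProfilePair:
    """On-filament and off-filament line samples with the corrected signal."""

    on_values: np.ndarray
    off_values: np.ndarray

    @property
    def corrected_signal(self) -> float:
        return float(np.mean(self.on_values) - np.mean(self.off_values))


def otsu_threshold(values, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Uses ``n_bins`` uniform bins over the observed min-max range and
    returns the center of the winning bin; ties break to the lowest
    qualifying threshold.  Foreground is conventionally ``values > t``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 pixels")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite pixel values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise ValueError("no separable classes: image is constant")
    hist, edges = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    csum = np.cumsum(hist * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum[:-1] / w0
        mu1 = (csum[-1] - csum[:-1]) / w1
        var_b = w0 * w1 * (mu0 - mu1) ** 2
    var_b[~np.isfinite(var_b)] = 0.0
    return float(centers[int(np.argmax(var_b))])  # argmax -> first (lowest) max


def _resolve_roi(roi, shape) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool:
        if roi_arr.shape != shape:
            raise ValueError("boolean ROI shape does not match image")
        return roi_arr
    # (row_start, row_stop, col_start, col_stop)
    r0, r1, c0, c1 = (int(r) for r in roi_arr.ravel())
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise ValueError(f"ROI {(r0, r1, c0, c1)} outside image bounds {shape}")
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = True
    return out


def mask_enrichment(
    mask_channel,
    measure_channel,
    roi=None,
    n_bins: int = 256,
    area_norm: str = "roi",
    condition_label: str = "",
    threshold: float | None = None,
) -> MaskStats:
    """Otsu-mask one channel and quantify another within the mask.

    The threshold is computed from ``mask_channel`` restricted to ``roi``
    (whole image by default; either a boolean mask or a
    ``(row_start, row_stop, col_start, col_stop)`` rectangle), unless an
    explicit ``threshold`` overrides the Otsu computation.  The
    area-normalized signal is the integrated in-mask measure divided by the
    ROI pixel area (``area_norm="roi"``) or the mask pixel area
    (``area_norm="mask"``).  An empty mask yields NaN statistics with
    ``valid`` False.
    """
    mask_ch = np.asarray(mask_channel, dtype=float)
    meas_ch = np.asarray(measure_channel, dtype=float)
    if mask_ch.shape != meas_ch.shape:
        raise ValueError("mask and measure channels differ in shape")
    if area_norm not in ("roi", "mask"):
        raise ValueError(f"unknown area_norm {area_norm!r}")
    roi_mask = _resolve_roi(roi, mask_ch.shape)
    if threshold is None:
        threshold = otsu_threshold(mask_ch[roi_mask], n_bins=n_bins)
    mask = (mask_ch > threshold) & roi_mask
    roi_area = int(roi_mask.sum())
    mask_area = int(mask.sum())
    if mask_area == 0:
        return MaskStats(
            threshold=threshold, mask_area=0, measure_mean=float("nan"),
            measure_area_normalized=float("nan"), out_mean=float("nan"),
            enrichment_ratio=float("nan"), roi_area=roi_area,
            condition_label=condition_label,
        )
    inside = meas_ch[mask]
    outside = meas_ch[roi_mask & ~mask]
    out_mean = float(outside.mean()) if outside.size else float("nan")
    denom = roi_area if area_norm == "roi" else mask_area
    return MaskStats(
        threshold=threshold,
        mask_area=mask_area,
        measure_mean=float(inside.mean()),
        measure_area_normalized=float(inside.sum() / denom),
        out_mean=out_mean,
        enrichment_ratio=float(inside.mean() / out_mean) if outside.size else float("nan"),
        roi_area=roi_area,
        condition_label=condition_label,
    )


def _sample_segment(channel: np.ndarray, segment, sampling_step: float) -> np.ndarray:
    (r0, c0), (r1, c1) = segment
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("degenerate zero-length segment")
    n = int(np.floor(length / sampling_step)) + 1
    ts = np.arange(n) * sampling_step / length
    rows = r0 + ts * (r1 - r0)
    cols = c0 + ts * (c1 - c0)
    h, w = channel.shape
    if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
        raise ValueError(f"segment {segment} extends outside the image")
    return map_coordinates(channel, [rows, cols], order=1, mode="nearest")


def line_profile_coloc(
    channel,
    on_segment,
    off_segment,
    sampling_step: float = 1.0,
) -> LineProfilePair:
    """Background-corrected filament signal from paired line profiles.

    Both segments are ``((row0, col0), (row1, col1))`` in pixel coordinates
    and are sampled by bilinear interpolation at ``sampling_step`` pixel
    spacing.  ``corrected_signal = mean(on) - mean(off)``: invariant to a
    global additive offset and equivariant under multiplicative gain.
    """
    ch = np.asarray(channel, dtype=float)
    if ch.ndim != 2:
        raise ValueError("channel must be a 2D raster")
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    on_vals = _sample_segment(ch, on_segment, sampling_step)
    off_vals = _sample_segment(ch, off_segment, sampling_step)
    return LineProfilePair(on_values=on_vals, off_values=off_vals)
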