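"""Readers and writers for the package's plain-text and image formats.

Tabular data travels as UTF-8 CSV with headers ('.' decimal); images as
multi-page TIFF (one page per channel) or NPZ with named arrays, each with
a JSON sidecar carrying channel names and synthetic ground truth.  Parsers
reject malformed input with located errors rather than coercing silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .dose import DoseResponseTable
from .images import LabeledImage
from .tracks import FilamentTrack, FilamentTrackSet
from .wave import WaveTraceSet

__all__ = [
    "SchemaError",
    "read_wave_csv", "write_wave_csv",
    "read_tracks_csv", "write_tracks_csv",
    "read_dose_csv", "write_dose_csv",
    "read_image", "write_image",
]

WAVE_COLUMNS = ("time_s", "roi_actin", "roi_tpm", "field_actin", "field_tpm")
TRACK_COLUMNS = ("track_id", "time_s", "x_nm", "y_nm")
DOSE_COLUMNS = ("conc_uM", "response", "replicate_id")

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A file does not match its declared schema."""


def _read_csv_checked(path, required, numeric) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at line {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: empty cell in column {col!r} at line {row}")
        df[col] = coerced
    return df


def _check_increasing(times: pd.Series, path, label="time_s") -> None:
    t = times.to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        row = int(bad[0]) + 3  # offending (second) row, one-based with header
        raise SchemaError(
            f"{path}: {label} not strictly increasing at line {row}"
        )


def read_wave_csv(path) -> WaveTraceSet:
    df = _read_csv_checked(path, WAVE_COLUMNS, WAVE_COLUMNS)
    _check_increasing(df["time_s"], path)
    neg = df[[c for c in WAVE_COLUMNS if c != "time_s"]].lt(0)
    if neg.any().any():
        col = neg.any()[neg.any()].index[0]
        row = int(neg[col].idxmax()) + 2
        raise SchemaError(f"{path}: negative intensity in {col!r} at line {row}")
    return WaveTraceSet(
        times=df["time_s"].to_numpy(),
        roi={"actin": df["roi_actin"].to_numpy(), "tpm": df["roi_tpm"].to_numpy()},
        field={"actin": df["field_actin"].to_numpy(), "tpm": df["field_tpm"].to_numpy()},
    )


def write_wave_csv(trace_set: WaveTraceSet, path) -> None:
    pd.DataFrame({
        "time_s": trace_set.times,
        "roi_actin": trace_set.roi["actin"],
        "roi_tpm": trace_set.roi["tpm"],
        "field_actin": trace_set.field["actin"],
        "field_tpm": trace_set.field["tpm"],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks_csv(path) -> FilamentTrackSet:
    df = _read_csv_checked(path, TRACK_COLUMNS, ("time_s", "x_nm", "y_nm"))
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        _check_increasing(grp["time_s"].reset_index(drop=True), path,
                          label=f"time_s (track {tid!r})")
        tracks.append(FilamentTrack(
            track_id=tid,
            times=grp["time_s"].to_numpy(),
            x=grp["x_nm"].to_numpy(),
            y=grp["y_nm"].to_numpy(),
        ))
    if not tracks:
        raise SchemaError(f"{path}: no tracks found")
    return FilamentTrackSet(tracks=tracks)


def write_tracks_csv(track_set: FilamentTrackSet, path) -> None:
    frames = [
        pd.DataFrame({"track_id": t.track_id, "time_s": t.times,
                      "x_nm": t.x, "y_nm": t.y})
        for t in track_set
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_dose_csv(path, response_kind: str = "bound_fraction") -> DoseResponseTable:
    df = _read_csv_checked(path, DOSE_COLUMNS, ("conc_uM", "response"))
    if (df["conc_uM"] < 0).any():
        row = int((df["conc_uM"] < 0).idxmax()) + 2
        raise SchemaError(f"{path}: negative concentration at line {row}")
    return DoseResponseTable(df, response_kind=response_kind)


def write_dose_csv(table: DoseResponseTable, path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _truth_to_jsonable(gt: dict | None):
    if gt is None:
        return None
    out = {}
    if "blob_mask" in gt:
        out["blob_mask_rle"] = None  # mask stored in the array container itself
    if "segments" in gt:
        out["segments"] = [list(map(list, s)) for s in gt["segments"]]
    if "blob_centers" in gt:
        out["blob_centers"] = [list(c) for c in gt["blob_centers"]]
    return out


def write_image(image: LabeledImage, path) -> None:
    """Write a LabeledImage as .npz (named arrays) or multi-page .tif/.tiff.

    A ``<name>.meta.json`` sidecar records channel order and any synthetic
    ground-truth geometry; the NPZ container additionally stores the true
    blob mask as an array.
    """
    path = Path(path)
    gt = image.ground_truth or {}
    meta = {
        "channels": list(image.channels),
        "pixel_size_nm": image.pixel_size,
        "ground_truth": _truth_to_jsonable(gt) if image.ground_truth else None,
    }
    if path.suffix == ".npz":
        arrays = dict(image.channels)
        if "blob_mask" in gt:
            arrays["__blob_mask__"] = gt["blob_mask"]
        np.savez(path, **arrays)
    elif path.suffix in (".tif", ".tiff"):
        stack = np.stack([image.channels[c] for c in image.channels]).astype(np.float32)
        tifffile.imwrite(path, stack, photometric="minisblack")
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_image(path) -> LabeledImage:
    path = Path(path)
    sidecar = _sidecar(path)
    meta = None
    if sidecar.exists():
        with open(sidecar, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    if path.suffix == ".npz":
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        blob_mask = arrays.pop("__blob_mask__", None)
        channels = arrays
    elif path.suffix in (".tif", ".tiff"):
        stack = np.asarray(tifffile.imread(path), dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
        names = (meta or {}).get("channels") or [
            f"channel{i}" for i in range(stack.shape[0])
        ]
        if len(names) != stack.shape[0]:
            raise SchemaError(
                f"{path}: sidecar lists {len(names)} channels, file has "
                f"{stack.shape[0]} pages"
            )
        channels = dict(zip(names, stack))
        blob_mask = None
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    gt = None
    meta_gt = (meta or {}).get("ground_truth")
    if meta_gt or blob_mask is not None:
        gt = dict(meta_gt or {})
        gt.pop("blob_mask_rle", None)
        if "segments" in gt:
            gt["segments"] = [tuple(map(tuple, s)) for s in gt["segments"]]
        if blob_mask is not None:
            gt["blob_mask"] = blob_mask.astype(bool)
    return LabeledImage(
        channels=channels,
        pixel_size=(meta or {}).get("pixel_size_nm"),
        ground_truth=gt,
    )
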