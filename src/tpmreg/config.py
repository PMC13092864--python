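"""Analysis configuration and run provenance records."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "RunRecord"]


@dataclass
class AnalysisConfig:
    """All pipeline tunables with their defaults.

    Wave pipeline: ``k_sd`` / ``baseline_window`` control onset detection,
    ``plateau_frames`` the normalization window, ``n_min`` the replicate
    floor below which late timepoints are truncated, and
    ``alpha`` / ``delta_threshold`` the dual significance criterion
    (p < 0.05 and Cliff's delta > 0.3).  ``exact_max_n`` bounds the exact
    Mann-Whitney enumeration.  Dose fitting: ``n_bootstrap`` CI resamples.
    Binding and motility calls: ``count_threshold`` filaments per field,
    ``motile_threshold`` in nm/s.  Images: ``otsu_bins`` histogram bins and
    ``sampling_step`` (px) for line profiles.
    """

    k_sd: float = 3.0
    baseline_window: int = 10
    plateau_frames: int = 5
    n_min: int = 3
    alpha: float = 0.05
    delta_threshold: float = 0.3
    absolute_delta: bool = False
    exact_max_n: int = 8
    n_bootstrap: int = 1000
    count_threshold: int = 5
    motile_threshold: float = 50.0
    sampling_step: float = 1.0
    otsu_bins: int = 256
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 <= self.delta_threshold <= 1:
            raise ValueError("delta_threshold must be in [-1, 1]")
        for name in ("baseline_window", "plateau_frames", "n_min",
                     "exact_max_n", "otsu_bins", "count_threshold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        for name in ("k_sd", "motile_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config, input digests, seed, outputs."""

    command: str
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: list = field(default_factory=list)
    version: str = ""
    created: str = ""

    @classmethod
    def create(cls, command: str, config: AnalysisConfig | dict, seed: int,
               inputs=(), outputs=()) -> "RunRecord":
        from . import __version__

        cfg = config.to_dict() if isinstance(config, AnalysisConfig) else dict(config)
        return cls(
            command=command,
            config=cfg,
            seed=int(seed),
            inputs={str(p): _sha256(Path(p)) for p in inputs},
            outputs=[str(p) for p in outputs],
            version=__version__,
            created=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
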