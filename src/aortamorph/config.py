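"""Run configuration: one root seed, split per pipeline stage."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    seed: int = 0
    voxel_mm: float = 0.5
    n_dilated: int = 35
    n_nondilated: int = 100
    bootstrap_replicates: int = 1000
    reader_noise_sd_mm: float = 0.3
    output_dir: str = "aortamorph-out"
    mode: str = "archetype"  # archetype | cohort | image
    mask_path: str | None = None
    landmarks_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("archetype", "cohort", "image"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("voxel_mm", "n_dilated", "n_nondilated",
                     "bootstrap_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reader_noise_sd_mm < 0:
            raise ValueError("reader_noise_sd_mm must be >= 0")
        if self.mode == "image" and not (self.mask_path and self.landmarks_path):
            raise ValueError("image mode requires mask_path and landmarks_path")

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed (< 2**31)."""
        tag = zlib.crc32(stage.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return int(ss.generate_state(1)[0] % (2**31))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
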