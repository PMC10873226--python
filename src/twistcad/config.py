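"""Run configuration, seed fan-out, and config hashing.

A single master seed drives the whole pipeline. Each module draws its own
seed as a hash of ``master_seed`` and the module name, so that modules stay
reproducible in isolation and no two stages share a random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .evaluate import DEFAULT_OPERATING_POINTS
from .fpreduce import ThresholdConfig
from .phantom import CohortConfig

__all__ = ["RunConfig", "subseed", "config_hash"]


def subseed(master_seed: int, name: str) -> int:
    """Deterministic per-module seed below 2**31 derived from the master."""
    digest = hashlib.blake2s(f"{master_seed}:{name}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable to a YAML file."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    detector_backend: str = "blob"  # "blob" or "heatmap"
    detector_params: dict = field(default_factory=dict)
    clip_margin_fraction: float = 0.2
    clip_patch_size: int = 32
    operating_points: tuple[float, ...] = DEFAULT_OPERATING_POINTS
    k_folds: int = 5
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.detector_backend not in ("blob", "heatmap"):
            raise ValueError(f"unknown detector backend {self.detector_backend!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def module_seed(self, name: str) -> int:
        return subseed(self.seed, name)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in data and isinstance(data["cohort"], dict):
            ckeys = {f.name for f in fields(CohortConfig)}
            bad = set(data["cohort"]) - ckeys
            if bad:
                raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
            c = dict(data["cohort"])
            for tup_key in ("volume_shape", "spacing"):
                if tup_key in c:
                    c[tup_key] = tuple(c[tup_key])
            if "kinetics" in c and isinstance(c["kinetics"], dict):
                from .phantom import KineticParams

                c["kinetics"] = {
                    name: KineticParams(**kp) if isinstance(kp, dict) else kp
                    for name, kp in c["kinetics"].items()
                }
            data["cohort"] = CohortConfig(**c)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            tkeys = {f.name for f in fields(ThresholdConfig)}
            bad = set(data["thresholds"]) - tkeys
            if bad:
                raise ValueError(f"unknown threshold config keys: {sorted(bad)}")
            data["thresholds"] = ThresholdConfig(**data["thresholds"])
        if "operating_points" in data:
            data["operating_points"] = tuple(data["operating_points"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full run configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
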