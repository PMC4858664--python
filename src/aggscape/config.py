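"""Run configuration: one file, one block per pipeline stage.

Blocks map onto the parameter dataclasses of the corresponding modules;
unknown keys are rejected rather than ignored so a typo cannot silently
fall back to defaults.  The configuration round-trips losslessly through
YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ensemble import KernelParams
from .errors import ConfigError
from .intrinsic import ProfileParams
from .structfeat import SwitchingParams
from .synthgen import SynthSpec

__all__ = ["FESParams", "DesignParams", "InputPaths", "RunConfig"]


@dataclass(frozen=True)
class FESParams:
    """Free-energy-surface settings: grid and temperature."""

    enabled: bool = True
    n_bins: int = 12
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be > 0")


@dataclass(frozen=True)
class DesignParams:
    """Candidate-site thresholds of the design stage."""

    intrinsic_threshold: float = 1.0
    delta_threshold: float = 0.2


@dataclass(frozen=True)
class InputPaths:
    """Externally supplied inputs; when absent, fixtures are generated."""

    fasta: str | None = None
    pdb_a: str | None = None
    pdb_b: str | None = None
    weights_a: str | None = None
    weights_b: str | None = None


_BLOCKS = {
    "profile": ProfileParams,
    "kernel": KernelParams,
    "switching": SwitchingParams,
    "fes": FESParams,
    "design": DesignParams,
    "synth": SynthSpec,
    "inputs": InputPaths,
}


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    profile: ProfileParams = field(default_factory=ProfileParams)
    kernel: KernelParams = field(default_factory=KernelParams)
    switching: SwitchingParams = field(default_factory=SwitchingParams)
    fes: FESParams = field(default_factory=FESParams)
    design: DesignParams = field(default_factory=DesignParams)
    synth: SynthSpec = field(default_factory=SynthSpec)
    inputs: InputPaths = field(default_factory=InputPaths)
    seed: int = 0
    verbosity: int = 1
    strands: tuple[tuple[str, int, int], ...] = ()

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        kwargs: dict[str, Any] = {}
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known_top
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        for name, block_cls in _BLOCKS.items():
            if name in data:
                block = data[name]
                if not isinstance(block, dict):
                    raise ConfigError(f"block {name!r} must be a mapping")
                try:
                    obj = block_cls(**{k: _coerce(v) for k, v in block.items()})
                except TypeError as exc:
                    raise ConfigError(f"block {name!r}: {exc}") from exc
                kwargs[name] = obj
        for scalar in ("seed", "verbosity"):
            if scalar in data:
                kwargs[scalar] = int(data[scalar])
        if "strands" in data:
            kwargs["strands"] = tuple(
                (str(s[0]), int(s[1]), int(s[2])) for s in data["strands"]
            )
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data or {})

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in _BLOCKS:
            out[name] = _listify(dataclasses.asdict(getattr(self, name)))
        out["seed"] = self.seed
        out["verbosity"] = self.verbosity
        out["strands"] = [list(s) for s in self.strands]
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable content hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _listify(value: Any) -> Any:
    """Deep tuple -> list conversion for YAML/JSON serialization."""
    if isinstance(value, tuple):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    return value


def _coerce(value: Any) -> Any:
    """YAML gives lists where dataclasses want tuples (hotspots etc.)."""
    if isinstance(value, list):
        return tuple(_coerce(v) for v in value)
    return value


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {obj!r}")
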