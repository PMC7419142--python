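"""Run configuration, manifests and result serialisation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circuit import DEFAULT_SIGMA, SPECIES

PROTOCOLS = (
    "bump_maintenance", "tuning_curves", "heading_change", "sigma_sweep",
    "attractor_states", "noise_robustness", "asymmetry_tolerance",
    "heterogeneity", "rotation",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated, fully serialisable description of one experiment run."""

    species: str = "fly"
    protocol: str = "bump_maintenance"
    sigma: float = DEFAULT_SIGMA
    include_peg: bool = True
    weights: str = "reference"      # 'reference' or a path to a weights JSON
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    protocol_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ConfigError(f"species must be one of {SPECIES}, "
                              f"got {self.species!r}")
        if self.protocol not in PROTOCOLS:
            raise ConfigError(f"protocol must be one of {PROTOCOLS}, "
                              f"got {self.protocol!r}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, "
                              f"got {self.seed!r}")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if not isinstance(self.protocol_params, dict):
            raise ConfigError("protocol_params must be a mapping")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_manifest(directory: str | Path, config: RunConfig,
                   extra: dict | None = None) -> Path:
    """Write a reproduction manifest (config + hash + package version)."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
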