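"""Run configuration: YAML loading, defaults and provenance manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import ConditionCalibration, StudyDesign, default_calibration

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 14
    icc: float = 0.5
    n_harmonics: int = 8
    samples: int = 128
    n_boot: int = 10_000
    df_method: str = "satterthwaite"
    heart_rates: dict = field(default_factory=dict)
    ess_targets: dict = field(default_factory=dict)  # "modality/intensity" -> [mean, sd]
    outdir: str = "results"

    def __post_init__(self):
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")

    def design(self) -> StudyDesign:
        return StudyDesign(n_participants=self.n_participants)

    def calibration(self) -> ConditionCalibration:
        overrides = None
        if self.ess_targets:
            from .synthetic import DEFAULT_ESS_TARGETS

            overrides = dict(DEFAULT_ESS_TARGETS)
            for key, (mean, sd) in self.ess_targets.items():
                modality, intensity = key.split("/")
                overrides[(modality, intensity)] = (float(mean), float(sd))
        return default_calibration(overrides, self.heart_rates or None)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_manifest(config: RunConfig, outdir: str | Path) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "package_version": __version__,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
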