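"""YAML analysis configuration and the JSON run manifest.

The config fixes every analysis choice that the protocol leaves open —
scored variables, reference group, scoring mode and bins, dispersion
convention, trajectory trimming and smoothing, tracker calibration — so a
run is fully described by (inputs, config, seed). Each CLI subcommand
writes a manifest recording exactly that.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .frailty import FrailtyConfig
from .locomotion import DEFAULT_RECORD_S, DEFAULT_SMOOTH_WINDOW, DEFAULT_TRIM_S


@dataclass(frozen=True)
class AnalysisConfig:
    """Full pipeline configuration with protocol defaults."""

    variables: tuple[str, ...] = (
        "total_distance_cm",
        "max_speed_cms",
        "mean_speed_cms",
        "bmi_gcm2",
    )
    reference_group: str = "2"
    mode: str = "absolute"
    bins: str = "literal"
    dispersion: str = "sd"  # or "sem", with dispersion_n to convert
    dispersion_n: int | None = None
    allow_missing: bool = False
    trim_s: float = DEFAULT_TRIM_S
    record_s: float = DEFAULT_RECORD_S
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    px_per_cm: float | None = None  # upstream tracker calibration, if any
    alpha: float = 0.05

    def frailty(self) -> FrailtyConfig:
        return FrailtyConfig(
            variables=tuple(self.variables),
            reference_group=self.reference_group,
            mode=self.mode,
            bins=self.bins,
            allow_missing=self.allow_missing,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | os.PathLike | None) -> AnalysisConfig:
    """Load a YAML config; missing keys fall back to protocol defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "variables" in raw:
        raw["variables"] = tuple(raw["variables"])
    return AnalysisConfig(**raw)


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable content hash of a configuration."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: str | os.PathLike,
    subcommand: str,
    cfg: AnalysisConfig,
    seed: int | None,
    inputs: list[str],
    extra: dict | None = None,
) -> str:
    """Write the JSON run manifest and return its path."""
    import numpy
    import pandas

    from . import __version__

    manifest = {
        "tool": "zebrafrail",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "inputs": [os.fspath(p) for p in inputs],
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = os.path.join(os.fspath(out_dir), "manifest.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
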