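"""Run configuration and manifests.

Every numeric constant of the analysis is config-visible: the 35%
count-threshold fraction, the 12-mm SPECT and 4-mm mask smoothing FWHMs,
the 0.5 mask binarization threshold, the extent threshold (Z >= 2.0), the
at-least-pathological regional cut (Z > 0.5), the display angles (10 deg
orbito-meatal, 34 deg hippocampal) and the global-mean reference.  Stages
record a manifest (config snapshot, package version, seeds, input hashes)
so identical reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "write_manifest", "sha256_of"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    analysis_threshold_frac: float = 0.35
    spect_fwhm_mm: float = 12.0
    mask_fwhm_mm: float = 4.0
    mask_binarize_threshold: float = 0.5
    z_extent: float = 2.0
    pathological_z_cut: float = 0.5
    om_angle_deg: float = 10.0
    hippocampal_angle_deg: float = 34.0
    global_mean_reference: float = 50.0
    sigma_floor_frac: float = 1e-3
    renormalize_in_mask: bool = False
    bootstrap_resamples: int = 2000
    seed: int = 0

    def __post_init__(self):
        checks = {
            "analysis_threshold_frac": 0.0 <= self.analysis_threshold_frac < 1.0,
            "spect_fwhm_mm": self.spect_fwhm_mm >= 0,
            "mask_fwhm_mm": self.mask_fwhm_mm >= 0,
            "mask_binarize_threshold": 0.0 < self.mask_binarize_threshold < 1.0,
            "z_extent": True,
            "pathological_z_cut": True,
            "om_angle_deg": -90 < self.om_angle_deg < 90,
            "hippocampal_angle_deg": -90 < self.hippocampal_angle_deg < 90,
            "global_mean_reference": self.global_mean_reference > 0,
            "sigma_floor_frac": self.sigma_floor_frac >= 0,
            "bootstrap_resamples": self.bootstrap_resamples >= 1,
        }
        for key, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid value for config key {key!r}: {getattr(self, key)}")

    @property
    def sigma_floor(self) -> float:
        return self.sigma_floor_frac * self.global_mean_reference

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: RunConfig,
                   inputs: dict[str, str | Path] | None = None,
                   extra: dict | None = None) -> Path:
    """Write a plain-text JSON manifest describing one pipeline stage run.

    ``inputs`` maps a logical name to an input file path; each entry is
    recorded with its SHA-256 content hash so identical reruns produce
    byte-identical manifests.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(path), "sha256": sha256_of(path)}
                   for name, path in (inputs or {}).items()},
        "extra": extra or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
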