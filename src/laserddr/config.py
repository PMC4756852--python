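"""YAML pipeline configuration: laser systems, medium constants, damage and
recruitment thresholds, quantification defaults.

An absent or empty file yields the built-in defaults (the two bundled
laser systems with water medium constants).  Validation is collected, not
fail-fast: a bad file raises one :class:`ConfigurationError` naming every
offending key.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .biophysics import DamageThresholds, MediumConstants
from .ddr_regime import RecruitmentThresholds
from .dosimetry import (
    BUILTIN_SYSTEMS,
    LaserSystemSpec,
    MacropulseStructure,
    PowerCalibration,
)
from .errors import ConfigurationError, LaserDDRError

__all__ = ["QuantifyDefaults", "PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class QuantifyDefaults:
    window_53bp1_min: float = 15.0
    window_trf2_min: float = 6.0
    detection_level: float = 0.1
    min_consecutive: int = 2

    def __post_init__(self) -> None:
        if self.window_53bp1_min <= 0 or self.window_trf2_min <= 0:
            raise ConfigurationError("detection windows must be > 0")
        if self.detection_level <= 0:
            raise ConfigurationError("detection_level must be > 0")
        if self.min_consecutive < 1:
            raise ConfigurationError("min_consecutive must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    systems: dict[str, LaserSystemSpec] = field(
        default_factory=lambda: dict(BUILTIN_SYSTEMS)
    )
    medium: MediumConstants = field(default_factory=MediumConstants)
    damage_thresholds: DamageThresholds = field(default_factory=DamageThresholds)
    recruitment_thresholds: RecruitmentThresholds = field(
        default_factory=RecruitmentThresholds
    )
    quantify: QuantifyDefaults = field(default_factory=QuantifyDefaults)
    seed: int = 0

    def system(self, name: str) -> LaserSystemSpec:
        try:
            return self.systems[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown system {name!r}; configured: {sorted(self.systems)}"
            ) from None


def _build_system(entry: dict, errors: list[str], idx: int) -> LaserSystemSpec | None:
    key = f"systems[{idx}]"
    try:
        cal_raw = dict(entry.pop("calibration"))
        if "rows" in cal_raw and cal_raw["rows"] is not None:
            cal_raw["rows"] = tuple(tuple(map(float, r)) for r in cal_raw["rows"])
        calibration = PowerCalibration(**cal_raw)
        macropulse = None
        if entry.get("macropulse") is not None:
            macropulse = MacropulseStructure(**entry.pop("macropulse"))
        else:
            entry.pop("macropulse", None)
        return LaserSystemSpec(calibration=calibration, macropulse=macropulse, **entry)
    except (KeyError, TypeError) as exc:
        errors.append(f"{key}: missing or misnamed field ({exc})")
    except LaserDDRError as exc:
        errors.append(f"{key}: {exc}")
    return None


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration, applying YAML overrides to defaults."""
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {p}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError("config root must be a mapping")
        raw = loaded

    errors: list[str] = []
    known = {
        "systems",
        "medium",
        "damage_thresholds",
        "recruitment_thresholds",
        "quantify",
        "seed",
    }
    for k in raw:
        if k not in known:
            errors.append(f"unknown top-level key {k!r}")

    systems = dict(BUILTIN_SYSTEMS)
    for i, entry in enumerate(raw.get("systems") or []):
        spec = _build_system(dict(entry), errors, i)
        if spec is not None:
            systems[spec.name] = spec

    def _section(name: str, cls, **extra):
        data = raw.get(name)
        if data is None:
            return cls(**extra)
        try:
            return cls(**{**extra, **data})
        except TypeError as exc:
            errors.append(f"{name}: misnamed field ({exc})")
        except LaserDDRError as exc:
            errors.append(f"{name}: {exc}")
        return cls(**extra)

    medium = _section("medium", MediumConstants)
    damage = _section("damage_thresholds", DamageThresholds)
    rec_raw = raw.get("recruitment_thresholds") or {}
    try:
        if "per_system" in rec_raw:
            rec_raw = dict(rec_raw)
            rec_raw["per_system"] = {
                k: tuple(map(float, v)) for k, v in rec_raw["per_system"].items()
            }
        recruitment = RecruitmentThresholds(**rec_raw)
    except (TypeError, LaserDDRError) as exc:
        errors.append(f"recruitment_thresholds: {exc}")
        recruitment = RecruitmentThresholds()
    quantify = _section("quantify", QuantifyDefaults)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    if errors:
        raise ConfigurationError("; ".join(errors))
    return PipelineConfig(
        systems=systems,
        medium=medium,
        damage_thresholds=damage,
        recruitment_thresholds=recruitment,
        quantify=quantify,
        seed=seed,
    )


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
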