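"""Run configuration: a schema-validated view over the module parameter
dataclasses, loadable from YAML/JSON.  Unknown keys are rejected so typos
cannot silently fall back to defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .blood import BloodKineticsParams
from .cohort import CohortParams, FociGeneratorParams
from .kinetics import DsbKineticsParams

__all__ = ["ConfigError", "DosimetryConfig", "StatsConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class DosimetryConfig:
    """Settings of the dosimetry stage: tube-SAF Monte Carlo size, the
    whole-body photon absorbed fraction, and the per-sample tube volume
    range."""

    saf_histories: int = 100_000
    phi_gamma_body: float = 0.33
    tube_volume_range_ml: tuple[float, float] = (3.0, 7.5)

    def __post_init__(self) -> None:
        if self.saf_histories < 1000:
            raise ConfigError("saf_histories must be at least 1000")
        if not 0 < self.phi_gamma_body < 1:
            raise ConfigError("phi_gamma_body must be in (0, 1)")
        lo, hi = self.tube_volume_range_ml
        if not 0 < lo < hi:
            raise ConfigError("tube_volume_range_ml must be an increasing positive pair")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    power_n_per_arm: int = 10
    power_effect_sd_multiple: float = 1.5
    power_n_reps: int = 5000
    power_effect_on_variance_scale: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.power_n_per_arm < 2:
            raise ConfigError("power_n_per_arm must be >= 2")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a simulated study run."""

    seed: int = 0
    outdir: str = "study_out"
    tac_noise_cv: float = 0.05
    cohort: CohortParams = field(default_factory=CohortParams)
    kinetics: BloodKineticsParams = field(default_factory=BloodKineticsParams)
    dsb: DsbKineticsParams = field(default_factory=DsbKineticsParams)
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)
    foci: FociGeneratorParams = field(default_factory=FociGeneratorParams)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.tac_noise_cv < 0:
            raise ConfigError("tac_noise_cv must be non-negative")


_BLOCKS = {
    "cohort": CohortParams,
    "kinetics": BloodKineticsParams,
    "dsb": DsbKineticsParams,
    "dosimetry": DosimetryConfig,
    "foci": FociGeneratorParams,
    "stats": StatsConfig,
}
_SCALARS = ("seed", "outdir", "tac_noise_cv")


def _coerce(value: Any, target_type: Any) -> Any:
    # YAML yields lists; tuple-typed dataclass fields need tuples
    if isinstance(value, list):
        return tuple(_coerce(v, None) for v in value)
    return value


def _build_block(cls: type, data: dict, block: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"block {block!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in block {block!r}: {sorted(unknown)}")
    if block == "cohort" and "arms" in data:
        raise ConfigError("overriding the arm allocation is not supported via config")
    try:
        return replace(cls(), **{k: _coerce(v, None) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in block {block!r}: {exc}") from exc


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a :class:`RunConfig` from a nested dict, rejecting unknown keys."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_BLOCKS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key in _SCALARS:
        if key in data:
            kwargs[key] = data[key]
    for block, cls in _BLOCKS.items():
        if block in data:
            kwargs[block] = _build_block(cls, data[block], block)
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: RunConfig) -> dict:
    """Plain-dict form of a config (tuples as lists), for manifests."""
    def unpack(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: unpack(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [unpack(v) for v in obj]
        return obj

    return unpack(config)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) run configuration."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # raises yaml.YAMLError on malformed input
    return config_from_dict(data)
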