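"""YAML experiment configuration: schema, defaults and validation.

An experiment file holds optional blocks ``optics``, ``scene``,
``corrections``, ``observers`` and ``analysis`` plus a global ``seed``.
Every random draw in a run is traceable to that seed (observer seeds are
spawned from it unless given explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from . import corrections as corr
from .observer import ObserverParams, default_cohort
from .optics import OpticalConfig

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in an experiment file."""


_OPTICS_KEYS = {
    "pupil_diameter", "wavelength", "pupil_grid", "pad_factor",
    "field_of_view", "max_defocus",
}
_SCENE_KEYS = {
    "seed", "background", "display", "glyph_luminance", "upper_fraction",
    "margin_fraction", "glyph_arcmin",
}
_ANALYSIS_KEYS = {
    "tolerance", "energy_mode", "binocular_rule", "metric", "demand_mode",
    "score_repetitions", "choice_repetitions",
}
_OBSERVER_KEYS = {
    "subject_id", "gain", "bias", "score_noise_sd", "choice_noise_sd",
    "distance_weights", "seed",
}
_TOP_KEYS = {"optics", "scene", "corrections", "observers", "analysis", "seed"}


@dataclass
class ExperimentConfig:
    """Validated experiment settings with defaults for every block."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    scene: dict[str, Any] = field(default_factory=dict)
    observers: list[ObserverParams] = field(default_factory=list)
    analysis: dict[str, Any] = field(default_factory=dict)
    custom_profiles: dict[str, corr.TemporalPowerProfile] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.observers:
            self.observers = default_cohort(base_seed=self.seed)
        self.analysis = {
            "tolerance": corr.DEFAULT_TOLERANCE,
            "energy_mode": "mean",
            "binocular_rule": "better_eye",
            "metric": "contrast",
            "demand_mode": "nominal",
            "score_repetitions": 3,
            "choice_repetitions": 6,
            **self.analysis,
        }
        self.scene = {"seed": self.seed, **self.scene}

    def catalog(self) -> list[corr.BinocularCorrection]:
        catalog = corr.build_catalog()
        if self.custom_profiles:
            profiles = {**corr.standard_profiles(), **self.custom_profiles}
            catalog = [
                corr.BinocularCorrection(
                    label=c.label,
                    dominant=profiles[c.dominant.label],
                    nondominant=profiles[c.nondominant.label],
                )
                for c in catalog
            ]
        return catalog


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{where}' block; "
            f"allowed: {sorted(allowed)}"
        )


def _parse_observers(items: list, global_seed: int) -> list[ObserverParams]:
    rng = np.random.default_rng(global_seed)
    observers = []
    for i, item in enumerate(items):
        if not isinstance(item, dict):
            raise ConfigError(f"observers[{i}] must be a mapping")
        _check_keys(item, _OBSERVER_KEYS, f"observers[{i}]")
        item = dict(item)
        item.setdefault("subject_id", f"S{i + 1}")
        item.setdefault("seed", int(rng.integers(2**31 - 1)))
        if "distance_weights" in item:
            item["distance_weights"] = tuple(float(w) for w in item["distance_weights"])
        try:
            observers.append(ObserverParams(**item))
        except ValueError as exc:
            raise ConfigError(f"observers[{i}]: {exc}") from exc
    return observers


def parse_config(data: dict | None) -> ExperimentConfig:
    """Validate a parsed YAML mapping into an :class:`ExperimentConfig`."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("experiment config must be a mapping")
    _check_keys(data, _TOP_KEYS, "top-level")
    seed = int(data.get("seed", 0))

    optics_block = data.get("optics", {}) or {}
    _check_keys(optics_block, _OPTICS_KEYS, "optics")
    try:
        optics = OpticalConfig(**optics_block)
    except ValueError as exc:
        raise ConfigError(f"optics: {exc}") from exc

    scene_block = dict(data.get("scene", {}) or {})
    _check_keys(scene_block, _SCENE_KEYS, "scene")

    analysis_block = dict(data.get("analysis", {}) or {})
    _check_keys(analysis_block, _ANALYSIS_KEYS, "analysis")

    custom = {}
    for spec in data.get("corrections", []) or []:
        try:
            profile = corr.profile_from_dict(spec)
        except ValueError as exc:
            raise ConfigError(f"corrections: {exc}") from exc
        custom[profile.label] = profile

    observers = _parse_observers(data.get("observers", []) or [], seed)
    return ExperimentConfig(
        optics=optics,
        scene=scene_block,
        observers=observers,
        analysis=analysis_block,
        custom_profiles=custom,
        seed=seed,
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config '{path}': {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in '{path}': {exc}") from exc
    return parse_config(data)
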