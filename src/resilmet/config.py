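"""Configuration objects for the synthetic cohort generator and the pipeline.

All tunable parameters live in two frozen dataclasses so that every default
is documented in exactly one place.  :func:`load_config` reads a YAML (or
JSON) mapping, rejects unknown keys, and type-checks every override.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["GeneratorConfig", "PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised when a configuration document or field is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic longitudinal serum-metabolomics cohort.

    The cohort emulates a population-based aging study: ~237 participants,
    three serum-sampling visits spaced ~7.5 years apart, a composite
    cognitive z-score declining 0.7 SD per decade after age 70 on average,
    and an untargeted LC-MS feature table with zero inflation induced by a
    detection limit.

    Units are noted per field; log-abundances are natural-log peak areas.
    """

    # --- cohort ---
    n_participants: int = 237
    n_visits: int = 3
    baseline_age_mean: float = 70.0      # years
    baseline_age_sd: float = 3.0         # years
    visit_spacing: float = 7.5           # years between consecutive visits
    population_slope: float = -0.7       # SD-units per decade
    slope_sd: float = 0.3                # between-person slope SD, SD/decade
    intercept_sd: float = 0.3            # between-person intercept SD, SD-units
    slope_intercept_corr: float = 0.0
    resid_sd: float = 0.25               # occasion-level residual SD, SD-units
    sex_effect: float = 0.2              # fixed offset for female, SD-units
    education_effect: float = 0.05       # SD-units per year of education (centered at 12)
    female_fraction: float = 0.64

    # --- feature table ---
    n_features: int = 500
    n_age_features: int = 25
    n_resilience_features: int = 25
    effect_size_age: float = 0.03        # log-abundance per year of age
    effect_size_resilience: float = 1.0  # log-abundance per unit resilience (SD/decade)
    feature_log_mean_low: float = math.log(2e4)   # ln(peak area)
    feature_log_mean_high: float = math.log(2e6)
    feature_log_sd: float = 0.5          # visit-level log-abundance SD
    detection_limit: float = 3e4         # peak-area units; areas below → 0
    blank_level: float = 1e3             # peak-area units in blank channels
    n_blanks: int = 6
    n_contaminants: int = 10             # blank-dominated features
    mz_min: float = 150.0                # Da
    mz_max: float = 1500.0
    rt_max: float = 12.5                 # minutes
    early_rt_fraction: float = 0.1       # fraction of features eluting < 0.7 min

    # --- spectra ---
    n_glucuronides: int = 8
    n_metabolites_per_parent: int = 3
    n_shared_fragments: int = 3          # backbone fragments carried by metabolites
    fragment_noise_sd: float = 0.002     # Da, instrument noise on fragment m/z

    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "n_participants", "n_visits", "baseline_age_sd", "visit_spacing",
            "slope_sd", "intercept_sd", "resid_sd", "n_features",
            "feature_log_sd", "n_blanks",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"GeneratorConfig.{name} must be strictly positive")
        nonneg = [
            "detection_limit", "blank_level", "n_age_features",
            "n_resilience_features", "n_contaminants", "n_glucuronides",
            "n_metabolites_per_parent", "fragment_noise_sd",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"GeneratorConfig.{name} must be non-negative")
        if self.n_age_features + self.n_resilience_features > self.n_features:
            raise ConfigError(
                "GeneratorConfig.n_age_features + n_resilience_features must "
                "not exceed n_features"
            )
        if abs(self.slope_intercept_corr) > 1:
            raise ConfigError("GeneratorConfig.slope_intercept_corr must lie in [-1, 1]")
        if not 0 <= self.female_fraction <= 1:
            raise ConfigError("GeneratorConfig.female_fraction must lie in [0, 1]")
        if not 0 <= self.early_rt_fraction <= 1:
            raise ConfigError("GeneratorConfig.early_rt_fraction must lie in [0, 1]")

    def replace(self, **kwargs: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-stage parameters (preprocessing, sparse PLS, statistics)."""

    rt_min_minutes: float = 0.7          # dead-volume cutoff
    blank_factor: float = 5.0            # sample/blank ratio required to keep
    blank_aggregate: str = "mean"        # mean | max over non-zero samples
    min_presence_spls: float = 0.4       # resilience branch presence fraction
    min_presence_lmm: float = 0.3        # aging branch presence fraction
    nzv_var_eps: float = 1e-8
    nzv_dominance: float = 0.95
    scale_features: bool = True          # unit-variance columns before sPLS
    keep: int | None = None              # None → tuned
    folds: int = 10
    n_permutations: int = 100
    hurdle_min_group: int = 5
    query_tol_da: float = 0.01
    min_matched_fragments: int = 3
    selection_rule: str = "require_singular"     # aging-branch reporting rule

    def __post_init__(self) -> None:
        if self.blank_aggregate not in ("mean", "max"):
            raise ConfigError("PipelineConfig.blank_aggregate must be 'mean' or 'max'")
        if self.selection_rule not in ("require_singular", "require_nonsingular"):
            raise ConfigError(
                "PipelineConfig.selection_rule must be 'require_singular' or "
                "'require_nonsingular'"
            )
        if not 0 < self.min_presence_spls <= 1:
            raise ConfigError("PipelineConfig.min_presence_spls must lie in (0, 1]")
        if not 0 < self.min_presence_lmm <= 1:
            raise ConfigError("PipelineConfig.min_presence_lmm must lie in (0, 1]")


_SECTIONS = {"generator": GeneratorConfig, "pipeline": PipelineConfig}


def _coerce(cls: type, key: str, value: Any) -> Any:
    ftypes = {f.name: f.type for f in fields(cls)}
    if key not in ftypes:
        raise ConfigError(f"unknown configuration key '{key}' for {cls.__name__}")
    if isinstance(value, bool):
        if "bool" not in str(ftypes[key]):
            raise ConfigError(f"key '{key}' expects a number, got boolean")
        return value
    expected = str(ftypes[key])
    if "int" in expected and not expected.startswith("str"):
        if isinstance(value, int):
            return value
        if isinstance(value, float) and value.is_integer():
            return int(value)
        if "None" in expected and value is None:
            return None
        raise ConfigError(f"key '{key}' expects an integer, got {value!r}")
    if "float" in expected:
        if isinstance(value, (int, float)):
            return float(value)
        raise ConfigError(f"key '{key}' expects a number, got {value!r}")
    if expected.startswith("str"):
        if isinstance(value, str):
            return value
        raise ConfigError(f"key '{key}' expects a string, got {value!r}")
    if expected.startswith("bool"):
        raise ConfigError(f"key '{key}' expects a boolean, got {value!r}")
    return value


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None,
                ) -> dict[str, Any]:
    """Load a YAML/JSON config document into validated dataclasses.

    The document has two optional top-level sections, ``generator`` and
    ``pipeline``; an empty document yields all defaults.  Unknown keys and
    type mismatches raise :class:`ConfigError` naming the key.
    """
    doc: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a mapping")
        doc = loaded
    if overrides:
        for sect, vals in overrides.items():
            doc.setdefault(sect, {}).update(vals)

    out: dict[str, Any] = {}
    for sect, payload in doc.items():
        if sect not in _SECTIONS:
            raise ConfigError(
                f"unknown configuration section '{sect}' "
                f"(expected one of {sorted(_SECTIONS)})"
            )
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section '{sect}' must be a mapping")
        cls = _SECTIONS[sect]
        kwargs = {k: _coerce(cls, k, v) for k, v in payload.items()}
        out[sect] = cls(**kwargs)
    out.setdefault("generator", GeneratorConfig())
    out.setdefault("pipeline", PipelineConfig())
    return out
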