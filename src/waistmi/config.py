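"""Shared configuration objects for the simulation pipeline.

All tunable quantities live in small dataclasses with defaults that define
the study conditions: a cohort of middle-aged adults (40-69 y at baseline),
paired waist-circumference measurements 13 years apart with marginal
correlation 0.81, and Weibull proportional-hazards event generation for
colorectal cancer (the outcome) and death (a censoring cause).

Configs can be loaded from YAML via :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "CATEGORY_LEVELS",
    "DESIGN_COLUMNS",
    "CohortConfig",
    "ConfigurationError",
    "load_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


#: Levels of each categorical covariate, reference level first.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "education": ("none_primary", "secondary_trade", "tertiary"),
    "cob": ("aus_nz", "uk", "mediterranean"),
    "smoking": ("never", "former", "current"),
    "physical": ("none", "low", "moderate", "high"),
    "alcohol": ("none", "low", "moderate", "high"),
}

#: Fixed column order of the covariate design matrix (k-1 dummies per
#: categorical, reference level dropped). Every model in the pipeline that
#: conditions on the baseline covariates uses this ordering.
DESIGN_COLUMNS: tuple[str, ...] = (
    "age",
    "female",
    "education_secondary_trade",
    "education_tertiary",
    "cob_uk",
    "cob_mediterranean",
    "smoking_former",
    "smoking_current",
    "physical_low",
    "physical_moderate",
    "physical_high",
    "alcohol_low",
    "alcohol_moderate",
    "alcohol_high",
)


def _default_prevalences() -> dict[str, tuple[float, ...]]:
    return {
        "education": (0.30, 0.45, 0.25),
        "cob": (0.70, 0.10, 0.20),
        "smoking": (0.55, 0.30, 0.15),
        "physical": (0.25, 0.25, 0.25, 0.25),
        "alcohol": (0.30, 0.40, 0.20, 0.10),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Marginal distributions of the baseline covariates.

    ``female_prevalence`` defaults to 0.59, the published cohort composition
    (24,469 women of 41,514 participants); the categorical prevalences are
    round plausible values for an Australian cohort of this era and are not
    claims about any real dataset. Age is uniform on [age_min, age_max].
    ``wave_gap`` is the fixed number of years between the two measurement
    waves.
    """

    n: int = 41_476
    age_min: float = 40.0
    age_max: float = 69.0
    female_prevalence: float = 0.59
    prevalences: dict[str, tuple[float, ...]] = field(
        default_factory=_default_prevalences
    )
    wave_gap: float = 13.0

    def __post_init__(self) -> None:
        if self.age_max <= self.age_min:
            raise ConfigurationError("age_max must exceed age_min")
        if not 0.0 <= self.female_prevalence <= 1.0:
            raise ConfigurationError("female_prevalence must lie in [0, 1]")
        for name, levels in CATEGORY_LEVELS.items():
            p = np.asarray(self.prevalences.get(name, ()), dtype=float)
            if p.size != len(levels):
                raise ConfigurationError(
                    f"prevalence vector for {name!r} must have "
                    f"{len(levels)} entries, got {p.size}"
                )
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"prevalence vector for {name!r} must be non-negative "
                    f"and sum to 1 (got sum {p.sum()!r})"
                )

    def with_n(self, n: int) -> "CohortConfig":
        return replace(self, n=n)


def load_config(path) -> dict:
    """Read a structured-text (YAML) configuration file.

    Recognised top-level sections mirror the pipeline stages: ``cohort``,
    ``exposure``, ``events``, ``missingness``, ``mi``. Returns the raw
    mapping; stage constructors consume the sections they understand.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return data
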