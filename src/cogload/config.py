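"""Validated configuration for the synthetic-cohort generator and pipeline.

The defaults encode the study conditions of the source sample: n = 81
participants aged 50-69 (66.7 % women), raw-measure marginals matching the
published descriptive tables, and standardized effects of reserve, load, sex
and age on latent cognition of the size suggested by the published models.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from ._errors import ConfigurationError
from .marginals import DEFAULT_MARGINALS, Marginal

__all__ = ["CohortConfig", "config_hash", "load_config"]


class MarginalSpec(BaseModel):
    """Pydantic mirror of :class:`cogload.marginals.Marginal`."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(gt=0)
    lo: float
    hi: float

    @field_validator("hi")
    @classmethod
    def _ordered(cls, v: float, info: Any) -> float:
        if "lo" in info.data and v <= info.data["lo"]:
            raise ValueError("hi must exceed lo")
        return v

    def to_marginal(self) -> Marginal:
        return Marginal(self.mean, self.sd, self.lo, self.hi)


def _default_marginals() -> dict[str, MarginalSpec]:
    return {
        name: MarginalSpec(mean=m.mean, sd=m.sd, lo=m.lo, hi=m.hi)
        for name, m in DEFAULT_MARGINALS.items()
    }


class CohortConfig(BaseModel):
    """Generator configuration; identical (config, seed) pairs are reproducible.

    Effects are standardized slopes of latent cognition on the (unit-variance)
    latent traits; ``effect_sex`` is the standardized male-minus-female mean
    difference with sex coded 0 = female, 1 = male, so the published
    female-advantage corresponds to a negative value.
    """

    model_config = ConfigDict(frozen=True, validate_default=True)

    n_participants: int = Field(default=81, ge=2)
    seed: int = Field(default=0, ge=0)
    prop_female: float = Field(default=54.0 / 81.0, ge=0.0, le=1.0)
    age_range: tuple[float, float] = (50.0, 69.0)
    effect_cr: float = 0.3
    effect_al: float = -0.2
    effect_sex: float = -0.5
    effect_age: float = -0.1
    noise_sd: float = Field(default=0.9, gt=0)
    marginals: dict[str, MarginalSpec] = Field(default_factory=_default_marginals)

    @field_validator("age_range")
    @classmethod
    def _age_ordered(cls, v: tuple[float, float]) -> tuple[float, float]:
        if v[0] >= v[1]:
            raise ValueError("age_range must satisfy min < max")
        return v

    def resolved_marginals(self) -> dict[str, Marginal]:
        out = {name: spec.to_marginal() for name, spec in self.marginals.items()}
        age = out["age"]
        if (age.lo, age.hi) != self.age_range:
            out["age"] = Marginal(age.mean, age.sd, *self.age_range)
        return out


def make_config(**kwargs: Any) -> CohortConfig:
    """Build a config, turning validation failures into ConfigurationError."""
    try:
        return CohortConfig(**kwargs)
    except ValidationError as exc:
        fields = ", ".join(str(err["loc"][0]) for err in exc.errors())
        raise ConfigurationError(f"invalid configuration field(s): {fields}") from exc


def config_hash(config: CohortConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str) -> CohortConfig:
    """Read a YAML/JSON key-value config file and validate it."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path!r} must contain a mapping")
    return make_config(**data)
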