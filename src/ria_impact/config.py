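"""Run configuration with schema validation (unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .effect_classifier import ClassifierConfig
from .ria_engine import AdjudicationPolicy, ReassessFlags


class EquivalenceRange(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low: float = 0.9
    high: float = 1.11

    @model_validator(mode="after")
    def _ordered(self):
        if not 0 < self.low < self.high:
            raise ValueError("require 0 < low < high")
        return self


class ReassessFlagsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    discrepant: bool = True
    consistent_non_no_concern: bool = True
    single_rating: bool = True
    no_rating: bool = True


class RunConfig(BaseModel):
    """All tunable pipeline parameters with their published defaults."""

    model_config = ConfigDict(extra="forbid")

    equivalence_range: EquivalenceRange = Field(
        default_factory=EquivalenceRange
    )
    pooling_method: str = "random_dl"
    measure: str = "RR"
    quantile_method: str = "linear"
    percent_decimals: int = 1
    response_window_days: int = 14
    reminder_extension_days: int = 7
    always_reassess_domains: list[int] = Field(default=[1, 2, 3])
    reassess_on: ReassessFlagsConfig = Field(
        default_factory=ReassessFlagsConfig
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.pooling_method not in ("fixed_iv", "random_dl"):
            raise ValueError(f"unknown pooling method {self.pooling_method!r}")
        if self.measure not in ("RR", "OR"):
            raise ValueError(f"unknown measure {self.measure!r}")
        bad = set(self.always_reassess_domains) - set(range(1, 7))
        if bad:
            raise ValueError(f"invalid adjudication domains {sorted(bad)}")
        if self.response_window_days < 0 or self.reminder_extension_days < 0:
            raise ValueError("response windows must be nonnegative")
        return self

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            range_low=self.equivalence_range.low,
            range_high=self.equivalence_range.high,
        )

    def adjudication_policy(self) -> AdjudicationPolicy:
        return AdjudicationPolicy(
            always_reassess_domains=frozenset(self.always_reassess_domains),
            reassess_on=ReassessFlags(**self.reassess_on.model_dump()),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.model_validate(data or {})
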