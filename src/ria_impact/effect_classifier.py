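"""Equivalence-range classification of pooled ratio effects.

A pooled RR/OR is judged against a prespecified equivalence range
(default 0.9-1.11, symmetric on the log-odds of a ratio):

* direction — where the point estimate sits: inside the closed range means
  no or minimal effect; below/above means benefit or harm depending on the
  outcome's polarity (for mortality a ratio < 0.9 is a benefit, for
  clinical improvement it is a harm);
* precision — precise when the 95% CI lies entirely within one side
  (touching a boundary does not count as crossing), imprecise when the CI
  strictly crosses at least one boundary;
* interpretation — the (direction, precision) pair, e.g. "precise benefit"
  or "imprecise no or minimal effect", or "not estimable".

Comparing the classification of the original meta-analysis with the
integrity-restricted sensitivity re-analysis yields a change report over
those three dimensions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .meta_engine import EffectEstimate, Polarity


class Direction(str, enum.Enum):
    BENEFIT = "benefit"
    HARM = "harm"
    NO_OR_MINIMAL = "no_or_minimal"


class Precision(str, enum.Enum):
    PRECISE = "precise"
    IMPRECISE = "imprecise"


@dataclass(frozen=True)
class ClassifierConfig:
    """Equivalence range on the ratio scale (closed interval)."""

    range_low: float = 0.9
    range_high: float = 1.11

    def __post_init__(self):
        if not 0 < self.range_low < self.range_high:
            raise ValueError(
                f"require 0 < range_low < range_high, got "
                f"[{self.range_low}, {self.range_high}]"
            )


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class EffectClass:
    """Direction/precision classification of one effect estimate."""

    direction: Optional[Direction]
    precision: Optional[Precision]
    not_estimable: bool = False

    @property
    def interpretation(self) -> str:
        if self.not_estimable:
            return "not_estimable"
        return f"{self.precision.value}_{self.direction.value}"


NOT_ESTIMABLE = EffectClass(None, None, not_estimable=True)


def classify_direction(
    point: float,
    polarity: Polarity | str = Polarity.LOWER_IS_BENEFIT,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> Direction:
    """Direction of a point estimate relative to the equivalence range."""
    if point <= 0:
        raise ValueError(f"ratio point estimate must be positive, got {point}")
    polarity = Polarity(polarity)
    if config.range_low <= point <= config.range_high:
        return Direction.NO_OR_MINIMAL
    below = point < config.range_low
    if polarity is Polarity.LOWER_IS_BENEFIT:
        return Direction.BENEFIT if below else Direction.HARM
    return Direction.HARM if below else Direction.BENEFIT


def classify_precision(
    ci_low: float,
    ci_high: float,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> Precision:
    """Precision of a 95% CI relative to the equivalence range.

    The CI is imprecise iff its open interval strictly contains a range
    boundary; an endpoint sitting exactly on a boundary is not a crossing.
    """
    if not 0 < ci_low <= ci_high:
        raise ValueError(f"invalid CI [{ci_low}, {ci_high}]")
    crosses = any(
        ci_low < bound < ci_high
        for bound in (config.range_low, config.range_high)
    )
    return Precision.IMPRECISE if crosses else Precision.PRECISE


def interpret(
    estimate: EffectEstimate,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> EffectClass:
    """Full classification of an effect estimate (passthrough when absent)."""
    if not estimate.estimable:
        return NOT_ESTIMABLE
    return EffectClass(
        direction=classify_direction(estimate.point, estimate.polarity,
                                     config),
        precision=classify_precision(estimate.ci_low, estimate.ci_high,
                                     config),
    )


@dataclass(frozen=True)
class ChangeReport:
    """Original-vs-sensitivity deltas over the three dimensions."""

    direction_changed: bool
    precision_changed: bool
    interpretation_changed: bool
    became_not_estimable: bool


def compare(original: EffectClass, sensitivity: EffectClass) -> ChangeReport:
    """Detect changes between the original and sensitivity classification."""
    became_ne = sensitivity.not_estimable and not original.not_estimable
    if original.not_estimable or sensitivity.not_estimable:
        dir_changed = became_ne or (
            original.not_estimable and not sensitivity.not_estimable
        )
        prec_changed = dir_changed
    else:
        dir_changed = original.direction is not sensitivity.direction
        prec_changed = original.precision is not sensitivity.precision
    return ChangeReport(
        direction_changed=dir_changed,
        precision_changed=prec_changed,
        interpretation_changed=(
            original.interpretation != sensitivity.interpretation
        ),
        became_not_estimable=became_ne,
    )


def color_token(
    point: float,
    ci_low: float,
    ci_high: float,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> str:
    """Report-rendering color for an estimate.

    Hue encodes the point's position (green below the range, yellow inside,
    red above); dark means precise, light imprecise.
    """
    if point < config.range_low:
        hue = "green"
    elif point > config.range_high:
        hue = "red"
    else:
        hue = "yellow"
    shade = (
        "dark"
        if classify_precision(ci_low, ci_high, config) is Precision.PRECISE
        else "light"
    )
    return f"{shade}_{hue}"
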