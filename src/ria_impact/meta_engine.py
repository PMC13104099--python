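"""Per-trial binary effect estimates and inverse-variance pooling.

Each trial contributes a 2x2 table (events / arm sizes).  Effects are the
risk ratio (RR) or odds ratio (OR) on the log scale with the standard
delta-method variances; a 0.5 continuity correction is added to all four
cells whenever any cell is zero, and trials with zero events in both arms
carry no information about a ratio and are dropped from pooling.

Pooling supports the common-effect inverse-variance model and the
DerSimonian-Laird random-effects model (moment estimator of the
between-trial variance tau^2), with Wald 95% confidence intervals
(z = 1.96) exponentiated back to the ratio scale — the configuration the
source systematic reviews report as their headline analyses.

The sensitivity re-analysis re-pools a meta-analysis restricted to trials
whose final research-integrity classification is "no concern".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import NoComparisonError, UnassessedStudyError
from .ria_engine import StudyAssessment, Verdict

Z_95 = 1.96  # normal quantile used for all 95% intervals


class Measure(str, enum.Enum):
    RR = "RR"
    OR = "OR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Polarity(str, enum.Enum):
    """Which direction of a ratio favours the intervention.

    Mortality-style outcomes benefit from ratios below 1
    (``lower_is_benefit``); improvement-style outcomes from ratios above 1.
    """

    LOWER_IS_BENEFIT = "lower_is_benefit"
    HIGHER_IS_BENEFIT = "higher_is_benefit"


class PoolingMethod(str, enum.Enum):
    FIXED_IV = "fixed_iv"
    RANDOM_DL = "random_dl"


@dataclass(frozen=True)
class TrialOutcomeTable:
    """2x2 event counts for one trial's binary outcome."""

    study_id: str
    events_intervention: int
    n_intervention: int
    events_control: int
    n_control: int
    outcome_name: str = ""
    patient_relevant: bool = True

    def __post_init__(self):
        for events, n, arm in (
            (self.events_intervention, self.n_intervention, "intervention"),
            (self.events_control, self.n_control, "control"),
        ):
            if n < 1:
                raise ValueError(
                    f"{self.study_id!r}: {arm} arm must randomize >= 1"
                )
            if not 0 <= events <= n:
                raise ValueError(
                    f"{self.study_id!r}: {arm} events {events} outside "
                    f"[0, {n}]"
                )

    @property
    def double_zero(self) -> bool:
        return self.events_intervention == 0 and self.events_control == 0

    @property
    def n_total(self) -> int:
        return self.n_intervention + self.n_control


@dataclass(frozen=True)
class LogEffect:
    """Log-scale trial effect with its standard error."""

    study_id: str
    measure: Measure
    y: float
    se: float
    estimable: bool = True
    zero_corrected: bool = False


def trial_effect(table: TrialOutcomeTable, measure: Measure | str = Measure.RR
                 ) -> LogEffect:
    """Log RR/OR and SE for one 2x2 table.

    RR = (a/n1)/(c/n2),  SE(logRR) = sqrt(1/a - 1/n1 + 1/c - 1/n2)
    OR = ad/bc,          SE(logOR) = sqrt(1/a + 1/b + 1/c + 1/d)

    A 0.5 continuity correction is added to all four cells when any cell is
    zero.  Double-zero trials are flagged non-estimable (non-contributing)
    rather than raising.
    """
    measure = Measure(measure)
    if table.double_zero:
        return LogEffect(table.study_id, measure, math.nan, math.nan,
                         estimable=False)
    a = float(table.events_intervention)
    c = float(table.events_control)
    b = float(table.n_intervention) - a
    d = float(table.n_control) - c
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n1, n2 = a + b, c + d
    if measure is Measure.RR:
        y = math.log((a / n1) / (c / n2))
        se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    else:
        y = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return LogEffect(table.study_id, measure, y, se, estimable=True,
                     zero_corrected=corrected)


@dataclass(frozen=True)
class EffectEstimate:
    """Ratio-scale pooled (or single-trial) effect with 95% CI."""

    measure: Measure
    estimable: bool
    k_trials: int
    point: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    polarity: Polarity = Polarity.LOWER_IS_BENEFIT

    def __post_init__(self):
        if self.estimable:
            if None in (self.point, self.ci_low, self.ci_high):
                raise ValueError("estimable effect requires point and CI")
            if not self.ci_low <= self.point <= self.ci_high:
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"point {self.point}"
                )


@dataclass(frozen=True)
class PoolingResult:
    effect: EffectEstimate
    method: PoolingMethod
    tau_squared: float = 0.0
    q_statistic: float = 0.0
    pooled_log: Optional[float] = None
    pooled_se: Optional[float] = None


def pool(
    effects: Iterable[LogEffect],
    method: PoolingMethod | str = PoolingMethod.RANDOM_DL,
    measure: Measure | str = Measure.RR,
    polarity: Polarity | str = Polarity.LOWER_IS_BENEFIT,
) -> PoolingResult:
    """Inverse-variance pooling of log-scale effects.

    Non-estimable inputs are dropped.  With no contributing trial the
    result is flagged not estimable; a single trial is returned as-is with
    tau^2 = 0 (reviews do print one-trial "pooled" rows).
    """
    method = PoolingMethod(method)
    measure = Measure(measure)
    polarity = Polarity(polarity)
    ys, vs = [], []
    for e in effects:
        if e.estimable and math.isfinite(e.y) and math.isfinite(e.se):
            ys.append(e.y)
            vs.append(e.se ** 2)
    k = len(ys)
    if k == 0:
        return PoolingResult(
            effect=EffectEstimate(measure, estimable=False, k_trials=0,
                                  polarity=polarity),
            method=method,
        )
    w = [1.0 / v for v in vs]
    sw = sum(w)
    y_fixed = sum(wi * yi for wi, yi in zip(w, ys)) / sw
    q = sum(wi * (yi - y_fixed) ** 2 for wi, yi in zip(w, ys))
    tau2 = 0.0
    if method is PoolingMethod.RANDOM_DL and k > 1:
        denom = sw - sum(wi ** 2 for wi in w) / sw
        if denom > 0:
            tau2 = max(0.0, (q - (k - 1)) / denom)
    if method is PoolingMethod.FIXED_IV or tau2 == 0.0:
        w_star = w
    else:
        w_star = [1.0 / (v + tau2) for v in vs]
    sw_star = sum(w_star)
    pooled = sum(wi * yi for wi, yi in zip(w_star, ys)) / sw_star
    se = math.sqrt(1.0 / sw_star)
    effect = EffectEstimate(
        measure=measure,
        estimable=True,
        k_trials=k,
        point=math.exp(pooled),
        ci_low=math.exp(pooled - Z_95 * se),
        ci_high=math.exp(pooled + Z_95 * se),
        polarity=polarity,
    )
    return PoolingResult(
        effect=effect, method=method, tau_squared=tau2, q_statistic=q,
        pooled_log=pooled, pooled_se=se,
    )


@dataclass(frozen=True)
class SensitivityResult:
    result: PoolingResult
    included_ids: tuple
    excluded_ids: tuple


def sensitivity_reanalysis(
    tables: Iterable[TrialOutcomeTable],
    final_assessments: Iterable[StudyAssessment] | Mapping[str, StudyAssessment],
    method: PoolingMethod | str = PoolingMethod.RANDOM_DL,
    measure: Measure | str = Measure.RR,
    polarity: Polarity | str = Polarity.LOWER_IS_BENEFIT,
) -> SensitivityResult:
    """Re-pool a meta-analysis keeping only trials that passed the RIA.

    Trials classified awaiting, excluded or non-RCT are removed; when no
    trial remains the re-analysis is not estimable.

    Raises
    ------
    UnassessedStudyError
        If a table's study has no final classification.
    """
    tables = list(tables)
    if isinstance(final_assessments, Mapping):
        by_id = dict(final_assessments)
    else:
        by_id = {a.study_id: a for a in final_assessments}
    included, excluded = [], []
    for t in tables:
        if t.study_id not in by_id:
            raise UnassessedStudyError(
                f"study {t.study_id!r} has an outcome table but no final "
                "RIA classification"
            )
        if by_id[t.study_id].overall is Verdict.NO_CONCERN:
            included.append(t)
        else:
            excluded.append(t.study_id)
    effects = [trial_effect(t, measure) for t in included]
    result = pool(effects, method=method, measure=measure, polarity=polarity)
    return SensitivityResult(
        result=result,
        included_ids=tuple(sorted(t.study_id for t in included)),
        excluded_ids=tuple(sorted(excluded)),
    )


@dataclass(frozen=True)
class Comparison:
    """One comparison arm-pair within a review, with its trials."""

    comparison_id: str
    tables: tuple = field(default_factory=tuple)

    @property
    def n_trials(self) -> int:
        return len(self.tables)

    @property
    def n_participants(self) -> int:
        return sum(t.n_total for t in self.tables)


def select_comparison(comparisons: Sequence[Comparison]) -> Comparison:
    """Pick the comparison carrying the most evidence.

    Largest trial count wins; ties break on total randomized participants,
    then on lexicographically smallest comparison id for determinism.
    """
    comparisons = list(comparisons)
    if not comparisons:
        raise NoComparisonError("no comparisons to select from")
    return min(
        comparisons,
        key=lambda c: (-c.n_trials, -c.n_participants, c.comparison_id),
    )
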