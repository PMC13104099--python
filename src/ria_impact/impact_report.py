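"""Corpus-level summaries of the integrity screen's impact.

Covers the evidence-base shrinkage statistics (median trials per review /
per meta-analysis before vs after the screen, retention proportions by
review type), risk-of-bias cross-tabulation against screen outcome,
per-assessor-tier feasibility (assessment time) accounting, and the
record-filter audit ledger that conserves study counts from the initially
extracted pool down to the assessed one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DuplicateRecordError, EmptySummaryError, LedgerError
from .ria_engine import N_DOMAINS, AssessorTier


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed reports)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class MedianIqr(NamedTuple):
    median: float
    q1: float
    q3: float


def median_iqr(values: Sequence[float], method: str = "linear") -> MedianIqr:
    """Median and quartiles of a value list.

    The median uses the midpoint convention (mean of the two central order
    statistics for even n).  Quartiles default to linear interpolation
    (numpy's ``method="linear"``, i.e. quantile type 7); other numpy
    quantile methods may be selected because printed IQRs in the literature
    rarely pin the convention down.  Medians are convention-robust and are
    the quantity summaries should be compared on.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise EmptySummaryError("median of an empty value list")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method=method)
    return MedianIqr(float(med), float(q1), float(q3))


class ReviewType(str, enum.Enum):
    COCHRANE = "cochrane"
    NON_COCHRANE = "non_cochrane"


@dataclass(frozen=True)
class ReviewRecord:
    """Before/after counts for one review (one row per intervention)."""

    review_id: str
    review_type: ReviewType
    intervention: str = ""
    is_nma: bool = False
    n_rcts_included: int = 0
    n_rcts_no_concern: int = 0
    n_rcts_in_primary_ma: int = 0
    n_rcts_in_sensitivity: int = 0

    def __post_init__(self):
        if self.n_rcts_no_concern > self.n_rcts_included:
            raise ValueError(
                f"{self.review_id!r}: no-concern count exceeds included count"
            )
        if self.n_rcts_in_sensitivity > self.n_rcts_in_primary_ma:
            raise ValueError(
                f"{self.review_id!r}: sensitivity count exceeds the primary "
                "meta-analysis count"
            )


class RetentionBy(str, enum.Enum):
    REVIEW = "review"
    META_ANALYSIS = "meta_analysis"
    REVIEW_TYPE = "review_type"


def retention_summary(
    reviews: Iterable[ReviewRecord],
    by: RetentionBy | str = RetentionBy.REVIEW,
    method: str = "linear",
):
    """Median (IQR) percentage of trials retained after the screen.

    ``by="review"`` uses included vs no-concern counts, ``"meta_analysis"``
    the primary meta-analysis vs sensitivity counts, and ``"review_type"``
    stratifies the meta-analysis-level retention into Cochrane vs
    non-Cochrane reviews.  Rows with a zero denominator are skipped.
    """
    by = RetentionBy(by)
    reviews = list(reviews)

    def pct(after: int, before: int) -> Optional[float]:
        return 100.0 * after / before if before > 0 else None

    if by is RetentionBy.REVIEW:
        vals = [pct(r.n_rcts_no_concern, r.n_rcts_included) for r in reviews]
        return median_iqr([v for v in vals if v is not None], method)
    if by is RetentionBy.META_ANALYSIS:
        vals = [
            pct(r.n_rcts_in_sensitivity, r.n_rcts_in_primary_ma)
            for r in reviews
        ]
        return median_iqr([v for v in vals if v is not None], method)
    out = {}
    for rt in ReviewType:
        vals = [
            pct(r.n_rcts_in_sensitivity, r.n_rcts_in_primary_ma)
            for r in reviews
            if r.review_type is rt
        ]
        vals = [v for v in vals if v is not None]
        if vals:
            out[rt.value] = median_iqr(vals, method)
    return out


class RobRating(str, enum.Enum):
    LOW = "low"
    SOME_CONCERNS = "some_concerns"
    HIGH = "high"


@dataclass(frozen=True)
class RobLabel:
    """Risk-of-bias rating of a trial plus its integrity-screen outcome."""

    study_id: str
    rob: RobRating
    ria_pass: bool


def rob_crosstab(
    labels: Iterable[RobLabel], decimals: int = 1
) -> pd.DataFrame:
    """Within-stratum RoB percentages for screen-pass vs screen-fail trials.

    Returns one row per stratum ("pass"/"fail") with counts and percentages
    per RoB category; empty strata are simply absent.  Percentages per
    stratum sum to 100 up to rounding.
    """
    labels = list(labels)
    seen = set()
    for lab in labels:
        if lab.study_id in seen:
            raise DuplicateRecordError(
                f"duplicate RoB label for study {lab.study_id!r}"
            )
        seen.add(lab.study_id)
    rows = []
    for passed, name in ((True, "pass"), (False, "fail")):
        stratum = [lab for lab in labels if lab.ria_pass is passed]
        if not stratum:
            continue
        n = len(stratum)
        row = {"stratum": name, "n": n}
        for cat in RobRating:
            count = sum(1 for lab in stratum if lab.rob is cat)
            row[f"n_{cat.value}"] = count
            row[f"pct_{cat.value}"] = round_half_away(100.0 * count / n,
                                                      decimals)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimeLog:
    """Mean per-study assessment duration for one tier and domain."""

    assessor_tier: AssessorTier
    domain: int
    mean_duration: float  # seconds per study

    def __post_init__(self):
        if self.mean_duration < 0:
            raise ValueError("duration must be nonnegative")
        if self.domain not in range(1, N_DOMAINS + 1):
            raise ValueError(f"domain must be 1-{N_DOMAINS}")


def format_hms(seconds: float) -> str:
    """Render seconds as h:mm:ss (rounded to whole seconds)."""
    total = int(round(seconds))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


@dataclass(frozen=True)
class TierFeasibility:
    tier: AssessorTier
    domain_means: Mapping[int, float]  # seconds
    total_seconds: float               # sum of the six domain means
    partial: bool                      # True when a domain mean is missing

    @property
    def total_hms(self) -> str:
        return format_hms(self.total_seconds)


def feasibility_summary(
    logs: Iterable[TimeLog],
) -> dict[str, TierFeasibility]:
    """Per-tier domain means and totals.

    Multiple logs for the same (tier, domain) are averaged.  The tier total
    is the sum of its six domain means; totals missing any domain are
    flagged partial.
    """
    acc: dict[tuple, list] = {}
    for log in logs:
        acc.setdefault((log.assessor_tier, log.domain), []).append(
            log.mean_duration
        )
    tiers = sorted({t for t, _ in acc}, key=lambda t: t.value)
    out = {}
    for tier in tiers:
        means = {
            d: float(np.mean(acc[(tier, d)]))
            for d in range(1, N_DOMAINS + 1)
            if (tier, d) in acc
        }
        out[tier.value] = TierFeasibility(
            tier=tier,
            domain_means=means,
            total_seconds=float(sum(means.values())),
            partial=len(means) < N_DOMAINS,
        )
    return out


@dataclass(frozen=True)
class FilterStage:
    """One removal step in the record-filter ledger."""

    stage: str
    n_removed: int
    reason: str = ""

    def __post_init__(self):
        if self.n_removed < 0:
            raise LedgerError(f"stage {self.stage!r}: negative removal")


@dataclass(frozen=True)
class FilterAccounting:
    n_initial: int
    n_final: int
    table: pd.DataFrame = field(repr=False)


def filter_accounting(
    n_initial: int, stages: Sequence[FilterStage]
) -> FilterAccounting:
    """Chain removal stages and audit that counts are conserved exactly.

    Raises
    ------
    LedgerError
        If any intermediate count would become negative.
    """
    if n_initial < 0:
        raise LedgerError("initial count must be nonnegative")
    rows = []
    n = n_initial
    for s in stages:
        n_out = n - s.n_removed
        if n_out < 0:
            raise LedgerError(
                f"stage {s.stage!r} removes {s.n_removed} from a pool of {n}"
            )
        rows.append({
            "stage": s.stage, "n_in": n, "n_removed": s.n_removed,
            "n_out": n_out, "reason": s.reason,
        })
        n = n_out
    return FilterAccounting(
        n_initial=n_initial, n_final=n,
        table=pd.DataFrame(
            rows, columns=["stage", "n_in", "n_removed", "n_out", "reason"]
        ),
    )
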