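"""Hierarchical six-domain research-integrity assessment (RIA) engine.

The RIA screens a randomized trial through six domains in fixed order —
retraction notices (1), prospective trial registration (2), ethics approval
and informed consent (3), authorship (4), plausibility of methods (5) and
plausibility of results (6).  At every domain an assessor issues one of
three decisions: *no concern*, *awaiting classification* (unresolved concern,
pending author clarification) or *exclude*.  An exclusion terminates the
walk: later domains are never assessed.  A study misclassified as an RCT can
additionally be flagged *non-RCT*, a second terminal state that is only
detectable in the registration and methods-plausibility domains.

This module implements the single-assessor overall decision, third-assessor
adjudication between two independent first-round assessors, reclassification
after author correspondence, and corpus-level classification accounting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import (
    DuplicateRecordError,
    IncompleteAdjudicationError,
    InconsistentStateError,
    MalformedAssessmentError,
)

N_DOMAINS = 6

DOMAIN_NAMES = {
    1: "retraction",
    2: "trial_registration",
    3: "ethics",
    4: "authorship",
    5: "plausibility_of_methods",
    6: "plausibility_of_results",
}

#: Domains in which a study can be unmasked as non-randomized.
NON_RCT_DOMAINS = frozenset({2, 5})


class Verdict(str, enum.Enum):
    """Decision on one domain (or the overall RIA) for one study."""

    NO_CONCERN = "no_concern"
    AWAITING = "awaiting"
    EXCLUDE = "exclude"
    NON_RCT = "non_rct"
    NOT_ASSESSED = "not_assessed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Verdicts that terminate the hierarchical walk.
TERMINAL_VERDICTS = frozenset({Verdict.EXCLUDE, Verdict.NON_RCT})

#: Verdicts an assessor can actively assign to a domain.
ACTIVE_VERDICTS = frozenset(
    {Verdict.NO_CONCERN, Verdict.AWAITING, Verdict.EXCLUDE, Verdict.NON_RCT}
)


class AssessorTier(str, enum.Enum):
    """Evidence-synthesis expertise of an assessor."""

    BEGINNER = "beginner"          # little/no experience (≤ 1 year)
    INTERMEDIATE = "intermediate"  # 1-6 years
    SENIOR = "senior"              # > 6 years

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DomainDecision:
    """One assessor's verdict on one RIA domain for one study."""

    study_id: str
    domain: int
    assessor_id: str
    assessor_tier: AssessorTier
    verdict: Verdict

    def __post_init__(self):
        if self.domain not in range(1, N_DOMAINS + 1):
            raise MalformedAssessmentError(
                f"domain must be 1-{N_DOMAINS}, got {self.domain}"
            )
        if (
            self.verdict is Verdict.NON_RCT
            and self.domain not in NON_RCT_DOMAINS
        ):
            raise MalformedAssessmentError(
                f"non_rct can only be issued in domains "
                f"{sorted(NON_RCT_DOMAINS)}, not domain {self.domain}"
            )


@dataclass(frozen=True)
class OverallResult:
    """Overall classification plus where the hierarchical walk stopped."""

    overall: Verdict
    truncated_at: int  # domain of the first terminal verdict, else 6


def assess_overall(verdicts: Sequence[Verdict]) -> OverallResult:
    """Fold a domain-ordered verdict vector into the overall RIA decision.

    The walk stops at the first terminal verdict (``exclude``/``non_rct``),
    which becomes the overall classification regardless of anything recorded
    for later domains.  Otherwise the study is ``awaiting`` if any domain is
    awaiting, and ``no_concern`` only when all six domains raised no concern.

    Raises
    ------
    MalformedAssessmentError
        If fewer than six verdicts are given without a terminal verdict, or
        ``not_assessed`` appears before the first terminal verdict.
    """
    verdicts = [Verdict(v) for v in verdicts]
    if len(verdicts) > N_DOMAINS:
        raise MalformedAssessmentError(
            f"expected at most {N_DOMAINS} verdicts, got {len(verdicts)}"
        )
    any_awaiting = False
    for i, v in enumerate(verdicts):
        if v in TERMINAL_VERDICTS:
            return OverallResult(overall=v, truncated_at=i + 1)
        if v is Verdict.NOT_ASSESSED:
            raise MalformedAssessmentError(
                f"not_assessed at domain {i + 1} before any terminal verdict"
            )
        any_awaiting = any_awaiting or v is Verdict.AWAITING
    if len(verdicts) < N_DOMAINS:
        raise MalformedAssessmentError(
            f"only {len(verdicts)} verdicts and no terminal verdict"
        )
    overall = Verdict.AWAITING if any_awaiting else Verdict.NO_CONCERN
    return OverallResult(overall=overall, truncated_at=N_DOMAINS)


@dataclass(frozen=True)
class StudyAssessment:
    """One assessor's ordered six-domain decision vector for one study."""

    study_id: str
    assessor_id: str
    assessor_tier: AssessorTier
    verdicts: tuple  # 6 Verdicts, not_assessed after the first terminal one

    def __post_init__(self):
        object.__setattr__(
            self, "verdicts", tuple(Verdict(v) for v in self.verdicts)
        )
        if len(self.verdicts) != N_DOMAINS:
            raise MalformedAssessmentError(
                f"study {self.study_id!r}: expected {N_DOMAINS} verdicts, "
                f"got {len(self.verdicts)}"
            )
        result = assess_overall(self._active_prefix())
        # everything after the first terminal verdict must be not_assessed
        for d in range(result.truncated_at, N_DOMAINS):
            if (
                result.overall in TERMINAL_VERDICTS
                and self.verdicts[d] is not Verdict.NOT_ASSESSED
            ):
                raise MalformedAssessmentError(
                    f"study {self.study_id!r}: domain {d + 1} rated after a "
                    f"terminal verdict at domain {result.truncated_at}"
                )

    def _active_prefix(self):
        """Verdicts up to and including the first terminal one."""
        out = []
        for v in self.verdicts:
            out.append(v)
            if v in TERMINAL_VERDICTS:
                break
        return out

    @property
    def overall(self) -> Verdict:
        return assess_overall(self._active_prefix()).overall

    @property
    def truncated_at(self) -> int:
        return assess_overall(self._active_prefix()).truncated_at

    def verdict(self, domain: int) -> Verdict:
        return self.verdicts[domain - 1]

    @classmethod
    def from_prefix(
        cls,
        study_id: str,
        assessor_id: str,
        assessor_tier: AssessorTier,
        prefix: Sequence[Verdict],
    ) -> "StudyAssessment":
        """Build from the assessed prefix, padding with ``not_assessed``."""
        prefix = [Verdict(v) for v in prefix]
        padded = prefix + [Verdict.NOT_ASSESSED] * (N_DOMAINS - len(prefix))
        return cls(study_id, assessor_id, AssessorTier(assessor_tier),
                   tuple(padded))

    def decisions(self) -> tuple:
        """The verdict vector as :class:`DomainDecision` records."""
        return tuple(
            DomainDecision(self.study_id, d, self.assessor_id,
                           self.assessor_tier, v)
            for d, v in enumerate(self.verdicts, start=1)
        )


@dataclass(frozen=True)
class RatingSheet:
    """Per-domain verdicts from one assessor, without hierarchical truncation.

    The adjudicating (third) assessor re-rates domains on demand, so their
    verdicts are not constrained to stop at their own first terminal call;
    any subset of domains may be rated.
    """

    study_id: str
    assessor_id: str
    assessor_tier: AssessorTier
    ratings: Mapping[int, Verdict]

    def __post_init__(self):
        clean = {}
        for d, v in self.ratings.items():
            d = int(d)
            v = Verdict(v)
            if d not in range(1, N_DOMAINS + 1):
                raise MalformedAssessmentError(f"invalid domain {d}")
            if v is not Verdict.NOT_ASSESSED:
                if v is Verdict.NON_RCT and d not in NON_RCT_DOMAINS:
                    raise MalformedAssessmentError(
                        f"non_rct can only be issued in domains "
                        f"{sorted(NON_RCT_DOMAINS)}, not domain {d}"
                    )
                clean[d] = v
        object.__setattr__(self, "ratings", clean)


@dataclass(frozen=True)
class ReassessFlags:
    """When domains outside the routine set go to the third assessor."""

    discrepant: bool = True              # the two first-round ratings differ
    consistent_non_no_concern: bool = True  # both agree on awaiting/exclude
    single_rating: bool = True           # only one assessor reached the domain
    no_rating: bool = True               # neither assessor reached the domain


@dataclass(frozen=True)
class AdjudicationPolicy:
    """Scope of the third (senior) assessor's reassessment.

    By default the senior assessor re-rates every study in domains 1-3, and
    in domains 4-6 only where the first-round pair is discrepant, agrees on a
    non-"no concern" rating, or where fewer than two ratings exist.
    """

    always_reassess_domains: frozenset = frozenset({1, 2, 3})
    reassess_on: ReassessFlags = field(default_factory=ReassessFlags)

    def __post_init__(self):
        extra = set(self.always_reassess_domains) - set(range(1, N_DOMAINS + 1))
        if extra:
            raise ValueError(f"invalid domains in policy: {sorted(extra)}")
        object.__setattr__(
            self, "always_reassess_domains",
            frozenset(self.always_reassess_domains),
        )


@dataclass(frozen=True)
class AdjudicationResult:
    final: StudyAssessment
    #: (study_id, domain) pairs the third assessor had to (re)rate,
    #: deterministically ordered.
    worklist: tuple
    #: domains left without any usable rating under a restrictive policy
    unresolved: tuple = ()


def _first_round_equal(a: Verdict, b: Verdict) -> bool:
    # first-round assessors have no non-RCT category; treat it as exclude
    collapse = {Verdict.NON_RCT: Verdict.EXCLUDE}
    return collapse.get(a, a) == collapse.get(b, b)


def adjudicate(
    first: StudyAssessment,
    second: StudyAssessment,
    third: Mapping[int, Verdict] | RatingSheet | StudyAssessment,
    policy: AdjudicationPolicy | None = None,
) -> AdjudicationResult:
    """Merge two first-round assessments under third-assessor adjudication.

    ``third`` may be a :class:`RatingSheet`, a partial domain→verdict
    mapping, or a full :class:`StudyAssessment`; it must cover every domain
    the policy routes to the senior assessor (up to the final terminal
    verdict).

    Raises
    ------
    IncompleteAdjudicationError
        If the third assessor lacks a verdict for a required domain.
    """
    policy = policy or AdjudicationPolicy()
    if first.study_id != second.study_id:
        raise MalformedAssessmentError(
            f"assessments cover different studies: "
            f"{first.study_id!r} vs {second.study_id!r}"
        )
    study_id = first.study_id
    if isinstance(third, StudyAssessment):
        third_map = {
            d: v
            for d, v in enumerate(third.verdicts, start=1)
            if v is not Verdict.NOT_ASSESSED
        }
        third_id, third_tier = third.assessor_id, third.assessor_tier
    elif isinstance(third, RatingSheet):
        third_map = dict(third.ratings)
        third_id, third_tier = third.assessor_id, third.assessor_tier
    else:
        third_map = {int(d): Verdict(v) for d, v in third.items()}
        third_id, third_tier = "adjudicated", AssessorTier.SENIOR

    final: list[Verdict] = []
    worklist: list[tuple[str, int]] = []
    unresolved: list[int] = []
    missing: list[int] = []
    terminal_hit = False
    for d in range(1, N_DOMAINS + 1):
        if terminal_hit:
            final.append(Verdict.NOT_ASSESSED)
            continue
        a, b = first.verdict(d), second.verdict(d)
        a_present = a is not Verdict.NOT_ASSESSED
        b_present = b is not Verdict.NOT_ASSESSED
        if d in policy.always_reassess_domains:
            needs_third = True
        else:
            flags = policy.reassess_on
            if a_present and b_present:
                if not _first_round_equal(a, b):
                    needs_third = flags.discrepant
                else:
                    needs_third = (
                        flags.consistent_non_no_concern
                        and a is not Verdict.NO_CONCERN
                    )
            elif a_present or b_present:
                needs_third = flags.single_rating
            else:
                needs_third = flags.no_rating
        if needs_third:
            worklist.append((study_id, d))
            if d not in third_map:
                missing.append(d)
                continue
            verdict = third_map[d]
        elif a_present:
            verdict = a  # consistent pair (or lone rating kept by policy)
        elif b_present:
            verdict = b
        else:
            # no rating anywhere and the policy does not reassess: the
            # domain stays open rather than being guessed
            unresolved.append(d)
            final.append(Verdict.NOT_ASSESSED)
            continue
        final.append(verdict)
        terminal_hit = verdict in TERMINAL_VERDICTS
    if missing:
        raise IncompleteAdjudicationError(study_id, missing)

    assessment = StudyAssessment(
        study_id=study_id,
        assessor_id=third_id,
        assessor_tier=third_tier,
        verdicts=tuple(final),
    ) if not unresolved else _pending_assessment(
        study_id, third_id, third_tier, final, unresolved
    )
    worklist.sort(key=lambda item: (item[0], item[1]))
    return AdjudicationResult(
        final=assessment,
        worklist=tuple(worklist),
        unresolved=tuple(unresolved),
    )


def _pending_assessment(study_id, assessor_id, tier, final, unresolved):
    """Represent still-open domains as awaiting (unresolved concern)."""
    verdicts = [
        Verdict.AWAITING if (d in unresolved) else v
        for d, v in enumerate(final, start=1)
    ]
    return StudyAssessment(study_id, assessor_id, AssessorTier(tier),
                           tuple(verdicts))


@dataclass(frozen=True)
class AuthorQuery:
    """One clarification request sent to a trial's authors."""

    study_id: str
    domain: int
    resolved: bool
    sent_date: Optional[date] = None
    response_date: Optional[date] = None

    def __post_init__(self):
        if (
            self.sent_date is not None
            and self.response_date is not None
            and self.response_date < self.sent_date
        ):
            raise ValueError(
                f"query for {self.study_id!r} domain {self.domain}: "
                "response precedes the request"
            )

    def in_window(self, window_days: int, extension_days: int) -> bool:
        """Whether the response arrived before the (extended) deadline.

        Queries without dates are judged on ``resolved`` alone.
        """
        if self.sent_date is None or self.response_date is None:
            return True
        deadline = self.sent_date + timedelta(days=window_days + extension_days)
        return self.response_date <= deadline


def apply_author_responses(
    final: StudyAssessment,
    queries: Iterable[AuthorQuery],
    response_window_days: int = 14,
    reminder_extension_days: int = 7,
) -> StudyAssessment:
    """Reclassify awaiting domains resolved through author correspondence.

    A domain flips from ``awaiting`` to ``no_concern`` only when a matching
    query is marked resolved and (when dates are recorded) the response
    arrived within the two-week window plus the reminder extension.  Authors
    who never respond leave the study awaiting classification.

    Raises
    ------
    InconsistentStateError
        If a query targets a study/domain that is not awaiting.
    """
    queries = list(queries)
    if not queries:
        return final
    verdicts = list(final.verdicts)
    for q in queries:
        if q.study_id != final.study_id:
            raise InconsistentStateError(
                f"query for study {q.study_id!r} applied to assessment of "
                f"{final.study_id!r}"
            )
        if verdicts[q.domain - 1] is not Verdict.AWAITING:
            raise InconsistentStateError(
                f"study {q.study_id!r} domain {q.domain} is "
                f"{verdicts[q.domain - 1]}, not awaiting classification"
            )
        if q.resolved and q.in_window(
            response_window_days, reminder_extension_days
        ):
            verdicts[q.domain - 1] = Verdict.NO_CONCERN
    return replace(final, verdicts=tuple(verdicts))


@dataclass(frozen=True)
class ClassificationSummary:
    """Absolute frequencies of final classifications for a study pool."""

    n_studies: int
    overall_counts: Mapping[str, int]      # overall verdict -> count
    domain_counts: Mapping[int, Mapping[str, int]]  # domain -> verdict -> n

    def overall_percentages(self, decimals: int = 1) -> dict:
        from .impact_report import round_half_away

        if self.n_studies == 0:
            return {k: 0.0 for k in self.overall_counts}
        return {
            k: round_half_away(100.0 * v / self.n_studies, decimals)
            for k, v in self.overall_counts.items()
        }


def classification_summary(
    assessments: Iterable[StudyAssessment],
) -> ClassificationSummary:
    """Tally final classifications per overall category and per domain.

    Raises
    ------
    DuplicateRecordError
        If two final assessments share a study id.
    """
    assessments = list(assessments)
    seen = set()
    for a in assessments:
        if a.study_id in seen:
            raise DuplicateRecordError(
                f"duplicate final assessment for study {a.study_id!r}"
            )
        seen.add(a.study_id)
    overall_keys = [
        Verdict.NO_CONCERN, Verdict.AWAITING, Verdict.EXCLUDE, Verdict.NON_RCT
    ]
    overall = {k.value: 0 for k in overall_keys}
    domain = {
        d: {v.value: 0 for v in Verdict} for d in range(1, N_DOMAINS + 1)
    }
    for a in assessments:
        overall[a.overall.value] += 1
        for d in range(1, N_DOMAINS + 1):
            domain[d][a.verdict(d).value] += 1
    return ClassificationSummary(
        n_studies=len(assessments),
        overall_counts=overall,
        domain_counts=domain,
    )
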