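"""Hierarchical decision workflow, adjudication and reclassification."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ria_impact.exceptions import (
    DuplicateRecordError,
    IncompleteAdjudicationError,
    InconsistentStateError,
    MalformedAssessmentError,
)
from ria_impact.ria_engine import (
    AdjudicationPolicy,
    AssessorTier,
    AuthorQuery,
    DomainDecision,
    ReassessFlags,
    StudyAssessment,
    Verdict,
    adjudicate,
    apply_author_responses,
    assess_overall,
    classification_summary,
)

from .conftest import AW, EX, NA, NC, NR, assessment


class TestAssessOverall:
    @pytest.mark.parametrize("verdicts, overall, truncated_at", [
        # exclusion in the registration domain truncates the walk
        ([NC, EX, NA, NA, NA, NA], EX, 2),
        ([NC] * 6, NC, 6),
        ([NC, AW, AW, NC, NC, NC], AW, 6),
        # a non-RCT unmasked at registration is terminal too
        ([NC, NR, NA, NA, NA, NA], NR, 2),
        ([EX, NA, NA, NA, NA, NA], EX, 1),
        ([AW] * 6, AW, 6),
    ])
    def test_examples(self, verdicts, overall, truncated_at):
        result = assess_overall(verdicts)
        assert result.overall is overall
        assert result.truncated_at == truncated_at

    def test_short_vector_without_terminal_is_malformed(self):
        with pytest.raises(MalformedAssessmentError):
            assess_overall([NC, NC, NC])

    def test_short_vector_with_terminal_is_fine(self):
        assert assess_overall([NC, EX]).overall is EX

    def test_not_assessed_before_terminal_is_malformed(self):
        with pytest.raises(MalformedAssessmentError):
            assess_overall([NC, NA, EX, NA, NA, NA])

    @given(
        prefix=st.lists(st.sampled_from([NC, AW]), min_size=0, max_size=5),
        terminal=st.sampled_from([EX, NR]),
        suffix=st.lists(
            st.sampled_from([NC, AW, EX, NR, NA]), min_size=0, max_size=5
        ),
    )
    @settings(max_examples=200, deadline=None)
    def test_terminal_shields_later_domains(self, prefix, terminal, suffix):
        """Verdicts after the first terminal one never change the overall."""
        verdicts = (prefix + [terminal] + suffix)[:6]
        result = assess_overall(verdicts)
        assert result.overall is terminal
        assert result.truncated_at == len(prefix) + 1


class TestDomainDecision:
    def test_non_rct_restricted_to_registration_and_methods(self):
        DomainDecision("s", 2, "a", AssessorTier.SENIOR, NR)
        DomainDecision("s", 5, "a", AssessorTier.SENIOR, NR)
        with pytest.raises(MalformedAssessmentError):
            DomainDecision("s", 3, "a", AssessorTier.SENIOR, NR)

    def test_domain_bounds(self):
        with pytest.raises(MalformedAssessmentError):
            DomainDecision("s", 7, "a", AssessorTier.BEGINNER, NC)


class TestStudyAssessment:
    def test_rating_after_terminal_rejected(self):
        with pytest.raises(MalformedAssessmentError):
            StudyAssessment("s", "a", AssessorTier.BEGINNER,
                            (NC, EX, NC, NA, NA, NA))

    def test_overall_no_concern_iff_all_no_concern(self):
        assert assessment("s", [NC] * 6).overall is NC
        assert assessment("s", [NC, NC, AW, NC, NC, NC]).overall is AW


class TestAdjudicate:
    def third(self, ratings):
        return {d: v for d, v in ratings.items()}

    def test_routine_domains_follow_third(self):
        first = assessment("s", [NC, EX], "A1")
        second = assessment("s", [NC] * 6, "A2", AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second,
            self.third({1: NC, 2: EX}),
        )
        assert result.final.overall is EX
        assert result.final.truncated_at == 2
        assert ("s", 2) in result.worklist

    def test_consistent_no_concern_pair_kept_in_later_domains(self):
        """Pairs agreeing on no concern in domains 4-6 are not re-rated."""
        first = assessment("s", [NC] * 6, "A1")
        second = assessment("s", [NC] * 6, "A2", AssessorTier.INTERMEDIATE)
        result = adjudicate(first, second, self.third({1: NC, 2: NC, 3: NC}))
        assert result.final.overall is NC
        assert all(d <= 3 for _, d in result.worklist)

    def test_consistent_awaiting_pair_goes_to_third(self):
        first = assessment("s", [NC, NC, NC, NC, AW, NC], "A1")
        second = assessment("s", [NC, NC, NC, NC, AW, NC], "A2",
                            AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second, self.third({1: NC, 2: NC, 3: NC, 5: NC})
        )
        assert ("s", 5) in result.worklist
        assert result.final.overall is NC  # senior resolved the concern

    def test_discrepant_later_domain_goes_to_third(self):
        first = assessment("s", [NC, NC, NC, NC, NC, AW], "A1")
        second = assessment("s", [NC] * 6, "A2", AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second, self.third({1: NC, 2: NC, 3: NC, 6: AW})
        )
        assert ("s", 6) in result.worklist
        assert result.final.overall is AW

    def test_single_and_no_rating_routed_to_third(self):
        # both first-round assessors excluded early, so domains 4-6 carry
        # no rating; the senior assessor supplies them
        first = assessment("s", [NC, EX], "A1")
        second = assessment("s", [NC, EX], "A2", AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second,
            self.third({1: NC, 2: NC, 3: NC, 4: NC, 5: NC, 6: NC}),
        )
        assert result.final.overall is NC
        assert {d for _, d in result.worklist} == {1, 2, 3, 4, 5, 6}

    def test_missing_required_third_rating_raises(self):
        first = assessment("s", [NC, NC, NC, NC, NC, AW], "A1")
        second = assessment("s", [NC] * 6, "A2", AssessorTier.INTERMEDIATE)
        with pytest.raises(IncompleteAdjudicationError) as err:
            adjudicate(first, second, self.third({1: NC, 2: NC, 3: NC}))
        assert err.value.missing_domains == (6,)

    def test_worklist_ordering_is_deterministic(self):
        first = assessment("s", [NC] * 6, "A1")
        second = assessment("s", [AW, AW, AW, AW, AW, AW], "A2",
                            AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second,
            self.third({d: NC for d in range(1, 7)}),
        )
        assert list(result.worklist) == sorted(result.worklist)

    def test_restrictive_policy_leaves_unrated_domains_open(self):
        """Without any reassessment flags, unrated later domains stay open
        (awaiting) rather than being guessed."""
        policy = AdjudicationPolicy(
            reassess_on=ReassessFlags(False, False, False, False)
        )
        first = assessment("s", [NC, EX], "A1")
        second = assessment("s", [NC, EX], "A2", AssessorTier.INTERMEDIATE)
        result = adjudicate(
            first, second, self.third({1: NC, 2: NC, 3: NC}), policy
        )
        assert result.unresolved == (4, 5, 6)
        assert result.final.overall is AW


class TestAuthorResponses:
    def test_resolved_ethics_query_clears_study(self):
        final = assessment("s", [NC, NC, AW, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        updated = apply_author_responses(
            final, [AuthorQuery("s", 3, resolved=True)]
        )
        assert updated.overall is NC

    def test_no_response_keeps_awaiting(self):
        final = assessment("s", [NC, NC, AW, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        updated = apply_author_responses(
            final, [AuthorQuery("s", 3, resolved=False)]
        )
        assert updated.overall is AW

    def test_second_awaiting_domain_keeps_overall_awaiting(self):
        final = assessment("s", [NC, AW, AW, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        updated = apply_author_responses(
            final, [AuthorQuery("s", 3, resolved=True)]
        )
        assert updated.verdict(3) is NC
        assert updated.overall is AW

    def test_empty_query_list_is_identity(self):
        final = assessment("s", [NC, AW, NC, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        assert apply_author_responses(final, []) is final

    def test_query_on_non_awaiting_domain_is_inconsistent(self):
        final = assessment("s", [NC] * 6, "A3", AssessorTier.SENIOR)
        with pytest.raises(InconsistentStateError):
            apply_author_responses(final, [AuthorQuery("s", 2, True)])

    def test_late_response_stays_awaiting(self):
        final = assessment("s", [NC, NC, AW, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        late = AuthorQuery(
            "s", 3, resolved=True,
            sent_date=dt.date(2022, 3, 1),
            response_date=dt.date(2022, 4, 15),  # past 14 + 7 days
        )
        assert apply_author_responses(final, [late]).overall is AW

    def test_in_window_response_clears(self):
        final = assessment("s", [NC, NC, AW, NC, NC, NC], "A3",
                           AssessorTier.SENIOR)
        timely = AuthorQuery(
            "s", 3, resolved=True,
            sent_date=dt.date(2022, 3, 1),
            response_date=dt.date(2022, 3, 18),  # within 14 + 7 days
        )
        assert apply_author_responses(final, [timely]).overall is NC


class TestClassificationSummary:
    def test_truncation_accounting(self):
        pool = (
            [assessment(f"x{i}", [NC, EX]) for i in range(3)]
            + [assessment(f"k{i}", [NC] * 6) for i in range(7)]
        )
        summary = classification_summary(pool)
        assert summary.n_studies == 10
        assert summary.domain_counts[3]["not_assessed"] >= 3

    def test_counts_conserved(self, small_corpus):
        finals = small_corpus.final_assessments()
        summary = classification_summary(finals)
        assert sum(summary.overall_counts.values()) == summary.n_studies
        for d in range(1, 7):
            assert sum(summary.domain_counts[d].values()) == summary.n_studies

    def test_duplicate_study_rejected(self):
        pool = [assessment("dup", [NC] * 6), assessment("dup", [NC] * 6)]
        with pytest.raises(DuplicateRecordError):
            classification_summary(pool)

    def test_empty_pool(self):
        summary = classification_summary([])
        assert summary.n_studies == 0
        assert all(v == 0 for v in summary.overall_counts.values())
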