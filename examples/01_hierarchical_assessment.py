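"""Walk one trial through the six-domain integrity screen.

Two first-round assessors disagree on the registration domain; the senior
third assessor settles it, and an author response later clears an ethics
concern.
"""

from ria_impact import (
    AssessorTier,
    AuthorQuery,
    StudyAssessment,
    Verdict,
    adjudicate,
    apply_author_responses,
)

NC, AW, EX = Verdict.NO_CONCERN, Verdict.AWAITING, Verdict.EXCLUDE

first = StudyAssessment.from_prefix(
    "trial-001", "A1", AssessorTier.BEGINNER, [NC, EX]
)  # the beginner excludes at domain 2 and stops
second = StudyAssessment.from_prefix(
    "trial-001", "A2", AssessorTier.INTERMEDIATE, [NC, NC, AW, NC, NC, NC]
)  # the expert sees a registration but flags ethics

# the senior assessor re-rates domains 1-3 routinely; domains 4-6 carry
# only one first-round rating here (the beginner stopped at domain 2), so
# they are also routed to the senior assessor
third = {1: NC, 2: NC, 3: AW, 4: NC, 5: NC, 6: NC}
result = adjudicate(first, second, third)
print("final verdicts :", [v.value for v in result.final.verdicts])
print("overall        :", result.final.overall.value)
print("reassessed     :", [d for _, d in result.worklist])

# the trial authors clarify the ethics approval within the 14+7-day window
updated = apply_author_responses(
    result.final, [AuthorQuery("trial-001", 3, resolved=True)]
)
print("after response :", updated.overall.value)
# The study ends as "no concern": the discrepant registration verdict was
# overturned by the senior assessor and the ethics query was resolved.
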