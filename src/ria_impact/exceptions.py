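"""Exception hierarchy for the RIA impact pipeline."""


class RiaError(Exception):
    """Base class for all package errors."""


class MalformedAssessmentError(RiaError, ValueError):
    """A six-domain verdict vector violates the hierarchical workflow."""


class IncompleteAdjudicationError(RiaError, ValueError):
    """The third assessor is missing a verdict required by the policy.

    The missing domains are available as ``.missing_domains``.
    """

    def __init__(self, study_id, missing_domains):
        self.study_id = study_id
        self.missing_domains = tuple(sorted(missing_domains))
        super().__init__(
            f"study {study_id!r}: third assessor has no verdict for "
            f"required domain(s) {list(self.missing_domains)}"
        )


class InconsistentStateError(RiaError, ValueError):
    """An author query targets a study/domain not awaiting classification."""


class DuplicateRecordError(RiaError, ValueError):
    """More than one final assessment (or label) for the same study."""


class UndefinedKappaError(RiaError, ZeroDivisionError):
    """Chance agreement is 1 so kappa is undefined (all mass in one cell)."""


class UnassessedStudyError(RiaError, KeyError):
    """An outcome table refers to a study with no final RIA classification."""


class EmptySummaryError(RiaError, ValueError):
    """A summary statistic was requested on an empty collection."""


class LedgerError(RiaError, ValueError):
    """A record-filter ledger does not conserve counts."""


class NoComparisonError(RiaError, ValueError):
    """Comparison selection was called with no comparisons."""


class ValidationError(RiaError, ValueError):
    """A CSV/config input failed schema validation.

    ``row`` is the 1-based line number in the file (header is line 1) and
    ``column`` the offending field, when known.
    """

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None:
            loc = f" (line {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + loc)
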