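"""CSV readers/writers for the pipeline's tabular schemas.

All files are UTF-8, comma-separated, double-quote escaped, LF-terminated,
with a mandatory header row.  Verdict tokens are strict and lower-case
(``no_concern|awaiting|exclude|non_rct|not_assessed``); malformed rows are
reported with their 1-based file line number (the header is line 1).
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import ValidationError
from .impact_report import ReviewRecord, ReviewType, RobLabel, RobRating
from .meta_engine import TrialOutcomeTable
from .ria_engine import (
    N_DOMAINS,
    AssessorTier,
    AuthorQuery,
    RatingSheet,
    StudyAssessment,
    Verdict,
)

_ASSESSMENT_COLUMNS = ["study_id", "assessor_id", "assessor_tier", "domain",
                       "verdict"]
_TRIAL_COLUMNS = ["study_id", "comparison_id", "outcome_name",
                  "patient_relevant", "events_int", "n_int", "events_ctl",
                  "n_ctl"]
_QUERY_COLUMNS = ["study_id", "domain", "sent_date", "response_date",
                  "resolved"]
_REVIEW_COLUMNS = ["review_id", "review_type", "intervention", "is_nma",
                   "n_rcts_included", "n_rcts_no_concern",
                   "n_rcts_in_primary_ma", "n_rcts_in_sensitivity"]


def _read_table(path, required_columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing column(s) {missing}", row=1
        )
    return df


def _parse_int(value, line, column, minimum=None):
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise ValidationError(f"not an integer: {value!r}", row=line,
                              column=column) from None
    if minimum is not None and out < minimum:
        raise ValidationError(f"value {out} below {minimum}", row=line,
                              column=column)
    return out


def _parse_bool(value, line, column):
    token = str(value).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    raise ValidationError(f"not a boolean: {value!r}", row=line,
                          column=column)


def read_assessments(path) -> list[StudyAssessment]:
    """Read long-format domain decisions into study assessments.

    Each (study, assessor) block must cover the contiguous assessed prefix
    of domains starting at 1 (rows after a terminal verdict may be omitted
    or written as ``not_assessed``).
    """
    df = _read_table(path, _ASSESSMENT_COLUMNS)
    blocks: dict[tuple, dict] = {}
    tiers: dict[tuple, AssessorTier] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        domain = _parse_int(row["domain"], line, "domain", minimum=1)
        if domain > N_DOMAINS:
            raise ValidationError(f"domain {domain} > {N_DOMAINS}",
                                  row=line, column="domain")
        try:
            verdict = Verdict(row["verdict"])
        except ValueError:
            raise ValidationError(
                f"unknown verdict token {row['verdict']!r}",
                row=line, column="verdict",
            ) from None
        try:
            tier = AssessorTier(row["assessor_tier"])
        except ValueError:
            raise ValidationError(
                f"unknown assessor tier {row['assessor_tier']!r}",
                row=line, column="assessor_tier",
            ) from None
        key = (row["study_id"], row["assessor_id"])
        block = blocks.setdefault(key, {})
        if domain in block:
            raise ValidationError(
                f"duplicate domain {domain} for study "
                f"{row['study_id']!r}/{row['assessor_id']!r}",
                row=line, column="domain",
            )
        block[domain] = verdict
        tiers[key] = tier
    out = []
    for (study_id, assessor_id), block in blocks.items():
        domains = sorted(block)
        if domains != list(range(1, len(domains) + 1)):
            raise ValidationError(
                f"study {study_id!r}/{assessor_id!r}: domains {domains} are "
                "not a contiguous prefix starting at 1"
            )
        verdicts = [block[d] for d in domains]
        # trim trailing not_assessed so the prefix constructor can pad
        while verdicts and verdicts[-1] is Verdict.NOT_ASSESSED:
            verdicts.pop()
        out.append(StudyAssessment.from_prefix(
            study_id, assessor_id, tiers[(study_id, assessor_id)], verdicts
        ))
    return out


def write_assessments(assessments: Iterable[StudyAssessment], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_ASSESSMENT_COLUMNS)
        for a in assessments:
            for d in range(1, N_DOMAINS + 1):
                writer.writerow([
                    a.study_id, a.assessor_id, a.assessor_tier.value, d,
                    a.verdict(d).value,
                ])


def read_rating_sheets(path) -> list[RatingSheet]:
    """Read per-domain verdicts without the hierarchical-truncation
    invariant (the adjudicating assessor's sheets)."""
    df = _read_table(path, _ASSESSMENT_COLUMNS)
    blocks: dict[tuple, dict] = {}
    tiers: dict[tuple, AssessorTier] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        domain = _parse_int(row["domain"], line, "domain", minimum=1)
        try:
            verdict = Verdict(row["verdict"])
            tier = AssessorTier(row["assessor_tier"])
        except ValueError as exc:
            raise ValidationError(str(exc), row=line) from None
        key = (row["study_id"], row["assessor_id"])
        blocks.setdefault(key, {})[domain] = verdict
        tiers[key] = tier
    return [
        RatingSheet(study_id, assessor_id, tiers[(study_id, assessor_id)],
                    ratings)
        for (study_id, assessor_id), ratings in blocks.items()
    ]


def write_rating_sheets(sheets: Iterable[RatingSheet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_ASSESSMENT_COLUMNS)
        for s in sheets:
            for d in range(1, N_DOMAINS + 1):
                verdict = s.ratings.get(d, Verdict.NOT_ASSESSED)
                writer.writerow([
                    s.study_id, s.assessor_id, s.assessor_tier.value, d,
                    verdict.value,
                ])


def read_trials(path) -> dict[str, list[TrialOutcomeTable]]:
    """Read trial 2x2 tables grouped by comparison id."""
    df = _read_table(path, _TRIAL_COLUMNS)
    out: dict[str, list[TrialOutcomeTable]] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        events_int = _parse_int(row["events_int"], line, "events_int", 0)
        n_int = _parse_int(row["n_int"], line, "n_int", 1)
        events_ctl = _parse_int(row["events_ctl"], line, "events_ctl", 0)
        n_ctl = _parse_int(row["n_ctl"], line, "n_ctl", 1)
        if events_int > n_int:
            raise ValidationError(
                f"events_int {events_int} > n_int {n_int}",
                row=line, column="events_int",
            )
        if events_ctl > n_ctl:
            raise ValidationError(
                f"events_ctl {events_ctl} > n_ctl {n_ctl}",
                row=line, column="events_ctl",
            )
        table = TrialOutcomeTable(
            study_id=row["study_id"],
            events_intervention=events_int,
            n_intervention=n_int,
            events_control=events_ctl,
            n_control=n_ctl,
            outcome_name=row["outcome_name"],
            patient_relevant=_parse_bool(row["patient_relevant"], line,
                                         "patient_relevant"),
        )
        out.setdefault(row["comparison_id"], []).append(table)
    return out


def write_trials(
    tables_by_comparison: Mapping[str, Iterable[TrialOutcomeTable]], path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_TRIAL_COLUMNS)
        for comparison_id, tables in tables_by_comparison.items():
            for t in tables:
                writer.writerow([
                    t.study_id, comparison_id, t.outcome_name,
                    t.patient_relevant, t.events_intervention,
                    t.n_intervention, t.events_control, t.n_control,
                ])


def read_reviews(path) -> list[ReviewRecord]:
    df = _read_table(path, _REVIEW_COLUMNS)
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            rtype = ReviewType(row["review_type"])
        except ValueError:
            raise ValidationError(
                f"unknown review type {row['review_type']!r}",
                row=line, column="review_type",
            ) from None
        try:
            out.append(ReviewRecord(
                review_id=row["review_id"],
                review_type=rtype,
                intervention=row["intervention"],
                is_nma=_parse_bool(row["is_nma"], line, "is_nma"),
                n_rcts_included=_parse_int(
                    row["n_rcts_included"], line, "n_rcts_included", 0),
                n_rcts_no_concern=_parse_int(
                    row["n_rcts_no_concern"], line, "n_rcts_no_concern", 0),
                n_rcts_in_primary_ma=_parse_int(
                    row["n_rcts_in_primary_ma"], line,
                    "n_rcts_in_primary_ma", 0),
                n_rcts_in_sensitivity=_parse_int(
                    row["n_rcts_in_sensitivity"], line,
                    "n_rcts_in_sensitivity", 0),
            ))
        except ValueError as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(str(exc), row=line) from None
    return out


def write_reviews(reviews: Iterable[ReviewRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_REVIEW_COLUMNS)
        for r in reviews:
            writer.writerow([
                r.review_id, r.review_type.value, r.intervention, r.is_nma,
                r.n_rcts_included, r.n_rcts_no_concern,
                r.n_rcts_in_primary_ma, r.n_rcts_in_sensitivity,
            ])


def _parse_date(value, line, column):
    token = str(value).strip()
    if not token:
        return None
    try:
        return _dt.date.fromisoformat(token)
    except ValueError:
        raise ValidationError(f"not an ISO date: {value!r}", row=line,
                              column=column) from None


def read_queries(path) -> list[AuthorQuery]:
    df = _read_table(path, _QUERY_COLUMNS)
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        out.append(AuthorQuery(
            study_id=row["study_id"],
            domain=_parse_int(row["domain"], line, "domain", 1),
            resolved=_parse_bool(row["resolved"], line, "resolved"),
            sent_date=_parse_date(row["sent_date"], line, "sent_date"),
            response_date=_parse_date(row["response_date"], line,
                                      "response_date"),
        ))
    return out


def write_queries(queries: Iterable[AuthorQuery], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_QUERY_COLUMNS)
        for q in queries:
            writer.writerow([
                q.study_id, q.domain,
                q.sent_date.isoformat() if q.sent_date else "",
                q.response_date.isoformat() if q.response_date else "",
                q.resolved,
            ])


def write_rob_labels(labels: Iterable[RobLabel], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["study_id", "rob", "ria_pass"])
        for lab in labels:
            writer.writerow([lab.study_id, lab.rob.value, lab.ria_pass])


def read_rob_labels(path) -> list[RobLabel]:
    df = _read_table(path, ["study_id", "rob", "ria_pass"])
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            rob = RobRating(row["rob"])
        except ValueError:
            raise ValidationError(f"unknown RoB rating {row['rob']!r}",
                                  row=line, column="rob") from None
        out.append(RobLabel(
            study_id=row["study_id"], rob=rob,
            ria_pass=_parse_bool(row["ria_pass"], line, "ria_pass"),
        ))
    return out
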