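"""Bundled summary data of a published integrity-screening exercise.

The package ships the row-level summary of a meta-epidemiological
application of the six-domain research-integrity assessment to 206
randomized trials drawn from 23 systematic reviews (26 review-intervention
rows) of COVID-19 drug interventions, as printed in the study report:
per-row trial counts before/after the screen, original and sensitivity
pooled estimates with 95% CIs, per-domain interrater-agreement statistics,
per-tier assessment-time means, record-filter stages, final classification
counts and author-correspondence tallies.

Trial-level ratings and 2x2 outcome data underlying those summaries were
never published; quantities that need them (3x3 agreement tables, re-pooled
effects) are therefore exercised on synthetic corpora instead
(:mod:`ria_impact.synthetic_data`).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .impact_report import FilterStage, RobLabel, RobRating, TimeLog
from .ria_engine import AssessorTier


def _read_csv(name: str, **kwargs) -> pd.DataFrame:
    ref = importlib.resources.files("ria_impact").joinpath(f"data/{name}")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, **kwargs)


def load_review_summary() -> pd.DataFrame:
    """26 review-intervention rows of the published impact table.

    ``k_original`` / ``k_sensitivity`` are trial counts in the primary-
    outcome meta-analysis before/after the screen; ``n_no_concern`` the
    per-row count of trials passing the screen.  Network-meta-analysis rows
    (``is_nma``) were never re-pooled.  One row (Naveed-2022) prints both a
    mixed RCT/NRSI pooled value (main columns, as used by the published
    medians) and an RCT-only recalculation (``*_rct_only`` columns).
    """
    df = _read_csv("review_summary.csv")
    df["is_nma"] = df["is_nma"].astype(bool)
    df["sens_estimable"] = df["sens_estimable"].astype(bool)
    return df


def load_assessment_times() -> pd.DataFrame:
    """Published per-domain mean assessment times (seconds) by tier.

    Tiers are "beginner" and "expert" (the published pooling of
    intermediate and senior second assessors).
    """
    return _read_csv("assessment_times.csv")


#: Printed per-tier totals of the published time table.  The expert total
#: prints as 20:51 while the printed per-domain means sum to 20:52; the
#: 1-second difference is rounding of the printed means.
PUBLISHED_TIME_TOTALS_HMS = {"beginner": "0:26:58", "expert": "0:20:51"}


def published_time_logs() -> list[TimeLog]:
    """The published mean times as :class:`TimeLog` records.

    The published "expert" tier maps onto :class:`AssessorTier.INTERMEDIATE`
    (the second assessor's modal tier).
    """
    tier_map = {"beginner": AssessorTier.BEGINNER,
                "expert": AssessorTier.INTERMEDIATE}
    df = load_assessment_times()
    return [
        TimeLog(tier_map[row.tier], int(row.domain), float(row.mean_seconds))
        for row in df.itertuples()
    ]


def load_agreement_summary() -> pd.DataFrame:
    """Published per-domain interrater agreement between the two
    first-round assessors (pair counts, kappa, linear-weighted kappa, SE,
    band).  The underlying 3x3 tables were not published."""
    return _read_csv("agreement_summary.csv")


#: Final overall classification counts of the 206 assessed reports.
FINAL_OVERALL_COUNTS = {
    "no_concern": 57,
    "awaiting": 79,
    "exclude": 59,
    "non_rct": 11,
}

#: Final (adjudicated) per-domain decision counts across the 206 reports.
FINAL_DOMAIN_COUNTS = {
    1: {"no_concern": 196, "awaiting": 2, "exclude": 8, "non_rct": 0,
        "not_assessed": 0},
    2: {"no_concern": 109, "awaiting": 28, "exclude": 51, "non_rct": 10,
        "not_assessed": 8},
    3: {"no_concern": 75, "awaiting": 62, "exclude": 0, "non_rct": 0,
        "not_assessed": 69},
    4: {"no_concern": 129, "awaiting": 8, "exclude": 0, "non_rct": 0,
        "not_assessed": 69},
    5: {"no_concern": 108, "awaiting": 28, "exclude": 0, "non_rct": 1,
        "not_assessed": 69},
    6: {"no_concern": 108, "awaiting": 28, "exclude": 0, "non_rct": 0,
        "not_assessed": 70},
}

#: Author-correspondence tallies per domain: requests sent, responses
#: received, and studies reclassified from awaiting to no concern.
AUTHOR_CORRESPONDENCE = {
    2: {"requests": 44, "responses": 11, "reclassified": 7},
    3: {"requests": 70, "responses": 20, "reclassified": 17},
    4: {"requests": 2, "responses": 0, "reclassified": 0},
    5: {"requests": 24, "responses": 2, "reclassified": 1},
    6: {"requests": 25, "responses": 3, "reclassified": 3},
}

#: Overall correspondence volume (queries can repeat per study/domain).
TOTAL_AUTHOR_QUERIES = 165
TOTAL_AUTHOR_RESPONSES = 35
TOTAL_RECLASSIFIED = 28


def record_filter_stages() -> tuple[int, list[FilterStage]]:
    """The published record-filter chain: 237 extracted reports down to the
    206 assessed ones."""
    return 237, [
        FilterStage("deduplicate", 13, "duplicate trial reports"),
        FilterStage("drop_protocol_only", 17,
                    "registered protocols without reported results"),
        FilterStage("drop_non_english", 1, "non-English-language article"),
    ]


#: Published within-stratum risk-of-bias percentages for trials passing vs
#: failing the screen (150 trials with RoB data: 61 pass, 89 fail).  The
#: fail-stratum high-risk cell prints as 21.4 although the reconstructed
#: counts give 19/89 = 21.3 (a rounding variant in the source).
PUBLISHED_ROB_PERCENTAGES = {
    "pass": {"low": 37.7, "some_concerns": 39.3, "high": 23.0},
    "fail": {"low": 30.3, "some_concerns": 48.3, "high": 21.4},
}


def reconstructed_rob_counts() -> dict[str, dict[str, int]]:
    """Integer RoB counts per stratum, reconstructed from the published
    rounded percentages (unique composition of 61 and 89 that reproduces
    them).  These counts were not printed; treat them as a reconstruction.
    """
    return {
        "pass": {"low": 23, "some_concerns": 24, "high": 14},
        "fail": {"low": 27, "some_concerns": 43, "high": 19},
    }


def reconstructed_rob_labels() -> list[RobLabel]:
    """Synthetic study-level RoB labels realizing the reconstructed counts.

    Study ids are synthetic placeholders; only the stratum totals carry
    information.
    """
    labels = []
    i = 0
    for stratum, counts in reconstructed_rob_counts().items():
        passed = stratum == "pass"
        for cat, n in counts.items():
            for _ in range(n):
                i += 1
                labels.append(
                    RobLabel(f"rob-{i:03d}", RobRating(cat), passed)
                )
    return labels
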