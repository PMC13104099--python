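"""Interrater agreement for the three ordered RIA categories.

Agreement between the two first-round assessors is quantified per domain
(and for the overall decision) with Cohen's kappa over the ordered scale
no concern (0) < awaiting classification (1) < exclude (2), using linear
agreement weights w_ij = 1 - |i-j|/2 so that a no-concern-vs-awaiting
disagreement costs half as much as no-concern-vs-exclude.

Because the workflow truncates on exclusion, later domains are rated by
fewer assessors; a pair is formed only when *both* assessors actively rated
the domain, and studies with one or zero ratings are tallied separately.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import UndefinedKappaError
from .ria_engine import N_DOMAINS, StudyAssessment, Verdict

#: Ordinal codes of the three kappa categories.  The senior assessor's
#: non-RCT verdict has no first-round counterpart and collapses to exclude.
CATEGORY_CODES = {
    Verdict.NO_CONCERN: 0,
    Verdict.AWAITING: 1,
    Verdict.EXCLUDE: 2,
    Verdict.NON_RCT: 2,
}

CATEGORY_LABELS = ("no_concern", "awaiting", "exclude")


class Band(str, enum.Enum):
    """Conventional interpretation bands for kappa."""

    NO_AGREEMENT = "no_agreement"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class RatingPair:
    """Both assessors' ordinal ratings of one study on one domain."""

    study_id: str
    rating_a: int
    rating_b: int

    def __post_init__(self):
        for r in (self.rating_a, self.rating_b):
            if r not in (0, 1, 2):
                raise ValueError(f"rating must be 0, 1 or 2, got {r}")


@dataclass(frozen=True)
class PairBuildResult:
    pairs: tuple
    n_one_rating: int   # exactly one assessor reached the domain
    n_no_rating: int    # neither did (excluded earlier by both)


def build_pairs(
    assessments_a: Iterable[StudyAssessment],
    assessments_b: Iterable[StudyAssessment],
    domain: int | None = None,
) -> PairBuildResult:
    """Pair up two assessors' ratings for one domain (or overall).

    ``domain=None`` pairs the overall classifications instead, which always
    exist for every study.  Only studies present in both collections are
    considered; a pair is emitted when both verdicts fall in the three
    rateable categories.
    """
    by_a = {a.study_id: a for a in assessments_a}
    by_b = {b.study_id: b for b in assessments_b}
    common = sorted(set(by_a) & set(by_b))
    pairs, one, none = [], 0, 0
    for sid in common:
        if domain is None:
            va, vb = by_a[sid].overall, by_b[sid].overall
        else:
            va, vb = by_a[sid].verdict(domain), by_b[sid].verdict(domain)
        ca, cb = CATEGORY_CODES.get(va), CATEGORY_CODES.get(vb)
        if ca is not None and cb is not None:
            pairs.append(RatingPair(sid, ca, cb))
        elif ca is not None or cb is not None:
            one += 1
        else:
            none += 1
    return PairBuildResult(tuple(pairs), one, none)


def confusion_matrix(pairs: Iterable[RatingPair]) -> np.ndarray:
    """3x3 count matrix with assessor A on rows and B on columns."""
    m = np.zeros((3, 3), dtype=float)
    for p in pairs:
        m[p.rating_a, p.rating_b] += 1
    return m


def linear_weights(k: int = 3) -> np.ndarray:
    """Agreement weights 1 - |i-j|/(k-1)."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def identity_weights(k: int = 3) -> np.ndarray:
    return np.eye(k)


@dataclass(frozen=True)
class AgreementResult:
    """Kappa statistics for one domain's paired ratings."""

    n: int
    confusion: np.ndarray
    p_observed: float
    p_expected: float
    kappa_unweighted: float
    kappa_weighted: float
    se: float
    band: Band
    pct_disagree: float

    @property
    def n_agree(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def n_disagree(self) -> int:
        return self.n - self.n_agree


def _kappa_from_probabilities(p: np.ndarray, w: np.ndarray):
    """(kappa, p_o, p_e) for a joint probability matrix ``p``."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "chance agreement is 1 (all mass in one category); "
            "kappa is undefined"
        )
    return (p_o - p_e) / (1.0 - p_e), p_o, p_e


def _kappa_se(p: np.ndarray, w: np.ndarray, n: int) -> float:
    """Large-sample standard error of weighted kappa.

    The asymptotic (non-null) variance of Fleiss, Cohen & Everitt for the
    weighted kappa of a single 2-way table:

        var = [ sum_ij p_ij (w_ij - (wbar_i. + wbar_.j)(1-k))^2
                - (k - p_e (1-k))^2 ] / ( n (1-p_e)^2 )

    where wbar_i. = sum_j w_ij p_.j and wbar_.j = sum_i w_ij p_i. .
    """
    kappa, _, p_e = _kappa_from_probabilities(p, w)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    wbar_row = w @ col          # wbar_i. over columns' marginal
    wbar_col = w.T @ row        # wbar_.j over rows' marginal
    penalty = (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    term = float((p * (w - penalty) ** 2).sum())
    var = (term - (kappa - p_e * (1.0 - kappa)) ** 2) / (
        n * (1.0 - p_e) ** 2
    )
    return math.sqrt(max(var, 0.0))


def weighted_kappa(
    pairs: Iterable[RatingPair] | np.ndarray,
    weights: str = "linear",
) -> AgreementResult:
    """Cohen's kappa for a list of rating pairs or a 3x3 count matrix.

    ``weights="linear"`` applies the linear agreement weights appropriate
    for the ordered three-category scale; ``weights="unweighted"`` uses
    identity weights (classical kappa).  The reported ``kappa_weighted``,
    standard error and band follow the requested weighting, while
    ``kappa_unweighted`` is always the identity-weight statistic.

    Raises
    ------
    UndefinedKappaError
        When all mass lies in a single cell so chance agreement is 1.
    ValueError
        On an empty input.
    """
    if isinstance(pairs, np.ndarray):
        m = np.asarray(pairs, dtype=float)
        if m.shape != (3, 3) or (m < 0).any():
            raise ValueError("count matrix must be 3x3 and nonnegative")
    else:
        m = confusion_matrix(pairs)
    n = int(m.sum())
    if n < 1:
        raise ValueError("kappa requires at least one rating pair")
    p = m / n
    if weights == "linear":
        w = linear_weights()
    elif weights == "unweighted":
        w = identity_weights()
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    kappa_w, p_o, p_e = _kappa_from_probabilities(p, w)
    try:
        kappa_u, _, _ = _kappa_from_probabilities(p, identity_weights())
    except UndefinedKappaError:
        kappa_u = float("nan")
    se = _kappa_se(p, w, n)
    pct_disagree = 100.0 * (n - float(np.trace(m))) / n
    return AgreementResult(
        n=n,
        confusion=m,
        p_observed=p_o,
        p_expected=p_e,
        kappa_unweighted=kappa_u,
        kappa_weighted=kappa_w,
        se=se,
        band=interpret_band(kappa_w),
        pct_disagree=pct_disagree,
    )


def _round_half_away(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def interpret_band(kappa: float) -> Band:
    """Interpretation band for a kappa value.

    Kappa is rounded half-away-from-zero to two decimals first, because the
    conventional bands are closed two-decimal ranges (0.00-0.20, 0.21-0.40,
    0.41-0.60, 0.61-0.80, 0.81-1.00) with negative values meaning no
    agreement.
    """
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    k = _round_half_away(kappa, 2)
    if k < 0:
        return Band.NO_AGREEMENT
    if k <= 0.20:
        return Band.SLIGHT
    if k <= 0.40:
        return Band.FAIR
    if k <= 0.60:
        return Band.MODERATE
    if k <= 0.80:
        return Band.SUBSTANTIAL
    return Band.ALMOST_PERFECT


def agreement_report(
    assessments_a: Iterable[StudyAssessment],
    assessments_b: Iterable[StudyAssessment],
    domains: Sequence[int] | None = None,
    include_overall: bool = True,
) -> pd.DataFrame:
    """Per-domain (plus overall) agreement table.

    One row per domain with pair counts, single/no-rating tallies, raw
    agreement, both kappas, the standard error and the interpretation band —
    the layout conventionally used to report RIA reliability.
    """
    assessments_a = list(assessments_a)
    assessments_b = list(assessments_b)
    domains = list(domains) if domains is not None else list(
        range(1, N_DOMAINS + 1)
    )
    keys: list = list(domains) + ([None] if include_overall else [])
    rows = []
    for d in keys:
        built = build_pairs(assessments_a, assessments_b, d)
        label = "overall" if d is None else d
        if not built.pairs:
            rows.append({
                "domain": label,
                "n_pairs": 0,
                "n_one_rating": built.n_one_rating,
                "n_no_rating": built.n_no_rating,
                "n_agree": 0, "n_disagree": 0,
                "pct_disagree": float("nan"),
                "kappa": float("nan"), "se": float("nan"),
                "weighted_kappa": float("nan"), "band": "",
            })
            continue
        res = weighted_kappa(built.pairs, weights="linear")
        rows.append({
            "domain": label,
            "n_pairs": res.n,
            "n_one_rating": built.n_one_rating,
            "n_no_rating": built.n_no_rating,
            "n_agree": res.n_agree,
            "n_disagree": res.n_disagree,
            "pct_disagree": res.pct_disagree,
            "kappa": res.kappa_unweighted,
            "se": res.se,
            "weighted_kappa": res.kappa_weighted,
            "band": res.band.value,
        })
    return pd.DataFrame(rows)


def expected_kappa_from_joint(joint: np.ndarray, weights: str = "linear"):
    """Weighted kappa implied by a joint rating probability matrix.

    Used as the closed-form counterpart of simulated two-rater data; the
    sample statistic converges to this value as the number of rated studies
    grows.
    """
    joint = np.asarray(joint, dtype=float)
    if not np.isclose(joint.sum(), 1.0):
        raise ValueError("joint probabilities must sum to 1")
    w = linear_weights() if weights == "linear" else identity_weights()
    kappa, _, _ = _kappa_from_probabilities(joint, w)
    return kappa
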