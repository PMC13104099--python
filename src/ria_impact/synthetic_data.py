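"""Synthetic review corpora with known ground truth.

Generates complete inputs for the whole pipeline — reviews, trials with
binomial 2x2 outcomes under a configurable true risk ratio, per-trial
integrity ground truth, two first-round assessors plus a senior third
assessor whose verdicts are drawn from tier-specific confusion matrices
(honoring the hierarchical truncation of the workflow), risk-of-bias
labels, and per-domain assessment-time logs — so every stage of the
pipeline is testable without any external data.

The default calibration (``data/calibration.yaml``, versioned) emulates a
206-trial COVID-19 drug-trial corpus: per-domain issue rates conditional on
reaching the domain, trial sizes with median ~160 randomized participants,
and assessment times of 21-27 minutes per trial.  Awaiting-level issues
co-occur within trials through a latent two-class "documentation quality"
mixture (see the YAML header); terminal issues are independent across
domains.

Randomness is hierarchical: every review, trial and assessor stream is
seeded by ``SeedSequence(seed, spawn_key=(review, trial, stream))``, so the
same seed yields a bit-identical corpus and appending reviews never
perturbs earlier ones.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .impact_report import RobLabel, RobRating, TimeLog
from .meta_engine import TrialOutcomeTable
from .reliability import expected_kappa_from_joint
from .ria_engine import (
    N_DOMAINS,
    NON_RCT_DOMAINS,
    AdjudicationPolicy,
    AdjudicationResult,
    AssessorTier,
    RatingSheet,
    StudyAssessment,
    Verdict,
    adjudicate,
)

_TRUTH_OK = "ok"
_TRUTH_AWAITING = "awaiting"
_TRUTH_EXCLUDE = "exclude"
_TRUTH_NON_RCT = "non_rct"

#: ordinal category of a true domain status, as seen by an assessor
_TRUTH_CATEGORY = {
    _TRUTH_OK: 0,
    _TRUTH_AWAITING: 1,
    _TRUTH_EXCLUDE: 2,
    _TRUTH_NON_RCT: 2,
}


@dataclass(frozen=True)
class NegativeBinomial:
    """Trial-count distribution (over-dispersed relative to Poisson)."""

    mean: float
    dispersion: float  # negative-binomial size parameter r
    minimum: int = 1

    def sample(self, rng: np.random.Generator) -> int:
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("negative-binomial mean/dispersion must be > 0")
        p = self.dispersion / (self.dispersion + self.mean)
        return max(self.minimum, int(rng.negative_binomial(self.dispersion,
                                                           p)))


@dataclass(frozen=True)
class LogNormal:
    """Arm-size (or duration) distribution on the positive axis."""

    mu: float
    sigma: float
    minimum: float = 1.0
    maximum: Optional[float] = None

    def sample(self, rng: np.random.Generator) -> float:
        if self.sigma < 0:
            raise ValueError("lognormal sigma must be nonnegative")
        x = float(rng.lognormal(self.mu, self.sigma))
        x = max(self.minimum, x)
        if self.maximum is not None:
            x = min(self.maximum, x)
        return x


@dataclass(frozen=True)
class DomainIssueRates:
    """Per-domain probabilities of integrity issues of each severity."""

    exclude: float = 0.0
    awaiting: float = 0.0
    non_rct: float = 0.0

    def __post_init__(self):
        for name in ("exclude", "awaiting", "non_rct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate {v} outside [0, 1]")
        if self.exclude + self.non_rct > 1.0:
            raise ValueError("terminal-issue rates exceed 1")


def _check_profile(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3) or (m < 0).any():
        raise ValueError("assessor profile must be a nonnegative 3x3 matrix")
    if not np.allclose(m.sum(axis=1), 1.0):
        raise ValueError("assessor profile rows must sum to 1")
    return m


def _load_defaults() -> dict:
    ref = importlib.resources.files("ria_impact").joinpath(
        "data/calibration.yaml"
    )
    return yaml.safe_load(ref.read_text(encoding="utf-8"))


_DEFAULTS = None


def default_calibration() -> dict:
    """The packaged, versioned default calibration (cached)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _load_defaults()
    return _DEFAULTS


def _default_issue_prevalence() -> dict:
    raw = default_calibration()["issue_prevalence"]
    return {int(d): DomainIssueRates(**v) for d, v in raw.items()}


def _default_profiles() -> dict:
    raw = default_calibration()["assessor_profiles"]
    return {
        AssessorTier(t): _check_profile(m) for t, m in raw.items()
    }


def _default_time_model() -> dict:
    cal = default_calibration()
    sigma = float(cal["time_sigma"])
    out = {}
    for tier, means in cal["time_model_mean_seconds"].items():
        for d, m in means.items():
            # mu chosen so the lognormal mean equals the configured mean
            out[(AssessorTier(tier), int(d))] = LogNormal(
                mu=float(np.log(m)) - sigma ** 2 / 2.0, sigma=sigma,
                minimum=1.0,
            )
    return out


@dataclass(frozen=True)
class CorpusSpec:
    """Full parameterization of a synthetic corpus."""

    seed: int = 0
    n_reviews: int = field(
        default_factory=lambda: int(default_calibration()["n_reviews"])
    )
    cochrane_fraction: float = field(
        default_factory=lambda: float(
            default_calibration()["cochrane_fraction"]
        )
    )
    trials_per_review: NegativeBinomial = field(
        default_factory=lambda: NegativeBinomial(
            mean=float(default_calibration()["trials_per_review"]["mean"]),
            dispersion=float(
                default_calibration()["trials_per_review"]["dispersion"]
            ),
            minimum=int(default_calibration()["trials_per_review"]["minimum"]),
        )
    )
    arm_size: LogNormal = field(
        default_factory=lambda: LogNormal(
            mu=float(default_calibration()["arm_size"]["mu"]),
            sigma=float(default_calibration()["arm_size"]["sigma"]),
            minimum=float(default_calibration()["arm_size"]["minimum"]),
            maximum=float(default_calibration()["arm_size"]["maximum"]),
        )
    )
    control_risk: float = field(
        default_factory=lambda: float(default_calibration()["control_risk"])
    )
    #: scalar applied to every review, or one value per review
    true_log_effect: float | Sequence[float] = field(
        default_factory=lambda: float(
            default_calibration()["true_log_effect"]
        )
    )
    issue_prevalence: Mapping[int, DomainIssueRates] = field(
        default_factory=_default_issue_prevalence
    )
    well_documented_fraction: float = field(
        default_factory=lambda: float(
            default_calibration()["well_documented_fraction"]
        )
    )
    assessor_profiles: Mapping[AssessorTier, np.ndarray] = field(
        default_factory=_default_profiles
    )
    second_assessor_tier: AssessorTier = AssessorTier.INTERMEDIATE
    rob_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(
            default_calibration()["rob_distribution"]
        )
    )
    time_model: Mapping[tuple, LogNormal] = field(
        default_factory=_default_time_model
    )

    def __post_init__(self):
        if not 0.0 <= self.control_risk <= 1.0:
            raise ValueError("control_risk must be a probability")
        if not 0.0 <= self.well_documented_fraction < 1.0:
            raise ValueError("well_documented_fraction must be in [0, 1)")
        for d, rates in self.issue_prevalence.items():
            if d not in range(1, N_DOMAINS + 1):
                raise ValueError(f"issue prevalence for invalid domain {d}")
            inflated = rates.awaiting / (1.0 - self.well_documented_fraction)
            if inflated > 1.0 + 1e-12:
                raise ValueError(
                    f"domain {d}: awaiting rate {rates.awaiting} cannot be "
                    f"concentrated on the poorly-documented class"
                )
            if rates.non_rct > 0 and d not in NON_RCT_DOMAINS:
                raise ValueError(
                    f"domain {d}: non-RCT issues only arise in domains "
                    f"{sorted(NON_RCT_DOMAINS)}"
                )
        for tier, m in self.assessor_profiles.items():
            _check_profile(m)
        total = sum(self.rob_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("rob_distribution must sum to 1")

    def effect_for_review(self, index: int) -> float:
        if np.isscalar(self.true_log_effect):
            return float(self.true_log_effect)
        return float(self.true_log_effect[index])


@dataclass(frozen=True)
class SyntheticReview:
    review_id: str
    review_type: str  # "cochrane" | "non_cochrane"
    true_log_effect: float


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth for one synthetic trial."""

    study_id: str
    review_id: str
    domain_status: tuple  # 6 of {"ok","awaiting","exclude","non_rct"}
    well_documented: bool
    true_log_rr: float
    n_intervention: int
    n_control: int

    @property
    def overall(self) -> Verdict:
        """The classification an error-free hierarchical assessor reaches."""
        awaiting = False
        for status in self.domain_status:
            if status == _TRUTH_EXCLUDE:
                return Verdict.EXCLUDE
            if status == _TRUTH_NON_RCT:
                return Verdict.NON_RCT
            awaiting = awaiting or status == _TRUTH_AWAITING
        return Verdict.AWAITING if awaiting else Verdict.NO_CONCERN

    @property
    def terminal_domain(self) -> Optional[int]:
        for d, status in enumerate(self.domain_status, start=1):
            if status in (_TRUTH_EXCLUDE, _TRUTH_NON_RCT):
                return d
        return None


@dataclass(frozen=True)
class SyntheticCorpus:
    spec: CorpusSpec
    reviews: tuple
    truths: tuple            # TrialTruth per trial
    outcome_tables: tuple    # TrialOutcomeTable per trial
    first_assessments: tuple
    second_assessments: tuple
    third_ratings: tuple     # RatingSheet per trial (untruncated)
    rob_labels: tuple
    time_logs: tuple

    def truth_by_id(self) -> dict:
        return {t.study_id: t for t in self.truths}

    def tables_for_review(self, review_id: str) -> list:
        ids = {t.study_id for t in self.truths if t.review_id == review_id}
        return [t for t in self.outcome_tables if t.study_id in ids]

    def adjudicated(
        self, policy: AdjudicationPolicy | None = None
    ) -> list[AdjudicationResult]:
        """Run third-assessor adjudication for every trial."""
        thirds = {s.study_id: s for s in self.third_ratings}
        out = []
        for first, second in zip(self.first_assessments,
                                 self.second_assessments):
            out.append(
                adjudicate(first, second, thirds[first.study_id], policy)
            )
        return out

    def final_assessments(
        self, policy: AdjudicationPolicy | None = None
    ) -> list[StudyAssessment]:
        return [r.final for r in self.adjudicated(policy)]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=spawn_key)
    )


def _sample_truth_vector(
    spec: CorpusSpec, rng: np.random.Generator
) -> tuple[tuple, bool]:
    well = bool(rng.random() < spec.well_documented_fraction)
    awaiting_scale = 0.0 if well else 1.0 / (
        1.0 - spec.well_documented_fraction
    )
    statuses = []
    for d in range(1, N_DOMAINS + 1):
        rates = spec.issue_prevalence.get(d, DomainIssueRates())
        u = rng.random()
        if u < rates.exclude:
            status = _TRUTH_EXCLUDE
        elif u < rates.exclude + rates.non_rct:
            status = _TRUTH_NON_RCT
        else:
            status = _TRUTH_OK
        # awaiting-level issues ride on the documentation-quality class and
        # are recorded even alongside a terminal issue (they only surface if
        # the trial survives to the domain without the terminal call)
        if status == _TRUTH_OK and rng.random() < min(
            1.0, rates.awaiting * awaiting_scale
        ):
            status = _TRUTH_AWAITING
        statuses.append(status)
    return tuple(statuses), well


def _rate_domain(
    truth: TrialTruth,
    domain: int,
    profile: np.ndarray,
    rng: np.random.Generator,
    emit_non_rct: bool,
) -> Verdict:
    status = truth.domain_status[domain - 1]
    rated = int(rng.choice(3, p=profile[_TRUTH_CATEGORY[status]]))
    if rated == 0:
        return Verdict.NO_CONCERN
    if rated == 1:
        return Verdict.AWAITING
    if (
        emit_non_rct
        and status == _TRUTH_NON_RCT
        and domain in NON_RCT_DOMAINS
    ):
        return Verdict.NON_RCT
    return Verdict.EXCLUDE


def _assess(
    truth: TrialTruth,
    assessor_id: str,
    tier: AssessorTier,
    profile: np.ndarray,
    rng: np.random.Generator,
    emit_non_rct: bool,
) -> StudyAssessment:
    """Hierarchical walk: rate each domain from the tier's confusion row,
    stopping at the assessor's own first terminal verdict."""
    verdicts = []
    for d in range(1, N_DOMAINS + 1):
        v = _rate_domain(truth, d, profile, rng, emit_non_rct)
        verdicts.append(v)
        if v in (Verdict.EXCLUDE, Verdict.NON_RCT):
            break
    return StudyAssessment.from_prefix(
        truth.study_id, assessor_id, tier, verdicts
    )


def _rate_all_domains(
    truth: TrialTruth,
    assessor_id: str,
    tier: AssessorTier,
    profile: np.ndarray,
    rng: np.random.Generator,
) -> RatingSheet:
    """Untruncated re-rating of all six domains (adjudicator's sheet).

    The senior assessor rates domains on demand during adjudication, so
    their sheet is not cut short by their own terminal verdicts; consensus
    truncation is applied downstream by :func:`ria_impact.adjudicate`.
    """
    ratings = {
        d: _rate_domain(truth, d, profile, rng, emit_non_rct=True)
        for d in range(1, N_DOMAINS + 1)
    }
    return RatingSheet(truth.study_id, assessor_id, tier, ratings)


def _time_logs_for(
    assessment: StudyAssessment,
    tier: AssessorTier,
    time_model: Mapping[tuple, LogNormal],
    rng: np.random.Generator,
) -> list[TimeLog]:
    logs = []
    for d in range(1, N_DOMAINS + 1):
        if assessment.verdict(d) is Verdict.NOT_ASSESSED:
            break
        dist = time_model.get((tier, d))
        if dist is None:
            continue
        logs.append(TimeLog(tier, d, dist.sample(rng)))
    return logs


def generate(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a full corpus from a spec (deterministic given the seed)."""
    rob_cats = list(RobRating)
    rob_p = [float(spec.rob_distribution[c.value]) for c in rob_cats]
    profiles = {t: np.asarray(m, dtype=float)
                for t, m in spec.assessor_profiles.items()}
    n_cochrane = int(round(spec.n_reviews * spec.cochrane_fraction))

    reviews, truths, tables = [], [], []
    firsts, seconds, thirds = [], [], []
    robs, logs = [], []
    for r in range(spec.n_reviews):
        review_id = f"R{r + 1:03d}"
        review_type = "cochrane" if r < n_cochrane else "non_cochrane"
        log_rr = spec.effect_for_review(r)
        rng_review = _rng(spec.seed, r)
        n_trials = spec.trials_per_review.sample(rng_review)
        reviews.append(SyntheticReview(review_id, review_type, log_rr))
        for t in range(n_trials):
            study_id = f"{review_id}-T{t + 1:03d}"
            rng_trial = _rng(spec.seed, r, t)
            statuses, well = _sample_truth_vector(spec, rng_trial)
            n_int = int(round(spec.arm_size.sample(rng_trial)))
            n_ctl = int(round(spec.arm_size.sample(rng_trial)))
            truth = TrialTruth(
                study_id=study_id, review_id=review_id,
                domain_status=statuses, well_documented=well,
                true_log_rr=log_rr,
                n_intervention=n_int, n_control=n_ctl,
            )
            truths.append(truth)
            p_ctl = spec.control_risk
            p_int = min(1.0, p_ctl * float(np.exp(log_rr)))
            tables.append(TrialOutcomeTable(
                study_id=study_id,
                events_intervention=int(rng_trial.binomial(n_int, p_int)),
                n_intervention=n_int,
                events_control=int(rng_trial.binomial(n_ctl, p_ctl)),
                n_control=n_ctl,
                outcome_name="all_cause_mortality",
            ))
            robs.append(RobLabel(
                study_id=study_id,
                rob=rob_cats[int(rng_trial.choice(len(rob_cats), p=rob_p))],
                ria_pass=truth.overall is Verdict.NO_CONCERN,
            ))
            streams = [
                ("A1", AssessorTier.BEGINNER, firsts),
                ("A2", spec.second_assessor_tier, seconds),
            ]
            for stream_idx, (aid, tier, sink) in enumerate(streams, start=1):
                rng_assessor = _rng(spec.seed, r, t, stream_idx)
                assessment = _assess(
                    truth, aid, tier, profiles[tier], rng_assessor,
                    emit_non_rct=False,
                )
                sink.append(assessment)
                rng_time = _rng(spec.seed, r, t, 10 + stream_idx)
                logs.extend(_time_logs_for(
                    assessment, tier, spec.time_model, rng_time
                ))
            rng_third = _rng(spec.seed, r, t, 3)
            thirds.append(_rate_all_domains(
                truth, "A3", AssessorTier.SENIOR,
                profiles[AssessorTier.SENIOR], rng_third,
            ))
    return SyntheticCorpus(
        spec=spec,
        reviews=tuple(reviews),
        truths=tuple(truths),
        outcome_tables=tuple(tables),
        first_assessments=tuple(firsts),
        second_assessments=tuple(seconds),
        third_ratings=tuple(thirds),
        rob_labels=tuple(robs),
        time_logs=tuple(logs),
    )


def error_free_profiles() -> dict:
    """Identity confusion matrices (assessors that never err)."""
    eye = np.eye(3)
    return {tier: eye.copy() for tier in AssessorTier}


def analytic_kappa(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    truth_distribution: Sequence[float],
    weights: str = "linear",
) -> float:
    """Exact weighted kappa implied by two raters' confusion profiles.

    Conditional on the true category t the raters are independent, so the
    joint rating distribution is sum_t P(t) row_a(t) x row_b(t); kappa
    follows in closed form from that matrix.  Serves as the convergence
    target for empirical kappa estimates on simulated ratings.
    """
    a = _check_profile(profile_a)
    b = _check_profile(profile_b)
    pi = np.asarray(truth_distribution, dtype=float)
    if pi.shape != (3,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValueError("truth distribution must be 3 nonnegative "
                         "probabilities summing to 1")
    joint = np.einsum("t,ti,tj->ij", pi, a, b)
    return expected_kappa_from_joint(joint, weights=weights)


def simulate_rating_pairs(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    truth_distribution: Sequence[float],
    n: int,
    rng: np.random.Generator,
):
    """Draw iid rating pairs from the two-rater confusion model."""
    from .reliability import RatingPair

    a = _check_profile(profile_a)
    b = _check_profile(profile_b)
    pi = np.asarray(truth_distribution, dtype=float)
    truths = rng.choice(3, size=n, p=pi)
    pairs = []
    for i, t in enumerate(truths):
        ra = int(rng.choice(3, p=a[t]))
        rb = int(rng.choice(3, p=b[t]))
        pairs.append(RatingPair(f"S{i}", ra, rb))
    return pairs
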