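import numpy as np
import pytest
from hypothesis import settings

from ria_impact.ria_engine import AssessorTier, StudyAssessment, Verdict

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ria_impact.synthetic_data import CorpusSpec, NegativeBinomial, generate

NC = Verdict.NO_CONCERN
AW = Verdict.AWAITING
EX = Verdict.EXCLUDE
NR = Verdict.NON_RCT
NA = Verdict.NOT_ASSESSED


def assessment(study_id, verdicts, assessor_id="A1",
               tier=AssessorTier.BEGINNER):
    """Build a StudyAssessment from the assessed verdict prefix."""
    return StudyAssessment.from_prefix(study_id, assessor_id, tier, verdicts)


@pytest.fixture(scope="session")
def review_summary():
    from ria_impact import datasets

    return datasets.load_review_summary()


@pytest.fixture(scope="session")
def small_corpus():
    """A modest default-calibration corpus shared across tests."""
    return generate(CorpusSpec(seed=42, n_reviews=8))


@pytest.fixture(scope="session")
def large_corpus():
    """~5000 trials under the default calibration (for statistical checks)."""
    spec = CorpusSpec(
        seed=7,
        n_reviews=10,
        trials_per_review=NegativeBinomial(mean=500, dispersion=1e9,
                                           minimum=1),
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
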