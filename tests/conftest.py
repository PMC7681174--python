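import numpy as np
import pytest

from isrsa import GridSpec, BetaVolumeSet, normalize_scores, score_cohort
from isrsa.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """Scored 12-subject cohort with clean data (no exclusions/missing)."""
    cfg = SimulationConfig(
        n_subjects=12, n_excluded_motion=0, n_excluded_attention=0,
        missing_fraction=0.0, multi_marked_fraction=0.0, seed=11,
    )
    table, _ = generate_cohort(cfg)
    scored, manifest = score_cohort(table)
    return scored, manifest


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    scored, _ = small_cohort
    return normalize_scores(scored["total"].to_numpy(),
                            scored["subject_id"].tolist())


def make_betas(n_subjects=6, shape=(6, 6, 6), seed=0, condition="baseline"):
    r = np.random.default_rng(seed)
    return BetaVolumeSet(
        data=r.standard_normal((n_subjects, *shape)),
        grid=GridSpec.isotropic(shape),
        condition=condition,
        subject_order=[f"sub-{i:02d}" for i in range(n_subjects)],
    )


@pytest.fixture
def random_betas():
    return make_betas()
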