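import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template_m():
    from carilow import make_template

    return make_template("M")


@pytest.fixture(scope="session")
def small_cohort():
    """6-identity cohort without renders; cheap enough for many tests."""
    from carilow import make_cohort

    return make_cohort(n_male=3, n_female=3, pool_size=8, seed=7, render=False)


@pytest.fixture(scope="session")
def small_cohort_rendered():
    from carilow import make_cohort

    return make_cohort(n_male=2, n_female=2, pool_size=6, seed=5, render=True)


@pytest.fixture(scope="session")
def cohort_dissim(small_cohort):
    from carilow.rater_sim import cohort_dissimilarities

    return cohort_dissimilarities(small_cohort)


@pytest.fixture(scope="session")
def small_schedule(small_cohort):
    from carilow.experiment_design import build_schedule

    return build_schedule(
        "E2", small_cohort.ids_by_sex("M"), small_cohort.ids_by_sex("F"), seed=7
    )


@pytest.fixture(scope="session")
def full_cohort():
    """The study-scale cohort (13 + 13 identities), landmarks only."""
    from carilow import make_cohort

    return make_cohort(seed=3, render=False)


@pytest.fixture(scope="session")
def full_dissim(full_cohort):
    from carilow.rater_sim import cohort_dissimilarities

    return cohort_dissimilarities(full_cohort)


@pytest.fixture(scope="session")
def full_schedule_e2(full_cohort):
    from carilow.experiment_design import build_schedule

    return build_schedule(
        "E2", full_cohort.ids_by_sex("M"), full_cohort.ids_by_sex("F"), seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
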