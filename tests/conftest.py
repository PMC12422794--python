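import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_degenerate_sampling_warnings():
    """Micro-fixtures routinely sample fewer targets than the default
    sample size; the resulting warnings are expected noise in tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def worked_world():
    from agealign import worked_example_world

    return worked_example_world()


@pytest.fixture(scope="session")
def worked_config():
    from agealign import worked_example_config

    return worked_example_config()


@pytest.fixture(scope="session")
def small_planted():
    """Small planted world + config sized for fast resampling tests."""
    from agealign import FixtureSpec, ScoringConfig, make_world

    spec = FixtureSpec(
        n_genes=400,
        pathways_per_hallmark=4,
        pathway_size_range=(8, 20),
        planted_hallmarks={"cellular senescence": 0.75},
        n_targets=60,
        seed=7,
    )
    cfg = ScoringConfig(
        top_k=40, sample_size=30, n_samples=25, n_perm=49, seed=7,
        significance_method="sign",
    )
    return make_world(spec), cfg
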