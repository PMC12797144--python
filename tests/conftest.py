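import numpy as np
import pytest

from connectopy import (
    SyntheticConfig,
    TimeseriesMatrix,
    build_similarity,
    generate_cohort,
)


def make_ts(rng, t, v, tag="seed"):
    return TimeseriesMatrix(
        data=rng.standard_normal((t, v)),
        voxel_ids=np.arange(v),
        region_tag=tag,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """5-subject cohort at default noise; shared across test modules."""
    return generate_cohort(SyntheticConfig(n_subjects=5, master_seed=7))


@pytest.fixture(scope="session")
def small_cohort_sims(small_cohort):
    """Within-seed similarity matrices for the small cohort."""
    return [build_similarity(s, None, "within_seed") for s in small_cohort.seed_ts]
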