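import numpy as np
import pytest
from hypothesis import settings

import semdens as sd

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ortho_space():
    """16 mutually orthonormal word embeddings (exact projection oracle)."""
    d = 16
    keys = [f"NN_w{i:02d}" for i in range(d)]
    return sd.EmbeddingSpace(keys, np.eye(d), {k: i + 1 for i, k in enumerate(keys)})


@pytest.fixture(scope="session")
def concept_space():
    """Small concept-structured synthetic space (session-cached)."""
    from semdens.synthetic import FixtureSpec, make_embedding_space
    return make_embedding_space(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort(concept_space):
    """Cohort with both effects at the strong default setting."""
    from semdens.synthetic import FixtureSpec, make_cohort
    return make_cohort(FixtureSpec(seed=7), concept_space)


@pytest.fixture
def fast_unpack():
    return sd.UnpackingConfig.desk_scale()
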