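import numpy as np
import pytest

from dockeval import ScoreSimSpec, gen_score_matrix


@pytest.fixture
def graded_matrix():
    """Three models with increasing active/decoy separation, 10% failures."""
    spec = ScoreSimSpec(
        n_models=3,
        n_actives=50,
        n_decoys=500,
        separation_per_model=[0.5, 1.0, 2.0],
        fail_rate=0.1,
        seed=11,
    )
    return gen_score_matrix(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
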