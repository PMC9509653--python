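import numpy as np
import pandas as pd
import pytest

import coexorder as cx
from coexorder.simulate import ModuleSpec, SyntheticSpec


@pytest.fixture
def small_em():
    """3 genes x 4 samples with known values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [0.5, 0.5, 0.5, 1.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return cx.ExpressionMatrix(data)


@pytest.fixture
def two_block_fixture():
    """Two planted 50-gene blocks plus loose genes; known partition."""
    rng = np.random.default_rng(7)
    spec = SyntheticSpec(
        modules=(ModuleSpec(50, (2.0, 3.0)), ModuleSpec(50, (2.0, 3.0))),
        n_background=40,
        samples_per_cell=10,
        noise_sd=1.0,
        seed=7,
    )
    return cx.generate(spec)


@pytest.fixture(scope="session")
def paper_like_runs():
    """Methods 1-4 on the documented fixture across 10 seeds (shared by the
    module-recovery and ordering-comparison acceptance checks)."""
    runs = []
    for seed in range(10):
        em, tt, truth = cx.generate(cx.default_paper_like_spec(seed))
        results = cx.run_all_methods(em, tt, cx.small_sample_config())
        runs.append((truth, results))
    return runs
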