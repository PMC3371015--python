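import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracles

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_dataset():
    """Small two-view dataset with a coupled label pair, for fast
    end-to-end runs."""
    from mmlgp.synthetic import GeneratorSpec, generate, sample_correlation

    spec = GeneratorSpec(
        n=40, Q=3, m=2, view_dims=(2, 2),
        C=sample_correlation(3, 0.8, pairs=[(0, 1)]),
        a=np.full(2, 1.5), offsets=np.full(3, -0.5),
        multilabel_frac=None, bandwidth_scale=0.7, seed=5,
    )
    return generate(spec)
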