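import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_log_gls(rng, n_ind, n_sites=1):
    """Random genotype log-likelihoods, max-normalized per individual."""
    gl = np.log(rng.uniform(0.01, 1.0, size=(n_sites, n_ind, 3)))
    gl -= gl.max(axis=2, keepdims=True)
    return gl if n_sites > 1 else gl[0]


def point_mass_log_gls(genotypes, big=1e4):
    """Near-perfect GLs: the true genotype has log-likelihood 0, the
    others -big (finite, but exp() == 0 in double precision)."""
    genotypes = np.asarray(genotypes)
    gl = np.full(genotypes.shape + (3,), -big)
    idx = np.indices(genotypes.shape)
    gl[(*idx, genotypes)] = 0.0
    return gl
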