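import numpy as np
import pytest

from elscan.model import ModelParams, SiteSequence


def random_params(rng, n_bins=4):
    """A random valid parameter set with well-separated lengths."""
    l_E = rng.uniform(0.001, 0.01)
    return ModelParams(
        l_I=rng.uniform(0.005, 0.05),
        l_E=l_E,
        l_ELS=l_E * rng.uniform(1.5, 20.0),
        p=rng.uniform(0.01, 0.5),
        eps_I=rng.uniform(0.005, 0.1),
        theta_E_fix=rng.uniform(0.3, 0.9),
        theta_I=np.sort(rng.uniform(0.05, 0.95, size=n_bins)),
        eps_E=0.01,
    )


def random_sequence(rng, L, n_bins=4, n_chrom=10, constant_d=None):
    """A random tiny site sequence (positions, classes, archaic alleles)."""
    if constant_d is None:
        spacing = rng.integers(100, 5000, size=L)
    else:
        spacing = np.full(L, int(constant_d * 1e6))
    pos = np.cumsum(spacing)
    # derived counts spanning all classes incl. fixed
    dcount = rng.integers(1, n_chrom + 1, size=L)
    return SiteSequence(
        pos=pos,
        derived_count=dcount,
        archaic_derived=rng.random(L) < 0.5,
        n_chrom=n_chrom,
        gpos={"uniform": pos * 1e-6},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params4(rng):
    return random_params(rng)
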