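import numpy as np
import pytest

from knockloc import simulate as sim


@pytest.fixture(scope="session")
def tiny_model3():
    """p=3, K=2 haplotype-cluster model, small enough for exact enumeration."""
    return sim.synthetic_hmm(p=3, K=2, seed=7)


@pytest.fixture(scope="session")
def tiny_model4():
    """p=4, K=2 model for the larger enumeration checks."""
    return sim.synthetic_hmm(p=4, K=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate simulated dataset shared by statistics/filter tests.

    Returns (model, H, X, variants, spec, y): n=500 individuals, p=120
    variants, a clustered causal architecture, and a Gaussian trait.
    """
    model = sim.synthetic_hmm(p=120, K=4, seed=13)
    H, X = sim.simulate_genotypes(model, 500, seed=17)
    vt = sim.variant_table(model, X)
    spec = sim.place_causal_clusters(vt, n_clusters=2, seed=19, h2_causal=0.4)
    y = sim.simulate_gaussian_trait(X, spec, seed=23)
    return model, H, X, vt, spec, y


def contiguous_partitions(p):
    """All partitions of 1..p into contiguous groups (2^(p-1) of them)."""
    import itertools

    for mask in itertools.product((0, 1), repeat=p - 1):
        yield np.r_[1, 1 + np.cumsum(mask)]
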