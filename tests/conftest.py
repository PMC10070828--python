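import numpy as np
import pytest

import sscac


@pytest.fixture(scope="session")
def config():
    return sscac.load_config()


@pytest.fixture(scope="session")
def small_subspace():
    """A small, well-separated union of 3 orthogonal subspaces (n=60)."""
    return sscac.make_subspace_data(n=60, m=30, c=3, d=3, noise_sigma=0.02,
                                    seed=11)


@pytest.fixture(scope="session")
def small_affinity(small_subspace, config):
    """Affinity graph of the small fixture, solved once per session."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Z, E, graph = sscac.solve_lrradp(small_subspace.X.values, config)
    return graph
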