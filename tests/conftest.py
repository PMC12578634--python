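import numpy as np
import pandas as pd
import pytest

from legacyscope import synthgen


@pytest.fixture(scope="session")
def design48():
    """6 sites x 8 replicates: the standard small factorial design."""
    return synthgen.gen_design(6, 8, (400.0, 1000.0), seed=11)


@pytest.fixture(scope="session")
def design96():
    """6 sites x 16 replicates: 24 samples per legacy x test-water cell."""
    return synthgen.gen_design(6, 16, (400.0, 1000.0), seed=11)


@pytest.fixture(scope="session")
def community48(design48):
    return synthgen.gen_community(
        design48, n_taxa=60, n_markers=12, slope=1.0, dispersion=0.3,
        zero_prob=0.0, depth=50_000, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def euclid_points():
    r = np.random.default_rng(7)
    pts = r.normal(size=(12, 2))
    from scipy.spatial.distance import pdist, squareform

    d = pd.DataFrame(squareform(pdist(pts)),
                     index=[f"s{i}" for i in range(12)],
                     columns=[f"s{i}" for i in range(12)])
    return pts, d
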