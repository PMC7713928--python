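import numpy as np
import pytest

import preyview as pv
from preyview.multivariate import DistanceMatrix, Permanova
from preyview.synthetic import make_illuminant


@pytest.fixture(scope="session")
def grid():
    return pv.DEFAULT_GRID


@pytest.fixture(scope="session")
def trichromat():
    return pv.goby_trichromat()


@pytest.fixture(scope="session")
def dichromat():
    return pv.goby_dichromat()


@pytest.fixture(scope="session")
def monochromat():
    return pv.mysid_monochromat()


@pytest.fixture(scope="session")
def illuminant_5m():
    return make_illuminant(depth=5.0)


@pytest.fixture(scope="session")
def null_permanova_pvalues():
    """1000 PERMANOVA p-values under a true multivariate null.

    Two groups of 10 points drawn from one bivariate normal; Euclidean
    distances; 199 permutations each.  Shared by the uniformity and
    type-I-error checks so the simulation runs once per session.
    """
    rng = np.random.default_rng(20240517)
    groups = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
    pvals = np.empty(1000)
    for i in range(1000):
        pts = rng.normal(size=(20, 2))
        dm = DistanceMatrix.from_points(pts, groups=groups)
        pvals[i] = Permanova(dm).fit(n_permutations=199, seed=rng).pvalue
    return pvals
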