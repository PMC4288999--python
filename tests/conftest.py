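import numpy as np
import pandas as pd
import pytest

import traitshift as ts


@pytest.fixture(scope="session")
def small_env():
    """20x20 landscape with 2 continuous and 1 categorical layer."""
    return ts.generate_landscape(20, 20, 2, 1, spatial_correlation_length=3,
                                 seed=11)


@pytest.fixture(scope="session")
def small_truths(small_env):
    return ts.generate_species(small_env, 8, seed=12)


@pytest.fixture(scope="session")
def small_occurrences(small_truths, small_env):
    return ts.sample_occurrences(small_truths, small_env, n_sites=350,
                                 seed=13)


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); hand-checkable covariance."""
    import dendropy
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick",
                             preserve_underscores=True)


@pytest.fixture()
def star_tree():
    import dendropy
    return dendropy.Tree.get(data="(A:2,B:2,C:2,D:2);", schema="newick",
                             preserve_underscores=True)


# canonical recovery-experiment helpers live in the package
from traitshift.validation import gaussian_niche_instance, implied_optimum  # noqa: E402,F401
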