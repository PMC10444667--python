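import numpy as np
import pytest

from factortree import Cutpoints, FactorTreeSpec, VineTree, gauss_legendre_01

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def rule25():
    return gauss_legendre_01(25)


@pytest.fixture
def rng():
    return np.random.default_rng(20231103)


@pytest.fixture(scope="session")
def small_tree_model():
    """d=4, K=3, 1-factor Gumbel + Frank D-vine; small enough to enumerate."""
    cp = Cutpoints.equal_categories(4, 3)
    tree = VineTree(4, ((0, 1), (1, 2), (2, 3)))
    return FactorTreeSpec.from_taus(
        cp,
        family1="gumbel", tau1=[0.6, 0.5, 0.4, 0.3],
        vine=tree, vine_family="frank", vine_tau=[0.4, 0.2, 0.1],
    )


@pytest.fixture(scope="session")
def two_factor_model():
    """d=3, K=3, 2-factor (Gumbel, t5) + BVN single-path vine."""
    cp = Cutpoints.equal_categories(3, 3)
    tree = VineTree(3, ((0, 1), (1, 2)))
    return FactorTreeSpec.from_taus(
        cp,
        family1="gumbel", tau1=[0.5, 0.4, 0.3],
        family2="t5", tau2=[0.35, 0.25, 0.15],
        vine=tree, vine_family="bvn", vine_tau=[0.3, 0.15],
    )
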