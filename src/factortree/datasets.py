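"""Synthetic fixture generators.

The fixtures emulate the study designs used throughout the package's tests:
equally weighted 5-category items linked to latent factors by Gumbel
copulas with equally spaced Kendall's-tau grids, plus a synthetic analogue
of a 20-item PTSD symptom checklist (2-factor tree model with t2 / Gumbel /
t5 trees, n=221) exhibiting more dependence in the joint upper tail.  Each
generator returns the data together with the generating model so recovery
can be assessed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .cutpoints import Cutpoints
from .data import OrdinalData
from .simulate import simulate
from .spec import FactorTreeSpec
from .trees import VineTree

__all__ = ["generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("table1-d8", "table1-d16", "table1-d24", "table2-d24", "ptsd-like", "custom")


def _dvine_edges(d: int):
    return tuple((j, j + 1) for j in range(d - 1))


def _one_factor_tree_gumbel(d: int) -> FactorTreeSpec:
    """1-factor tree, Gumbel everywhere: factor taus equally spaced
    0.70..0.40, D-vine residual taus 0.40..0.10, K=5 equal categories."""
    cp = Cutpoints.equal_categories(d, 5)
    return FactorTreeSpec.from_taus(
        cp,
        family1="gumbel", tau1=np.linspace(0.70, 0.40, d),
        vine=VineTree(d, _dvine_edges(d)),
        vine_family="gumbel", vine_tau=np.linspace(0.40, 0.10, d - 1),
    )


def _two_factor_tree_gumbel(d: int) -> FactorTreeSpec:
    """2-factor tree, Gumbel everywhere: factor taus 0.70..0.40 and
    0.55..0.25, D-vine residual taus 0.40..0.10."""
    cp = Cutpoints.equal_categories(d, 5)
    return FactorTreeSpec.from_taus(
        cp,
        family1="gumbel", tau1=np.linspace(0.70, 0.40, d),
        family2="gumbel", tau2=np.linspace(0.55, 0.25, d),
        vine=VineTree(d, _dvine_edges(d)),
        vine_family="gumbel", vine_tau=np.linspace(0.40, 0.10, d - 1),
    )


# synthetic stand-in for the 20-item PTSD checklist analysis: taus of a
# fitted 2-factor tree model with t2 (factor 1), Gumbel (factor 2) and t5
# (residual tree) copulas; the real dataset is not bundled
_PTSD_TAU1 = [-0.17, -0.08, -0.12, -0.34, -0.21, -0.13, -0.09, 0.04, 0.24, -0.12,
              -0.07, 0.28, 0.34, 0.35, 0.11, 0.10, 0.04, 0.12, 0.28, 0.13]
_PTSD_TAU2 = [0.50, 0.45, 0.52, 0.57, 0.56, 0.26, 0.39, 0.19, 0.33, 0.30,
              0.48, 0.50, 0.49, 0.36, 0.44, 0.28, 0.33, 0.46, 0.43, 0.40]
_PTSD_EDGES_TAU = [  # 1-based item pairs with residual t5 taus
    ((1, 18), -0.18), ((18, 17), 0.22), ((18, 14), -0.20), ((18, 10), -0.10),
    ((10, 11), 0.36), ((11, 9), 0.29), ((9, 2), -0.18), ((2, 3), 0.26),
    ((3, 20), 0.05), ((2, 16), 0.13), ((16, 15), 0.17), ((9, 4), 0.29),
    ((20, 5), 0.05), ((14, 13), 0.27), ((5, 6), 0.12), ((6, 7), 0.23),
    ((7, 19), -0.21), ((16, 8), 0.12), ((19, 12), 0.08),
]


def _ptsd_like_model() -> FactorTreeSpec:
    d, K = 20, 5
    cp = Cutpoints.equal_categories(d, K)
    edges = tuple((j - 1, k - 1) for (j, k), _ in _PTSD_EDGES_TAU)
    taus = [t for _, t in _PTSD_EDGES_TAU]
    return FactorTreeSpec.from_taus(
        cp,
        family1="t2", tau1=_PTSD_TAU1,
        family2="gumbel", tau2=_PTSD_TAU2,
        vine=VineTree(d, edges), vine_family="t5", vine_tau=taus,
    )


def generate_fixture(
    kind: str,
    seed: Optional[int] = None,
    n: Optional[int] = None,
    model: Optional[FactorTreeSpec] = None,
) -> Tuple[OrdinalData, FactorTreeSpec]:
    """Generate a named synthetic dataset and return (data, generating model).

    Kinds: ``table1-d8`` / ``table1-d16`` / ``table1-d24`` (1-factor tree,
    Gumbel), ``table2-d24`` (2-factor tree, Gumbel), ``ptsd-like`` (d=20,
    K=5, n=221, t2/Gumbel/t5), and ``custom`` (pass ``model`` explicitly).
    """
    if kind == "custom":
        if model is None:
            raise ValueError("kind='custom' requires a model")
        n = n or 500
    elif kind.startswith("table1-d"):
        d = int(kind.split("d")[-1])
        if d not in (8, 16, 24):
            raise ValueError(f"unknown fixture kind {kind!r}")
        model = _one_factor_tree_gumbel(d)
        n = n or 500
    elif kind == "table2-d24":
        model = _two_factor_tree_gumbel(24)
        n = n or 500
    elif kind == "ptsd-like":
        model = _ptsd_like_model()
        n = n or 221
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    return simulate(model, n, seed=seed), model
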