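"""Full specification of a factor tree copula model.

A model has p in {0, 1, 2} uniform latent factors, per-item linking copulas
for each factor tree (theta_1j for Y_j -- X_1, theta_2j for Y_j -- X_2 given
X_1), an optional Markov tree of residual conditional copulas (delta_jk for
Y_j -- Y_k given the factors), and per-item cutpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .copulas import CopulaFamily, CopulaSpec, parse_family, tau_from_theta, theta_from_tau
from .cutpoints import Cutpoints
from .trees import VineTree

__all__ = ["FactorTreeSpec"]


def _indep() -> CopulaSpec:
    return CopulaSpec(CopulaFamily("independence"), None)


@dataclass(frozen=True)
class FactorTreeSpec:
    """A factor tree copula model specification with concrete parameters."""

    p: int
    cutpoints: Cutpoints
    tree1: Optional[List[CopulaSpec]] = None
    tree2: Optional[List[CopulaSpec]] = None
    vine: Optional[VineTree] = None
    vine_specs: Optional[List[CopulaSpec]] = None

    def __post_init__(self):
        d = self.cutpoints.d
        if self.p not in (0, 1, 2):
            raise ValueError("number of factors p must be 0, 1 or 2")
        if self.p >= 1:
            if self.tree1 is None or len(self.tree1) != d:
                raise ValueError(f"tree1 must have one copula per item (d={d})")
        elif self.tree1 is not None:
            raise ValueError("tree1 given but p=0")
        if self.p == 2:
            if self.tree2 is None or len(self.tree2) != d:
                raise ValueError(f"tree2 must have one copula per item (d={d})")
        elif self.tree2 is not None:
            raise ValueError("tree2 given but p < 2")
        if self.vine is not None and self.vine.edges:
            if self.vine.d != d:
                raise ValueError("vine dimension does not match cutpoints")
            if self.vine_specs is None or len(self.vine_specs) != self.vine.n_edges:
                raise ValueError("need one copula per vine edge")
        else:
            if self.vine_specs:
                raise ValueError("vine_specs given without a vine tree")
            object.__setattr__(self, "vine", None)
            object.__setattr__(self, "vine_specs", None)
        if self.p == 0 and self.vine is None:
            # degenerate: independence model (allowed; pmf is product of margins)
            pass

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_taus(
        cls,
        cutpoints: Cutpoints,
        family1: Optional[str] = None,
        tau1: Optional[Sequence[float]] = None,
        family2: Optional[str] = None,
        tau2: Optional[Sequence[float]] = None,
        vine: Optional[VineTree] = None,
        vine_family: Optional[str] = None,
        vine_tau: Optional[Sequence[float]] = None,
    ) -> "FactorTreeSpec":
        """Build a model from family names and Kendall's tau values."""
        d = cutpoints.d

        def tree(fam, taus, m):
            f = parse_family(fam)
            taus = np.asarray(taus, dtype=float)
            if len(taus) != m:
                raise ValueError("tau sequence has wrong length")
            return [theta_from_tau(f, t) if f.tag != "independence" else _indep() for t in taus]

        p = 0
        t1 = t2 = vs = None
        if family1 is not None:
            p = 1
            t1 = tree(family1, tau1, d)
        if family2 is not None:
            if p == 0:
                raise ValueError("cannot give a second factor without a first")
            p = 2
            t2 = tree(family2, tau2, d)
        if vine is not None and vine.edges:
            vs = tree(vine_family, vine_tau, vine.n_edges)
        return cls(p=p, cutpoints=cutpoints, tree1=t1, tree2=t2, vine=vine, vine_specs=vs)

    # -- basic properties ----------------------------------------------------

    @property
    def d(self) -> int:
        return self.cutpoints.d

    @property
    def K(self) -> np.ndarray:
        return self.cutpoints.K

    @property
    def has_vine(self) -> bool:
        return self.vine is not None and self.vine.n_edges > 0

    def all_bvn(self) -> bool:
        """True when every non-independence link is a BVN copula."""
        for lst in (self.tree1, self.tree2, self.vine_specs):
            if lst:
                for s in lst:
                    if s.tag not in ("bvn", "independence"):
                        return False
        return True

    @property
    def n_dependence_params(self) -> int:
        """Number of free dependence parameters.

        Counts one per non-independence link; for the 2-factor model with
        all-BVN factor trees one second-factor parameter is fixed at zero
        for identification, so d + (d - 1) parameters for the factor part.
        The t degrees of freedom nu come from a fixed grid and are never
        counted.
        """
        n = 0
        for lst in (self.tree1, self.tree2, self.vine_specs):
            if lst:
                n += sum(s.family.n_free_params for s in lst)
        if self.p == 2 and all(
            s.tag == "bvn" for s in (self.tree1 + self.tree2)
        ):
            n -= 1
        return n

    def taus(self) -> List[float]:
        """Kendall's tau for every link, in (tree1, tree2, vine) order."""
        out = []
        for lst in (self.tree1, self.tree2, self.vine_specs):
            if lst:
                out.extend(tau_from_theta(s) for s in lst)
        return out

    def with_cutpoints(self, cutpoints: Cutpoints) -> "FactorTreeSpec":
        return replace(self, cutpoints=cutpoints)
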