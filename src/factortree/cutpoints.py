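"""Ordinal cutpoints on the uniform and normal scales."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import norm

from .data import OrdinalData

__all__ = ["Cutpoints", "estimate_cutpoints"]


@dataclass(frozen=True)
class Cutpoints:
    """Per-item cutpoints a_{j,0}=0 < a_{j,1} <= ... < a_{j,K_j}=1.

    ``a[j]`` has length K_j + 1 with fixed endpoints 0 and 1; ``alpha[j]``
    are the normal-scale images Phi^{-1}(a_{j,k}) (+-inf at the endpoints).
    """

    a: List[np.ndarray]

    def __post_init__(self):
        clean = []
        for j, aj in enumerate(self.a):
            aj = np.asarray(aj, dtype=float)
            if aj[0] != 0.0 or aj[-1] != 1.0:
                raise ValueError(f"item {j + 1}: cutpoints must start at 0 and end at 1")
            if np.any(np.diff(aj) <= 0):
                raise ValueError(f"item {j + 1}: cutpoints must be strictly increasing")
            clean.append(aj)
        object.__setattr__(self, "a", clean)

    @classmethod
    def from_interior(cls, interior: Sequence[Sequence[float]]) -> "Cutpoints":
        """Build from per-item interior cutpoints (without the 0/1 endpoints)."""
        return cls([np.concatenate(([0.0], np.asarray(c, float), [1.0])) for c in interior])

    @classmethod
    def equal_categories(cls, d: int, K: int) -> "Cutpoints":
        """Equally weighted categories: a_{j,k} = k / K for every item."""
        return cls([np.linspace(0.0, 1.0, K + 1)] * d)

    @property
    def d(self) -> int:
        return len(self.a)

    @property
    def K(self) -> np.ndarray:
        return np.array([len(aj) - 1 for aj in self.a])

    @property
    def alpha(self) -> List[np.ndarray]:
        return [norm.ppf(aj) for aj in self.a]

    def marginal_pmf(self, j: int) -> np.ndarray:
        return np.diff(self.a[j])


def estimate_cutpoints(data: OrdinalData) -> Cutpoints:
    """Cutpoints from univariate sample proportions (IFM step one).

    a-hat_{j,k} is the cumulative proportion of categories 0..k-1 for item
    j.  Data with unobserved interior categories must be compacted first
    (``OrdinalData.compact``); a zero-count category would give a zero-width
    interval, which the vine pmf cannot tolerate.
    """
    if data.n < 1:
        raise ValueError("need at least one observation")
    a = []
    for j in range(data.d):
        counts = data.counts(j)
        if (counts == 0).any():
            raise ValueError(
                f"item {j + 1} has zero-count categories; call OrdinalData.compact() first"
            )
        cum = np.concatenate(([0], np.cumsum(counts))) / data.n
        cum[-1] = 1.0
        a.append(cum)
    return Cutpoints(a)
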