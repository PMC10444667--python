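"""Gauss-Legendre quadrature on (0, 1) for integrating out latent factors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QuadratureRule", "gauss_legendre_01", "DEFAULT_NQ"]

#: default number of quadrature points; adequate precision for the model pmfs
DEFAULT_NQ = 25


@dataclass(frozen=True)
class QuadratureRule:
    """Nodes in (0, 1) and positive weights summing to one."""

    nodes: np.ndarray
    weights: np.ndarray

    @property
    def size(self) -> int:
        return len(self.nodes)


def gauss_legendre_01(nq: int = DEFAULT_NQ) -> QuadratureRule:
    """Gauss-Legendre rule affinely mapped from (-1, 1) to (0, 1).

    Integrates polynomials of degree <= 2 nq - 1 exactly; the weights sum to
    one and the nodes are symmetric about 1/2.
    """
    if nq < 1:
        raise ValueError(f"nq must be >= 1, got {nq}")
    x, w = np.polynomial.legendre.leggauss(int(nq))
    return QuadratureRule(nodes=(x + 1.0) / 2.0, weights=w / 2.0)
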