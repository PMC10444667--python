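"""Probability mass functions of factor tree copula models.

The pmf of the 1-factor tree model is a one-dimensional integral over the
uniform latent factor of a Markov-tree conditional pmf,

    pi_d(y) = int_0^1 prod_j f_{j|X1}(y_j|x)
              prod_{jk in E} f_{jk|X1}(y_j, y_k|x) /
                             (f_{j|X1}(y_j|x) f_{k|X1}(y_k|x)) dx,

and the 2-factor tree model replaces the conditional quantities by their
two-factor analogues under a double integral.  Both are evaluated with
Gauss-Legendre quadrature mapped to (0, 1); with an empty edge set they
reduce exactly to the 1-/2-factor copula model, and with no factors to the
1-truncated vine (Markov tree) model, whose pmf is available in closed form.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .copulas import CopulaSpec, copula_cdf, copula_hfun
from .cutpoints import Cutpoints
from .data import OrdinalData
from .quadrature import QuadratureRule, gauss_legendre_01
from .spec import FactorTreeSpec
from .trees import VineTree

__all__ = [
    "cond_cdf_item_given_x1",
    "cond_cdf_item_given_x1x2",
    "icc_1f",
    "icc_2f",
    "pair_pmf_cond",
    "vine_pmf",
    "model_pmf",
    "pmf_rows",
    "loglik",
]

log = logging.getLogger("factortree")

#: floor for pmfs before taking logs, and for ratio denominators
PMF_FLOOR = 1e-300
DEN_FLOOR = 1e-30


# ---------------------------------------------------------------------------
# conditional cdf tables
# ---------------------------------------------------------------------------

def _tables_x1(model: FactorTreeSpec, x1: np.ndarray) -> List[np.ndarray]:
    """Per item: C_{j|X1}(a_{j,k} | x1) for k = 0..K_j, shape (K_j+1, m)."""
    out = []
    for j in range(model.d):
        a = model.cutpoints.a[j][:, None]
        H = copula_hfun(a, x1[None, :], model.tree1[j])
        H[0, :] = 0.0
        H[-1, :] = 1.0
        out.append(np.maximum.accumulate(H, axis=0))
    return out


def _tables_x1x2(
    model: FactorTreeSpec, x1: np.ndarray, x2: np.ndarray, paired: bool
) -> List[np.ndarray]:
    """Per item: conditional cdf given both factors.

    With ``paired`` the latent values are matched elementwise (simulation);
    otherwise a tensor grid (K_j+1, m1, m2) is built (quadrature).
    """
    out = []
    for j in range(model.d):
        a = model.cutpoints.a[j][:, None]
        H = copula_hfun(a, x1[None, :], model.tree1[j])  # (K+1, m1)
        if paired:
            G = copula_hfun(H, x2[None, :], model.tree2[j])
        else:
            G = copula_hfun(H[:, :, None], x2[None, None, :], model.tree2[j])
        G[0] = 0.0
        G[-1] = 1.0
        out.append(np.maximum.accumulate(G, axis=0))
    return out


def _cond_tables(model: FactorTreeSpec, x1, x2=None, paired=False) -> List[np.ndarray]:
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    if model.p == 1:
        return _tables_x1(model, x1)
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    return _tables_x1x2(model, x1, x2, paired)


def _pair_rect(delta: CopulaSpec, Hj: np.ndarray, Hk: np.ndarray) -> np.ndarray:
    """Rectangle probabilities of the edge copula applied to two cdf tables.

    Hj, Hk have leading axis K+1 (cutpoint index) and matching trailing
    axes; returns (K_j, K_k, ...).  Tiny negatives from cancellation are
    clipped at zero.
    """
    C = copula_cdf(Hj[:, None, ...], Hk[None, :, ...], delta)
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.maximum(P, 0.0)


# ---------------------------------------------------------------------------
# spec-level scalar operations
# ---------------------------------------------------------------------------

def cond_cdf_item_given_x1(y: int, x: float, j: int, model: FactorTreeSpec) -> float:
    """Pr(Y_j <= y | X_1 = x) = C_{j|X1}(a_{j,y+1} | x); y = -1 gives 0."""
    if not 0 <= j < model.d:
        raise IndexError(f"item index {j} out of range")
    if y < 0:
        return 0.0
    a = model.cutpoints.a[j][min(y + 1, model.K[j])]
    return float(copula_hfun(a, x, model.tree1[j]))


def icc_1f(y: int, x: float, j: int, model: FactorTreeSpec) -> float:
    """Item characteristic curve of the 1-factor model:
    f_{j|X1}(y|x) = C_{j|X1}(a_{j,y+1}|x) - C_{j|X1}(a_{j,y}|x)."""
    hi = cond_cdf_item_given_x1(y, x, j, model)
    lo = cond_cdf_item_given_x1(y - 1, x, j, model)
    return max(hi - lo, 0.0)


def cond_cdf_item_given_x1x2(y: int, x1: float, x2: float, j: int, model: FactorTreeSpec) -> float:
    """Pr(Y_j <= y | X_1 = x1, X_2 = x2), the two-factor conditional cdf."""
    if model.p != 2:
        raise ValueError("two-factor conditional cdf requires p = 2")
    if not 0 <= j < model.d:
        raise IndexError(f"item index {j} out of range")
    if y < 0:
        return 0.0
    if y >= model.K[j] - 1:
        return 1.0
    inner = cond_cdf_item_given_x1(y, x1, j, model)
    return float(copula_hfun(inner, x2, model.tree2[j]))


def icc_2f(y: int, x1: float, x2: float, j: int, model: FactorTreeSpec) -> float:
    """Item characteristic curve of the 2-factor model."""
    hi = cond_cdf_item_given_x1x2(y, x1, x2, j, model)
    lo = cond_cdf_item_given_x1x2(y - 1, x1, x2, j, model)
    return max(hi - lo, 0.0)


def pair_pmf_cond(yj: int, yk: int, x, edge: Tuple[int, int], model: FactorTreeSpec) -> float:
    """Conditional pair pmf f_{jk|X}(y_j, y_k | x) for a vine edge.

    ``x`` is a scalar latent value for p=1 or a pair (x1, x2) for p=2.
    """
    e = tuple(sorted(int(v) for v in edge))
    if model.vine is None or e not in model.vine.edges:
        raise ValueError(f"edge {edge} is not in the residual tree")
    idx = model.vine.edges.index(e)
    j, k = e
    if model.p == 1:
        Fj = np.array([cond_cdf_item_given_x1(yj - 1, x, j, model),
                       cond_cdf_item_given_x1(yj, x, j, model)])
        Fk = np.array([cond_cdf_item_given_x1(yk - 1, x, k, model),
                       cond_cdf_item_given_x1(yk, x, k, model)])
    elif model.p == 2:
        x1, x2 = x
        Fj = np.array([cond_cdf_item_given_x1x2(yj - 1, x1, x2, j, model),
                       cond_cdf_item_given_x1x2(yj, x1, x2, j, model)])
        Fk = np.array([cond_cdf_item_given_x1x2(yk - 1, x1, x2, k, model),
                       cond_cdf_item_given_x1x2(yk, x1, x2, k, model)])
    else:
        raise ValueError("pair_pmf_cond requires p >= 1")
    spec = model.vine_specs[idx]
    C = copula_cdf(Fj[:, None], Fk[None, :], spec)
    return float(max(C[1, 1] - C[0, 1] - C[1, 0] + C[0, 0], 0.0))


# ---------------------------------------------------------------------------
# vectorized row pmfs
# ---------------------------------------------------------------------------

def _rows(y) -> np.ndarray:
    y = np.asarray(y, dtype=np.int64)
    return y[None, :] if y.ndim == 1 else y


def vine_pmf(
    y,
    tree: Optional[VineTree],
    cutpoints: Cutpoints,
    edge_specs: Optional[Sequence[CopulaSpec]] = None,
) -> np.ndarray:
    """Closed-form pmf of the 1-truncated vine (Markov tree) model.

    pi_d(y) = prod_j Pr(Y_j=y_j) * prod_{jk in E}
              Pr(Y_j=y_j, Y_k=y_k) / (Pr(Y_j=y_j) Pr(Y_k=y_k)),
    with the bivariate term the rectangle probability of the edge copula
    applied to the marginal cdfs.  With an empty tree this is the product
    of the marginal pmfs.
    """
    Y = _rows(y)
    n, d = Y.shape
    marg = [cutpoints.marginal_pmf(j) for j in range(d)]
    for j in range(d):
        if np.any(marg[j][Y[:, j]] <= 0):
            bad = int(np.flatnonzero(marg[j][Y[:, j]] <= 0)[0])
            raise ValueError(
                f"row {bad + 1}, item {j + 1}: category with zero marginal probability"
            )
    out = np.ones(n)
    for j in range(d):
        out *= marg[j][Y[:, j]]
    if tree is not None and tree.n_edges:
        for (j, k), spec in zip(tree.edges, edge_specs):
            aj = cutpoints.a[j][:, None]
            ak = cutpoints.a[k][None, :]
            C = copula_cdf(aj, ak, spec)
            P = np.maximum(C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1], 0.0)
            out *= P[Y[:, j], Y[:, k]] / np.maximum(marg[j][Y[:, j]] * marg[k][Y[:, k]], DEN_FLOOR)
    return out if np.asarray(y).ndim > 1 else float(out[0])


def pmf_rows(y, model: FactorTreeSpec, rule: Optional[QuadratureRule] = None) -> np.ndarray:
    """Joint pmf of the model for each response row, shape (n,)."""
    Y = _rows(y)
    n, d = Y.shape
    if d != model.d:
        raise ValueError(f"rows have {d} items, model has {model.d}")
    if model.p == 0:
        out = vine_pmf(Y, model.vine, model.cutpoints, model.vine_specs)
        return np.atleast_1d(out)
    rule = rule or gauss_legendre_01()

    if model.p == 1:
        H = _cond_tables(model, rule.nodes)
        w = rule.weights
    else:
        H = _cond_tables(model, rule.nodes, rule.nodes, paired=False)
        H = [G.reshape(G.shape[0], -1) for G in H]  # flatten the (q1, q2) grid
        w = np.outer(rule.weights, rule.weights).ravel()

    F = [np.maximum(np.diff(Hj, axis=0), 0.0) for Hj in H]
    L = np.ones((n, len(w)))
    for j in range(d):
        L *= F[j][Y[:, j], :]
    if model.has_vine:
        for (j, k), spec in zip(model.vine.edges, model.vine_specs):
            P = _pair_rect(spec, H[j], H[k])
            num = P[Y[:, j], Y[:, k], :]
            den = F[j][Y[:, j], :] * F[k][Y[:, k], :]
            L *= num / np.maximum(den, DEN_FLOOR)
    return np.maximum(L @ w, PMF_FLOOR)


def model_pmf(y, model: FactorTreeSpec, rule: Optional[QuadratureRule] = None):
    """Joint pmf pi_d(y) of a factor tree copula model.

    Accepts a single response vector (returns a float) or an (n, d) array.
    """
    out = pmf_rows(y, model, rule)
    return float(out[0]) if np.asarray(y).ndim == 1 else out


def loglik(data, model: FactorTreeSpec, rule: Optional[QuadratureRule] = None) -> float:
    """Joint log-likelihood: the sum over rows of log pi_d(y_i)."""
    Y = data.y if isinstance(data, OrdinalData) else _rows(data)
    p = pmf_rows(Y, model, rule)
    lp = np.log(p)
    if not np.all(np.isfinite(lp)):
        bad = int(np.flatnonzero(~np.isfinite(lp))[0])
        raise FloatingPointError(f"non-finite log-likelihood term at row {bad + 1}")
    return float(lp.sum())
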