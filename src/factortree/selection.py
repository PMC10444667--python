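"""Model selection: residual-tree structure, copula families, diagnostics.

Two spanning-tree algorithms choose the residual Markov tree: the
*polychoric* algorithm weights item pairs by their polychoric correlations,
the *partial* algorithm by the partial correlations of the underlying
normal variables given the factor(s) of a fitted normal ogive (all-BVN
factor copula) model.  A sequential heuristic then picks one copula family
per tree by maximized log-likelihood.  Discrepancy measures compare the
observed polychoric correlation matrix with a Gaussian-analogue model's
implied matrix, and Vuong's procedure compares non-nested fitted models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import OrdinalData
from .model import FactorTreeCopulaModel, FactorTreeCopulaResults
from .polychoric import polychoric_matrix
from .spec import FactorTreeSpec
from .trees import VineTree, max_spanning_tree, tree_path

__all__ = [
    "partial_corr_matrix",
    "implied_correlation_matrix",
    "discrepancies",
    "select_families",
    "SelectionResult",
    "vuong_interval",
    "VuongInterval",
    "FACTOR_CANDIDATES",
    "VINE_CANDIDATES",
]

log = logging.getLogger("factortree")

#: default candidate families; one family per tree, never mixed within a tree
FACTOR_CANDIDATES = ("bvn", "t2", "t3", "t5", "t7", "gumbel", "sgumbel")
VINE_CANDIDATES = FACTOR_CANDIDATES + ("frank",)


# ---------------------------------------------------------------------------
# correlation machinery for the Gaussian analogue
# ---------------------------------------------------------------------------

def partial_corr_matrix(
    R: np.ndarray,
    loadings: Sequence[np.ndarray] | np.ndarray,
    level: int = 1,
) -> np.ndarray:
    """Partial correlations of the underlying normals given the factor(s).

    ``loadings`` are normal-ogive parameters: theta_1 for level 1, the pair
    (theta_1, theta_2) for level 2, where theta_2 are partial correlations
    with the second factor given the first.  Level 1 computes
    (r_jk - t1j t1k) / sqrt((1 - t1j^2)(1 - t1k^2)); level 2 applies the
    same recursion again with theta_2.
    """
    R = np.asarray(R, dtype=float)
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    if level == 1 and not isinstance(loadings, (tuple, list)):
        loadings = (loadings,)
    th1 = np.asarray(loadings[0], dtype=float)
    if np.any(np.abs(th1) >= 1.0):
        raise ValueError("|loading| must be < 1 for partial correlations")
    s1 = np.sqrt(1.0 - th1 ** 2)
    P = (R - np.outer(th1, th1)) / np.outer(s1, s1)
    if level == 2:
        th2 = np.asarray(loadings[1], dtype=float)
        if np.any(np.abs(th2) >= 1.0):
            raise ValueError("|loading| must be < 1 for partial correlations")
        s2 = np.sqrt(1.0 - th2 ** 2)
        P = (P - np.outer(th2, th2)) / np.outer(s2, s2)
    np.fill_diagonal(P, 1.0)
    return P


def implied_correlation_matrix(model: FactorTreeSpec) -> np.ndarray:
    """Correlation matrix of the underlying normals for an all-BVN model.

    Factor part: r_jk = t1j t1k (one factor) or
    r_jk = t1j t1k + t2j t2k sqrt((1-t1j^2)(1-t1k^2)) (two factors).  For
    the residual tree, the conditional correlation of a pair given the
    factors is the product of the edge partial correlations along the
    unique tree path (Markov-tree property), then back-transformed through
    the factor recursion.
    """
    if not model.all_bvn():
        raise ValueError("implied correlation matrix is defined for all-BVN models only")
    d = model.d

    def thetas(lst):
        return np.array([0.0 if s.tag == "independence" else s.theta for s in lst])

    th1 = thetas(model.tree1) if model.p >= 1 else np.zeros(d)
    th2 = thetas(model.tree2) if model.p == 2 else np.zeros(d)

    cond = np.eye(d)
    if model.has_vine:
        delta = {e: (0.0 if s.tag == "independence" else s.theta)
                 for e, s in zip(model.vine.edges, model.vine_specs)}
        for j in range(d):
            for k in range(j + 1, d):
                rho = 1.0
                for e in tree_path(model.vine, j, k):
                    rho *= delta[e]
                cond[j, k] = cond[k, j] = rho
    R = cond.copy()
    if model.p == 2:
        s2 = np.sqrt(1.0 - th2 ** 2)
        R = R * np.outer(s2, s2) + np.outer(th2, th2)
    if model.p >= 1:
        s1 = np.sqrt(1.0 - th1 ** 2)
        R = R * np.outer(s1, s1) + np.outer(th1, th1)
    np.fill_diagonal(R, 1.0)
    return R


def discrepancies(R_model: np.ndarray, R_observed: np.ndarray) -> Tuple[float, float, float]:
    """(D1, D2, D3) between a model and an observed correlation matrix.

    D1 is the maximum and D2 the average absolute off-diagonal difference;
    D3 = log det(R_model) - log det(R_observed) + tr(R_model^-1 R_observed) - d
    is nonnegative for positive-definite inputs and zero iff they coincide.
    """
    Rm = np.asarray(R_model, dtype=float)
    Ro = np.asarray(R_observed, dtype=float)
    d = Rm.shape[0]
    if Rm.shape != Ro.shape or Rm.shape != (d, d):
        raise ValueError("correlation matrices must be square and congruent")
    off = ~np.eye(d, dtype=bool)
    diff = np.abs(Rm - Ro)[off]
    sign_m, logdet_m = np.linalg.slogdet(Rm)
    sign_o, logdet_o = np.linalg.slogdet(Ro)
    if sign_m <= 0:
        raise np.linalg.LinAlgError("model correlation matrix is singular or indefinite")
    d3 = logdet_m - logdet_o + float(np.trace(np.linalg.solve(Rm, Ro))) - d
    return float(diff.max()), float(diff.mean()), float(d3)


# ---------------------------------------------------------------------------
# Vuong comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VuongInterval:
    """AIC-adjusted 95% Vuong interval for comparing two fitted models."""

    dbar: float
    s: float
    ci_low: float
    ci_high: float

    @property
    def favors(self) -> int:
        """2 if the interval lies above 0 (model 2 better), 1 if below, else 0."""
        if self.ci_low > 0:
            return 2
        if self.ci_high < 0:
            return 1
        return 0


def vuong_interval(pmf1, pmf2, dim1: int, dim2: int) -> VuongInterval:
    """Vuong's non-nested comparison from per-row fitted pmfs.

    D_i = log(pi2_i / pi1_i); with dbar the mean and s the (n-1)-denominator
    standard deviation, the AIC-adjusted 95% CI is
    dbar - (dim2 - dim1)/n +- 1.96 s / sqrt(n).  An interval above zero
    favors model 2.
    """
    p1 = np.asarray(pmf1, dtype=float)
    p2 = np.asarray(pmf2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("pmf vectors must have equal length")
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        bad = int(np.flatnonzero((p1 <= 0) | (p2 <= 0))[0])
        raise ValueError(f"nonpositive pmf value at row {bad + 1}")
    n = len(p1)
    D = np.log(p2) - np.log(p1)
    dbar = float(D.mean())
    s = float(D.std(ddof=1))
    adj = (dim2 - dim1) / n
    half = 1.96 * s / np.sqrt(n)
    return VuongInterval(dbar, s, dbar - adj - half, dbar - adj + half)


# ---------------------------------------------------------------------------
# sequential family selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    results: FactorTreeCopulaResults
    tree: Optional[VineTree]
    families: Tuple[str, ...]
    trace: pd.DataFrame


def _fit(cache, data, p, edges, families, nq, **kw):
    key = (tuple(families), edges.edges if edges is not None else None)
    if key not in cache:
        m = FactorTreeCopulaModel(data, n_factors=p, edges=edges, families=families, nq=nq)
        cache[key] = m.fit(compute_se=False, **kw)
    return cache[key]


def select_families(
    data,
    p: int = 1,
    tree_algorithm: str = "partial",
    factor_candidates: Sequence[str] = FACTOR_CANDIDATES,
    vine_candidates: Sequence[str] = VINE_CANDIDATES,
    edges=None,
    nq: int = 25,
    allow_no_vine: bool = False,
) -> SelectionResult:
    """Sequential copula-family selection for a p-factor tree model.

    Starting from BVN factor links and an independence residual tree, each
    tree in turn is assigned the single candidate family (no mixing within
    a tree) that maximizes the joint log-likelihood: first factor, then
    (for p=2) second factor, then the residual tree, whose structure is
    chosen by the requested spanning-tree algorithm (or fixed ``edges``).
    With ``allow_no_vine`` the factor-only model competes by AIC at the end;
    with an empty ``vine_candidates`` the residual-tree stage is skipped and
    the selected factor-only model is returned.
    """
    if not isinstance(data, OrdinalData):
        data = OrdinalData(np.asarray(data))
    data = data.compact()
    if p not in (1, 2):
        raise ValueError("family selection needs p in {1, 2}")
    if tree_algorithm not in ("partial", "polychoric"):
        raise ValueError("tree_algorithm must be 'partial' or 'polychoric'")

    cache: dict = {}
    rows: List[tuple] = []

    def note(stage, family, res, selected=False):
        rows.append((stage, family, res.llf, res.aic, res.n_params, selected))

    # stage 1: first factor
    best1, best1_res = None, None
    for fam in factor_candidates:
        fams = (fam, "bvn") if p == 2 else (fam,)
        res = _fit(cache, data, p, None, fams, nq)
        note("factor1", fam, res)
        if best1_res is None or res.llf > best1_res.llf:
            best1, best1_res = fam, res
    rows = [(s, f, l, a, np_, f == best1 if s == "factor1" else sel)
            for (s, f, l, a, np_, sel) in rows]
    log.info("factor 1: selected %s (loglik %.2f)", best1, best1_res.llf)

    # stage 2: second factor
    best2 = None
    if p == 2:
        best2_res = None
        for fam in factor_candidates:
            res = _fit(cache, data, p, None, (best1, fam), nq)
            note("factor2", fam, res, selected=False)
            if best2_res is None or res.llf > best2_res.llf:
                best2, best2_res = fam, res
        rows = [(s, f, l, a, np_, sel or (s == "factor2" and f == best2))
                for (s, f, l, a, np_, sel) in rows]
        log.info("factor 2: selected %s (loglik %.2f)", best2, best2_res.llf)
        factor_res = best2_res
    else:
        factor_res = best1_res

    factor_fams = (best1, best2) if p == 2 else (best1,)
    if not vine_candidates:
        trace = pd.DataFrame(
            rows, columns=["stage", "family", "loglik", "aic", "n_params", "selected"]
        )
        return SelectionResult(results=factor_res, tree=None,
                               families=factor_fams, trace=trace)

    # stage 3: residual tree structure
    if edges is not None:
        tree = edges if isinstance(edges, VineTree) else VineTree(data.d, tuple(edges))
    else:
        R = polychoric_matrix(data)
        if tree_algorithm == "polychoric":
            W = R
        else:
            ogive = _fit(cache, data, p, None, ("bvn", "bvn")[: (2 if p == 2 else 1)], nq)
            frame = ogive.params_frame()
            th1 = frame.loc[frame.tree == "factor1", "theta"].to_numpy()
            if p == 2:
                th2 = frame.loc[frame.tree == "factor2", "theta"].to_numpy()
                W = partial_corr_matrix(R, (th1, th2), level=2)
            else:
                W = partial_corr_matrix(R, th1, level=1)
        tree = max_spanning_tree(W)
    log.info("residual tree (%s): %s", tree_algorithm,
             [(j + 1, k + 1) for j, k in tree.edges])

    # stage 4: residual-tree family
    bestv, bestv_res = None, None
    for fam in vine_candidates:
        res = _fit(cache, data, p, tree, factor_fams + (fam,), nq)
        note("vine", fam, res)
        if bestv_res is None or res.llf > bestv_res.llf:
            bestv, bestv_res = fam, res
    rows = [(s, f, l, a, np_, sel or (s == "vine" and f == bestv))
            for (s, f, l, a, np_, sel) in rows]
    log.info("residual tree: selected %s (loglik %.2f)", bestv, bestv_res.llf)

    final, fams, final_tree = bestv_res, factor_fams + (bestv,), tree
    if allow_no_vine and factor_res.aic < bestv_res.aic:
        log.info("no-vine model preferred by AIC (%.1f < %.1f)",
                 factor_res.aic, bestv_res.aic)
        final, fams, final_tree = factor_res, factor_fams, None

    trace = pd.DataFrame(
        rows, columns=["stage", "family", "loglik", "aic", "n_params", "selected"]
    )
    return SelectionResult(results=final, tree=final_tree, families=fams, trace=trace)
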