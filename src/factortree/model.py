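"""Two-step IFM estimation of factor tree copula models.

`FactorTreeCopulaModel` is constructed from ordinal data plus a model
skeleton (number of factors, residual tree edges, one copula family per
tree); `fit()` estimates cutpoints from univariate sample proportions
(step one), then maximizes the joint log-likelihood over the dependence
parameters with cutpoints held fixed (step two), using a quasi-Newton
method on unconstrained transforms of the parameters.  The returned
`FactorTreeCopulaResults` carries estimates on both the copula-parameter
and Kendall's-tau scales, Hessian-based standard errors on the tau scale,
the log-likelihood and AIC, and a summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .copulas import CopulaFamily, CopulaSpec, parse_family, tau_from_theta, theta_from_tau
from .cutpoints import Cutpoints, estimate_cutpoints
from .data import OrdinalData
from .pmf import loglik, pmf_rows
from .quadrature import QuadratureRule, gauss_legendre_01
from .spec import FactorTreeSpec
from .trees import VineTree

__all__ = ["FactorTreeCopulaModel", "FactorTreeCopulaResults", "numeric_hessian", "hessian_se"]

log = logging.getLogger("factortree")

#: default start values on the Kendall's-tau scale
START_TAU_FACTOR = 0.3
START_TAU_VINE = 0.1


# -- unconstrained transforms ------------------------------------------------

_ETA_CAP = 12.0


def _theta_from_eta(eta: float, tag: str) -> float:
    eta = float(np.clip(eta, -_ETA_CAP, _ETA_CAP))
    if tag in ("bvn", "t"):
        return float(np.tanh(eta))
    if tag in ("gumbel", "sgumbel"):
        return 1.0 + float(np.exp(eta))
    if tag == "frank":
        th = eta * 3.0  # identity up to scale; keeps steps comparable across families
        return th if abs(th) > 1e-8 else 1e-8
    raise ValueError(tag)


def _eta_from_theta(theta: float, tag: str) -> float:
    if tag in ("bvn", "t"):
        return float(np.arctanh(np.clip(theta, -1 + 1e-12, 1 - 1e-12)))
    if tag in ("gumbel", "sgumbel"):
        return float(np.log(max(theta - 1.0, 1e-10)))
    if tag == "frank":
        return float(theta) / 3.0
    raise ValueError(tag)


@dataclass(frozen=True)
class _Slot:
    tree: str  # "factor1" | "factor2" | "vine"
    index: int  # item index, or edge index for the vine
    family: CopulaFamily
    fixed_theta: Optional[float] = None  # identification constraint

    @property
    def label(self) -> str:
        return f"{self.tree}[{self.index + 1}]"


def numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    H = np.empty((m, m))
    f0 = f(x)

    def at(delta):
        return f(x + delta)

    for i in range(m):
        ei = np.zeros(m)
        ei[i] = step
        H[i, i] = (at(ei) - 2.0 * f0 + at(-ei)) / step ** 2
        for j in range(i + 1, m):
            ej = np.zeros(m)
            ej[j] = step
            H[i, j] = H[j, i] = (
                at(ei + ej) - at(ei - ej) - at(-ei + ej) + at(-ei - ej)
            ) / (4.0 * step ** 2)
    return H


def hessian_se(negll, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Standard errors from the inverse observed Hessian of a negative
    log-likelihood; entries are NaN where the Hessian is not positive
    definite enough to invert meaningfully."""
    H = numeric_hessian(negll, x, step)
    se = np.full(len(x), np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        ok = diag > 0
        se[ok] = np.sqrt(diag[ok])
    except np.linalg.LinAlgError:
        log.warning("Hessian not invertible; standard errors unavailable")
    return se


class FactorTreeCopulaModel:
    """Factor tree copula model for an n x d ordinal response matrix.

    Parameters
    ----------
    data : OrdinalData or integer array
        Responses coded 0..K_j-1 (relabeled densely if needed).
    n_factors : {0, 1, 2}
        Number of uniform latent factors.
    edges : VineTree, iterable of (j, k) pairs (0-based), or None
        Residual Markov-tree structure; None for a pure factor model.
    families : sequence of family names, one per tree present
        In order (factor 1, factor 2, vine), e.g. ``("t2", "gumbel", "t5")``
        for a 2-factor tree model; a single name is recycled.
    nq : int
        Gauss-Legendre quadrature size per latent dimension.
    """

    def __init__(self, data, n_factors: int = 1, edges=None,
                 families: Union[str, Sequence[str], None] = None, nq: int = 25):
        if not isinstance(data, OrdinalData):
            data = OrdinalData(np.asarray(data))
        data = data.compact()
        self.data = data
        self.p = int(n_factors)
        if self.p not in (0, 1, 2):
            raise ValueError("n_factors must be 0, 1 or 2")
        self.cutpoints: Cutpoints = estimate_cutpoints(data)
        self.rule: QuadratureRule = gauss_legendre_01(nq)

        if edges is None:
            self.vine: Optional[VineTree] = None
        elif isinstance(edges, VineTree):
            self.vine = edges if edges.n_edges else None
        else:
            self.vine = VineTree(data.d, tuple(tuple(e) for e in edges))
        if self.p == 0 and self.vine is None:
            raise ValueError("model needs at least one factor or a residual tree")

        n_trees = (1 if self.p >= 1 else 0) + (1 if self.p == 2 else 0) + (1 if self.vine else 0)
        if families is None:
            families = ["bvn"] * n_trees
        elif isinstance(families, str):
            families = [families] * n_trees
        else:
            families = list(families)
            if len(families) == 1 and n_trees > 1:
                families = families * n_trees
        if len(families) != n_trees:
            raise ValueError(f"model has {n_trees} trees, got {len(families)} families")
        fams = [parse_family(f) for f in families]

        it = iter(fams)
        self.family1 = next(it) if self.p >= 1 else None
        self.family2 = next(it) if self.p == 2 else None
        self.vine_family = next(it) if self.vine else None

        self._slots = self._build_slots()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FactorTreeCopulaModel":
        data = OrdinalData(df.to_numpy(), labels=[str(c) for c in df.columns])
        return cls(data, **kwargs)

    # -- parameterization ----------------------------------------------------

    def _build_slots(self) -> List[_Slot]:
        d = self.data.d
        slots: List[_Slot] = []
        # for the normal ogive (all-BVN) 2-factor model one second-factor
        # parameter is not identified and is fixed at zero
        fix_last_f2 = (
            self.p == 2
            and self.family1.tag == "bvn"
            and self.family2.tag == "bvn"
        )
        if self.p >= 1 and self.family1.tag != "independence":
            slots += [_Slot("factor1", j, self.family1) for j in range(d)]
        if self.p == 2 and self.family2.tag != "independence":
            for j in range(d):
                fixed = 0.0 if (fix_last_f2 and j == d - 1) else None
                slots.append(_Slot("factor2", j, self.family2, fixed))
        if self.vine is not None and self.vine_family.tag != "independence":
            slots += [_Slot("vine", e, self.vine_family) for e in range(self.vine.n_edges)]
        return slots

    @property
    def free_slots(self) -> List[_Slot]:
        return [s for s in self._slots if s.fixed_theta is None]

    @property
    def n_params(self) -> int:
        return len(self.free_slots)

    def _spec_from_thetas(self, thetas: Sequence[float]) -> FactorTreeSpec:
        d = self.data.d
        it = iter(thetas)
        indep = CopulaSpec(CopulaFamily("independence"), None)

        def tree_specs(tree_name, fam, m):
            if fam is None:
                return None
            if fam.tag == "independence":
                return [indep] * m
            out = []
            for s in self._slots:
                if s.tree == tree_name:
                    th = s.fixed_theta if s.fixed_theta is not None else next(it)
                    out.append(CopulaSpec(fam, float(th)))
            return out

        t1 = tree_specs("factor1", self.family1, d)
        t2 = tree_specs("factor2", self.family2, d)
        vs = tree_specs("vine", self.vine_family, self.vine.n_edges if self.vine else 0)
        return FactorTreeSpec(
            p=self.p, cutpoints=self.cutpoints, tree1=t1, tree2=t2,
            vine=self.vine, vine_specs=vs,
        )

    def loglike_thetas(self, thetas: Sequence[float]) -> float:
        """Joint log-likelihood at the given free dependence parameters."""
        return loglik(self.data, self._spec_from_thetas(thetas), self.rule)

    def start_thetas(self, start_tau: Optional[Sequence[float]] = None) -> np.ndarray:
        """Default start values: tau = 0.3 on factor trees, 0.1 on vine edges."""
        slots = self.free_slots
        if start_tau is not None:
            taus = list(start_tau)
            if len(taus) != len(slots):
                raise ValueError("start_tau has wrong length")
        else:
            taus = [START_TAU_VINE if s.tree == "vine" else START_TAU_FACTOR for s in slots]
        return np.array(
            [theta_from_tau(s.family, t).theta for s, t in zip(slots, taus)]
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        start_tau: Optional[Sequence[float]] = None,
        compute_se: bool = True,
        maxiter: int = 500,
        gtol: float = 1e-5,
    ) -> "FactorTreeCopulaResults":
        """Maximize the log-likelihood over the dependence parameters.

        Optimization runs on unconstrained transforms (atanh for BVN/t,
        log(theta - 1) for Gumbel/s.Gumbel, scaled identity for Frank); a
        fit that stops at the iteration cap is flagged, not raised.
        """
        slots = self.free_slots
        tags = [s.family.tag for s in slots]
        if not slots:
            llf = self.loglike_thetas([])
            return FactorTreeCopulaResults(self, self._spec_from_thetas([]), llf,
                                           np.array([]), None, True, 0)
        x0 = np.array(
            [_eta_from_theta(th, t) for th, t in zip(self.start_thetas(start_tau), tags)]
        )

        def negll(eta):
            thetas = [_theta_from_eta(e, t) for e, t in zip(eta, tags)]
            try:
                return -self.loglike_thetas(thetas)
            except FloatingPointError:
                return 1e12

        res = optimize.minimize(
            negll, x0, method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        thetas = [_theta_from_eta(e, t) for e, t in zip(res.x, tags)]
        spec = self._spec_from_thetas(thetas)
        llf = -float(res.fun)
        converged = bool(res.success)
        if not converged:
            log.warning("optimizer did not converge: %s", res.message)

        se_tau = None
        if compute_se:
            se_tau = self._se_tau(thetas)
        return FactorTreeCopulaResults(self, spec, llf, np.asarray(thetas), se_tau,
                                       converged, int(res.nit))

    def _se_tau(self, thetas: Sequence[float]) -> np.ndarray:
        """Hessian-based standard errors on the Kendall's-tau scale.

        Step-one cutpoint uncertainty is ignored, so these are approximate
        IFM standard errors.
        """
        slots = self.free_slots
        tau_hat = np.array(
            [tau_from_theta(CopulaSpec(s.family, th)) for s, th in zip(slots, thetas)]
        )

        def negll_tau(taus):
            try:
                ths = [theta_from_tau(s.family, float(np.clip(t, -0.999, 0.999))).theta
                       for s, t in zip(slots, taus)]
                return -self.loglike_thetas(ths)
            except (ValueError, FloatingPointError):
                return 1e12

        return hessian_se(negll_tau, tau_hat)


class FactorTreeCopulaResults:
    """Estimates, uncertainty and diagnostics from a fitted factor tree model."""

    def __init__(self, model: FactorTreeCopulaModel, spec: FactorTreeSpec, llf: float,
                 thetas: np.ndarray, se_tau: Optional[np.ndarray],
                 converged: bool, iterations: int):
        self.model = model
        self.spec = spec
        self.llf = llf
        self.thetas = thetas
        self.se_tau = se_tau
        self.converged = converged
        self.iterations = iterations

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        """AIC = -2 loglik + 2 (number of dependence parameters); cutpoints
        and the t degrees of freedom are not counted."""
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def tau(self) -> np.ndarray:
        slots = self.model.free_slots
        return np.array(
            [tau_from_theta(CopulaSpec(s.family, th)) for s, th in zip(slots, self.thetas)]
        )

    def row_pmf(self) -> np.ndarray:
        """Fitted pmf of each observed response row."""
        return pmf_rows(self.model.data.y, self.spec, self.model.rule)

    def params_frame(self) -> pd.DataFrame:
        """Tabular report: link, tree, family, theta-hat, tau-hat, SE(tau)."""
        model = self.model
        rows = []
        ths = iter(self.thetas)
        taus = iter(self.tau)
        ses = iter(self.se_tau) if self.se_tau is not None else None
        for s in model._slots:
            if s.tree == "vine":
                j, k = model.vine.edges[s.index]
                link = f"{j + 1},{k + 1}"
            else:
                link = str(s.index + 1)
            if s.fixed_theta is not None:
                rows.append((s.tree, link, s.family.name, s.fixed_theta,
                             tau_from_theta(CopulaSpec(s.family, s.fixed_theta)), np.nan, True))
            else:
                rows.append((s.tree, link, s.family.name, next(ths), next(taus),
                             next(ses) if ses is not None else np.nan, False))
        return pd.DataFrame(
            rows, columns=["tree", "link", "family", "theta", "tau", "se_tau", "fixed"]
        )

    def summary(self) -> str:
        head = (
            f"Factor tree copula model: p={self.model.p} factor(s), "
            f"{self.model.vine.n_edges if self.model.vine else 0} residual edges, "
            f"d={self.model.data.d}, n={self.model.data.n}\n"
            f"loglik = {self.llf:.2f}   AIC = {self.aic:.1f}   "
            f"#dependence params = {self.n_params}\n"
            f"converged = {self.converged} ({self.iterations} iterations); "
            f"SEs are IFM (cutpoint uncertainty ignored)\n"
        )
        with pd.option_context("display.max_rows", 200, "display.width", 120):
            return head + self.params_frame().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )

    def __repr__(self):
        return (f"<FactorTreeCopulaResults p={self.model.p} "
                f"llf={self.llf:.2f} aic={self.aic:.1f} converged={self.converged}>")
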