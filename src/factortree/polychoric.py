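"""Polychoric correlations and empirical semi-correlations.

The polychoric correlation of two ordinal items is the ML estimate of the
latent bivariate-normal correlation given cutpoints fixed at their
univariate estimates (two-stage ML).  The empirical semi-correlations are
polychoric correlations recomputed on the sub-sample where both items fall
below / above their normal-scale zero cutpoint; comparing the lower and
upper values diagnoses reflection asymmetry (tail asymmetry) in the data.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .copulas import bvn_cdf
from .cutpoints import Cutpoints, estimate_cutpoints
from .data import OrdinalData

__all__ = ["polychoric", "polychoric_matrix", "empirical_semicorrelations"]

log = logging.getLogger("factortree")

_RHO_CLIP = 0.999
_Z_BOUND = float(np.arctanh(_RHO_CLIP))
_ALPHA_CLIP = 8.2  # normal-scale cutpoints clipped here; tail mass < 1e-16


def _polychoric_table(table: np.ndarray, alpha_j: np.ndarray, alpha_k: np.ndarray) -> float:
    aj = np.clip(alpha_j, -_ALPHA_CLIP, _ALPHA_CLIP)[:, None]
    ak = np.clip(alpha_k, -_ALPHA_CLIP, _ALPHA_CLIP)[None, :]

    def nll(z):
        C = bvn_cdf(aj, ak, np.tanh(z))
        P = np.maximum(C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1], 1e-300)
        return -float((table * np.log(P)).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(-_Z_BOUND, _Z_BOUND), method="bounded",
        options={"xatol": 1e-10},
    )
    rho = float(np.tanh(res.x))
    if abs(rho) >= _RHO_CLIP - 1e-4:
        warnings.warn("polychoric estimate at the boundary; clipped to +-0.999")
        rho = float(np.sign(rho) * _RHO_CLIP)
    return rho


def polychoric(yj, yk, cutpoints: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> float:
    """Two-stage ML polychoric correlation of two ordinal columns.

    ``cutpoints`` optionally supplies the two uniform-scale cutpoint vectors
    (with 0/1 endpoints); by default they are estimated from the columns.
    """
    yj = np.asarray(yj, dtype=np.int64)
    yk = np.asarray(yk, dtype=np.int64)
    if yj.shape != yk.shape:
        raise ValueError("columns must have equal length")
    sub = OrdinalData(np.column_stack([yj, yk])).compact()
    if cutpoints is None:
        cp = estimate_cutpoints(sub)
        a_j, a_k = cp.a[0], cp.a[1]
    else:
        a_j, a_k = (np.asarray(a, float) for a in cutpoints)
    from scipy.stats import norm

    table = np.zeros((len(a_j) - 1, len(a_k) - 1))
    np.add.at(table, (sub.y[:, 0], sub.y[:, 1]), 1.0)
    return _polychoric_table(table, norm.ppf(a_j), norm.ppf(a_k))


def polychoric_matrix(data: OrdinalData, cutpoints: Optional[Cutpoints] = None) -> np.ndarray:
    """Symmetric d x d matrix of pairwise polychoric correlations."""
    cp = cutpoints or estimate_cutpoints(data)
    alpha = cp.alpha
    d = data.d
    R = np.eye(d)
    for j in range(d):
        for k in range(j + 1, d):
            table = np.zeros((data.K[j], data.K[k]))
            np.add.at(table, (data.y[:, j], data.y[:, k]), 1.0)
            R[j, k] = R[k, j] = _polychoric_table(table, alpha[j], alpha[k])
    return R


def _zero_split(cp: Cutpoints, j: int) -> int:
    """Interior cutpoint index closest to zero on the normal scale."""
    alpha_int = cp.alpha[j][1:-1]
    return int(np.argmin(np.abs(alpha_int))) + 1


def empirical_semicorrelations(
    data: OrdinalData, cutpoints: Optional[Cutpoints] = None
):
    """Averages over item pairs of (rho_N, rho_minus, rho_plus).

    rho_N is the full polychoric correlation.  For the semi-correlations
    each item is dichotomized at the cutpoint nearest zero on the normal
    scale; the lower (upper) value is the polychoric correlation of the
    sub-sample with both items below (at or above) their split, with
    cutpoints re-estimated on the sub-sample.  Pairs whose quadrant
    sub-table is degenerate are skipped with a warning.
    """
    cp = cutpoints or estimate_cutpoints(data)
    d = data.d
    splits = [_zero_split(cp, j) for j in range(d)]
    full, lower, upper = [], [], []
    for j in range(d):
        for k in range(j + 1, d):
            table = np.zeros((data.K[j], data.K[k]))
            np.add.at(table, (data.y[:, j], data.y[:, k]), 1.0)
            full.append(_polychoric_table(table, cp.alpha[j], cp.alpha[k]))
            for side, store in (("lower", lower), ("upper", upper)):
                if side == "lower":
                    mask = (data.y[:, j] < splits[j]) & (data.y[:, k] < splits[k])
                    yj, yk = data.y[mask, j], data.y[mask, k]
                else:
                    mask = (data.y[:, j] >= splits[j]) & (data.y[:, k] >= splits[k])
                    yj, yk = data.y[mask, j] - splits[j], data.y[mask, k] - splits[k]
                if mask.sum() < 10 or len(np.unique(yj)) < 2 or len(np.unique(yk)) < 2:
                    log.warning(
                        "items %d,%d: %s quadrant degenerate; pair skipped",
                        j + 1, k + 1, side,
                    )
                    continue
                store.append(polychoric(yj, yk))
    if not lower or not upper:
        raise ValueError("all pairs degenerate in one quadrant; cannot average")
    return float(np.mean(full)), float(np.mean(lower)), float(np.mean(upper))
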