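"""Parametric bivariate copula families.

The families used to link items to latent factors and to each other are the
bivariate normal (BVN), Student t_nu, Gumbel, survival Gumbel, Frank and
independence copulas.  Each family exposes its cdf ``C(u, v; theta)``, its
h-function (the conditional cdf ``\\partial C / \\partial u``), its density,
and maps between the dependence parameter ``theta`` and Kendall's tau.

Normal-scores correlations and semi-correlations (the correlation of
``(Phi^{-1}(U), Phi^{-1}(V))`` overall and restricted to the joint
lower/upper quadrant) are computed by tensor-product Gauss-Legendre
integration against the copula density; they are the theoretical analogue of
the polychoric (semi-)correlations used as tail-asymmetry diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize, special
from scipy.stats import norm

__all__ = [
    "CopulaFamily",
    "CopulaSpec",
    "parse_family",
    "copula_cdf",
    "copula_hfun",
    "copula_pdf",
    "reflect",
    "tau_from_theta",
    "theta_from_tau",
    "normal_scores_summary",
    "calibrate_to_rhoN",
    "bvn_cdf",
]

#: clipping applied to u, v before transcendental transforms; cutpoints at the
#: boundary (a_{j,0}=0, a_{j,K}=1) legitimately enter h-functions.
EPS = 1e-10

_TAGS = ("independence", "bvn", "t", "gumbel", "sgumbel", "frank")

#: candidate degrees of freedom for the t copula; nu is selected from this
#: grid, never estimated continuously, and is not counted as a free parameter.
T_NU_GRID = (2.0, 3.0, 5.0, 7.0)


@dataclass(frozen=True)
class CopulaFamily:
    """A copula family tag, plus degrees of freedom for the t family."""

    tag: str
    nu: Optional[float] = None

    def __post_init__(self):
        if self.tag not in _TAGS:
            raise ValueError(f"unknown copula family tag {self.tag!r}")
        if self.tag == "t":
            if self.nu is None or self.nu <= 0:
                raise ValueError("t copula requires nu > 0")
        elif self.nu is not None:
            raise ValueError(f"nu is only meaningful for the t family, got tag {self.tag!r}")

    @property
    def name(self) -> str:
        if self.tag == "t":
            nu = self.nu
            return f"t{int(nu)}" if float(nu).is_integer() else f"t{nu}"
        return {"independence": "indep"}.get(self.tag, self.tag)

    @property
    def n_free_params(self) -> int:
        return 0 if self.tag == "independence" else 1


@dataclass(frozen=True)
class CopulaSpec:
    """A copula family together with its dependence parameter theta.

    Parameter domains: BVN/t theta in [-1, 1]; Gumbel/survival Gumbel
    theta >= 1; Frank theta real and nonzero; independence has no parameter.
    """

    family: CopulaFamily
    theta: Optional[float] = None

    def __post_init__(self):
        tag = self.family.tag
        th = self.theta
        if tag == "independence":
            if th is not None:
                raise ValueError("independence copula takes no parameter")
            return
        if th is None:
            raise ValueError(f"{tag} copula requires a parameter theta")
        if tag in ("bvn", "t") and not -1.0 <= th <= 1.0:
            raise ValueError(f"{tag} copula requires theta in [-1, 1], got {th}")
        if tag in ("gumbel", "sgumbel") and th < 1.0:
            raise ValueError(f"{tag} copula requires theta >= 1, got {th}")
        if tag == "frank" and th == 0.0:
            raise ValueError("frank copula requires theta != 0")

    @property
    def tag(self) -> str:
        return self.family.tag


_FAMILY_ALIASES = {
    "indep": CopulaFamily("independence"),
    "independence": CopulaFamily("independence"),
    "bvn": CopulaFamily("bvn"),
    "gumbel": CopulaFamily("gumbel"),
    "sgumbel": CopulaFamily("sgumbel"),
    "frank": CopulaFamily("frank"),
}


def parse_family(name: str) -> CopulaFamily:
    """Parse a family name such as ``bvn``, ``t5``, ``gumbel`` or ``indep``."""
    name = name.strip().lower()
    if name in _FAMILY_ALIASES:
        return _FAMILY_ALIASES[name]
    if name.startswith("t"):
        try:
            nu = float(name[1:])
        except ValueError:
            raise ValueError(f"unknown copula family {name!r}") from None
        return CopulaFamily("t", nu)
    raise ValueError(f"unknown copula family {name!r}")


def _clip01(x):
    return np.clip(np.asarray(x, dtype=float), EPS, 1.0 - EPS)


# ---------------------------------------------------------------------------
# bivariate normal cdf (vectorized, via Owen's T)
# ---------------------------------------------------------------------------

def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal, vectorized.

    Uses the Owen's-T identity, which is fast and accurate away from
    |rho| = 1; the comonotone/countermonotone limits are handled exactly.
    """
    h, k, rho = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (h, k, rho)))
    h = h.copy()
    k = k.copy()
    rho = np.clip(rho, -1.0, 1.0)

    out = np.empty(h.shape, dtype=float)
    hi = np.abs(rho) >= 1.0 - 1e-12
    if np.any(hi):
        pos = hi & (rho > 0)
        neg = hi & (rho < 0)
        out[pos] = norm.cdf(np.minimum(h[pos], k[pos]))
        out[neg] = np.maximum(norm.cdf(h[neg]) + norm.cdf(k[neg]) - 1.0, 0.0)
    lo = ~hi
    if np.any(lo):
        hh = h[lo]
        kk = k[lo]
        r = rho[lo]
        # nudge exact zeros off the axis: the limit is continuous and the
        # perturbation is far below the accuracy of Owen's T itself
        hh = np.where(hh == 0.0, 1e-15, hh)
        kk = np.where(kk == 0.0, 1e-15, kk)
        s = np.sqrt(1.0 - r * r)
        ah = (kk - r * hh) / (hh * s)
        ak = (hh - r * kk) / (kk * s)
        delta = np.where(hh * kk > 0, 0.0, 0.5)
        val = (
            0.5 * (norm.cdf(hh) + norm.cdf(kk))
            - special.owens_t(hh, ah)
            - special.owens_t(kk, ak)
            - delta
        )
        out[lo] = np.clip(val, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Student-t helpers
# ---------------------------------------------------------------------------

def _t_cdf(x, nu):
    return special.stdtr(nu, x)


def _t_ppf(u, nu):
    return special.stdtrit(nu, u)


def _t_pdf(x, nu):
    return np.exp(
        special.gammaln((nu + 1.0) / 2.0)
        - special.gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - (nu + 1.0) / 2.0 * np.log1p(x * x / nu)
    )


_T_CDF_GL_NODES = 24
_t_gl_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n):
    if n not in _t_gl_cache:
        x, w = np.polynomial.legendre.leggauss(n)
        _t_gl_cache[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _t_gl_cache[n]


def _t_copula_cdf(u, v, theta, nu):
    """t copula cdf by one-dimensional quadrature.

    Conditioning on the first coordinate X = sqrt(nu) tan(phi) gives

        C(u, v) = c_nu sqrt(nu) int_{-pi/2}^{phi_u} cos(phi)^{nu-1}
                  T_{nu+1}( a (y cos(phi) - rho sqrt(nu) sin(phi)) ) dphi,

    a smooth bounded integrand that Gauss-Legendre resolves to ~1e-12.
    """
    u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
    x, w = _gl_nodes(_T_CDF_GL_NODES)
    xu = _t_ppf(u, nu)
    y = _t_ppf(v, nu)
    phi_u = np.arctan(xu / np.sqrt(nu))
    lo = -np.pi / 2.0
    half = (phi_u - lo) / 2.0
    phi = lo + (phi_u - lo)[..., None] * x  # nodes in (-pi/2, phi_u)
    a = np.sqrt((nu + 1.0) / (nu * (1.0 - theta * theta)))
    arg = a * (y[..., None] * np.cos(phi) - theta * np.sqrt(nu) * np.sin(phi))
    integrand = np.cos(phi) ** (nu - 1.0) * _t_cdf(arg, nu + 1.0)
    c_nu = np.exp(
        special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0)
    ) / np.sqrt(nu * np.pi)
    return c_nu * np.sqrt(nu) * 2.0 * half * np.sum(w * integrand, axis=-1)


def _t_hfun_raw(v, u, theta, nu):
    tu = _t_ppf(_clip01(u), nu)
    tv = _t_ppf(_clip01(v), nu)
    z = (tv - theta * tu) * np.sqrt((nu + 1.0) / ((nu + tu * tu) * (1.0 - theta * theta)))
    return _t_cdf(z, nu + 1.0)


# ---------------------------------------------------------------------------
# cdf / h-function / density dispatch
# ---------------------------------------------------------------------------

# Gumbel quantities are computed in log space: with x = -log u, y = -log v,
# log S = logaddexp(theta log x, theta log y) stays finite for large theta.

def _gumbel_logS(u, v, theta):
    lx = np.log(-np.log(u))
    ly = np.log(-np.log(v))
    return np.logaddexp(theta * lx, theta * ly), lx, ly


def _gumbel_cdf_raw(u, v, theta):
    logS, _, _ = _gumbel_logS(u, v, theta)
    return np.exp(-np.exp(logS / theta))


def _gumbel_hfun_raw(v, u, theta):
    logS, lx, _ = _gumbel_logS(u, v, theta)
    log_h = -np.exp(logS / theta) + (1.0 / theta - 1.0) * logS + (theta - 1.0) * lx - np.log(u)
    return np.exp(log_h)


def _gumbel_pdf_raw(u, v, theta):
    logS, lx, ly = _gumbel_logS(u, v, theta)
    log_c = (
        -np.exp(logS / theta)
        + (theta - 1.0) * (lx + ly)
        - np.log(u * v)
        + (2.0 / theta - 2.0) * logS
        + np.log1p((theta - 1.0) * np.exp(-logS / theta))
    )
    return np.exp(log_c)


def _frank_cdf_raw(u, v, theta):
    em1 = np.expm1(-theta)
    return -np.log1p(np.expm1(-theta * u) * np.expm1(-theta * v) / em1) / theta


def _frank_hfun_raw(v, u, theta):
    eu = np.exp(-theta * u)
    ev1 = np.expm1(-theta * v)
    em1 = np.expm1(-theta)
    return eu * ev1 / (em1 + np.expm1(-theta * u) * ev1)


def _frank_pdf_raw(u, v, theta):
    # cancellation-free denominator: em1 + expm1(-tu) expm1(-tv) expanded
    den = (
        np.exp(-theta * u) + np.exp(-theta * v)
        - np.exp(-theta) - np.exp(-theta * (u + v))
    )
    num = theta * -np.expm1(-theta) * np.exp(-theta * (u + v))
    return num / (den * den)


def copula_cdf(u, v, spec: CopulaSpec):
    """Copula cdf C(u, v; theta), vectorized over u and v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    tag = spec.tag
    th = spec.theta
    uc, vc = _clip01(u), _clip01(v)
    if tag == "independence":
        out = u * v
    elif tag == "bvn":
        out = bvn_cdf(norm.ppf(uc), norm.ppf(vc), th)
    elif tag == "t":
        out = _t_copula_cdf(uc, vc, th, spec.family.nu)
    elif tag == "gumbel":
        out = _gumbel_cdf_raw(uc, vc, th)
    elif tag == "sgumbel":
        out = uc + vc - 1.0 + _gumbel_cdf_raw(1.0 - uc, 1.0 - vc, th)
    elif tag == "frank":
        out = _frank_cdf_raw(uc, vc, th)
    else:  # pragma: no cover
        raise ValueError(tag)
    out = np.clip(out, np.maximum(u + v - 1.0, 0.0), np.minimum(u, v))
    return out if out.shape else float(out)


def copula_hfun(v, u, spec: CopulaSpec):
    """h-function C_{2|1}(v | u) = dC(u, v)/du, vectorized."""
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    tag = spec.tag
    th = spec.theta
    uc, vc = _clip01(u), _clip01(v)
    if tag == "independence":
        out = v.astype(float)
    elif tag == "bvn":
        zu = norm.ppf(uc)
        zv = norm.ppf(vc)
        out = norm.cdf((zv - th * zu) / np.sqrt(1.0 - th * th))
    elif tag == "t":
        out = _t_hfun_raw(vc, uc, th, spec.family.nu)
    elif tag == "gumbel":
        out = _gumbel_hfun_raw(vc, uc, th)
    elif tag == "sgumbel":
        out = 1.0 - _gumbel_hfun_raw(1.0 - vc, 1.0 - uc, th)
    elif tag == "frank":
        out = _frank_hfun_raw(vc, uc, th)
    else:  # pragma: no cover
        raise ValueError(tag)
    # exact boundary behaviour: h(0|u)=0, h(1|u)=1
    out = np.where(v <= 0.0, 0.0, np.where(v >= 1.0, 1.0, out))
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def copula_pdf(u, v, spec: CopulaSpec):
    """Copula density c(u, v; theta), vectorized."""
    u = _clip01(u)
    v = _clip01(v)
    tag = spec.tag
    th = spec.theta
    if tag == "independence":
        out = np.ones(np.broadcast(u, v).shape)
    elif tag == "bvn":
        z1 = norm.ppf(u)
        z2 = norm.ppf(v)
        r2 = 1.0 - th * th
        out = np.exp(-(th * th * (z1 * z1 + z2 * z2) - 2.0 * th * z1 * z2) / (2.0 * r2)) / np.sqrt(r2)
    elif tag == "t":
        nu = spec.family.nu
        x1 = _t_ppf(u, nu)
        x2 = _t_ppf(v, nu)
        r2 = 1.0 - th * th
        quad = (x1 * x1 - 2.0 * th * x1 * x2 + x2 * x2) / (nu * r2)
        f2 = (1.0 + quad) ** (-(nu + 2.0) / 2.0) / (2.0 * np.pi * np.sqrt(r2))
        out = f2 / (_t_pdf(x1, nu) * _t_pdf(x2, nu))
    elif tag == "gumbel":
        out = _gumbel_pdf_raw(u, v, th)
    elif tag == "sgumbel":
        out = _gumbel_pdf_raw(1.0 - u, 1.0 - v, th)
    elif tag == "frank":
        out = _frank_pdf_raw(u, v, th)
    else:  # pragma: no cover
        raise ValueError(tag)
    out = np.asarray(out, dtype=float)
    return out if out.shape else float(out)


def reflect(spec: CopulaSpec) -> CopulaSpec:
    """Return the survival (reflected) copula of ``spec``.

    The reflected cdf is ``u + v - 1 + C(1-u, 1-v)``.  Gumbel and survival
    Gumbel are each other's reflections; BVN, t, Frank and independence are
    reflection symmetric, so reflection returns the same family and
    parameter.  Reflecting twice recovers the original copula.
    """
    if spec.tag == "gumbel":
        return CopulaSpec(CopulaFamily("sgumbel"), spec.theta)
    if spec.tag == "sgumbel":
        return CopulaSpec(CopulaFamily("gumbel"), spec.theta)
    return spec


# ---------------------------------------------------------------------------
# Kendall's tau maps
# ---------------------------------------------------------------------------

def _debye1(theta):
    """Debye function D1(theta) = (1/theta) int_0^theta t/(e^t - 1) dt."""
    val, _ = integrate.quad(lambda t: t / np.expm1(t) if t != 0 else 1.0, 0.0, theta)
    return val / theta


def _frank_tau(theta):
    return 1.0 - 4.0 / theta * (1.0 - _debye1(theta))


def tau_from_theta(spec: CopulaSpec) -> float:
    """Kendall's tau implied by the copula parameter.

    Gumbel / survival Gumbel: tau = 1 - 1/theta.  BVN / t: tau =
    (2/pi) arcsin(theta).  Frank: the Debye-D1 formula.  Independence: 0.
    """
    tag = spec.tag
    if tag == "independence":
        return 0.0
    th = spec.theta
    if tag in ("gumbel", "sgumbel"):
        return 1.0 - 1.0 / th
    if tag in ("bvn", "t"):
        return 2.0 / np.pi * np.arcsin(th)
    if tag == "frank":
        return _frank_tau(th)
    raise ValueError(tag)  # pragma: no cover


def theta_from_tau(family: CopulaFamily, tau: float) -> CopulaSpec:
    """Invert the tau map; raises for a tau the family cannot attain."""
    tag = family.tag
    if tag == "independence":
        if tau != 0.0:
            raise ValueError("independence copula only attains tau = 0")
        return CopulaSpec(family, None)
    if tag in ("gumbel", "sgumbel"):
        if not 0.0 <= tau < 1.0:
            raise ValueError(f"{tag} copula attains tau in [0, 1), got {tau}")
        return CopulaSpec(family, 1.0 / (1.0 - tau))
    if tag in ("bvn", "t"):
        if not -1.0 < tau < 1.0:
            raise ValueError(f"{tag} copula attains tau in (-1, 1), got {tau}")
        return CopulaSpec(family, float(np.sin(np.pi * tau / 2.0)))
    if tag == "frank":
        if tau == 0.0 or not -1.0 < tau < 1.0:
            raise ValueError(f"frank copula attains tau in (-1, 1) \\ {{0}}, got {tau}")
        th = optimize.brentq(
            lambda t: _frank_tau(t) - tau,
            1e-6 if tau > 0 else -500.0,
            500.0 if tau > 0 else -1e-6,
            xtol=1e-12,
        )
        return CopulaSpec(family, float(th))
    raise ValueError(tag)  # pragma: no cover


# ---------------------------------------------------------------------------
# normal-scores correlations and semi-correlations
# ---------------------------------------------------------------------------

def _ns_moments(spec: CopulaSpec, lo1, hi1, lo2, hi2, npts):
    """Moments of normal scores (Z1, Z2) over the box [lo1,hi1] x [lo2,hi2].

    The joint density of the normal scores is c(Phi(z1), Phi(z2))
    phi(z1) phi(z2); moments are computed by a tensor Gauss-Legendre rule.
    """
    x, w = np.polynomial.legendre.leggauss(npts)
    z1 = (lo1 + hi1) / 2.0 + (hi1 - lo1) / 2.0 * x
    w1 = (hi1 - lo1) / 2.0 * w
    z2 = (lo2 + hi2) / 2.0 + (hi2 - lo2) / 2.0 * x
    w2 = (hi2 - lo2) / 2.0 * w
    Z1, Z2 = np.meshgrid(z1, z2, indexing="ij")
    dens = copula_pdf(norm.cdf(Z1), norm.cdf(Z2), spec) * norm.pdf(Z1) * norm.pdf(Z2)
    W = np.outer(w1, w2) * dens
    m = W.sum()
    e1 = (W * Z1).sum()
    e2 = (W * Z2).sum()
    e11 = (W * Z1 * Z1).sum()
    e22 = (W * Z2 * Z2).sum()
    e12 = (W * Z1 * Z2).sum()
    return m, e1, e2, e11, e22, e12


def _region_corr(spec, lo1, hi1, lo2, hi2, npts):
    m, e1, e2, e11, e22, e12 = _ns_moments(spec, lo1, hi1, lo2, hi2, npts)
    if m <= 0:
        raise FloatingPointError("semi-correlation integration failed: zero quadrant mass")
    mu1, mu2 = e1 / m, e2 / m
    v1 = e11 / m - mu1 * mu1
    v2 = e22 / m - mu2 * mu2
    if v1 <= 0 or v2 <= 0:
        raise FloatingPointError("semi-correlation integration failed: nonpositive variance")
    return (e12 / m - mu1 * mu2) / np.sqrt(v1 * v2)


_ZMAX = 8.5


def normal_scores_summary(spec: CopulaSpec, npts: int = 120):
    """(rho_N, rho_minus, rho_plus): correlation of the normal scores and the
    correlations conditional on both scores negative / both positive.

    For reflection-symmetric families rho_minus = rho_plus; Gumbel has
    rho_minus < rho_plus and survival Gumbel the reverse.
    """
    if spec.tag == "independence":
        return 0.0, 0.0, 0.0
    rho_n = _region_corr(spec, -_ZMAX, _ZMAX, -_ZMAX, _ZMAX, npts)
    rho_minus = _region_corr(spec, -_ZMAX, 0.0, -_ZMAX, 0.0, npts)
    rho_plus = _region_corr(spec, 0.0, _ZMAX, 0.0, _ZMAX, npts)
    return float(rho_n), float(rho_minus), float(rho_plus)


def _rho_n(spec, npts=80):
    if spec.tag == "independence":
        return 0.0
    if spec.tag == "bvn":
        return spec.theta
    return _region_corr(spec, -_ZMAX, _ZMAX, -_ZMAX, _ZMAX, npts)


def calibrate_to_rhoN(family: CopulaFamily, rhoN_target: float, tol: float = 1e-5) -> CopulaSpec:
    """Find the parameter giving a target normal-scores correlation rho_N."""
    tag = family.tag
    if tag == "independence":
        if abs(rhoN_target) > tol:
            raise ValueError("independence copula only attains rho_N = 0")
        return CopulaSpec(family, None)
    if tag == "bvn":
        # normal scores of the BVN copula are exactly bivariate normal
        if not -1.0 < rhoN_target < 1.0:
            raise ValueError("bvn copula attains rho_N in (-1, 1)")
        return CopulaSpec(family, float(rhoN_target))
    if tag in ("gumbel", "sgumbel"):
        if rhoN_target < 0.0:
            raise ValueError(f"{tag} copula cannot attain negative rho_N")
        if rhoN_target == 0.0:
            return CopulaSpec(family, 1.0)
        lo, hi = 1.0 + 1e-8, 50.0
    elif tag == "t":
        if not -1.0 < rhoN_target < 1.0:
            raise ValueError("t copula attains rho_N in (-1, 1)")
        lo, hi = -0.9999, 0.9999
    elif tag == "frank":
        if not -1.0 < rhoN_target < 1.0 or rhoN_target == 0.0:
            raise ValueError("frank copula attains rho_N in (-1, 1) \\ {0}")
        lo, hi = (1e-4, 100.0) if rhoN_target > 0 else (-100.0, -1e-4)
    else:  # pragma: no cover
        raise ValueError(tag)

    def f(th):
        return _rho_n(CopulaSpec(family, th)) - rhoN_target

    th = optimize.brentq(f, lo, hi, xtol=tol * 1e-2)
    return CopulaSpec(family, float(th))
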