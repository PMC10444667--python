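"""Bivariate copula families: cdfs, h-functions, tau maps, semi-correlations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kendalltau, multivariate_normal, norm

from factortree.copulas import (
    CopulaFamily,
    CopulaSpec,
    bvn_cdf,
    calibrate_to_rhoN,
    copula_cdf,
    copula_hfun,
    copula_pdf,
    normal_scores_summary,
    parse_family,
    reflect,
    tau_from_theta,
    theta_from_tau,
)

ALL_SPECS = [
    CopulaSpec(CopulaFamily("independence"), None),
    CopulaSpec(CopulaFamily("bvn"), 0.5),
    CopulaSpec(CopulaFamily("bvn"), -0.7),
    CopulaSpec(CopulaFamily("t", 3.0), 0.4),
    CopulaSpec(CopulaFamily("t", 5.0), -0.3),
    CopulaSpec(CopulaFamily("gumbel"), 1.6),
    CopulaSpec(CopulaFamily("gumbel"), 3.0),
    CopulaSpec(CopulaFamily("sgumbel"), 2.0),
    CopulaSpec(CopulaFamily("frank"), 4.0),
    CopulaSpec(CopulaFamily("frank"), -6.0),
]

IDS = [f"{s.tag}{'' if s.theta is None else s.theta}" for s in ALL_SPECS]


# ---------------------------------------------------------------------------
# cdf
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("spec", ALL_SPECS, ids=IDS)
def test_cdf_frechet_bounds_and_margins(spec):
    """C lies between the Fréchet bounds and has uniform margins."""
    g = np.linspace(0.0, 1.0, 21)
    U, V = np.meshgrid(g, g)
    C = copula_cdf(U, V, spec)
    assert np.all(C >= np.maximum(U + V - 1.0, 0.0) - 1e-9)
    assert np.all(C <= np.minimum(U, V) + 1e-9)
    assert np.allclose(copula_cdf(g, np.ones_like(g), spec), g, atol=1e-8)
    assert np.allclose(copula_cdf(np.ones_like(g), g, spec), g, atol=1e-8)
    assert np.allclose(copula_cdf(g, np.zeros_like(g), spec), 0.0, atol=1e-9)


def test_cdf_known_values():
    """Gumbel at theta=1 is independence; theta=2 has the closed form
    C(1/2,1/2) = 2^(-sqrt 2); Frank boundary returns the margin."""
    assert copula_cdf(0.5, 0.5, CopulaSpec(CopulaFamily("gumbel"), 1.0)) == pytest.approx(0.25, abs=1e-9)
    assert copula_cdf(0.3, 1.0, CopulaSpec(CopulaFamily("frank"), 4.0)) == pytest.approx(0.3, abs=1e-8)
    assert copula_cdf(0.5, 0.5, CopulaSpec(CopulaFamily("gumbel"), 2.0)) == pytest.approx(
        2.0 ** -np.sqrt(2.0), abs=1e-10
    )


def test_bvn_cdf_matches_scipy(rng):
    pts = rng.normal(scale=1.5, size=(40, 2))
    rhos = rng.uniform(-0.95, 0.95, size=40)
    ref = [
        multivariate_normal(cov=[[1, r], [r, 1]]).cdf(p) for p, r in zip(pts, rhos)
    ]
    assert np.allclose(bvn_cdf(pts[:, 0], pts[:, 1], rhos), ref, atol=1e-12)


def test_t_cdf_matches_scipy_multivariate_t():
    from scipy.special import stdtrit
    from scipy.stats import multivariate_t

    spec = CopulaSpec(CopulaFamily("t", 5.0), 0.6)
    for u, v in [(0.3, 0.7), (0.1, 0.2), (0.9, 0.95)]:
        x = np.array([stdtrit(5, u), stdtrit(5, v)])
        ref = multivariate_t(shape=[[1, 0.6], [0.6, 1]], df=5, seed=7).cdf(x)
        assert copula_cdf(u, v, spec) == pytest.approx(ref, abs=5e-4)


def test_invalid_parameters_raise():
    with pytest.raises(ValueError, match="gumbel"):
        CopulaSpec(CopulaFamily("gumbel"), 0.5)
    with pytest.raises(ValueError, match="bvn"):
        CopulaSpec(CopulaFamily("bvn"), 1.5)
    with pytest.raises(ValueError, match="frank"):
        CopulaSpec(CopulaFamily("frank"), 0.0)
    with pytest.raises(ValueError):
        CopulaFamily("t")  # nu required


# ---------------------------------------------------------------------------
# h-functions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("spec", ALL_SPECS, ids=IDS)
def test_hfun_is_partial_derivative(spec, rng):
    """h(v|u) matches the central finite difference of C in u."""
    u = rng.uniform(0.05, 0.95, size=25)
    v = rng.uniform(0.05, 0.95, size=25)
    eps = 1e-6
    num = (copula_cdf(u + eps, v, spec) - copula_cdf(u - eps, v, spec)) / (2 * eps)
    assert np.allclose(copula_hfun(v, u, spec), num, atol=1e-5)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=IDS)
def test_hfun_boundaries_and_monotonicity(spec):
    u = 0.37
    v = np.linspace(0.0, 1.0, 41)
    h = copula_hfun(v, u, spec)
    assert h[0] == 0.0 and h[-1] == 1.0
    assert np.all(np.diff(h) >= -1e-12)
    assert np.all((h >= 0) & (h <= 1))


def test_hfun_independence_returns_v():
    spec = CopulaSpec(CopulaFamily("independence"), None)
    assert copula_hfun(0.7, 0.4, spec) == pytest.approx(0.7)


@given(st.floats(0.02, 0.98), st.floats(0.02, 0.98), st.floats(-0.9, 0.9))
def test_bvn_hfun_bounds_property(v, u, theta):
    h = copula_hfun(v, u, CopulaSpec(CopulaFamily("bvn"), theta))
    assert 0.0 <= h <= 1.0


# ---------------------------------------------------------------------------
# reflection
# ---------------------------------------------------------------------------

def _reflected_cdf(u, v, spec):
    return u + v - 1.0 + copula_cdf(1.0 - u, 1.0 - v, spec)


def test_reflect_identity_on_grid():
    g = np.linspace(0.05, 0.95, 10)
    U, V = np.meshgrid(g, g)
    gum = CopulaSpec(CopulaFamily("gumbel"), 1.8)
    assert np.allclose(copula_cdf(U, V, reflect(gum)), _reflected_cdf(U, V, gum), atol=1e-10)
    # reflection-symmetric families are their own reflections
    for spec in (CopulaSpec(CopulaFamily("bvn"), 0.45), CopulaSpec(CopulaFamily("frank"), 3.0)):
        assert np.allclose(copula_cdf(U, V, reflect(spec)), _reflected_cdf(U, V, spec), atol=1e-8)
    # involution
    frank = CopulaSpec(CopulaFamily("frank"), 3.0)
    assert reflect(reflect(frank)) == frank
    assert reflect(reflect(gum)) == gum


# ---------------------------------------------------------------------------
# Kendall's tau maps
# ---------------------------------------------------------------------------

def test_tau_closed_forms():
    assert tau_from_theta(CopulaSpec(CopulaFamily("gumbel"), 2.0)) == pytest.approx(0.5)
    assert tau_from_theta(CopulaSpec(CopulaFamily("bvn"), 0.5)) == pytest.approx(1.0 / 3.0)
    assert theta_from_tau(CopulaFamily("gumbel"), 0.7).theta == pytest.approx(10.0 / 3.0)
    assert theta_from_tau(CopulaFamily("t", 3.0), 0.0).theta == pytest.approx(0.0)


@pytest.mark.parametrize(
    "family,taus",
    [
        (CopulaFamily("gumbel"), [0.05, 0.3, 0.6, 0.9]),
        (CopulaFamily("sgumbel"), [0.1, 0.5, 0.8]),
        (CopulaFamily("bvn"), [-0.8, -0.2, 0.3, 0.9]),
        (CopulaFamily("t", 5.0), [-0.5, 0.4]),
        (CopulaFamily("frank"), [-0.7, -0.1, 0.2, 0.5, 0.85]),
    ],
)
def test_tau_round_trip(family, taus):
    for tau in taus:
        spec = theta_from_tau(family, tau)
        tol = 1e-8 if family.tag == "frank" else 1e-10
        assert tau_from_theta(spec) == pytest.approx(tau, abs=tol)


def test_tau_domain_errors():
    with pytest.raises(ValueError):
        theta_from_tau(CopulaFamily("gumbel"), -0.2)
    with pytest.raises(ValueError):
        theta_from_tau(CopulaFamily("bvn"), 1.0)


def test_frank_tau_against_concordance_oracle(rng):
    """Frank Debye-formula tau agrees with sample Kendall's tau of pairs
    simulated by conditional inversion."""
    theta = 5.0
    n = 60_000
    u = rng.random(n)
    w = rng.random(n)
    # invert h(v|u) = w in closed form
    e = w * np.expm1(-theta) / (np.exp(-theta * u) - w * np.expm1(-theta * u))
    v = -np.log1p(e) / theta
    tau_mc = kendalltau(u, v).statistic
    assert tau_from_theta(CopulaSpec(CopulaFamily("frank"), theta)) == pytest.approx(
        tau_mc, abs=0.012
    )


# ---------------------------------------------------------------------------
# normal-scores correlations / semi-correlations
# ---------------------------------------------------------------------------

def test_semicorrelation_symmetry_structure():
    """Reflection-symmetric families have equal lower and upper
    semi-correlations; Gumbel has rho- < rho+ and s.Gumbel the reverse."""
    for name in ("bvn", "t5", "frank"):
        spec = theta_from_tau(parse_family(name), 0.4)
        _, lo, hi = normal_scores_summary(spec)
        assert lo == pytest.approx(hi, abs=1e-6)
    _, lo, hi = normal_scores_summary(theta_from_tau(parse_family("gumbel"), 0.4))
    assert lo < hi
    _, slo, shi = normal_scores_summary(theta_from_tau(parse_family("sgumbel"), 0.4))
    assert slo > shi
    assert slo == pytest.approx(hi, abs=1e-8)  # reflection swaps the tails


def test_independence_summary_is_zero():
    assert normal_scores_summary(CopulaSpec(CopulaFamily("independence"), None)) == (0, 0, 0)


def test_calibrate_to_rhoN():
    assert calibrate_to_rhoN(CopulaFamily("bvn"), 0.35).theta == pytest.approx(0.35)
    assert calibrate_to_rhoN(CopulaFamily("gumbel"), 0.0).theta == pytest.approx(1.0)
    spec = calibrate_to_rhoN(CopulaFamily("t", 5.0), 0.35)
    rn, _, _ = normal_scores_summary(spec)
    assert rn == pytest.approx(0.35, abs=1e-4)
    with pytest.raises(ValueError):
        calibrate_to_rhoN(CopulaFamily("gumbel"), -0.3)


def test_calibrated_t_matches_monte_carlo(rng):
    """rho_N of the calibrated t copula cross-checked by simulating normal
    scores from the bivariate t."""
    spec = calibrate_to_rhoN(CopulaFamily("t", 5.0), 0.35)
    n = 2_000_000
    L = np.linalg.cholesky([[1.0, spec.theta], [spec.theta, 1.0]])
    z = rng.standard_normal((n, 2)) @ L.T
    w = rng.chisquare(5, size=n) / 5.0
    x = z / np.sqrt(w)[:, None]
    from scipy.stats import t as tdist

    zn = norm.ppf(tdist.cdf(x, 5))
    assert np.corrcoef(zn[:, 0], zn[:, 1])[0, 1] == pytest.approx(0.35, abs=4e-3)


def test_pdf_integrates_to_hfun(rng):
    """int_0^v c(u, t) dt = h(v | u) for a couple of families."""
    from scipy.integrate import quad

    for spec in (CopulaSpec(CopulaFamily("gumbel"), 2.0), CopulaSpec(CopulaFamily("frank"), 4.0),
                 CopulaSpec(CopulaFamily("t", 3.0), 0.5)):
        u, v = 0.4, 0.65
        val, _ = quad(lambda t: copula_pdf(u, t, spec), 0, v, limit=200)
        assert val == pytest.approx(copula_hfun(v, u, spec), abs=1e-6)


def test_parse_family_names():
    assert parse_family("t5") == CopulaFamily("t", 5.0)
    assert parse_family("indep").tag == "independence"
    assert parse_family("BVN").tag == "bvn"
    with pytest.raises(ValueError):
        parse_family("clayton")
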