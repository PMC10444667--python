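"""Structure selection, discrepancies, Vuong comparison, family selection."""

import numpy as np
import pytest

from factortree import Cutpoints, FactorTreeSpec, VineTree
from factortree.datasets import generate_fixture
from factortree.polychoric import polychoric_matrix
from factortree.selection import (
    discrepancies,
    implied_correlation_matrix,
    partial_corr_matrix,
    select_families,
    vuong_interval,
)
from factortree.simulate import simulate
from factortree.trees import max_spanning_tree


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------

def test_partial_corr_arithmetic():
    R = np.array([[1.0, 0.5], [0.5, 1.0]])
    P = partial_corr_matrix(R, np.array([0.5, 0.5]), level=1)
    assert P[0, 1] == pytest.approx(1.0 / 3.0)
    # r_jk = theta_j theta_k -> residual partial correlation zero
    th = np.array([0.8, 0.6])
    R2 = np.outer(th, th)
    np.fill_diagonal(R2, 1.0)
    assert partial_corr_matrix(R2, th, level=1)[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_partial_corr_level2_matches_regression_oracle(rng):
    """Level-2 partials agree with the partial correlation of (Z_j, Z_k)
    given (Z_01, Z_02) computed from the joint 4x4 correlation matrix by
    matrix inversion."""
    th1 = rng.uniform(0.2, 0.7, size=4)
    th2 = rng.uniform(0.1, 0.5, size=4)
    resid = np.eye(4)  # conditional independence given the two factors
    s1 = np.sqrt(1 - th1 ** 2)
    s2 = np.sqrt(1 - th2 ** 2)
    R = resid * np.outer(s2, s2) * np.outer(s1, s1)
    R += np.outer(th2, th2) * np.outer(s1, s1) + np.outer(th1, th1)
    np.fill_diagonal(R, 1.0)
    P = partial_corr_matrix(R, (th1, th2), level=2)
    for j in range(4):
        for k in range(j + 1, 4):
            # joint correlation matrix of (Zj, Zk, Z01, Z02)
            lj = [1.0, R[j, k], th1[j], th2[j] * s1[j]]
            lk = [R[j, k], 1.0, th1[k], th2[k] * s1[k]]
            S = np.array([lj, lk, [th1[j], th1[k], 1, 0], [th2[j] * s1[j], th2[k] * s1[k], 0, 1]])
            Om = np.linalg.inv(S)
            oracle = -Om[0, 1] / np.sqrt(Om[0, 0] * Om[1, 1])
            assert P[j, k] == pytest.approx(oracle, abs=1e-10)


def test_partial_corr_rejects_unit_loading():
    R = np.eye(2)
    with pytest.raises(ValueError):
        partial_corr_matrix(R, np.array([1.0, 0.5]), level=1)


# ---------------------------------------------------------------------------
# implied correlation matrix of the Gaussian analogue
# ---------------------------------------------------------------------------

def _tau(th):
    return 2 / np.pi * np.arcsin(th)


def test_implied_corr_factor_formula():
    cp = Cutpoints.equal_categories(2, 3)
    m = FactorTreeSpec.from_taus(cp, family1="bvn", tau1=[_tau(0.8), _tau(0.6)])
    R = implied_correlation_matrix(m)
    assert R[0, 1] == pytest.approx(0.48)


def test_implied_corr_path_product():
    """Non-adjacent pair, path 1-2-3 with deltas 0.5, 0.4: conditional
    correlation 0.20 before the back-transform."""
    cp = Cutpoints.equal_categories(3, 3)
    th1 = np.array([0.7, 0.6, 0.5])
    tree = VineTree(3, ((0, 1), (1, 2)))
    m = FactorTreeSpec.from_taus(
        cp, family1="bvn", tau1=[_tau(t) for t in th1],
        vine=tree, vine_family="bvn", vine_tau=[_tau(0.5), _tau(0.4)],
    )
    R = implied_correlation_matrix(m)
    cond = 0.5 * 0.4
    expect = th1[0] * th1[2] + cond * np.sqrt((1 - th1[0] ** 2) * (1 - th1[2] ** 2))
    assert R[0, 2] == pytest.approx(expect, abs=1e-12)


def test_implied_corr_matches_simulation():
    cp = Cutpoints.equal_categories(4, 5)
    tree = VineTree(4, ((0, 1), (1, 2), (2, 3)))
    m = FactorTreeSpec.from_taus(
        cp, family1="bvn", tau1=[_tau(t) for t in (0.7, 0.6, 0.5, 0.4)],
        vine=tree, vine_family="bvn", vine_tau=[_tau(t) for t in (0.5, 0.4, 0.3)],
    )
    data = simulate(m, 30_000, seed=7)
    assert np.abs(implied_correlation_matrix(m) - polychoric_matrix(data)).max() < 0.03


def test_implied_corr_requires_bvn(small_tree_model):
    with pytest.raises(ValueError, match="BVN"):
        implied_correlation_matrix(small_tree_model)


# ---------------------------------------------------------------------------
# discrepancy measures
# ---------------------------------------------------------------------------

def test_discrepancies_zero_at_equality(rng):
    A = rng.uniform(-0.3, 0.3, size=(4, 4))
    R = (A + A.T) / 2 + np.eye(4) * 2
    D = np.sqrt(np.diag(R))
    R = R / np.outer(D, D)
    assert discrepancies(R, R) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)
    assert discrepancies(np.eye(3), np.eye(3)) == (0.0, 0.0, 0.0)


def test_d3_positive_for_distinct_pd_matrices():
    R1 = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1.0]])
    R2 = np.eye(3)
    d1, d2, d3 = discrepancies(R1, R2)
    assert d1 == pytest.approx(0.5) and d2 == pytest.approx((0.5 + 0.2 + 0.3) / 3)
    assert d3 > 0
    with pytest.raises(np.linalg.LinAlgError):
        discrepancies(np.ones((2, 2)), np.eye(2))


# ---------------------------------------------------------------------------
# Vuong intervals
# ---------------------------------------------------------------------------

def test_vuong_identical_models_centred_on_dim_penalty():
    p = np.full(50, 0.01)
    vi = vuong_interval(p, p, dim1=3, dim2=5)
    assert vi.dbar == 0.0 and vi.s == 0.0
    assert vi.ci_low == pytest.approx(-(5 - 3) / 50)
    assert vi.ci_high == pytest.approx(-(5 - 3) / 50)


def test_vuong_hand_computed():
    D = np.array([0.1, -0.1, 0.3, -0.3])
    vi = vuong_interval(np.ones(4), np.exp(D), dim1=2, dim2=2)
    s = np.std(D, ddof=1)
    assert vi.s == pytest.approx(s)
    assert vi.ci_low == pytest.approx(-1.96 * s / 2)
    assert vi.ci_high == pytest.approx(+1.96 * s / 2)
    assert vi.favors == 0
    with pytest.raises(ValueError, match="row"):
        vuong_interval(np.array([0.1, 0.0]), np.array([0.1, 0.1]), 1, 1)


# ---------------------------------------------------------------------------
# structure recovery and family selection
# ---------------------------------------------------------------------------

def test_partial_algorithm_recovers_dvine_edges():
    """On 1-factor tree data with a D-vine residual structure, the partial
    correlation algorithm recovers the true edges far above the chance
    rate (a random spanning tree contains a given edge with probability
    2/d = 0.25 at d=8), and the strongest edge almost always."""
    _, truth = generate_fixture("table1-d8", seed=0, n=2)
    edges = truth.vine.edges
    reps, hits, strongest = 8, 0, 0
    for r in range(reps):
        data = simulate(truth, 500, seed=300 + r)
        R = polychoric_matrix(data)
        from factortree import FactorTreeCopulaModel
        og = FactorTreeCopulaModel(data, n_factors=1, families="bvn").fit(compute_se=False)
        th1 = np.sin(np.pi * og.tau / 2.0)
        W = partial_corr_matrix(R, th1, level=1)
        tree = max_spanning_tree(W)
        hits += sum(e in tree.edges for e in edges)
        strongest += edges[0] in tree.edges
    assert hits >= 0.65 * reps * len(edges)
    assert strongest >= 0.75 * reps


def test_select_families_recovers_gumbel_factor():
    cp = Cutpoints.equal_categories(6, 5)
    truth = FactorTreeSpec.from_taus(cp, family1="gumbel",
                                     tau1=np.linspace(0.65, 0.4, 6))
    data = simulate(truth, 600, seed=21)
    sel = select_families(data, p=1, factor_candidates=("bvn", "gumbel", "sgumbel"),
                          vine_candidates=())
    assert sel.families == ("gumbel",)
    assert (sel.trace.loglik[sel.trace.selected].max()
            == sel.trace.loglik.max())


def test_select_families_full_pipeline_runs():
    data, truth = generate_fixture("table1-d8", seed=33)
    sel = select_families(
        data, p=1, tree_algorithm="partial",
        factor_candidates=("bvn", "gumbel"),
        vine_candidates=("bvn", "gumbel", "frank"),
    )
    assert sel.tree is not None and sel.tree.n_edges == 7
    assert sel.results.n_params == 15
    assert set(sel.trace.stage) == {"factor1", "vine"}
    # each stage's winner maximizes that stage's log-likelihood
    for stage in ("factor1", "vine"):
        sub = sel.trace[sel.trace.stage == stage]
        assert sub.loglik[sub.selected].iloc[0] == sub.loglik.max()
    # the vine-stage winner never falls below the factor-only incumbent
    f_best = sel.trace[sel.trace.stage == "factor1"].loglik.max()
    v_best = sel.trace[sel.trace.stage == "vine"].loglik.max()
    assert v_best >= f_best - 1e-6


def test_select_families_bvn_only_candidates():
    data, _ = generate_fixture("table1-d8", seed=12, n=300)
    sel = select_families(data, p=1, factor_candidates=("bvn",),
                          vine_candidates=("bvn",), tree_algorithm="polychoric")
    assert sel.families == ("bvn", "bvn")
    assert sel.results.spec.all_bvn()


def test_allow_no_vine_prefers_factor_model_when_no_residual_dependence():
    cp = Cutpoints.equal_categories(5, 4)
    truth = FactorTreeSpec.from_taus(cp, family1="bvn",
                                     tau1=[_tau(t) for t in (0.7, 0.6, 0.6, 0.5, 0.5)])
    data = simulate(truth, 700, seed=9)
    sel = select_families(data, p=1, factor_candidates=("bvn",),
                          vine_candidates=("bvn", "frank"), allow_no_vine=True,
                          tree_algorithm="polychoric")
    # with no residual dependence the d-1 extra parameters cost more AIC
    # than the vine's likelihood gain in most samples
    if sel.tree is None:
        assert sel.results.n_params == 5
    else:  # AIC may still favor the vine by chance; the trace must show both
        assert {"factor1", "vine"} <= set(sel.trace.stage)
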