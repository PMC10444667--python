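# Methods

## Model

Let Y₁,…,Y_d be ordinal items, Y_j ∈ {0,…,K_j−1}, with uniform-scale
cutpoints a_{j,0}=0 < a_{j,1} ≤ … < a_{j,K_j}=1 (normal-scale images
α_{j,k} = Φ⁻¹(a_{j,k})).  The latent factors X₁, X₂ are independent U(0,1).
Three nested model classes are implemented:

* **p-factor copula model** (p = 1, 2): items conditionally independent
  given the factors.  The conditional cdf of item j given X₁ = x is the
  h-function C_{j|X₁}(a_{j,y+1}|x) = ∂C_{X₁j}(x, a_{j,y+1})/∂x; for p = 2 a
  second h-function in C_{X₂j} is applied to it.  Equivalent to a C-vine
  rooted at the factors, truncated after tree p.
* **Markov tree (1-truncated vine)**: spanning tree ℰ over the items; the
  pmf is the product of margins times, per edge, the ratio of the
  bivariate rectangle probability to the product of margins.  Closed form,
  no integration.
* **Factor tree models**: both parts combined; the Markov tree is placed
  on the *conditional* distributions given the factors, with the standard
  simplifying assumption that the conditional copulas do not depend on the
  conditioning value.  The pmf is a 1- or 2-dimensional integral of the
  tree-structured conditional pmf over the factors.

Parameter identification notes baked into the code: the two-factor all-BVN
model (bidimensional normal ogive) fixes the last item's second-factor
parameter at 0 (2d−1 free parameters); for non-BVN families all 2d factor
parameters are free; the sign of a whole factor column is not identified
for symmetric families (reversing the latent orientation leaves the model
invariant), and the 2-factor tree model is only weakly identified for
small d — the tests use d = 8 for 2-factor recovery.

## Numerical evaluation

The latent factors are integrated by Gauss–Legendre quadrature mapped to
(0,1), n_q = 25 nodes per dimension by default.  All quantities entering a
likelihood are precomputed as tables over the quadrature grid: per item
the conditional cdf at every cutpoint (K_j+1 × n_q, or × n_q² for p=2),
per edge the rectangle probabilities of the edge copula applied to those
tables.  A likelihood evaluation then reduces to table gathers, which
keeps IFM fits at n = 500, d = 8 below a second.

Measured quadrature accuracy (d=3, all outcomes): |pmf(n_q=25) −
pmf(n_q=50)| < 5·10⁻⁵, with the worst error at outcome-space corner
cells, where the conditional cdfs develop endpoint boundary layers in the
latent variable (convergence in n_q is algebraic there, ~n_q^−2.4, not
spectral); the total mass over all K^d outcomes is 1 within 10⁻⁶ because
signed quadrature errors cancel in the sum.

Copula numerics: u, v arguments are clipped to [10⁻¹⁰, 1−10⁻¹⁰] before
transcendental transforms (boundary cutpoints 0 and 1 legitimately enter
h-functions; the exact boundary values are restored afterwards).  The BVN
cdf uses the Owen's-T identity (vectorized, ~10⁻¹⁵ absolute error).  The
bivariate t cdf is computed by conditioning on the first coordinate with
the substitution x = √ν·tan φ, giving a smooth bounded integrand that a
24-node Gauss–Legendre rule resolves to ~10⁻⁷ (ν = 2, the hardest case) or
better; ν is always taken from the fixed grid {2, 3, 5, 7} and is never a
free parameter.  Gumbel quantities are computed in log space so that large
θ cannot overflow.  Rectangle probabilities are clipped at 0 (floating
cancellation), ratio denominators floored at 10⁻³⁰, and pmfs floored at
10⁻³⁰⁰ before logs.

## Estimation (two-step IFM)

Step 1 estimates cutpoints as cumulative univariate sample proportions;
items with unobserved categories are compacted (relabeled densely, logged)
because the Markov-tree pmf divides by marginal category probabilities.
Step 2 maximizes the joint log-likelihood over the dependence parameters
with cutpoints fixed, by L-BFGS-B on unconstrained transforms — atanh θ
for BVN/t, log(θ−1) for Gumbel/survival Gumbel, a scaled identity for
Frank — with start values τ = 0.3 on factor trees and τ = 0.1 on vine
edges (mid-range, matching the typical decay of dependence across trees),
gradient tolerance 10⁻⁵, at most 500 iterations.  Non-convergence flags
the result rather than raising.

Standard errors are square roots of the diagonal of the inverse numerical
(central-difference) Hessian of −ℓ parameterized directly on the Kendall-τ
scale, so no delta-method step is needed.  They ignore step-1 cutpoint
uncertainty and are labeled approximate in the output.  AIC = −2ℓ + 2m
counts only dependence parameters: d for one factor, 2d−1 (all-BVN) or 2d
for two factors, plus d−1 when a residual tree is present.

## Model selection

Residual-tree structure: pairwise weights log(1−r²) are minimized over
spanning trees by Prim's algorithm (ties broken by lexicographically
smallest pair for determinism), with r either the polychoric correlation
(two-stage ML: cutpoints fixed, scalar bounded search on atanh ρ) or the
partial correlation of the underlying normals given the factors of a
fitted normal-ogive model.

Families are selected sequentially, one family per tree (families are
never mixed within a tree): starting from BVN factor links and an
independence residual tree, each stage refits the model under every
candidate family for the current tree — {bvn, t2, t3, t5, t7, gumbel,
sgumbel} for the factor trees, the same set plus frank for the residual
tree — and keeps the log-likelihood maximizer.  The residual tree is
always adopted after the factor stages; the factor-only model competes by
AIC only when `allow_no_vine` is requested.

Diagnostics: empirical semi-correlations dichotomize each item at the
interior cutpoint nearest zero on the normal scale and recompute the
polychoric correlation on the joint-lower / joint-upper sub-sample with
cutpoints re-estimated from the sub-sample (pairs with degenerate
quadrant sub-tables are skipped with a warning and excluded from the
average).  This sample convention estimates the quadrant-conditional
normal-scores correlation, whose theoretical counterpart the copula module
computes by tensor Gauss–Legendre integration of the normal-scores density
over the quadrant (120² nodes, ~10⁻⁶ accuracy).  D₃ uses log-determinants
and a linear solve rather than explicit inverses.  The Vuong interval uses
σ = s, the (n−1)-denominator standard deviation of the per-row
log-likelihood ratios, with the AIC dimension adjustment.

## Simulation

Sampling is exact: per row the factors are drawn uniformly; the
lowest-index item (tree root) is drawn from its conditional pmf given the
factors by inverse cdf; remaining items follow in breadth-first order,
each drawn from its conditional pmf given its already-drawn tree neighbor
and the latent point.  Any traversal order over a Markov tree yields the
same law; breadth-first from the lowest index is fixed for
reproducibility.  A chi-square goodness-of-fit check of simulated
frequencies against the enumerated pmf (d=3, 27 cells, n=1.5·10⁵) is part
of the test suite for all three model classes.

The study harness spawns one substream per replicate from a master seed
(replicate-level reproducibility), refits by IFM, drops and counts
non-convergent replicates, and reports n·bias, n·SD (reps−1 denominator)
and n·RMSE per parameter on the τ scale.

## What the synthetic generators emulate — and what they do not

The named fixtures reproduce the simulation designs used throughout:
equally weighted K=5 categories, Gumbel links with equally spaced τ grids
(factor 0.70→0.40, second factor 0.55→0.25, residual tree 0.40→0.10), and
D-vine (serial) residual structure.  The `ptsd-like` generator is a
synthetic stand-in for a 20-item PTSD checklist (n=221): a 2-factor tree
model with t₂ / Gumbel / t₅ trees whose τ values follow the fitted
application model, producing the real data's signature excess dependence
in the joint upper tail.  It does not reproduce the real data's skewed
category frequencies (it uses equal cutpoints), its exact correlation
matrix, or sampling artefacts such as respondent heterogeneity; passing
tests on these fixtures demonstrate internal correctness and recovery
under the model, not fit to any real dataset.

## Problem sizes used by the test suite and acceptance script

Replicated studies are scaled to desk size as the package's own choice:
the dispersion study runs 100 replicates in the test suite (60 in the
acceptance script) of n=500, d=8; the family-selection frequency runs 50
(30) replicates; 2-factor recovery is checked on a single d=8 replicate
at n=1500.  The application-scale 2-factor tree fit with t-family
residual copulas (d=20, 59 parameters) takes hours of CPU and is exercised
only when the external PTSD dataset is supplied.

## Known limitations

* Only 1-truncated residual structure (a tree) and at most two factors.
* One copula family per tree; per-item family mixing is out of scope.
* IFM standard errors ignore cutpoint estimation (no Godambe sandwich).
* Near independence the individual factor loadings are weakly identified
  (only their products are); selection between reflection-symmetric t
  families with close ν is inherently unstable in small samples.
* The literature's semi-correlation reference table mixes calibration
  conventions across families; this package computes one principled
  quantity (quadrant-conditional normal-scores correlation under exact
  ρ_N calibration) throughout.
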