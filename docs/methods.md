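# Methods

This note documents the models, algorithms, and numerical conventions in
`islandrad`, including the choices made where several defensible options
existed, and what the synthetic-data tests do and do not establish about
real data.

## Data model

Trees are rooted, strictly bifurcating, and ultrametric, with branch
lengths in Myr and ages measured backward from the present (tips at age 0).
Ultrametricity is enforced at a relative tolerance of 1e-6 of tree height;
deviant trees are rejected loudly (no silent smoothing), with the error
naming the tip most deviant from the median tip depth.  Polytomies and
zero-length branches are rejected: every likelihood below assumes a binary
tree.  Regime paintings (stochastic character maps) store per-branch
`(state, duration)` segments rootward-to-tipward; adjacent equal-state
segments are merged on ingest so paintings have a canonical, comparable
form.  The simmap-annotated Newick dialect (`taxon:{state,dur:state,dur}`)
round-trips losslessly and is read by phytools' `read.simmap` (verified in
the test suite).

## Birth-death diversification

### Likelihood

The single-regime likelihood is the Nee density of the ordered internal
node ages conditioned on the crown age and survival of both crown lineages.
Incomplete sampling enters analytically: each extant species appears in the
tree independently with probability ρ.  With r = λ − μ,

    p0(t) = 1 − ρ r / (ρλ + (λ(1−ρ) − μ) e^{−rt})
    p1(t) = ρ r² e^{−rt} / (ρλ + (λ(1−ρ) − μ) e^{−rt})²,

and for node ages x₁ ≥ x₂ ≥ … (crown first),

    lnL = ln (n−1)! + Σ_{i≥2} ln(λ p1(x_i)) + 2 ln p1(x₁) − 2 ln(1 − p0(x₁)).

The ordered-history factor (n−1)! is part of the convention; with μ = 0,
ρ = 1 the expression reduces exactly to the product of exponential
waiting-time densities between speciation events (k lineages wait at rate
kλ), which the tests verify both by hand on a 3-tip tree and against a
brute-force oracle on random trees.

### Clade-partitioned models

A partition assigns every tip to a named set (focal clades must be
monophyletic; the complement is the background).  Rates may be linked or
unlinked between sets.  The partitioned likelihood assigns each non-crown
speciation event the (λ, μ, ρ) of the set whose clade contains it, keeping
the crown terms under the background regime:

    lnL = ln (n−1)! + Σ_{i≥2} ln(λ_{r(i)} p1_{r(i)}(x_i))
          + 2 ln p1_bg(x₁) − 2 ln(1 − p0_bg(x₁)).

This convention was chosen over decomposing the tree into a crown-
conditioned clade subtree plus a collapsed background tree because (a) it
collapses *exactly* to the unpartitioned likelihood when all sets share one
rate pair — the subtree decomposition double-counts the clade crown-age
density and drops one λ factor, so the identity only holds approximately —
and (b) the per-node assignment is exact for every node whose descendant
lineages stay inside one regime, which covers all nodes of a focal clade;
only the handful of background nodes ancestral to a focal clade use an
approximate survival term.  The exact linked-case identity is asserted in
the tests at 1e-8.

### Inference

MCMC is Metropolis-Hastings on log-transformed rates with Gaussian steps in
log space (multiplicative proposals, sd 0.25), one coordinate per
iteration, under independent Exponential(mean 1 Myr⁻¹) priors on λ and μ
(weakly informative on the Myr timescales of the study systems; exposed in
`DiversificationModelSpec`).  Defaults mirror standard practice: 10⁶
iterations thinned to 10³ at full scale.  Convergence is monitored by the
acceptance rate and Geyer initial-positive-sequence effective sample sizes
(the ESS of a constant trace is reported as NaN, not infinity); the test
gate requires ESS > 200.

Marginal likelihoods use thermodynamic integration: K = 10 power-posterior
temperatures placed at Beta(0.3, 1) quantiles (dense near β = 0, where the
expected log-likelihood changes fastest), trapezoidal integration of the
mean log-likelihood over β, chains warm-started along the ladder.  The
trapezoid has a small negative bias when the integrand is strongly concave;
the quadrature cross-check in the tests uses a finer ladder (K = 14) to
meet its 0.05 tolerance, and K is configurable wherever it matters.

Bayes factors are reported as 2·ΔlnML and categorized on the Kass-Raftery
scale; Bayesian model averaging resamples each model's post-burn-in (10%)
trace with probability proportional to exp(lnML) under equal model priors
(log-sum-exp shifted, so spreads beyond 700 log units cannot overflow), and
summaries report the median and shortest (HPD) 95% interval of
r = λ − μ per partition set.

## Binary-character histories

The Mk machinery uses the closed-form two-state transition matrix
P(t) = Π + e^{−(q01+q10)t}(I − Π) (validated against `scipy.linalg.expm`),
Felsenstein pruning with per-node rescaling, and a uniform root prior by
default (configurable; the stationary prior is the natural alternative and
matters only when rates are strongly asymmetric).  ER fits use bounded 1-D
search in log rate; ARD fits use L-BFGS-B in 2-D with restarts; rates are
bounded in [1e-9, 1e3] per Myr and boundary fits are flagged.  The
ER-vs-ARD likelihood-ratio test uses χ²₁.

Stochastic character maps are sampled jointly: the root state from its
marginal posterior, each child given its parent from
P(s_p, s_c | branch) · L_c(s_c), then branch interiors from the
endpoint-conditioned chain by uniformization — the jump count from
P(N = n | a, b, t) ∝ Poisson(Λt)(n) (R^n)_{ab} with Λ = max |q_ii| and
R = I + Q/Λ, the conditioned jump chain sequentially, jump times as uniform
order statistics, and virtual (self) jumps removed.  This is exact for any
q·t; the tests verify single-branch conditional change counts against the
uniformization series expectation and node-state frequencies against the
up-down marginals over 10⁴ maps.  Rates are fixed at their ML estimates
when sampling maps (the "empirical" treatment); the pipeline runs the
module twice — 1000 maps for the life-history character, 100 maps for
island occupancy (the regime trees for the continuous models).

## Continuous-trait models on painted trees

Six models, in OUwie-style naming: BM1, BMS (per-regime rate), OU1, OUM
(per-regime optimum θ), OUMA (per-regime θ and pull α), OUMV (per-regime θ
and rate σ²).  Free-parameter counts: 2, 1+R, 3, 2+R, 1+2R, 1+2R for R
regimes.

All six reduce to one integral representation.  Let A(v) be the pull
accumulated from the root to point v (Σ α·duration along the path) and
I(v) = ∫₀^{s_v} σ²(s) e^{2A(s)} ds accumulated along the root-to-v path.
Then

    Cov(i, j) = e^{−A(i) − A(j)} · I(mrca(i, j)),

with BM the α = 0 case.  I(v) is accumulated per segment in closed form in
log space, so α up to the 10³ bound cannot overflow.  Tip means are
θ-weighted sums with weights that telescope along each path and, together
with the root weight, sum to one.

The root is anchored at the root-regime optimum for OU models (no free root
state), while BM models estimate the root value x₀ as the GLS mean — a
common convention in the tools of this field; the covariance parameters are
optimized by L-BFGS-B in log space (α ∈ [1e-9, 1e3] Myr⁻¹,
σ² ∈ [1e-9, 1e4]) with 5 jittered restarts by default, and θ (or x₀) is
profiled out exactly by generalized least squares at each candidate — the
search is never more than 2R-dimensional.  Weight-matrix rank deficiencies
(e.g. a regime with vanishing pull) are handled by least-squares rather
than a hard inverse.

Model screening follows two rules.  (1) Hessian screen: the
finite-difference Hessian of −lnL over the full parameter vector must be
positive definite; eigenvalues below 1e-8 of the largest magnitude count as
failures, because a pull parameter collapsing to its lower bound leaves the
optimum direction numerically flat and the profiled θ arbitrarily large
(observed: θ estimates of order 10⁷ from such fits before screening).
(2) Failed-model screen: a fit whose lnL exceeds the median across the six
models by more than 100 natural-log units (configurable `failure_margin`,
operationalizing "orders of magnitude") is excluded as spurious.

AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); Akaike weights over retained fits.
Parameter averaging is per regime; a parameter absent from a model (α, θ in
BM) is averaged over the models that define it with weights renormalized.
Within-map averages are pooled across the 100 occupancy maps as a mean plus
the per-map distribution.  Parametric-bootstrap CIs simulate from the
fitted model on the same painted tree (exact multivariate-normal draws, no
Euler discretization), refit warm-started at the estimates, and take
2.5/97.5 percentiles; a CI is flagged unreliable when more than 20% of
refits fail.

## Trait-space saturation

For all unordered tip pairs, relative phylogenetic distance
x = d_cophenetic / max whole-tree distance and relative disparity
y = |Δ log height| / max whole-tree disparity.  The saturation curve is the
running maximum of y over pairs ordered by x, stored at the breakpoints
where the maximum rises (plus the terminal pair, making the support
explicit); it is a right-continuous step function, 0 left of its first
breakpoint.  Nested (island/nonisland) curves use within-set pairs only but
whole-tree normalizers, so both live in the same 0-1 space.  Jackknife
envelopes re-prune 10% of taxa from the whole tree (sets recomputed after
pruning; draws leaving a set under 3 taxa are redrawn) and report pointwise
2.5/97.5 percentiles on a common grid.

Congruence: D_max is the two-sample KS distance between the two curves'
values at 100 evenly spaced points over the intersection of their supports.
The p-value deliberately does **not** treat those 100 grid values as
independent samples — a step curve with a dozen jumps carries roughly a
dozen observations, and the naive calibration rejects even exchangeable
random splits of one clade essentially always.  Instead the asymptotic
two-sample formula is evaluated with effective sample sizes equal to each
curve's breakpoint count inside the shared support.  Measured behaviour
with this calibration: rejection in 4/20 exchangeable random splits, 6/20
fully homogeneous nested scenarios, and 17/20 scenarios with the island
trait rate doubled.

One property of the construction deserves emphasis: when the island clade
diversifies much faster than the background, the curves differ even at
equal trait rates, because the young, dense island clade concentrates all
its pairs at small relative distances and a running maximum over many pairs
sits higher than one over few.  Early island saturation is therefore
evidence of rapid trait-space filling *per unit relative divergence*, which
conflates rate and density effects; the congruence test's null is curve
identity, not equal σ².  Size calibration accordingly uses scenarios
homogeneous in both λ and σ².

Trajectory classification fits y = a + bx, y = a(e^{bx} − 1), and
y = a ln(1 + bx) by least squares and labels the curve by the best RMSE —
except that "linear" is retained whenever its RMSE is within 1.2× the best
family's, because a running maximum is mildly concave even under Brownian
truth and the two-parameter logarithmic family nests near-linear shapes;
without the margin essentially every curve is labelled logarithmic.

## Synthetic data

`simulate_bd_tree` conditions on the tip count with the generalized
sampling approach: run the process well past n (to a cap of 3n lineages),
record the lineage-count trajectory, and cut at a time drawn uniformly from
the total time spent with exactly n extant lineages; extinct lineages are
then pruned.  Stopping at the n-th birth instead would bias the pendant
branch lengths.  Trait values are exact multivariate-normal draws via the
Cholesky factor of the model covariance — the same code path later used by
the parametric bootstrap — so simulator and likelihood share one analytic
core and their agreement is checked as a cross-module moment test.

The default scenario mirrors the empirical contrast the pipeline targets:
background λ = 0.2, island λ = 1.4 per Myr (pure birth), 30 + 60 tips, full
sampling, island occupancy switching half-way along the island stem,
woodiness following occupancy with background Mk noise at 0.01 per Myr
(yielding occasional extra woody origins and reversals, as real radiations
show), and log heights under Brownian motion with σ² = 1 (background) vs 2
(island) in (log_e cm)² per Myr around a root of 3 log_e cm (~20 cm).  All
generators consume a single integer master seed; composite scenarios derive
per-stage streams with fixed offsets, so each stage is independently
reproducible.

What the synthetic tests establish: internal correctness (likelihoods
against enumeration/closed forms/independent R implementations), estimator
consistency, calibration of the tests, and end-to-end recovery of the
generating regime differences.  What they do not establish: robustness to
the features real datasets add — divergence-time uncertainty, non-constant
rates through time, trait measurement error, state-dependent
diversification, or misassigned regimes.  The binary island/nonisland
painting also ignores within-branch uncertainty about *where* occupancy
changed except insofar as the 100 sampled maps vary.

## Scale and runtime conventions

Full-scale settings (10⁶ MCMC generations, 1000 life-history maps, 1000
jackknife rounds, 200 bootstrap replicates) are the `PipelineSettings`
defaults, reduced by a single `scale` factor (default 0.1) for desk-scale
runs; the acceptance script runs at scale 0.1 on the 90-tip default
scenario.  Simulation-based tests use reduced replicate counts with
tolerance bands widened by the corresponding binomial or √n factors, chosen
when the tests were written; the full-size checks (10⁴ stochastic maps,
200-simulation LRT calibration, 200-tip model selection) run once per test
session and are shared between the unit and acceptance suites.
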