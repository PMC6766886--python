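# islandrad

Comparative phylogenetics of island plant radiations: do clades that
dispersed to (oceanic or sky) islands and evolved secondary woodiness
diversify faster, disparify their growth forms faster, and occupy more
trait space than their non-island relatives?

`islandrad` implements the full analysis pipeline for that question as a
reusable, tested Python library, together with a synthetic-data generator
that reproduces the statistical structure of such study systems — so every
stage can be exercised and validated without any external data download.

## What it computes

Given an ultrametric time tree (Newick, branch lengths in Myr), a per-tip
trait table (binary life history herbaceous/woody, binary island/nonisland
occupancy, continuous mean plant height in log_e cm), and a clade partition
with per-clade sampling fractions ρ:

1. **Species diversification** (`islandrad.diversification`).
   Crown-conditioned Nee birth–death likelihoods with analytic ρ-sampling;
   clade-partitioned models that link or unlink (λ, μ) between island and
   background; MCMC under exponential priors; log marginal likelihoods by
   thermodynamic integration over power posteriors; Bayes factors
   BF = 2·ΔlnML on the Kass–Raftery scale (<2 negligible, 2–6 positive,
   6–10 strong, >10 very strong); Bayesian model averaging of net
   diversification r = λ − μ with 95% HPD intervals.
2. **Origins of secondary woodiness** (`islandrad.ancestral`).
   Binary Mk models (ER/ARD) by Felsenstein pruning, likelihood-ratio test,
   marginal ancestral states by the up-down algorithm, stochastic character
   maps (joint node sampling + endpoint-conditioned uniformization bridges),
   and per-direction transition counts with 95% credible intervals.
3. **Mode and rate of disparification** (`islandrad.traitmodels`).
   Six models of log plant-height evolution on regime-painted trees —
   BM1, BMS, OU1, OUM, OUMA, OUMV (single/multi-rate Brownian motion;
   single/multi-optimum Ornstein–Uhlenbeck with regime-specific optimum θ,
   pull α, or rate σ²) — with exact mean/covariance integration along the
   painted branches, GLS-profiled optima, Hessian eigenvalue screening,
   failed-model exclusion, AICc weights w = e^(−Δ/2)/Σe^(−Δ/2), parameter
   averaging across models and across 100 stochastic occupancy maps, and
   parametric-bootstrap confidence intervals.
4. **Trait-space saturation** (`islandrad.saturation`).
   Nested saturation curves (running maximum of relative pairwise disparity
   against relative cophenetic distance, normalized by whole-tree maxima),
   jackknife 95% envelopes (random pruning of 10% of taxa), curve
   congruence by a Kolmogorov–Smirnov test calibrated on the curves'
   information content, and linear/exponential/logarithmic trajectory
   classification.

`islandrad.simulate` provides the generator: birth–death trees conditioned
on tip count (generalized sampling algorithm), a nested island clade grafted
with its own rates, exact Gillespie Mk histories, and trait draws from the
exact multivariate normal each model implies.

## Worked example

```python
from islandrad import simulate as sim, diversification as dv

data = sim.make_scenario(sim.ScenarioSpec(seed=1))   # 90 tips, 60 on-island
models = {"linked": dv.DiversificationModelSpec.linked(data.partition),
          "unlinked": dv.DiversificationModelSpec.unlinked(data.partition)}
traces, lnmls = {}, {}
for i, (name, spec) in enumerate(models.items()):
    traces[name] = dv.mcmc_sample(data.tree, data.partition, spec,
                                  iterations=50_000, thin=50, seed=i)
    lnmls[name] = dv.marginal_likelihood(data.tree, data.partition, spec,
                                         iterations=10_000, thin=10, seed=100 + i)
comp = dv.bayes_factor_classify(lnmls["unlinked"], lnmls["linked"])
bma = dv.bma_combine(traces, lnmls, data.partition, seed=7)
```

prints (via `examples/02_diversification.py`):

```
2lnBF = 69.3 -> very strong support for unlinked rates
island      r = 1.38 (1.06-1.81) per Myr
background  r = 0.22 (0.15-0.29) per Myr
```

The Bayes factor decisively favours separate island/background rates, and
the model-averaged net diversification of the island clade (median with 95%
HPD in brackets) sits an order of magnitude above the background — the
island-radiation signature the scenario was generated with (λ_isl = 1.4,
λ_bg = 0.2 per Myr).

The other capabilities have matching narrative scripts in `examples/`
(scenario construction, stochastic mapping of woodiness origins, six-model
trait analysis, saturation curves).  `islandrad.pipeline.run_pipeline`
chains all four stages and writes summary tables, JSON reports, and
density/saturation plots; a thin CLI (`islandrad simulate|all|...`) drives
it from a YAML config.

## Layout

```
src/islandrad/
  trees.py           time trees, simmap I/O, distances, pruning, partitions
  simulate.py        synthetic trees, Mk histories, exact trait draws
  diversification.py birth-death likelihoods, MCMC, TI, BF, BMA, ESS, HPD
  ancestral.py       Mk fitting, LRT, ancestral states, stochastic maps
  traitmodels.py     six BM/OU models, screening, AICc averaging, bootstrap
  saturation.py      saturation curves, jackknife, KS congruence
  pipeline.py, cli.py  orchestration and the thin command-line front end
docs/methods.md      model and algorithm documentation, design choices
examples/            one narrative script per capability
tests/               pytest suite incl. acceptance and R cross-validation
```
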