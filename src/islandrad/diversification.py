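"""Clade-partitioned birth-death diversification inference.

The likelihood is the Nee-style density of the ordered internal-node ages of
an ultrametric tree under a constant-rate birth-death process, conditioned on
the crown age and the survival of both crown lineages, with incomplete
sampling folded in analytically: each extant lineage is included in the tree
independently with probability rho.  Writing r = lambda - mu,

    p0(t) = 1 - rho r / (rho lambda + (lambda (1 - rho) - mu) e^{-r t})
    p1(t) = rho r^2 e^{-r t} / (rho lambda + (lambda (1 - rho) - mu) e^{-r t})^2

(the probabilities that a lineage alive t Myr ago leaves zero, respectively
exactly one, sampled descendant), and the log-likelihood of a tree with
internal-node ages x_1 >= x_2 >= ... (crown first) is

    lnL = ln (n-1)! + sum_{i>=2} ln(lambda p1(x_i))
          + 2 ln p1(x_1) - 2 ln(1 - p0(x_1)).

For mu = 0, rho = 1 this reduces to the product of exponential waiting-time
densities between speciation events (k lineages wait with rate k lambda),
which is the closed form used as the oracle in the tests.

Clade-partitioned models assign every non-crown speciation event the rates
of the partition set whose clade contains it; the crown terms use the
background rates.  When all sets share one rate pair the sum collapses
exactly to the unpartitioned likelihood, and the per-node assignment is
exact for every node whose descendant paths remain inside one regime (all
nodes of a focal clade).

Marginal likelihoods come from thermodynamic integration over power
posteriors; model comparison uses Bayes factors on the 2 ln scale with the
Kass-Raftery categories; Bayesian model averaging resamples each model's
posterior in proportion to its marginal likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import BACKGROUND, CladePartition, TimeTree

__all__ = [
    "DiversificationModelSpec",
    "McmcTrace",
    "ModelComparison",
    "bd_loglik",
    "partitioned_loglik",
    "mcmc_sample",
    "marginal_likelihood",
    "bayes_factor_classify",
    "bma_combine",
    "hpd_interval",
    "ess",
]


def _p0_p1_log(t: np.ndarray, lam: float, mu: float, rho: float):
    """(p0(t), log p1(t)) for the rho-sampled birth-death process."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < 1e-12:  # critical case, lambda == mu
        denom = 1.0 + rho * lam * t
        p0 = 1.0 - rho / denom
        logp1 = math.log(rho) - 2.0 * np.log(denom)
        return p0, logp1
    ert = np.exp(-r * t)
    denom = rho * lam + (lam * (1.0 - rho) - mu) * ert
    p0 = 1.0 - rho * r / denom
    logp1 = math.log(rho) + 2.0 * math.log(abs(r)) - r * t - 2.0 * np.log(np.abs(denom))
    return p0, logp1


def bd_loglik(tree: TimeTree, lam: float, mu: float, rho: float = 1.0) -> float:
    """Crown-conditioned birth-death log-likelihood with sampling fraction."""
    if lam <= 0 or mu < 0:
        raise ValueError("need lambda > 0 and mu >= 0")
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must lie in (0, 1]")
    ages = tree.internal_node_ages()
    return _bd_loglik_ages(ages[0], ages[1:], tree.n_tips, lam, mu, rho)


def _bd_loglik_ages(crown_age, other_ages, n, lam, mu, rho) -> float:
    other_ages = np.asarray(other_ages, dtype=float)
    p0c, logp1c = _p0_p1_log(np.array([crown_age]), lam, mu, rho)
    if p0c[0] >= 1.0:
        return -math.inf
    lnl = math.lgamma(n) + 2.0 * float(logp1c[0]) - 2.0 * math.log1p(-float(p0c[0]))
    if other_ages.size:
        _, logp1 = _p0_p1_log(other_ages, lam, mu, rho)
        lnl += other_ages.size * math.log(lam) + float(np.sum(logp1))
    return lnl


@dataclass
class DiversificationModelSpec:
    """A linked/unlinked rate model over a clade partition.

    ``linkage`` maps each partition set name to a rate-pair id; sets sharing
    an id share (lambda, mu).  ``process`` is "pure-birth" (mu fixed at 0) or
    "birth-death".  Priors are independent exponentials on lambda and mu.
    """

    process: str = "pure-birth"
    linkage: dict[str, int] = field(default_factory=dict)
    prior_mean_lambda: float = 1.0
    prior_mean_mu: float = 1.0

    def __post_init__(self):
        if self.process not in ("pure-birth", "birth-death"):
            raise ValueError("process must be 'pure-birth' or 'birth-death'")

    def pair_ids(self) -> list[int]:
        return sorted(set(self.linkage.values()))

    @property
    def estimates_mu(self) -> bool:
        return self.process == "birth-death"

    def n_params(self) -> int:
        return len(self.pair_ids()) * (2 if self.estimates_mu else 1)

    @classmethod
    def linked(cls, partition: CladePartition, process="pure-birth", **kw):
        return cls(process=process, linkage={n: 0 for n in partition.names}, **kw)

    @classmethod
    def unlinked(cls, partition: CladePartition, process="pure-birth", **kw):
        return cls(process=process,
                   linkage={n: i for i, n in enumerate(partition.names)}, **kw)


class _PartitionedLikelihood:
    """Pre-indexed per-node regime assignment for fast repeated evaluation."""

    def __init__(self, tree: TimeTree, partition: CladePartition,
                 spec: DiversificationModelSpec):
        partition.validate_against(tree)
        self.n = tree.n_tips
        self.spec = spec
        pair_ids = spec.pair_ids()
        self.pair_pos = {pid: i for i, pid in enumerate(pair_ids)}
        self.n_pairs = len(pair_ids)
        self.rho = {name: partition.rho[name] for name in partition.names}
        # assign each internal node to a partition set: a node belongs to a
        # focal clade iff it descends from (or is) that clade's crown node
        node_set: dict[int, str] = {}
        clade_nodes: dict[str, set[int]] = {}
        for name in partition.focal_clades():
            crown = tree.mrca(partition.sets[name])
            members = set()
            stack = [crown]
            while stack:
                v = stack.pop()
                members.add(v.index)
                stack.extend(v.children)
            clade_nodes[name] = members
        internal = [v for v in tree.postorder if v.children and v is not tree.root]
        self.crown_age = tree.crown_age()
        self.crown_set = BACKGROUND if BACKGROUND in partition.sets else partition.names[0]
        ages, sets = [], []
        for v in internal:
            name = self.crown_set
            for cname, members in clade_nodes.items():
                if v.index in members:
                    name = cname
                    break
            ages.append(tree.age(v))
            sets.append(name)
        self.node_ages = np.asarray(ages)
        self.node_sets = sets
        # group node ages by (pair id, rho) for vectorized evaluation
        self.groups: list[tuple[int, float, np.ndarray]] = []
        keys = {}
        for age, name in zip(self.node_ages, self.node_sets):
            key = (spec.linkage[name], self.rho[name])
            keys.setdefault(key, []).append(age)
        for (pid, rho), a in sorted(keys.items()):
            self.groups.append((self.pair_pos[pid], rho, np.asarray(a)))
        self.crown_pair = self.pair_pos[spec.linkage[self.crown_set]]
        self.crown_rho = self.rho[self.crown_set]

    def loglik(self, lams: np.ndarray, mus: np.ndarray) -> float:
        """lams/mus indexed by pair position."""
        if np.any(lams <= 0) or np.any(mus < 0):
            return -math.inf
        lam_c, mu_c = lams[self.crown_pair], mus[self.crown_pair]
        p0c, logp1c = _p0_p1_log(np.array([self.crown_age]), lam_c, mu_c,
                                 self.crown_rho)
        if not np.isfinite(logp1c).all() or p0c[0] >= 1.0:
            return -math.inf
        lnl = (math.lgamma(self.n) + 2.0 * float(logp1c[0])
               - 2.0 * math.log1p(-float(p0c[0])))
        for pos, rho, ages in self.groups:
            _, logp1 = _p0_p1_log(ages, lams[pos], mus[pos], rho)
            if not np.isfinite(logp1).all():
                return -math.inf
            lnl += ages.size * math.log(lams[pos]) + float(np.sum(logp1))
        return lnl


def partitioned_loglik(tree: TimeTree, partition: CladePartition,
                       spec: DiversificationModelSpec, params: dict) -> float:
    """Log-likelihood of a linked/unlinked model.

    ``params`` maps pair id -> (lambda, mu); pure-birth models ignore mu
    entries (fixed 0).
    """
    pl = _PartitionedLikelihood(tree, partition, spec)
    lams = np.zeros(pl.n_pairs)
    mus = np.zeros(pl.n_pairs)
    for pid, pos in pl.pair_pos.items():
        val = params[pid]
        lam, mu = (val if isinstance(val, (tuple, list)) else (val, 0.0))
        lams[pos] = lam
        mus[pos] = 0.0 if not spec.estimates_mu else mu
    return pl.loglik(lams, mus)


# -- MCMC ------------------------------------------------------------------------


@dataclass
class McmcTrace:
    """Thinned posterior sample for one model."""

    samples: pd.DataFrame  # columns: iteration, lambda_<pid>, [mu_<pid>], lnl, lnprior
    acceptance_rate: float
    spec: DiversificationModelSpec

    def column(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy()

    def post_burnin(self, burnin: float = 0.10) -> pd.DataFrame:
        cut = int(math.floor(burnin * len(self.samples)))
        return self.samples.iloc[cut:]


def mcmc_sample(tree: TimeTree, partition: CladePartition,
                spec: DiversificationModelSpec, iterations: int = 1_000_000,
                thin: int = 1000, seed: int = 0, beta: float = 1.0,
                proposal_sd: float = 0.25, init: dict | None = None) -> McmcTrace:
    """Metropolis-Hastings on log-transformed rates with multiplicative
    proposals; ``beta`` tempers the likelihood (power posterior), with
    beta = 0 sampling the prior."""
    if iterations < 10 * thin:
        raise ValueError("iterations must be at least 10 x thin")
    pl = _PartitionedLikelihood(tree, partition, spec)
    rng = np.random.default_rng(seed)
    npairs = pl.n_pairs
    est_mu = spec.estimates_mu
    k = npairs * (2 if est_mu else 1)
    # state: log rates [log lam_0.., log mu_0..]
    x = np.full(k, math.log(0.5))
    if init is not None:
        for pid, pos in pl.pair_pos.items():
            lam, mu = init[pid]
            x[pos] = math.log(lam)
            if est_mu:
                x[npairs + pos] = math.log(max(mu, 1e-8))

    def unpack(xv):
        lams = np.exp(xv[:npairs])
        mus = np.exp(xv[npairs:]) if est_mu else np.zeros(npairs)
        return lams, mus

    def log_prior(xv):
        # exponential priors on the natural-scale rates; the Jacobian of the
        # log transform adds +x per coordinate (sampling is in log space)
        lams, mus = unpack(xv)
        lp = float(-np.sum(lams) / spec.prior_mean_lambda
                   - npairs * math.log(spec.prior_mean_lambda)
                   + np.sum(xv[:npairs]))
        if est_mu:
            lp += float(-np.sum(mus) / spec.prior_mean_mu
                        - npairs * math.log(spec.prior_mean_mu)
                        + np.sum(xv[npairs:]))
        return lp

    lams, mus = unpack(x)
    cur_lnl = pl.loglik(lams, mus)
    cur_lp = log_prior(x)
    rows = []
    accepted = proposed = 0
    normals = rng.standard_normal(iterations)
    uniforms = rng.random(iterations)
    coords = rng.integers(0, k, size=iterations)
    for it in range(iterations):
        j = coords[it]
        xp = x.copy()
        xp[j] += proposal_sd * normals[it]
        lams, mus = unpack(xp)
        new_lnl = pl.loglik(lams, mus)
        new_lp = log_prior(xp)
        proposed += 1
        if math.log(uniforms[it] + 1e-300) < (beta * (new_lnl - cur_lnl)
                                              + (new_lp - cur_lp)):
            x, cur_lnl, cur_lp = xp, new_lnl, new_lp
            accepted += 1
        if (it + 1) % thin == 0:
            lams, mus = unpack(x)
            row = {"iteration": it + 1}
            for pid, pos in pl.pair_pos.items():
                row[f"lambda_{pid}"] = lams[pos]
                if est_mu:
                    row[f"mu_{pid}"] = mus[pos]
            row["lnl"] = cur_lnl
            row["lnprior"] = cur_lp
            rows.append(row)
    rate = accepted / max(proposed, 1)
    if rate == 0.0:
        raise RuntimeError("MCMC accepted no proposals; check model and data")
    return McmcTrace(samples=pd.DataFrame(rows), acceptance_rate=rate, spec=spec)


def marginal_likelihood(tree: TimeTree, partition: CladePartition,
                        spec: DiversificationModelSpec, iterations: int = 100_000,
                        thin: int = 100, K: int = 10, seed: int = 0) -> float:
    """Log marginal likelihood by thermodynamic integration.

    Power-posterior temperatures beta_k are quantiles of Beta(0.3, 1) (dense
    near 0, where the integrand changes fastest); the mean log-likelihood at
    each beta is integrated over [0, 1] by the trapezoid rule.
    """
    betas = np.concatenate([[0.0], ((np.arange(1, K) / (K - 1)) ** (1.0 / 0.3))])
    means = []
    init = None
    for i, beta in enumerate(betas):
        trace = mcmc_sample(tree, partition, spec, iterations=iterations,
                            thin=thin, seed=seed + 1000 * i, beta=float(beta),
                            init=init)
        post = trace.post_burnin(0.25)
        means.append(float(post["lnl"].mean()))
        pid0 = spec.pair_ids()
        init = {pid: (float(post[f"lambda_{pid}"].iloc[-1]),
                      float(post[f"mu_{pid}"].iloc[-1]) if spec.estimates_mu else 0.0)
                for pid in pid0}
    means = np.asarray(means)
    diffs = np.diff(means)
    if np.any(diffs < -2.0 * max(1.0, np.std(means) / 5)):
        import warnings

        warnings.warn("mean log-likelihood not monotone in beta; TI estimate noisy")
    return float(np.trapezoid(means, betas))


# -- model comparison ------------------------------------------------------------


KASS_RAFTERY = ((2.0, "negligible"), (6.0, "positive"), (10.0, "strong"),
                (math.inf, "very strong"))


@dataclass
class ModelComparison:
    """Bayes-factor comparison of model 1 against model 0."""

    lnml_1: float
    lnml_0: float
    bf: float  # 2 (lnML1 - lnML0)
    category: str
    favors: int  # 1 or 0


def bayes_factor_classify(lnml_1: float, lnml_0: float) -> ModelComparison:
    """BF = 2(lnML1 - lnML0), categorized on the Kass-Raftery scale
    (<2 negligible, 2-6 positive, 6-10 strong, >10 very strong)."""
    if not (math.isfinite(lnml_1) and math.isfinite(lnml_0)):
        raise ValueError("marginal likelihoods must be finite")
    bf = 2.0 * (lnml_1 - lnml_0)
    mag = abs(bf)
    for cutoff, label in KASS_RAFTERY:
        if mag < cutoff or cutoff == math.inf:
            category = label
            break
    return ModelComparison(lnml_1=lnml_1, lnml_0=lnml_0, bf=bf,
                           category=category, favors=1 if bf >= 0 else 0)


def bma_combine(traces: dict[str, McmcTrace], lnmls: dict[str, float],
                partition: CladePartition, burnin: float = 0.10,
                n_draws: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Bayesian model averaging of per-partition-set rates.

    Model posterior probabilities are proportional to exp(lnML) under equal
    model priors; draws are resampled from each model's post-burn-in trace in
    proportion.  The result has one row per draw with columns
    ``lambda_<set>``, ``mu_<set>``, ``r_<set>`` (net diversification
    lambda - mu) for every partition set.
    """
    if not traces:
        raise ValueError("need at least one model trace")
    names = list(traces)
    logw = np.array([lnmls[m] for m in names])
    logw -= logw.max()  # log-sum-exp shift, robust to spreads > 700
    w = np.exp(logw)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_draws, w)
    frames = []
    for model, n_m in zip(names, counts):
        if n_m == 0:
            continue
        trace = traces[model]
        post = trace.post_burnin(burnin)
        if post.empty:
            raise ValueError(f"model {model!r} trace empty after burn-in")
        idx = rng.integers(0, len(post), size=n_m)
        sub = post.iloc[idx]
        rec = {"model": model}
        for set_name in partition.names:
            pid = trace.spec.linkage[set_name]
            lam = sub[f"lambda_{pid}"].to_numpy()
            mu = (sub[f"mu_{pid}"].to_numpy() if f"mu_{pid}" in sub.columns
                  else np.zeros(n_m))
            rec[f"lambda_{set_name}"] = lam
            rec[f"mu_{set_name}"] = mu
            rec[f"r_{set_name}"] = lam - mu
        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def hpd_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    m = max(1, int(math.ceil(level * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def ess(trace) -> float:
    """Effective sample size by Geyer's initial-positive-sequence estimator.

    Returns NaN (undefined) for a constant trace rather than infinity.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("trace too short for ESS")
    x = x - x.mean()
    var = float(x @ x) / n
    if var <= 0:
        return math.nan
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    tau = rho[0]  # = 1
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))
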