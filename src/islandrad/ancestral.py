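"""Binary-character Mk inference and stochastic character mapping.

Maximum-likelihood fitting of the equal-rates (ER) and all-rates-different
(ARD) Mk models by Felsenstein pruning, a likelihood-ratio test between
them, marginal ancestral-state posteriors by the up-down algorithm, and
stochastic character maps: joint samples of the full character history,
drawn node-by-node from the conditional distribution and filled in along
branches by endpoint-conditioned uniformization sampling.

For two states the transition probability matrix has the closed form
P(t) = Pi + e^{-(q01+q10) t} (I - Pi), with Pi the stationary matrix; the
general matrix-exponential path is kept for validation.

The default treats the fitted rates as known when sampling maps (the
"empirical" approach); rate uncertainty can instead be integrated over with
a simple MCMC on the rates under a Gamma prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar, minimize
from scipy.stats import chi2

from .trees import RegimePaintedTree, TimeTree

__all__ = [
    "MkModel",
    "MapSummary",
    "mk_loglik",
    "fit_mk",
    "lrt_er_vs_ard",
    "marginal_ancestral_states",
    "stochastic_character_map",
    "count_state_changes",
    "summarize_maps",
]

RATE_BOUNDS = (1e-9, 1e3)


@dataclass
class MkModel:
    """Two-state Mk model: states (ancestral, derived order is by label),
    generator Q in events/Myr, and a root prior (uniform by default)."""

    states: tuple[str, str]
    q01: float  # rate states[0] -> states[1]
    q10: float
    constraint: str = "ER"
    root_prior: np.ndarray | None = None
    lnl: float = math.nan
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.states) != 2:
            raise ValueError("binary characters only")
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")
        if self.constraint == "ER" and not math.isclose(self.q01, self.q10):
            raise ValueError("ER model requires q01 == q10")
        if self.root_prior is None:
            self.root_prior = np.array([0.5, 0.5])
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if not math.isclose(self.root_prior.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("root prior must sum to 1")

    @property
    def Q(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])

    def pmat(self, t: float) -> np.ndarray:
        """Closed-form 2-state transition probabilities over time t."""
        s = self.q01 + self.q10
        if s <= 0.0:
            return np.eye(2)
        pi = np.array([self.q10 / s, self.q01 / s])
        e = math.exp(-s * t)
        P = np.empty((2, 2))
        P[0, 0] = pi[0] + e * (1.0 - pi[0])
        P[0, 1] = pi[1] - e * pi[1]
        P[1, 1] = pi[1] + e * (1.0 - pi[1])
        P[1, 0] = pi[0] - e * pi[0]
        return P

    def pmat_expm(self, t: float) -> np.ndarray:
        """Matrix-exponential path, used to cross-check the closed form."""
        return expm(self.Q * t)


def _tip_partials(tree: TimeTree, tip_states: dict, states) -> np.ndarray:
    """(n_nodes, 2) conditional likelihood array initialized at tips; missing
    states are uninformative (1, 1)."""
    idx = {s: i for i, s in enumerate(states)}
    part = np.ones((len(tree.postorder), 2))
    for tip in tree.tips:
        s = tip_states.get(tip.label)
        if s is None or s == "":
            continue
        if s not in idx:
            raise ValueError(f"tip state {s!r} not among {tuple(states)}")
        part[tip.index] = 0.0
        part[tip.index, idx[s]] = 1.0
    return part


def _down_pass(tree: TimeTree, model: MkModel, tip_states: dict):
    """Felsenstein pruning: per-node conditional likelihoods of the tip data
    below each node, with per-node log scaling factors."""
    part = _tip_partials(tree, tip_states, model.states)
    logscale = np.zeros(len(tree.postorder))
    pmats = {}
    for node in tree.postorder:
        if node.is_leaf:
            continue
        vals = np.ones(2)
        ls = 0.0
        for child in node.children:
            P = model.pmat(child.length)
            pmats[child.index] = P
            vals = vals * (P @ part[child.index])
            ls += logscale[child.index]
        m = vals.max()
        if m <= 0.0:
            raise ValueError("zero likelihood: data impossible under model")
        part[node.index] = vals / m
        logscale[node.index] = ls + math.log(m)
    return part, logscale, pmats


def mk_loglik(tree: TimeTree, tip_states: dict, model: MkModel) -> float:
    """Pruning log-likelihood of binary tip states under an Mk model."""
    part, logscale, _ = _down_pass(tree, model, tip_states)
    ri = tree.root.index
    return float(np.log(model.root_prior @ part[ri]) + logscale[ri])


def fit_mk(tree: TimeTree, tip_states: dict, constraint: str = "ER",
           root_prior=None, n_restarts: int = 3, seed: int = 0) -> MkModel:
    """ML rates by bounded optimization in log-rate space with restarts.

    If only one state is observed the optimum sits at the lower rate bound
    and the returned model carries a "boundary" flag.
    """
    states = tuple(sorted({s for s in tip_states.values() if s}))
    if len(states) == 1:
        states = (states[0], states[0] + "_other")
    elif len(states) != 2:
        raise ValueError(f"need one or two observed states, got {states}")
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])
    rng = np.random.default_rng(seed)

    if constraint == "ER":
        def neg(lq):
            m = MkModel(states=states, q01=math.exp(lq), q10=math.exp(lq),
                        constraint="ER", root_prior=root_prior)
            return -mk_loglik(tree, tip_states, m)

        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        q = math.exp(res.x)
        model = MkModel(states=states, q01=q, q10=q, constraint="ER",
                        root_prior=root_prior)
    elif constraint == "ARD":
        def neg2(lq):
            m = MkModel(states=states, q01=math.exp(lq[0]), q10=math.exp(lq[1]),
                        constraint="ARD", root_prior=root_prior)
            return -mk_loglik(tree, tip_states, m)

        starts = [np.array([math.log(1.0 / max(tree.height, 1e-6))] * 2)]
        starts += [rng.uniform(-4, 1, size=2) for _ in range(max(0, n_restarts - 1))]
        best = None
        for x0 in starts:
            res = minimize(neg2, x0, method="L-BFGS-B",
                           bounds=[(lo, hi), (lo, hi)])
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("Mk optimization failed to converge")
        model = MkModel(states=states, q01=math.exp(best.x[0]),
                        q10=math.exp(best.x[1]), constraint="ARD",
                        root_prior=root_prior)
    else:
        raise ValueError("constraint must be 'ER' or 'ARD'")
    model.lnl = mk_loglik(tree, tip_states, model)
    for q in (model.q01, model.q10):
        if q <= RATE_BOUNDS[0] * 1.01 or q >= RATE_BOUNDS[1] * 0.99:
            model.flags.append("boundary")
            break
    observed = {s for s in tip_states.values() if s}
    if len(observed) < 2:
        model.flags.append("single_observed_state")
    return model


def lrt_er_vs_ard(fit_er: MkModel, fit_ard: MkModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of ARD against nested ER: statistic
    2(lnL_ARD - lnL_ER) ~ chi^2 with 1 df for a binary character."""
    stat = 2.0 * (fit_ard.lnl - fit_er.lnl)
    if stat < -1e-6:
        raise RuntimeError(
            f"ARD fit worse than ER by {-stat:.3g}; optimization failure"
        )
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=1))
    return stat, 1, p


def marginal_ancestral_states(tree: TimeTree, tip_states: dict,
                              model: MkModel) -> dict[int, np.ndarray]:
    """Marginal posterior over states for every node (keyed by node index),
    by the standard up-down (inside-outside) recursion."""
    part, logscale, pmats = _down_pass(tree, model, tip_states)
    up: dict[int, np.ndarray] = {tree.root.index: model.root_prior.copy()}
    for node in tree.preorder:
        if node.is_leaf:
            continue
        for child in node.children:
            sib_factor = np.ones(2)
            for sib in node.children:
                if sib is not child:
                    sib_factor = sib_factor * (pmats[sib.index] @ part[sib.index])
            msg = up[node.index] * sib_factor
            up[child.index] = pmats[child.index].T @ msg
    out = {}
    for node in tree.postorder:
        post = up[node.index] * part[node.index]
        out[node.index] = post / post.sum()
    return out


# -- endpoint-conditioned path sampling ------------------------------------------


def _bridge_uniformization(a: int, b: int, t: float, model: MkModel, rng,
                           max_events: int = 10_000) -> list[tuple[int, float]]:
    """Sample a CTMC path on [0, t] conditioned on endpoints (a, b) by
    uniformization; returns (state, duration) segments including both ends."""
    Q = model.Q
    lam = max(-Q[0, 0], -Q[1, 1])
    if lam <= 0.0:
        if a != b:
            raise RuntimeError("endpoints differ but rates are zero")
        return [(a, t)]
    R = np.eye(2) + Q / lam
    # powers of R up to a truncation chosen by the Poisson tail
    P_ab = model.pmat(t)[a, b]
    if P_ab <= 0.0:
        raise RuntimeError("impossible endpoint combination")
    mean_n = lam * t
    n_max = int(mean_n + 10.0 * math.sqrt(mean_n) + 20)
    Rpow = [np.eye(2)]
    for _ in range(n_max):
        Rpow.append(Rpow[-1] @ R)
    # P(N = n | a, b) ∝ Poisson(lam t)(n) (R^n)_ab
    log_pois = -mean_n + np.arange(n_max + 1) * math.log(max(mean_n, 1e-300)) \
        - np.array([math.lgamma(k + 1) for k in range(n_max + 1)])
    probs = np.exp(log_pois) * np.array([Rpow[k][a, b] for k in range(n_max + 1)])
    total = probs.sum()
    probs /= total
    n = int(rng.choice(n_max + 1, p=probs))
    # jump chain conditioned on endpoints
    states = [a]
    for k in range(1, n + 1):
        prev = states[-1]
        wts = np.array([R[prev, s] * Rpow[n - k][s, b] for s in (0, 1)])
        wts_sum = wts.sum()
        if wts_sum <= 0:
            raise RuntimeError("uniformization dead end (pathological rates)")
        states.append(int(rng.choice(2, p=wts / wts_sum)))
    times = np.sort(rng.uniform(0.0, t, size=n))
    segs: list[tuple[int, float]] = []
    cur, start = a, 0.0
    for s, tt in zip(states[1:], times):
        if s != cur:
            segs.append((cur, tt - start))
            cur, start = s, tt
    segs.append((cur, t - start))
    return segs


def stochastic_character_map(tree: TimeTree, tip_states: dict, model: MkModel,
                             n_maps: int, seed: int = 0) -> list[RegimePaintedTree]:
    """Sample full character histories consistent with the tip data.

    Node states are drawn from their joint conditional distribution (root
    from its posterior, children given parents); branch interiors are filled
    by endpoint-conditioned uniformization sampling.  Rates are fixed at the
    supplied model ("empirical" treatment).
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    part, logscale, pmats = _down_pass(tree, model, tip_states)
    rng = np.random.default_rng(seed)
    ri = tree.root.index
    root_post = model.root_prior * part[ri]
    root_post = root_post / root_post.sum()
    maps = []
    base = tree.copy()
    for _ in range(n_maps):
        t = base.copy()
        node_state = {ri: int(rng.choice(2, p=root_post))}
        for node in t.preorder:
            for child in node.children:
                P = pmats[child.index]
                w = P[node_state[node.index]] * part[child.index]
                node_state[child.index] = int(rng.choice(2, p=w / w.sum()))
        for node in t.preorder:
            if node is t.root:
                continue
            segs = _bridge_uniformization(node_state[node.parent.index],
                                          node_state[node.index],
                                          node.length, model, rng)
            node.segments = [(model.states[s], d) for s, d in segs]
        maps.append(RegimePaintedTree(t, root_state=model.states[node_state[ri]]))
    return maps


def count_state_changes(maps: list[RegimePaintedTree], level: float = 0.95):
    """Mean and central credible interval of per-direction change counts
    across maps; returns {(from, to): (mean, (lo, hi))}."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    states = sorted({s for m in maps for s in m.states()})
    directions = [(a, b) for a in states for b in states if a != b]
    counts = {d: [] for d in directions}
    for m in maps:
        c = m.n_changes()
        for d in directions:
            counts[d].append(c.get(d, 0))
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    out = {}
    for d in directions:
        arr = np.asarray(counts[d], dtype=float)
        out[d] = (float(arr.mean()),
                  (float(np.percentile(arr, lo_q)), float(np.percentile(arr, hi_q))))
    return out


@dataclass
class MapSummary:
    """Posterior summary over a set of stochastic maps on one tree."""

    states: list[str]
    branch_fractions: dict[int, np.ndarray]  # node index -> mean time fraction
    node_posterior: dict[int, np.ndarray]  # node index -> state frequencies
    change_counts: dict  # (from, to) -> (mean, (lo, hi))

    def modal_state(self, node_index: int) -> str:
        return self.states[int(np.argmax(self.node_posterior[node_index]))]


def summarize_maps(maps: list[RegimePaintedTree]) -> MapSummary:
    """Per-branch time fractions in each state and per-node state posteriors
    averaged over maps.  All maps must share one topology (tip labels and
    branch lengths)."""
    if not maps:
        raise ValueError("no maps supplied")
    ref = maps[0].tree
    for m in maps[1:]:
        if m.tree.tip_labels != ref.tip_labels:
            raise ValueError("maps disagree in tip labels")
        if abs(m.tree.height - ref.height) > 1e-6 * ref.height:
            raise ValueError("maps disagree in tree height")
    states = sorted({s for m in maps for s in m.states()})
    s_idx = {s: i for i, s in enumerate(states)}
    nn = len(ref.postorder)
    frac = {i: np.zeros(len(states)) for i in range(nn)}
    post = {i: np.zeros(len(states)) for i in range(nn)}
    for m in maps:
        for node in m.tree.postorder:
            post[node.index][s_idx[m.node_state(node)]] += 1.0
            if node is m.tree.root:
                continue
            for s, d in node.segments:
                frac[node.index][s_idx[s]] += d / node.length
    for i in range(nn):
        post[i] /= len(maps)
        frac[i] /= len(maps)
    frac[ref.root.index] = post[ref.root.index].copy()
    return MapSummary(states=states, branch_fractions=frac,
                      node_posterior=post,
                      change_counts=count_state_changes(maps) if len(maps) > 1 else {})
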