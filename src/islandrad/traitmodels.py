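"""Continuous-trait models on regime-painted trees.

Six models of log plant-height evolution, named as in the OUwie tradition:

====== ==========================================================
BM1    Brownian motion, one rate, free root value x0
BMS    Brownian motion, one rate per regime, free root value
OU1    Ornstein-Uhlenbeck, single optimum theta, single alpha/sigma2
OUM    OU, one optimum per regime, shared alpha and sigma2
OUMA   OU, optimum and pull alpha per regime, shared sigma2
OUMV   OU, optimum and rate sigma2 per regime, shared alpha
====== ==========================================================

All models induce a multivariate normal distribution over tip values whose
mean and covariance follow from integrating the process along the painted
branches.  With A(v) the pull integral (sum of alpha x duration) from the
root to point v, and I(v) = int_0^{s_v} sigma2(s) e^{2A(s)} ds accumulated
along the root-to-v path, tip covariances are

    Cov(i, j) = exp(-A(i) - A(j)) * I(mrca(i, j)),

which covers every model above (BM is the alpha = 0 case).  I(v) is
accumulated in log space segment by segment, so arbitrarily strong pull
(alpha up to 1e3 per Myr) does not overflow.

The root is anchored at the root-regime optimum for OU models (no free root
state); BM models estimate the root value x0 as the GLS mean.  Optimum
parameters (theta, or x0) are profiled out by generalized least squares at
each (alpha, sigma2), which is exact and keeps the numerical search low
dimensional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .trees import RegimePaintedTree

__all__ = [
    "MODEL_NAMES",
    "ModelFit",
    "PaintedModel",
    "model_mean_and_cov",
    "model_loglik",
    "fit_model",
    "fit_all_models",
    "hessian_screen",
    "failed_model_screen",
    "aicc_weights",
    "average_parameters",
    "average_across_trees",
    "parametric_bootstrap_ci",
]

MODEL_NAMES = ("BM1", "BMS", "OU1", "OUM", "OUMA", "OUMV")

#: optimizer box constraints (natural scale)
ALPHA_BOUNDS = (1e-9, 1e3)
SIGMA2_BOUNDS = (1e-9, 1e4)

_LOG2PI = math.log(2.0 * math.pi)


def _log_expm1(z: float) -> float:
    """log(e^z - 1) without overflow for large z."""
    if z < 1e-10:
        return math.log(z) if z > 0 else -math.inf
    if z > 33.0:
        return z + math.log1p(-math.exp(-z))
    return math.log(math.expm1(z))


@dataclass
class ModelFit:
    """One continuous-model fit on one painted tree."""

    name: str
    params: dict
    lnl: float
    k: int
    n: int
    status: str = "ok"  # ok | hessian_fail | model_fail
    hessian_eigenvalues: np.ndarray | None = None
    aicc: float = math.nan
    delta_aicc: float = math.nan
    weight: float = math.nan
    flags: list = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return self.status == "ok"


class PaintedModel:
    """Pre-indexed painted tree plus the model likelihood machinery.

    Building this object once per painted tree amortizes the MRCA matrix and
    branch-segment flattening over the many likelihood evaluations a model
    search performs.
    """

    def __init__(self, painted: RegimePaintedTree):
        self.painted = painted
        tree = painted.tree
        self.tree = tree
        self.tip_labels = list(tree.tip_labels)
        self.n = tree.n_tips
        self.regimes = painted.states()
        self.r_index = {r: i for i, r in enumerate(self.regimes)}
        self.R = len(self.regimes)
        self.root_regime = self.r_index[painted.root_state]

        nodes = tree.postorder
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        for v in nodes:
            if v.parent is not None:
                self.parent[v.index] = v.parent.index
        # branch segments rootward->tipward per node
        self.segments: list[list[tuple[int, float]]] = [[] for _ in nodes]
        for v in nodes:
            if v.parent is not None:
                self.segments[v.index] = [
                    (self.r_index[s], d) for s, d in v.segments
                ]
        self.tip_idx = np.array([t.index for t in tree.tips])
        self.preorder_idx = [v.index for v in tree.preorder]
        self.root_idx = tree.root.index
        self._mrca = self._mrca_matrix()

    def _mrca_matrix(self) -> np.ndarray:
        n = self.n
        tree = self.tree
        pos = {t.index: i for i, t in enumerate(tree.tips)}
        M = np.zeros((n, n), dtype=int)
        sets: dict[int, list[int]] = {}
        for v in tree.postorder:
            if v.is_leaf:
                M[pos[v.index], pos[v.index]] = v.index
                sets[v.index] = [pos[v.index]]
                continue
            groups = [sets.pop(c.index) for c in v.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            M[i, j] = M[j, i] = v.index
            sets[v.index] = [x for g in groups for x in g]
        return M

    # -- per-parameterization quantities --------------------------------------

    def _accumulate(self, alpha: np.ndarray, sigma2: np.ndarray):
        """Per-node pull integral A, log trait variance integral logI, and
        per-node regime weight vectors for the OU mean."""
        nn = self.n_nodes
        A = np.zeros(nn)
        logI = np.full(nn, -np.inf)
        W = np.zeros((nn, self.R))
        W[self.root_idx, self.root_regime] = 1.0
        for vi in self.preorder_idx:
            p = self.parent[vi]
            if p < 0:
                continue
            a0 = A[p]
            li = logI[p]
            # branch decay and theta contributions, rootward to tipward
            segs = self.segments[vi]
            # pull accumulated over the branch
            branch_decay = 0.0
            contribs = []  # (regime, log weight pieces) handled after total known
            a_run = a0
            for r, d in segs:
                ar = alpha[r]
                z = 2.0 * ar * d
                if ar > 0.0:
                    term = math.log(sigma2[r]) + 2.0 * a_run + _log_expm1(z) - math.log(2.0 * ar)
                else:
                    term = math.log(sigma2[r] * d) + 2.0 * a_run
                li = np.logaddexp(li, term)
                a_run += ar * d
                branch_decay += ar * d
                contribs.append((r, a_run, ar * d))
            A[vi] = a0 + branch_decay
            logI[vi] = li
            # mean weights: w(v) = w(p) e^{-branch_decay} + per-segment terms
            W[vi] = W[p] * math.exp(-branch_decay)
            a_total = A[vi]
            for r, a_end, seg_pull in contribs:
                # decay from segment end to node vi
                d_after = a_total - a_end
                W[vi, r] += math.exp(-d_after) - math.exp(-d_after - seg_pull)
        return A, logI, W

    def cov_matrix(self, alpha: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
        A, logI, _ = self._accumulate(alpha, sigma2)
        At = A[self.tip_idx]
        C = np.exp(logI[self._mrca] - At[:, None] - At[None, :])
        np.fill_diagonal(C, np.exp(logI[self.tip_idx] - 2.0 * At))
        return C

    def mean_design(self, name: str, alpha: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
        """Design matrix X such that the tip mean vector is X @ beta."""
        if name in ("BM1", "BMS"):
            return np.ones((self.n, 1))
        _, _, W = self._accumulate(alpha, sigma2)
        Wt = W[self.tip_idx]
        if name == "OU1":
            return Wt.sum(axis=1, keepdims=True)  # weights sum to 1: single theta
        return Wt

    def expand(self, name: str, params: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-regime (alpha, sigma2, theta-or-x0) arrays for a parameter dict."""
        R = self.R

        def per_regime(value) -> np.ndarray:
            if isinstance(value, dict):
                return np.array([float(value[r]) for r in self.regimes])
            return np.full(R, float(value))

        if name == "BM1":
            return np.zeros(R), per_regime(params["sigma2"]), per_regime(params["x0"])
        if name == "BMS":
            return np.zeros(R), per_regime(params["sigma2"]), per_regime(params["x0"])
        if name == "OU1":
            return (per_regime(params["alpha"]), per_regime(params["sigma2"]),
                    per_regime(params["theta"]))
        if name == "OUM":
            return (per_regime(params["alpha"]), per_regime(params["sigma2"]),
                    per_regime(params["theta"]))
        if name == "OUMA":
            return (per_regime(params["alpha"]), per_regime(params["sigma2"]),
                    per_regime(params["theta"]))
        if name == "OUMV":
            return (per_regime(params["alpha"]), per_regime(params["sigma2"]),
                    per_regime(params["theta"]))
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    def mean_and_cov(self, name: str, params: dict) -> tuple[np.ndarray, np.ndarray]:
        alpha, sigma2, loc = self.expand(name, params)
        if np.any(sigma2 <= 0):
            raise ValueError("sigma2 must be positive")
        if name.startswith("OU") and np.any(alpha <= 0):
            raise ValueError("alpha must be positive for OU models")
        A, logI, W = self._accumulate(alpha, sigma2)
        At = A[self.tip_idx]
        C = np.exp(logI[self._mrca] - At[:, None] - At[None, :])
        np.fill_diagonal(C, np.exp(logI[self.tip_idx] - 2.0 * At))
        if name in ("BM1", "BMS"):
            mean = np.full(self.n, loc[0])
        else:
            mean = W[self.tip_idx] @ loc
        return mean, C

    def loglik(self, name: str, params: dict, traits: np.ndarray) -> float:
        mean, C = self.mean_and_cov(name, params)
        return _mvn_loglik(traits - mean, C)


def _mvn_loglik(resid: np.ndarray, C: np.ndarray) -> float:
    n = resid.shape[0]
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        eig = np.linalg.eigvalsh(C)
        raise ValueError(
            f"model covariance not positive definite (min eigenvalue {eig.min():.3g})"
        )
    diag = np.diag(L)
    cond = (diag.max() / diag.min()) ** 2
    if cond > 1e12:
        raise ValueError(f"ill-conditioned model covariance (condition ~{cond:.3g})")
    z = np.linalg.solve(L, resid)
    return -0.5 * (n * _LOG2PI) - np.log(diag).sum() - 0.5 * float(z @ z)


def _gls_profile(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profile the mean parameters: beta-hat, residual, lnL at the optimum."""
    L = np.linalg.cholesky(C)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = y.shape[0]
    lnl = -0.5 * n * _LOG2PI - np.log(np.diag(L)).sum() - 0.5 * float(resid @ resid)
    return beta, lnl


def model_mean_and_cov(painted: RegimePaintedTree, name: str, params: dict):
    """Tip mean vector and covariance matrix (tip order = tree.tip_labels)."""
    return PaintedModel(painted).mean_and_cov(name, params)


def model_loglik(painted: RegimePaintedTree, traits, name: str, params: dict) -> float:
    """Multivariate-normal log-likelihood of tip trait values under a model.

    ``traits`` may be an array in tip order or a mapping label -> value.
    """
    pm = PaintedModel(painted)
    y = _trait_vector(pm, traits)
    return pm.loglik(name, params, y)


def _trait_vector(pm: PaintedModel, traits) -> np.ndarray:
    if isinstance(traits, dict):
        return np.array([float(traits[t]) for t in pm.tip_labels])
    y = np.asarray(traits, dtype=float)
    if y.shape != (pm.n,):
        raise ValueError(f"expected {pm.n} trait values, got shape {y.shape}")
    return y


# -- fitting ---------------------------------------------------------------------


def _free_param_layout(name: str, R: int):
    """(number of log-alpha entries, number of log-sigma2 entries)."""
    return {
        "BM1": (0, 1),
        "BMS": (0, R),
        "OU1": (1, 1),
        "OUM": (1, 1),
        "OUMA": (R, 1),
        "OUMV": (1, R),
    }[name]


def param_count(name: str, R: int) -> int:
    """Free-parameter count k used for AICc."""
    return {
        "BM1": 2,
        "BMS": 1 + R,
        "OU1": 3,
        "OUM": 2 + R,
        "OUMA": 1 + 2 * R,
        "OUMV": 1 + 2 * R,
    }[name]


def _phi_to_arrays(name: str, phi: np.ndarray, R: int):
    na, ns = _free_param_layout(name, R)
    raw_a = np.exp(phi[:na])
    raw_s = np.exp(phi[na:na + ns])
    alpha = np.zeros(R) if na == 0 else (np.full(R, raw_a[0]) if na == 1 else raw_a)
    sigma2 = np.full(R, raw_s[0]) if ns == 1 else raw_s
    return alpha, sigma2


def _assemble_params(pm: PaintedModel, name: str, alpha, sigma2, beta) -> dict:
    regs = pm.regimes
    out: dict = {}
    if name in ("BM1", "BMS"):
        out["x0"] = float(beta[0])
        out["sigma2"] = (float(sigma2[0]) if name == "BM1"
                         else {r: float(sigma2[i]) for i, r in enumerate(regs)})
        return out
    out["alpha"] = (float(alpha[0]) if name in ("OU1", "OUM", "OUMV")
                    else {r: float(alpha[i]) for i, r in enumerate(regs)})
    out["sigma2"] = (float(sigma2[0]) if name in ("OU1", "OUM", "OUMA")
                     else {r: float(sigma2[i]) for i, r in enumerate(regs)})
    if name == "OU1":
        out["theta"] = float(beta[0])
    else:
        out["theta"] = {r: float(beta[i]) for i, r in enumerate(regs)}
    return out


def fit_model(
    painted_or_pm,
    traits,
    name: str,
    n_restarts: int = 5,
    seed: int | None = 0,
    compute_hessian: bool = True,
    start: dict | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model, optimizing log(alpha), log(sigma2)
    by L-BFGS-B with jittered restarts; optima/root value profiled by GLS."""
    pm = painted_or_pm if isinstance(painted_or_pm, PaintedModel) else PaintedModel(painted_or_pm)
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    y = _trait_vector(pm, traits)
    n, R = pm.n, pm.R
    if n < 10:
        import warnings

        warnings.warn(f"fitting {name} on only {n} tips; estimates will be unstable")
    rng = np.random.default_rng(seed)
    na, ns = _free_param_layout(name, R)
    k_free = na + ns
    lo = np.concatenate([np.full(na, math.log(ALPHA_BOUNDS[0])),
                         np.full(ns, math.log(SIGMA2_BOUNDS[0]))])
    hi = np.concatenate([np.full(na, math.log(ALPHA_BOUNDS[1])),
                         np.full(ns, math.log(SIGMA2_BOUNDS[1]))])

    def neg_lnl(phi: np.ndarray) -> float:
        alpha, sigma2 = _phi_to_arrays(name, phi, R)
        try:
            C = pm.cov_matrix(alpha, sigma2)
            X = pm.mean_design(name, alpha, sigma2)
            _, lnl = _gls_profile(C, X, y)
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e10
        if not math.isfinite(lnl):
            return 1e10
        return -lnl

    # moment-based initial guess: sigma2 ~ trait variance / tree height
    T = max(pm.tree.height, 1e-6)
    s_init = max(float(np.var(y)) / T, 1e-6)
    a_init = 1.0 / T
    if start is not None:
        a_arr, s_arr, _ = pm.expand(name, start)
        a_free = a_arr if na == R else a_arr[:na]
        s_free = s_arr if ns == R else s_arr[:ns]
        base = np.concatenate([
            np.log(np.clip(a_free, *ALPHA_BOUNDS)),
            np.log(np.clip(s_free, *SIGMA2_BOUNDS)),
        ])
    else:
        base = np.concatenate([np.full(na, math.log(a_init)), np.full(ns, math.log(s_init))])
    best = None
    for trial in range(max(1, n_restarts)):
        x0 = base if trial == 0 else base + rng.normal(0.0, 1.0, size=k_free)
        x0 = np.clip(x0, lo, hi)
        res = minimize(neg_lnl, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)),
                       options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e9:
        return ModelFit(name=name, params={}, lnl=-math.inf, k=param_count(name, R),
                        n=n, status="model_fail", flags=["non-convergence"])
    phi = np.asarray(best.x)
    alpha, sigma2 = _phi_to_arrays(name, phi, R)
    C = pm.cov_matrix(alpha, sigma2)
    X = pm.mean_design(name, alpha, sigma2)
    beta, lnl = _gls_profile(C, X, y)
    flags = []
    if np.any(np.abs(phi - lo) < 1e-6) or np.any(np.abs(phi - hi) < 1e-6):
        flags.append("boundary")
    params = _assemble_params(pm, name, alpha, sigma2, beta)
    fit = ModelFit(name=name, params=params, lnl=float(lnl), k=param_count(name, R),
                   n=n, flags=flags)
    if compute_hessian:
        fit.hessian_eigenvalues = _neg_lnl_hessian_eigs(pm, name, y, phi, beta)
        hessian_screen(fit)
    return fit


def _neg_lnl_hessian_eigs(pm, name, y, phi, beta) -> np.ndarray:
    """Eigenvalues of the finite-difference Hessian of -lnL at the optimum,
    over the full free-parameter vector (log-scale covariance params + mean
    params)."""
    p0 = np.concatenate([phi, np.asarray(beta, dtype=float).ravel()])
    kc = len(phi)

    def f(p: np.ndarray) -> float:
        alpha, sigma2 = _phi_to_arrays(name, p[:kc], pm.R)
        try:
            C = pm.cov_matrix(alpha, sigma2)
            X = pm.mean_design(name, alpha, sigma2)
            mean = X @ p[kc:]
            return -_mvn_loglik(y - mean, C)
        except (np.linalg.LinAlgError, ValueError):
            return 1e10

    k = len(p0)
    h = 1e-4 * np.maximum(np.abs(p0), 1e-2)
    H = np.zeros((k, k))
    f0 = f(p0)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fpp = f(p0 + ei); fmm = f(p0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            fa = f(p0 + ei + ej); fb = f(p0 + ei - ej)
            fc = f(p0 - ei + ej); fd = f(p0 - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4 * h[i] * h[j])
    return np.linalg.eigvalsh(H)


def fit_all_models(painted, traits, names=MODEL_NAMES, **kw) -> list[ModelFit]:
    pm = painted if isinstance(painted, PaintedModel) else PaintedModel(painted)
    fits = [fit_model(pm, traits, name, **kw) for name in names]
    failed_model_screen(fits)
    return fits


# -- screening, weights, averaging -----------------------------------------------


def hessian_screen(fit: ModelFit, rtol: float = 1e-8) -> str:
    """Flag fits whose negative-log-likelihood Hessian is not positive
    definite (a non-positive eigenvalue means the optimizer did not find a
    proper local maximum, so the estimates are unreliable).

    Eigenvalues are compared against ``rtol`` times the largest magnitude:
    a numerically-zero direction (e.g. an optimum unidentified because the
    pull alpha collapsed to its lower bound) fails the screen just like a
    negative one.
    """
    if fit.status == "model_fail":
        return fit.status
    if fit.hessian_eigenvalues is None:
        raise ValueError("fit has no stored Hessian eigenvalues")
    eigs = fit.hessian_eigenvalues
    if np.any(eigs <= rtol * np.abs(eigs).max()):
        fit.status = "hessian_fail"
    return fit.status


def failed_model_screen(fits: list[ModelFit], failure_margin: float = 100.0) -> list[str]:
    """Flag fits whose log-likelihood exceeds the median across models by more
    than ``failure_margin`` natural-log units — a symptom of a spuriously
    inflated likelihood from an over-parameterized model."""
    if len(fits) < 2:
        return [f.status for f in fits]
    lnls = np.array([f.lnl for f in fits if math.isfinite(f.lnl)])
    if lnls.size == 0:
        return [f.status for f in fits]
    med = float(np.median(lnls))
    for f in fits:
        if math.isfinite(f.lnl) and f.lnl - med > failure_margin:
            f.status = "model_fail"
            f.flags.append("spurious_lnl")
    return [f.status for f in fits]


def aicc_weights(fits: list[ModelFit]) -> list[ModelFit]:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); Akaike weights over retained fits.

    Fits with n <= k+1 are excluded with a warning flag.  Weights of excluded
    fits are set to 0.
    """
    retained = []
    for f in fits:
        if not f.retained:
            f.weight = 0.0
            f.aicc = math.nan
            continue
        if f.n <= f.k + 1:
            f.status = "model_fail"
            f.flags.append("n_too_small_for_aicc")
            f.weight = 0.0
            continue
        f.aicc = -2.0 * f.lnl + 2.0 * f.k + 2.0 * f.k * (f.k + 1) / (f.n - f.k - 1)
        retained.append(f)
    if not retained:
        return fits
    best = min(f.aicc for f in retained)
    rel = []
    for f in retained:
        f.delta_aicc = f.aicc - best
        rel.append(math.exp(-0.5 * f.delta_aicc))
    total = sum(rel)
    for f, r in zip(retained, rel):
        f.weight = r / total
    return fits


def _expanded_estimates(fit: ModelFit, regimes: list[str]) -> dict[str, dict[str, float]]:
    """Per-regime {sigma2, alpha, theta} for one fit; parameters a model lacks
    are absent (BM models define no alpha or theta)."""

    def spread(v):
        return {r: float(v[r]) for r in regimes} if isinstance(v, dict) else {r: float(v) for r in regimes}

    out: dict[str, dict[str, float]] = {}
    out["sigma2"] = spread(fit.params["sigma2"])
    if fit.name.startswith("OU"):
        out["alpha"] = spread(fit.params["alpha"])
        out["theta"] = spread(fit.params["theta"])
    return out


def average_parameters(fits: list[ModelFit], regimes: list[str]) -> dict:
    """Akaike-weight averaged sigma2/alpha/theta per regime over retained fits.

    A parameter absent from a model (alpha, theta in BM) is averaged over the
    models that define it, with weights renormalized over those models.
    Returns {param: {regime: value}}; a parameter defined by no retained model
    is reported as None.
    """
    fits = aicc_weights(list(fits))
    retained = [f for f in fits if f.retained and f.weight > 0]
    out: dict[str, dict[str, float] | None] = {}
    for pname in ("sigma2", "alpha", "theta"):
        acc = {r: 0.0 for r in regimes}
        wsum = 0.0
        for f in retained:
            est = _expanded_estimates(f, regimes)
            if pname not in est:
                continue
            wsum += f.weight
            for r in regimes:
                acc[r] += f.weight * est[pname][r]
        if wsum <= 0:
            out[pname] = None
        else:
            out[pname] = {r: acc[r] / wsum for r in regimes}
    return out


def average_across_trees(per_tree_averages: list[dict], regimes: list[str]) -> dict:
    """Pool within-tree model averages across painted trees.

    Returns {param: {regime: {"mean": m, "values": array}}} where "values" is
    the per-tree distribution (the basis of the density-plot summaries).
    """
    out: dict = {}
    for pname in ("sigma2", "alpha", "theta"):
        out[pname] = {}
        for r in regimes:
            vals = np.array([
                t[pname][r] for t in per_tree_averages
                if t.get(pname) is not None
            ])
            out[pname][r] = {
                "mean": float(vals.mean()) if vals.size else math.nan,
                "values": vals,
            }
    return out


def parametric_bootstrap_ci(
    painted: RegimePaintedTree,
    fit: ModelFit,
    n_boot: int,
    seed: int = 0,
    level: float = 0.95,
    n_restarts: int = 1,
) -> dict:
    """Percentile bootstrap confidence intervals for one fitted model.

    Simulates ``n_boot`` trait datasets from the fitted model on the same
    painted tree, refits the model to each (warm-started at the estimates),
    and returns per-parameter percentile intervals.  Flagged unreliable if
    more than 20% of refits fail.
    """
    from .simulate import simulate_continuous_trait  # local import: avoids cycle

    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if fit.status != "ok":
        raise ValueError(f"cannot bootstrap a fit with status {fit.status!r}")
    pm = PaintedModel(painted)
    regimes = pm.regimes
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    for b in range(n_boot):
        y = simulate_continuous_trait(painted, fit.name, fit.params,
                                      seed=int(rng.integers(2**31 - 1)))
        bf = fit_model(pm, y, fit.name, n_restarts=n_restarts,
                       seed=int(rng.integers(2**31 - 1)),
                       compute_hessian=False, start=fit.params)
        if bf.status == "model_fail":
            failures += 1
            continue
        est = _expanded_estimates(bf, regimes)
        row = {}
        for pname, per_reg in est.items():
            for r, v in per_reg.items():
                row[f"{pname}[{r}]"] = v
        if "x0" in bf.params:
            row["x0"] = bf.params["x0"]
        rows.append(row)
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    cis = {}
    if rows:
        import pandas as pd

        df = pd.DataFrame(rows)
        for col in df.columns:
            cis[col] = (float(np.percentile(df[col], lo_q)),
                        float(np.percentile(df[col], hi_q)))
    unreliable = failures > 0.2 * n_boot
    return {"ci": cis, "n_ok": len(rows), "n_fail": failures, "unreliable": unreliable}
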