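"""Trait-space saturation analysis (TSA).

Compares how fast nested clades fill their trait space: for every pair of
taxa, take the cophenetic (phylogenetic) distance and the absolute trait
difference, rescale both into the 0-1 space of the whole tree, and trace the
running maximum of relative disparity as pairs accumulate with increasing
relative phylogenetic distance — the saturation curve.  A curve hugging the
diagonal indicates Brownian-like disparification; early saturation (high
disparity among recently diverged species, a logarithmic-looking curve) is
the signature of rapid trait-space filling.

Island and nonisland ("nested") curves are built from within-set pairs only
but normalized by whole-tree maxima, so they are directly comparable.
Uncertainty comes from jackknife resampling (random pruning of a fraction of
taxa); congruence between two curves is tested with a two-sample
Kolmogorov-Smirnov test on curve values sampled along a common grid over the
shared support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .trees import TimeTree, cophenetic_matrix, prune_tips

__all__ = [
    "SaturationCurve",
    "KSResult",
    "pairwise_disparity",
    "saturation_curve",
    "nested_saturation",
    "jackknife_envelope",
    "ks_congruence",
    "overlap_fraction",
    "classify_trajectory",
]


@dataclass
class SaturationCurve:
    """Breakpoints of the running-maximum saturation function.

    ``x`` (relative cophenetic distance) is strictly increasing; ``y``
    (relative trait disparity) is non-decreasing; both live in [0, 1] when
    normalized by whole-tree maxima.  The curve is a right-continuous step
    function equal to 0 left of the first breakpoint.
    """

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size or self.x.size == 0:
            raise ValueError("x and y must be non-empty and matched")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("breakpoint x values must be strictly increasing")
        if np.any(np.diff(self.y) < 0):
            raise ValueError("saturation curve must be non-decreasing")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def __call__(self, grid) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        idx = np.searchsorted(self.x, grid, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], 0.0)
        return out


@dataclass
class KSResult:
    d_max: float
    p_value: float
    grid_size: int


def pairwise_disparity(heights, labels=None):
    """Absolute pairwise differences of a univariate trait.

    ``heights`` may be an array or a {taxon: value} mapping; taxa with
    missing (NaN) trait values are dropped with a warning.  Returns
    (matrix, labels).
    """
    if isinstance(heights, dict):
        labels = list(heights)
        vals = np.array([heights[k] for k in labels], dtype=float)
    else:
        vals = np.asarray(heights, dtype=float)
        labels = list(labels) if labels is not None else list(range(vals.size))
    ok = np.isfinite(vals)
    if not ok.all():
        import warnings

        dropped = [l for l, o in zip(labels, ok) if not o]
        warnings.warn(f"dropping taxa with missing trait values: {dropped}")
        vals = vals[ok]
        labels = [l for l, o in zip(labels, ok) if o]
    if vals.size < 3:
        raise ValueError("need at least 3 taxa with trait values")
    D = np.abs(vals[:, None] - vals[None, :])
    return D, labels


def saturation_curve(phylo_dist: np.ndarray, trait_dist: np.ndarray,
                     norm_phylo: float, norm_trait: float,
                     label: str = "") -> SaturationCurve:
    """Running maximum of relative disparity over pairs ordered by relative
    phylogenetic distance; breakpoints are recorded where the maximum
    increases (plus the final pair, closing the support)."""
    if norm_phylo <= 0 or norm_trait <= 0:
        raise ValueError("normalizers must be positive")
    P = np.asarray(phylo_dist, dtype=float)
    T = np.asarray(trait_dist, dtype=float)
    if P.shape != T.shape or P.shape[0] != P.shape[1]:
        raise ValueError("distance matrices must be square and matched")
    iu = np.triu_indices(P.shape[0], k=1)
    x = P[iu] / norm_phylo
    y = T[iu] / norm_trait
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x[0] == x[-1]:
        import warnings

        warnings.warn("all pairwise phylogenetic distances equal; "
                      "degenerate single-point curve")
        return SaturationCurve(x=np.array([x[0]]), y=np.array([y.max()]),
                               label=label)
    run = np.maximum.accumulate(y)
    # last pair at each distinct x (ties share one breakpoint)
    keep = np.r_[x[1:] != x[:-1], True]
    xs, rs = x[keep], run[keep]
    rises = np.r_[True, rs[1:] > rs[:-1]]
    rises[-1] = True  # keep the terminal point so the support is explicit
    return SaturationCurve(x=xs[rises], y=rs[rises], label=label)


def nested_saturation(tree: TimeTree, heights: dict, island_tips,
                      labels: tuple[str, str] = ("island", "nonisland")):
    """Island and nonisland saturation curves from within-set pairs only,
    both normalized by the whole tree's maximum cophenetic distance and
    maximum pairwise disparity."""
    island_tips = set(island_tips)
    nonisland = [t for t in tree.tip_labels if t not in island_tips]
    if len(island_tips) < 3 or len(nonisland) < 3:
        raise ValueError("both island and nonisland sets need >= 3 taxa")
    mrca = tree.mrca(island_tips)
    if set(tree.subtree_tip_labels(mrca)) != island_tips:
        raise ValueError("island set is not monophyletic")
    C = cophenetic_matrix(tree)
    D, dlabels = pairwise_disparity({t: heights[t] for t in tree.tip_labels})
    C = C.loc[dlabels, dlabels].to_numpy()
    norm_p = float(C.max())
    norm_t = float(D.max())
    curves = []
    for name, members in ((labels[0], [t for t in dlabels if t in island_tips]),
                          (labels[1], [t for t in dlabels if t not in island_tips])):
        idx = [dlabels.index(t) for t in members]
        sub = np.ix_(idx, idx)
        curves.append(saturation_curve(C[sub], D[sub], norm_p, norm_t, label=name))
    return tuple(curves)


def jackknife_envelope(tree: TimeTree, heights: dict, island_tips,
                       rounds: int = 1000, drop: float = 0.10, seed: int = 0,
                       grid_size: int = 100):
    """Pointwise 95% bands for the nested curves under jackknife pruning.

    Each round removes floor(drop * n) tips uniformly from the whole tree and
    recomputes both nested curves; rounds that leave a set with fewer than 3
    taxa are redrawn.  Returns (grid, band_island, band_nonisland) with each
    band of shape (2, grid_size) holding the 2.5/97.5 percentiles.
    """
    if not (0.0 <= drop < 1.0):
        raise ValueError("drop must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    island_tips = set(island_tips)
    all_tips = list(tree.tip_labels)
    n_drop = int(math.floor(drop * len(all_tips)))
    grid = np.linspace(0.0, 1.0, grid_size)
    vals_i = np.empty((rounds, grid_size))
    vals_n = np.empty((rounds, grid_size))
    redraws = 0
    for r in range(rounds):
        for _ in range(1000):
            dropped = set(rng.choice(all_tips, size=n_drop, replace=False)) if n_drop else set()
            keep = [t for t in all_tips if t not in dropped]
            kept_isl = [t for t in keep if t in island_tips]
            if len(kept_isl) >= 3 and len(keep) - len(kept_isl) >= 3:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a jackknife sample keeping both sets")
        sub = prune_tips(tree, keep) if dropped else tree
        ci, cn = nested_saturation(sub, heights, set(kept_isl))
        vals_i[r] = ci(grid)
        vals_n[r] = cn(grid)
    band_i = np.percentile(vals_i, [2.5, 97.5], axis=0)
    band_n = np.percentile(vals_n, [2.5, 97.5], axis=0)
    return grid, band_i, band_n


def ks_congruence(curve_a: SaturationCurve, curve_b: SaturationCurve,
                  grid_size: int = 100) -> KSResult:
    """Two-sample, two-sided Kolmogorov-Smirnov congruence test.

    D_max is the largest distance between the empirical distributions of the
    two curves' values sampled at ``grid_size`` evenly spaced points over the
    intersection of their supports.  Because grid samples of a step curve are
    heavily autocorrelated, the p-value is computed with the asymptotic
    two-sample formula using *effective* sample sizes equal to each curve's
    number of breakpoints inside the shared support — the number of actual
    disparity-maximum events behind each curve.  (Treating the grid points as
    independent samples rejects exchangeable curves almost always.)
    """
    lo = max(curve_a.support[0], curve_b.support[0])
    hi = min(curve_a.support[1], curve_b.support[1])
    if hi <= lo:
        raise ValueError("curve supports do not intersect")
    grid = np.linspace(lo, hi, grid_size)
    ya, yb = curve_a(grid), curve_b(grid)
    if np.array_equal(ya, yb):
        return KSResult(d_max=0.0, p_value=1.0, grid_size=grid_size)
    d_max = float(stats.ks_2samp(ya, yb, alternative="two-sided",
                                 method="asymp").statistic)
    na = max(int(np.sum((curve_a.x >= lo) & (curve_a.x <= hi))), 2)
    nb = max(int(np.sum((curve_b.x >= lo) & (curve_b.x <= hi))), 2)
    en = math.sqrt(na * nb / (na + nb))
    p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d_max))
    return KSResult(d_max=d_max, p_value=min(max(p, 0.0), 1.0),
                    grid_size=grid_size)


def overlap_fraction(band_a: np.ndarray, band_b: np.ndarray) -> float:
    """Fraction of grid points where two pointwise 95% bands intersect."""
    band_a = np.asarray(band_a, dtype=float)
    band_b = np.asarray(band_b, dtype=float)
    if band_a.shape != band_b.shape or band_a.shape[0] != 2:
        raise ValueError("bands must both have shape (2, grid)")
    lo = np.maximum(band_a[0], band_b[0])
    hi = np.minimum(band_a[1], band_b[1])
    return float(np.mean(lo <= hi))


def classify_trajectory(curve: SaturationCurve, linear_margin: float = 1.2):
    """Label a curve linear / exponential / logarithmic by least-squares fit.

    Families: y = a + b x; y = a (e^{b x} - 1); y = a ln(1 + b x).  Because a
    running maximum is mildly concave even under neutral (Brownian)
    disparification, the curved families are preferred only when they beat
    the linear fit clearly: the label is "linear" whenever the linear RMSE is
    within ``linear_margin`` times the best family's RMSE.  Returns
    (label, {family: rmse}); "undetermined" with empty fits when the curve
    has fewer than 5 breakpoints.
    """
    x, y = curve.x, curve.y
    if x.size < 5:
        return "undetermined", {}

    def rmse(pred):
        return float(np.sqrt(np.mean((pred - y) ** 2)))

    fits = {}
    b, a = np.polyfit(x, y, 1)
    fits["linear"] = rmse(a + b * x)
    for name, fn, p0 in (
        ("exponential", lambda x, a, b: a * (np.exp(b * x) - 1.0), (0.5, 1.0)),
        ("logarithmic", lambda x, a, b: a * np.log1p(b * x), (0.5, 5.0)),
    ):
        try:
            popt, _ = optimize.curve_fit(
                fn, x, y, p0=p0, bounds=([1e-8, 1e-8], [1e4, 1e4]),
                maxfev=10000)
            fits[name] = rmse(fn(x, *popt))
        except (RuntimeError, ValueError):
            fits[name] = math.inf
    label = min(fits, key=fits.get)
    if label != "linear" and fits["linear"] <= linear_margin * fits[label]:
        label = "linear"
    return label, fits
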