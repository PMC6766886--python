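"""End-to-end orchestration of the four analysis stages.

Given an ultrametric tree, a trait table, and a clade partition, the
pipeline runs

1. diversification — linked vs unlinked (pure-birth or birth-death) models,
   thermodynamic-integration marginal likelihoods, Bayes factors, Bayesian
   model averaging of net diversification per partition set;
2. ancestral history — ER/ARD Mk fits and LRT for the life-history
   character, stochastic character maps, per-direction transition counts,
   plus occupancy maps for the trait stage;
3. trait evolution — the six BM/OU models over the occupancy maps, Hessian
   and failed-model screening, AICc model averaging, parametric bootstrap;
4. trait-space saturation — nested island/nonisland curves, jackknife
   bands, KS congruence, trajectory classification.

Every run is reproducible from a single master seed; all artifacts are
stamped with the seed and a hash of the settings.  Full-scale settings
(1e6 MCMC generations, 1000 life-history maps, 1000 jackknife rounds) are
obtained with ``scale=1``; the default desk scale divides the expensive
loops by 10.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestral, diversification as dv, saturation as sat, traitmodels as tm
from .trees import (
    BACKGROUND,
    CladePartition,
    TimeTree,
    TraitTable,
    parse_newick,
)

__all__ = ["PipelineSettings", "PipelineConfig", "PipelineStageError",
           "run_pipeline", "make_report", "load_config"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineSettings:
    """Stage parameters; full-scale values divided by ``scale``."""

    process: str = "pure-birth"
    mcmc_iterations: int = 1_000_000
    mcmc_thin: int = 1000
    ti_iterations: int = 100_000
    ti_K: int = 10
    burnin: float = 0.10
    n_maps_life: int = 1000
    n_maps_occupancy: int = 100
    n_trait_maps_fitted: int = 100
    n_boot: int = 200
    jackknife_rounds: int = 1000
    jackknife_drop: float = 0.10
    ks_grid: int = 100
    failure_margin: float = 100.0
    n_restarts: int = 3
    scale: float = 0.1

    def scaled(self, value: int, minimum: int) -> int:
        return max(minimum, int(round(value * self.scale)))

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineConfig:
    """File-based run description (the YAML the CLI consumes)."""

    tree_path: str
    traits_path: str
    rho: dict = field(default_factory=dict)  # clade label -> sampling fraction
    island_clade: str = "island"
    settings: PipelineSettings = field(default_factory=PipelineSettings)
    seed: int = 0
    outdir: str | None = None

    def load(self) -> tuple[TimeTree, TraitTable, CladePartition]:
        tree = parse_newick(Path(self.tree_path).read_text())
        traits = TraitTable.from_csv(self.traits_path)
        traits.validate_against(tree)
        sets: dict[str, set] = {}
        for _, row in traits.data.iterrows():
            sets.setdefault(str(row["clade"]), set()).add(row["taxon"])
        partition = CladePartition(sets=sets, rho=dict(self.rho))
        partition.validate_against(tree)
        return tree, traits, partition


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    settings = PipelineSettings(**raw.pop("settings", {}))
    return PipelineConfig(settings=settings, **raw)


# -- stages ----------------------------------------------------------------------


def run_diversification_stage(tree, partition, settings: PipelineSettings,
                              seed: int) -> dict:
    s = settings
    iters = s.scaled(s.mcmc_iterations, 10_000)
    thin = max(1, int(iters / max(1, s.mcmc_iterations // s.mcmc_thin)))
    ti_iters = s.scaled(s.ti_iterations, 5_000)
    models = {
        "linked": dv.DiversificationModelSpec.linked(partition, s.process),
        "unlinked": dv.DiversificationModelSpec.unlinked(partition, s.process),
    }
    traces, lnmls, diagnostics = {}, {}, {}
    for i, (name, spec) in enumerate(models.items()):
        trace = dv.mcmc_sample(tree, partition, spec, iterations=iters,
                               thin=thin, seed=seed + i)
        lam_cols = [c for c in trace.samples.columns if c.startswith("lambda_")]
        ess_vals = {c: dv.ess(trace.post_burnin(s.burnin)[c].to_numpy())
                    for c in lam_cols}
        diagnostics[name] = {"acceptance_rate": trace.acceptance_rate,
                             "ess": ess_vals}
        traces[name] = trace
        lnmls[name] = dv.marginal_likelihood(
            tree, partition, spec, iterations=ti_iters,
            thin=max(1, ti_iters // 200), K=s.ti_K, seed=seed + 100 + i)
    comparison = dv.bayes_factor_classify(lnmls["unlinked"], lnmls["linked"])
    bma = dv.bma_combine(traces, lnmls, partition, burnin=s.burnin,
                         seed=seed + 7)
    summary = {}
    for name in partition.names:
        draws = bma[f"r_{name}"].to_numpy()
        lo, hi = dv.hpd_interval(draws)
        summary[name] = {"r_median": float(np.median(draws)),
                         "r_hpd": (lo, hi)}
    return {"lnml": lnmls, "bf_unlinked_vs_linked": comparison.bf,
            "bf_category": comparison.category, "bma": bma,
            "summary": summary, "diagnostics": diagnostics}


def run_ancestral_stage(tree, traits: TraitTable, partition,
                        settings: PipelineSettings, seed: int) -> dict:
    s = settings
    life = traits.states("life_history", tree)
    fit_er = ancestral.fit_mk(tree, life, "ER")
    fit_ard = ancestral.fit_mk(tree, life, "ARD")
    stat, df, p = ancestral.lrt_er_vs_ard(fit_er, fit_ard)
    chosen = fit_ard if p < 0.05 else fit_er
    n_life = max(20, int(round(s.n_maps_life * s.scale)))
    life_maps = ancestral.stochastic_character_map(tree, life, chosen,
                                                   n_maps=n_life, seed=seed)
    life_summary = ancestral.summarize_maps(life_maps)
    occ = traits.states("occupancy", tree)
    occ_fit = ancestral.fit_mk(tree, occ, "ER")
    n_occ = max(10, int(round(s.n_maps_occupancy * s.scale)))
    occ_maps = ancestral.stochastic_character_map(tree, occ, occ_fit,
                                                  n_maps=n_occ, seed=seed + 1)
    return {
        "fit_er": fit_er, "fit_ard": fit_ard,
        "lrt": {"statistic": stat, "df": df, "p": p},
        "model_used": chosen.constraint,
        "life_maps": life_maps, "life_summary": life_summary,
        "transition_counts": life_summary.change_counts,
        "occupancy_maps": occ_maps,
    }


def run_traits_stage(occupancy_maps, traits: TraitTable, tree,
                     settings: PipelineSettings, seed: int) -> dict:
    s = settings
    heights = traits.heights(tree)
    per_tree = []
    all_fits = []
    regimes = None
    n_fit = min(len(occupancy_maps), max(5, int(round(s.n_trait_maps_fitted * s.scale))))
    for i, painted in enumerate(occupancy_maps[:n_fit]):
        pm = tm.PaintedModel(painted)
        regimes = pm.regimes if regimes is None else regimes
        y = np.array([dict(zip(tree.tip_labels, heights))[t] for t in pm.tip_labels])
        fits = tm.fit_all_models(pm, y, n_restarts=s.n_restarts, seed=seed + i)
        tm.failed_model_screen(fits, s.failure_margin)
        tm.aicc_weights(fits)
        per_tree.append(tm.average_parameters(fits, pm.regimes))
        all_fits.append(fits)
    pooled = tm.average_across_trees(per_tree, regimes)
    # bootstrap the best retained fit on the first map
    first_fits = [f for f in all_fits[0] if f.retained]
    boot = None
    if first_fits:
        best = min(first_fits, key=lambda f: f.aicc)
        n_boot = max(20, int(round(s.n_boot * s.scale)))
        boot = tm.parametric_bootstrap_ci(occupancy_maps[0], best, n_boot,
                                          seed=seed + 99)
        boot["model"] = best.name
    return {"per_tree_averages": per_tree, "pooled": pooled,
            "fits": all_fits, "bootstrap": boot, "regimes": regimes}


def run_tsa_stage(tree, traits: TraitTable, partition,
                  settings: PipelineSettings, seed: int,
                  island_clade: str = "island") -> dict:
    s = settings
    heights = dict(zip(tree.tip_labels, traits.heights(tree)))
    island = partition.sets[island_clade]
    curve_i, curve_n = sat.nested_saturation(tree, heights, island)
    rounds = max(50, int(round(s.jackknife_rounds * s.scale)))
    grid, band_i, band_n = sat.jackknife_envelope(
        tree, heights, island, rounds=rounds, drop=s.jackknife_drop,
        seed=seed, grid_size=s.ks_grid)
    ks = sat.ks_congruence(curve_i, curve_n, grid_size=s.ks_grid)
    return {
        "curve_island": curve_i, "curve_nonisland": curve_n,
        "grid": grid, "band_island": band_i, "band_nonisland": band_n,
        "ks": ks,
        "overlap_fraction": sat.overlap_fraction(band_i, band_n),
        "trajectory_island": sat.classify_trajectory(curve_i)[0],
        "trajectory_nonisland": sat.classify_trajectory(curve_n)[0],
    }


# -- orchestration ---------------------------------------------------------------


def run_pipeline(tree: TimeTree, traits: TraitTable, partition: CladePartition,
                 settings: PipelineSettings | None = None, seed: int = 0,
                 outdir=None, island_clade: str = "island",
                 stages=("diversification", "ancestral", "traits", "tsa")) -> dict:
    """Run the full analysis; returns the result bundle and, if ``outdir`` is
    given, writes summary CSV/JSON artifacts stamped with seed and settings
    hash.  A stage failure halts the run, retaining earlier outputs and
    writing a machine-readable error report."""
    settings = settings or PipelineSettings()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"seed": seed, "settings_hash": settings.hash(),
                     "timings": {}}
    partition.validate_against(tree)
    traits.validate_against(tree)

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            results[name] = fn(*args, **kw)
        except Exception as exc:
            if out is not None:
                (out / "error.json").write_text(json.dumps(
                    {"stage": name, "error": str(exc),
                     "type": type(exc).__name__}, indent=2))
            raise PipelineStageError(name, exc) from exc
        results["timings"][name] = time.perf_counter() - t0

    if "diversification" in stages:
        stage("diversification", run_diversification_stage, tree, partition,
              settings, seed)
    if "ancestral" in stages:
        stage("ancestral", run_ancestral_stage, tree, traits, partition,
              settings, seed + 1000)
    if "traits" in stages:
        occ_maps = results.get("ancestral", {}).get("occupancy_maps")
        if occ_maps is None:
            anc = run_ancestral_stage(tree, traits, partition, settings,
                                      seed + 1000)
            occ_maps = anc["occupancy_maps"]
        stage("traits", run_traits_stage, occ_maps, traits, tree, settings,
              seed + 2000)
    if "tsa" in stages:
        stage("tsa", run_tsa_stage, tree, traits, partition, settings,
              seed + 3000, island_clade)
    if out is not None:
        _write_outputs(results, tree, partition, out, island_clade)
    return results


def _fmt_ci(pair) -> str:
    return f"({pair[0]:.2f}-{pair[1]:.2f})"


def summary_table(results: dict, partition: CladePartition) -> pd.DataFrame:
    """Per-clade summary: crown age, richness sampled, net diversification
    median with 95% HPD, and model-averaged theta/alpha/sigma2."""
    rows = []
    div = results.get("diversification", {})
    pooled = results.get("traits", {}).get("pooled")
    regime_of = {"island": "island", BACKGROUND: "nonisland"}
    for name in partition.names:
        row = {"clade": name, "n_sampled": len(partition.sets[name]),
               "rho": partition.rho[name]}
        if div:
            s = div["summary"][name]
            row["r_median"] = round(s["r_median"], 3)
            row["r_hpd_low"] = round(s["r_hpd"][0], 3)
            row["r_hpd_high"] = round(s["r_hpd"][1], 3)
        if pooled is not None:
            reg = regime_of.get(name, name)
            for p in ("theta", "alpha", "sigma2"):
                info = pooled.get(p, {}).get(reg)
                if info is not None and math.isfinite(info["mean"]):
                    row[p] = round(info["mean"], 3)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(results, tree, partition, out: Path, island_clade) -> None:
    stamp = {"seed": results["seed"], "settings_hash": results["settings_hash"]}
    table = summary_table(results, partition)
    for k, v in stamp.items():
        table[k] = v
    table.to_csv(out / "summary.csv", index=False)
    if "diversification" in results:
        div = results["diversification"]
        div["bma"].to_csv(out / "bma_posterior.csv", index=False)
        (out / "model_comparison.json").write_text(json.dumps({
            "lnml": div["lnml"], "bf_unlinked_vs_linked": div["bf_unlinked_vs_linked"],
            "category": div["bf_category"], **stamp}, indent=2))
    if "ancestral" in results:
        anc = results["ancestral"]
        (out / "transition_counts.json").write_text(json.dumps({
            "counts": {f"{a}->{b}": {"mean": m, "ci95": ci}
                       for (a, b), (m, ci) in anc["transition_counts"].items()},
            "lrt": anc["lrt"], "model_used": anc["model_used"], **stamp},
            indent=2))
    if "tsa" in results:
        tsa = results["tsa"]
        pd.DataFrame({"x": tsa["grid"],
                      "island_lo": tsa["band_island"][0],
                      "island_hi": tsa["band_island"][1],
                      "nonisland_lo": tsa["band_nonisland"][0],
                      "nonisland_hi": tsa["band_nonisland"][1],
                      }).to_csv(out / "saturation_bands.csv", index=False)
        (out / "ks.json").write_text(json.dumps({
            "d_max": tsa["ks"].d_max, "p_value": tsa["ks"].p_value,
            "overlap_fraction": tsa["overlap_fraction"], **stamp}, indent=2))
    try:
        _write_plots(results, out)
    except Exception as exc:  # plotting must never sink a finished run
        (out / "plot_warnings.txt").write_text(f"plotting failed: {exc}\n")
    (out / "report.md").write_text(make_report(results, partition)[0])


def _write_plots(results, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "diversification" in results:
        bma = results["diversification"]["bma"]
        fig, ax = plt.subplots(figsize=(5, 3.2))
        colors = {"island": "firebrick", BACKGROUND: "steelblue"}
        for col in bma.columns:
            if not col.startswith("r_"):
                continue
            name = col[2:]
            ax.hist(bma[col], bins=60, density=True, alpha=0.5,
                    color=colors.get(name), label=name)
        ax.set_xlabel("net diversification r (per Myr)")
        ax.set_ylabel("posterior density")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "rates_density.png", dpi=150)
        plt.close(fig)
    if "tsa" in results:
        tsa = results["tsa"]
        fig, ax = plt.subplots(figsize=(4.2, 4.2))
        grid = tsa["grid"]
        for key, curve_key, color in (("band_island", "curve_island", "firebrick"),
                                      ("band_nonisland", "curve_nonisland",
                                       "steelblue")):
            band = tsa[key]
            curve = tsa[curve_key]
            ax.fill_between(grid, band[0], band[1], alpha=0.25, color=color)
            ax.plot(grid, curve(grid), color=color, label=curve.label or key)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.set_xlabel("relative phylogenetic distance")
        ax.set_ylabel("relative trait disparity")
        ax.set_title(f"D_max = {tsa['ks'].d_max:.2f}, p = {tsa['ks'].p_value:.3f}",
                     fontsize=9)
        ax.legend(frameon=False, loc="lower right")
        fig.tight_layout()
        fig.savefig(out / "saturation_curves.png", dpi=150)
        plt.close(fig)


def make_report(results: dict, partition: CladePartition) -> tuple[str, dict]:
    """Human-readable markdown summary plus a JSON-serializable dict."""
    lines = ["# islandrad pipeline report", ""]
    js: dict = {"seed": results.get("seed"),
                "settings_hash": results.get("settings_hash")}
    lines.append(f"seed: {js['seed']}; settings hash: {js['settings_hash']}")
    lines.append("")
    lines.append("## Species diversification")
    if "diversification" in results:
        div = results["diversification"]
        bf = div["bf_unlinked_vs_linked"]
        lines.append(
            f"2lnBF (unlinked vs linked) = {bf:.2f} — {div['bf_category']} "
            f"support for {'unlinked' if bf >= 0 else 'linked'} rates.")
        for name, s in div["summary"].items():
            lines.append(f"- {name}: net diversification r = "
                         f"{s['r_median']:.2f} {_fmt_ci(s['r_hpd'])} per Myr")
        js["diversification"] = {
            "bf": bf, "category": div["bf_category"],
            "summary": {k: {"r_median": v["r_median"],
                            "r_hpd": list(v["r_hpd"])}
                        for k, v in div["summary"].items()}}
    else:
        lines.append("not run")
    lines.append("")
    lines.append("## Origins of the derived life history")
    if "ancestral" in results:
        anc = results["ancestral"]
        lines.append(f"LRT ER vs ARD: statistic {anc['lrt']['statistic']:.2f}, "
                     f"p = {anc['lrt']['p']:.3f}; maps drawn under "
                     f"{anc['model_used']}.")
        for (a, b), (m, ci) in anc["transition_counts"].items():
            lines.append(f"- {a} -> {b}: {m:.2f} "
                         f"(95% credible interval: {ci[0]:.2f}-{ci[1]:.2f}) events")
        js["ancestral"] = {"lrt": anc["lrt"], "model_used": anc["model_used"],
                           "counts": {f"{a}->{b}": [m, list(ci)] for (a, b), (m, ci)
                                      in anc["transition_counts"].items()}}
    else:
        lines.append("not run")
    lines.append("")
    lines.append("## Mode and rate of disparification")
    if "traits" in results:
        pooled = results["traits"]["pooled"]
        for p in ("theta", "alpha", "sigma2"):
            vals = {r: info["mean"] for r, info in pooled[p].items()
                    if math.isfinite(info["mean"])}
            if vals:
                pretty = ", ".join(f"{r}: {v:.2f}" for r, v in vals.items())
                lines.append(f"- model-averaged {p}: {pretty}")
        boot = results["traits"]["bootstrap"]
        if boot is not None:
            lines.append(f"- bootstrap ({boot['model']}): "
                         + "; ".join(f"{k} 95% CI {_fmt_ci(v)}"
                                     for k, v in sorted(boot["ci"].items())))
        js["traits"] = {"pooled": {p: {r: info["mean"] for r, info in d.items()}
                                   for p, d in pooled.items() if d}}
    else:
        lines.append("not run")
    lines.append("")
    lines.append("## Trait-space saturation")
    if "tsa" in results:
        tsa = results["tsa"]
        lines.append(f"KS congruence: D_max = {tsa['ks'].d_max:.3f}, "
                     f"p = {tsa['ks'].p_value:.4f}; band overlap "
                     f"{tsa['overlap_fraction']:.2f}.")
        lines.append(f"Trajectories: island {tsa['trajectory_island']}, "
                     f"nonisland {tsa['trajectory_nonisland']}.")
        js["tsa"] = {"d_max": tsa["ks"].d_max, "p": tsa["ks"].p_value,
                     "overlap_fraction": tsa["overlap_fraction"]}
    else:
        lines.append("not run")
    lines.append("")
    return "\n".join(lines), js
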