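"""Six-model continuous-trait analysis on a regime-painted tree.

Samples island/nonisland occupancy maps, fits the six BM/OU models to log
plant height on each, screens out poorly estimated fits (Hessian
eigenvalues, spurious likelihoods), and reports AICc weights and the
model-averaged phenotypic rate sigma^2 per regime.
"""

from islandrad import ancestral as anc
from islandrad import simulate as sim
from islandrad import traitmodels as tm

data = sim.make_scenario(sim.ScenarioSpec(seed=1))
occ = data.traits.states("occupancy", data.tree)
occ_fit = anc.fit_mk(data.tree, occ, "ER")
maps = anc.stochastic_character_map(data.tree, occ, occ_fit, n_maps=5, seed=3)
heights = data.traits.heights(data.tree)

per_tree = []
for i, painted in enumerate(maps):
    pm = tm.PaintedModel(painted)
    y = [dict(zip(data.tree.tip_labels, heights))[t] for t in pm.tip_labels]
    fits = tm.fit_all_models(pm, y, n_restarts=2, seed=i)
    tm.aicc_weights(fits)
    if i == 0:
        print(f"{'model':6s} {'lnL':>9s} {'AICc':>9s} {'dAICc':>7s} "
              f"{'w':>6s}  status")
        for f in sorted(fits, key=lambda f: f.aicc if f.retained else 1e9):
            print(f"{f.name:6s} {f.lnl:9.2f} {f.aicc:9.2f} "
                  f"{f.delta_aicc:7.2f} {f.weight:6.3f}  {f.status}")
    per_tree.append(tm.average_parameters(fits, pm.regimes))

pooled = tm.average_across_trees(per_tree, ["island", "nonisland"])
print()
for regime in ("island", "nonisland"):
    print(f"model-averaged sigma^2 [{regime:9s}] = "
          f"{pooled['sigma2'][regime]['mean']:.2f} (log_e cm)^2 per Myr")
print()
print("Interpretation: the island regime's averaged phenotypic rate exceeds")
print("the background's — growth form disparifies faster on the island,")
print("matching the doubled island rate used to generate the data.")
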