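"""Nested trait-space saturation analysis with jackknife and KS test.

Builds the island and nonisland saturation curves (running maxima of
relative pairwise height disparity against relative cophenetic distance,
both normalized by whole-tree maxima), wraps them in jackknife 95% bands,
and tests curve congruence with the effective-sample-size-calibrated
Kolmogorov-Smirnov test.
"""

from islandrad import saturation as sat
from islandrad import simulate as sim

data = sim.make_scenario(sim.ScenarioSpec(seed=1))
heights = dict(zip(data.tree.tip_labels, data.traits.heights(data.tree)))
island = data.partition.sets["island"]

curve_i, curve_n = sat.nested_saturation(data.tree, heights, island)
print(f"island    curve: support x <= {curve_i.support[1]:.2f}, "
      f"max y = {curve_i.y[-1]:.2f} ({curve_i.x.size} breakpoints)")
print(f"nonisland curve: support x <= {curve_n.support[1]:.2f}, "
      f"max y = {curve_n.y[-1]:.2f} ({curve_n.x.size} breakpoints)")

grid, band_i, band_n = sat.jackknife_envelope(data.tree, heights, island,
                                              rounds=200, drop=0.10, seed=4)
ks = sat.ks_congruence(curve_i, curve_n)
print(f"KS congruence: D_max = {ks.d_max:.2f}, p = {ks.p_value:.4f}")
print(f"95% band overlap fraction: {sat.overlap_fraction(band_i, band_n):.2f}")
print(f"trajectories: island {sat.classify_trajectory(curve_i)[0]}, "
      f"nonisland {sat.classify_trajectory(curve_n)[0]}")
print()
print("Interpretation: the island curve reaches high relative disparity")
print("within a small fraction of the tree's divergence depth — trait space")
print("saturates early, the signature of accelerated disparification.")
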