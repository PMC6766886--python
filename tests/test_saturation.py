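"""Saturation curves, jackknife envelopes, KS congruence, classification."""

import math

import numpy as np
import pytest

from islandrad import saturation as sat
from islandrad import simulate as sim
from islandrad import trees as tr


class TestPairwiseDisparity:
    def test_hand_example(self):
        D, labels = sat.pairwise_disparity({"a": 0.0, "b": 1.0, "c": 3.0})
        assert D[labels.index("a"), labels.index("b")] == 1.0
        assert D[labels.index("a"), labels.index("c")] == 3.0
        assert D[labels.index("b"), labels.index("c")] == 2.0

    def test_constant_trait_zero_matrix(self):
        D, _ = sat.pairwise_disparity({"a": 2.0, "b": 2.0, "c": 2.0})
        assert np.all(D == 0.0)

    def test_translation_invariance(self):
        h = {"a": 0.3, "b": 1.7, "c": -0.4, "d": 2.2}
        D1, _ = sat.pairwise_disparity(h)
        D2, _ = sat.pairwise_disparity({k: v + 10 for k, v in h.items()})
        assert np.allclose(D1, D2)

    def test_missing_values_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            D, labels = sat.pairwise_disparity(
                {"a": 0.0, "b": 1.0, "c": 3.0, "d": float("nan")})
        assert "d" not in labels


class TestSaturationCurve:
    def test_whole_tree_curve_terminates_at_one_one(self, yule50):
        rng = np.random.default_rng(0)
        heights = {t: rng.normal() for t in yule50.tip_labels}
        C = tr.cophenetic_matrix(yule50).to_numpy()
        D, _ = sat.pairwise_disparity(heights)
        curve = sat.saturation_curve(C, D, C.max(), D.max())
        assert curve.x[-1] == pytest.approx(1.0)
        assert curve.y[-1] == pytest.approx(1.0)

    def test_monotone_and_bounded(self, yule50):
        rng = np.random.default_rng(1)
        heights = {t: rng.normal() for t in yule50.tip_labels}
        C = tr.cophenetic_matrix(yule50).to_numpy()
        D, _ = sat.pairwise_disparity(heights)
        curve = sat.saturation_curve(C, D, C.max(), D.max())
        assert np.all(np.diff(curve.x) > 0)
        assert np.all(np.diff(curve.y) >= 0)
        assert curve.y[-1] <= 1.0 + 1e-12

    def test_rank_agreement_tracks_diagonal(self):
        # construct distances in perfect rank agreement
        n = 12
        vals = np.linspace(0, 1, n)
        P = np.abs(vals[:, None] - vals[None, :])
        curve = sat.saturation_curve(P, P, P.max(), P.max())
        assert np.corrcoef(curve.x, curve.y)[0, 1] > 0.99
        assert np.abs(curve.x - curve.y).max() < 1e-12

    def test_bm_curves_nearer_diagonal_than_strong_ou(self):
        """BM traits track the diagonal; strong-pull OU saturates early."""
        dev_bm, dev_ou = [], []
        for r in range(20):
            tree = sim.simulate_bd_tree(1.0, 0.0, 60, seed=300 + r)
            painted, _ = sim.simulate_mk_history(tree, np.zeros((2, 2)),
                                                 ["0", "1"], "0", seed=r)
            C = tr.cophenetic_matrix(tree).to_numpy()
            grid = np.linspace(0.05, 1.0, 50)
            for name, params, out in (
                ("BM1", {"x0": 0.0, "sigma2": 1.0}, dev_bm),
                ("OU1", {"alpha": 5.0, "sigma2": 1.0, "theta": 0.0}, dev_ou),
            ):
                y = sim.simulate_continuous_trait(painted, name, params,
                                                  seed=1000 + r)
                D, _ = sat.pairwise_disparity(dict(zip(tree.tip_labels, y)))
                curve = sat.saturation_curve(C, D, C.max(), D.max())
                out.append(np.mean(np.abs(curve(grid) - grid)))
        assert np.mean(dev_bm) < np.mean(dev_ou)

    def test_degenerate_distances_warn(self):
        P = np.ones((4, 4)) - np.eye(4)
        T = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
        with pytest.warns(UserWarning, match="degenerate"):
            curve = sat.saturation_curve(P, T, 1.0, 3.0)
        assert curve.x.size == 1


class TestNestedSaturation:
    def test_island_curve_support_bounded_by_clade_depth(self, island_scenario):
        data = island_scenario
        heights = dict(zip(data.tree.tip_labels,
                           data.traits.heights(data.tree)))
        ci, cn = sat.nested_saturation(data.tree, heights,
                                       data.partition.sets["island"])
        island_max = 2 * data.tree.age(
            data.tree.mrca(data.partition.sets["island"]))
        tree_max = tr.cophenetic_matrix(data.tree).to_numpy().max()
        assert ci.support[1] == pytest.approx(island_max / tree_max, rel=1e-9)
        assert cn.support[1] <= 1.0 + 1e-12

    def test_near_whole_tree_subset_recovers_whole_curve(self, yule50):
        rng = np.random.default_rng(2)
        heights = {t: rng.normal() for t in yule50.tip_labels}
        # the "island" set is a clade covering most of the tree
        crown_child = max(yule50.root.children,
                          key=lambda c: len(yule50.subtree_tip_labels(c)))
        big = set(yule50.subtree_tip_labels(crown_child))
        small = set(yule50.tip_labels) - big
        if len(small) < 3:  # ensure both sets valid for this seed
            pytest.skip("degenerate crown split")
        ci, cn = sat.nested_saturation(yule50, heights, big)
        C = tr.cophenetic_matrix(yule50).to_numpy()
        D, _ = sat.pairwise_disparity(heights)
        whole = sat.saturation_curve(C, D, C.max(), D.max())
        grid = np.linspace(*ci.support, 30)
        assert np.mean(np.abs(ci(grid) - whole(grid))) < 0.2

    def test_non_monophyletic_island_rejected(self, yule50):
        rng = np.random.default_rng(3)
        heights = {t: rng.normal() for t in yule50.tip_labels}
        with pytest.raises(ValueError, match="monophyletic"):
            sat.nested_saturation(yule50, heights, set(yule50.tip_labels[::2]))

    def test_small_set_rejected(self, island_scenario):
        data = island_scenario
        heights = dict(zip(data.tree.tip_labels,
                           data.traits.heights(data.tree)))
        two = set(list(data.partition.sets["island"])[:2])
        with pytest.raises(ValueError):
            sat.nested_saturation(data.tree, heights, two)

    def test_fast_island_fills_trait_space_early(self):
        """With doubled island rate the island curve reaches higher relative
        disparity at small relative distances than the nonisland curve."""
        wins = 0
        reps = 10
        for r in range(reps):
            data = sim.make_scenario(sim.ScenarioSpec(seed=700 + r))
            heights = dict(zip(data.tree.tip_labels,
                               data.traits.heights(data.tree)))
            ci, cn = sat.nested_saturation(data.tree, heights,
                                           data.partition.sets["island"])
            x_probe = ci.support[1]  # edge of the island support
            wins += ci(x_probe)[0] > cn(x_probe)[0]
        assert wins >= 0.8 * reps


class TestJackknife:
    def test_zero_drop_zero_width(self, island_scenario):
        data = island_scenario
        heights = dict(zip(data.tree.tip_labels,
                           data.traits.heights(data.tree)))
        grid, bi, bn = sat.jackknife_envelope(
            data.tree, heights, data.partition.sets["island"], rounds=5,
            drop=0.0, seed=0)
        assert np.allclose(bi[0], bi[1])
        assert np.allclose(bn[0], bn[1])

    def test_band_contains_full_data_curve(self, island_scenario):
        data = island_scenario
        heights = dict(zip(data.tree.tip_labels,
                           data.traits.heights(data.tree)))
        ci, cn = sat.nested_saturation(data.tree, heights,
                                       data.partition.sets["island"])
        grid, bi, bn = sat.jackknife_envelope(
            data.tree, heights, data.partition.sets["island"], rounds=200,
            drop=0.10, seed=1)
        on_support = (grid >= cn.support[0]) & (grid <= cn.support[1])
        y = cn(grid[on_support])
        inside = (y >= bn[0][on_support] - 1e-9) & (y <= bn[1][on_support] + 1e-9)
        assert inside.mean() >= 0.9

    def test_deterministic_under_seed(self, island_scenario):
        data = island_scenario
        heights = dict(zip(data.tree.tip_labels,
                           data.traits.heights(data.tree)))
        a = sat.jackknife_envelope(data.tree, heights,
                                   data.partition.sets["island"], rounds=20,
                                   seed=3)
        b = sat.jackknife_envelope(data.tree, heights,
                                   data.partition.sets["island"], rounds=20,
                                   seed=3)
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[2], b[2])


class TestKsCongruence:
    def test_identical_curves(self):
        c = sat.SaturationCurve(x=np.array([0.1, 0.5, 1.0]),
                                y=np.array([0.2, 0.6, 1.0]))
        res = sat.ks_congruence(c, c)
        assert res.d_max == 0.0 and res.p_value == 1.0

    def test_maximal_separation(self):
        x = np.linspace(0.05, 1.0, 30)
        a = sat.SaturationCurve(x=x, y=np.linspace(0.9, 1.0, 30))
        b = sat.SaturationCurve(x=x, y=np.linspace(0.0, 0.1, 30))
        res = sat.ks_congruence(a, b)
        assert res.d_max == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_size_control_on_exchangeable_split(self):
        """Randomly splitting one clade's taxa in two gives near-nominal
        rejection: the p calibration respects the information actually in
        the curves."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 20
        for r in range(reps):
            tree = sim.simulate_bd_tree(0.5, 0.0, 60, seed=8000 + r)
            painted, _ = sim.simulate_mk_history(tree, np.zeros((2, 2)),
                                                 ["0", "1"], "0", seed=r)
            y = sim.simulate_continuous_trait(painted, "BM1",
                                              {"x0": 0.0, "sigma2": 1.0},
                                              seed=100 + r)
            C = tr.cophenetic_matrix(tree).to_numpy()
            D, _ = sat.pairwise_disparity(dict(zip(tree.tip_labels, y)))
            idx = rng.permutation(60)
            a, b = sorted(idx[:30]), sorted(idx[30:])
            ca = sat.saturation_curve(C[np.ix_(a, a)], D[np.ix_(a, a)],
                                      C.max(), D.max())
            cb = sat.saturation_curve(C[np.ix_(b, b)], D[np.ix_(b, b)],
                                      C.max(), D.max())
            rejections += sat.ks_congruence(ca, cb).p_value < 0.05
        assert rejections / reps <= 0.30

    def test_disjoint_supports_rejected(self):
        a = sat.SaturationCurve(x=np.array([0.1, 0.2]), y=np.array([0.5, 0.6]))
        b = sat.SaturationCurve(x=np.array([0.8, 0.9]), y=np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            sat.ks_congruence(a, b)


class TestOverlapFraction:
    def test_identical_bands_full_overlap(self):
        band = np.vstack([np.zeros(50), np.ones(50)])
        assert sat.overlap_fraction(band, band) == 1.0

    def test_disjoint_bands_zero(self):
        a = np.vstack([np.zeros(50), np.full(50, 0.2)])
        b = np.vstack([np.full(50, 0.5), np.ones(50)])
        assert sat.overlap_fraction(a, b) == 0.0

    def test_monotone_in_band_width(self):
        rng = np.random.default_rng(0)
        mid_a, mid_b = 0.3 + 0.1 * rng.random(50), 0.6 + 0.1 * rng.random(50)
        for w1, w2 in [(0.05, 0.2), (0.1, 0.3)]:
            narrow = sat.overlap_fraction(np.vstack([mid_a - w1, mid_a + w1]),
                                          np.vstack([mid_b - w1, mid_b + w1]))
            wide = sat.overlap_fraction(np.vstack([mid_a - w2, mid_a + w2]),
                                        np.vstack([mid_b - w2, mid_b + w2]))
            assert wide >= narrow


class TestClassify:
    def test_exact_diagonal_linear(self):
        x = np.linspace(0.1, 1.0, 20)
        label, fits = sat.classify_trajectory(sat.SaturationCurve(x=x, y=x))
        assert label == "linear"

    def test_logarithmic_constructed(self):
        x = np.linspace(0.05, 1.0, 25)
        y = np.log1p(9 * x) / math.log(10)
        label, _ = sat.classify_trajectory(sat.SaturationCurve(x=x, y=y))
        assert label == "logarithmic"

    def test_exponential_constructed(self):
        x = np.linspace(0.05, 1.0, 25)
        y = 0.2 * (np.exp(1.8 * x) - 1.0)
        label, _ = sat.classify_trajectory(sat.SaturationCurve(x=x, y=y))
        assert label == "exponential"

    def test_too_few_breakpoints_undetermined(self):
        c = sat.SaturationCurve(x=np.array([0.2, 0.9]), y=np.array([0.1, 0.8]))
        label, fits = sat.classify_trajectory(c)
        assert label == "undetermined" and fits == {}

    def test_bm_labelled_linear_more_often_than_strong_ou(self):
        labels = {"BM1": [], "OU1": []}
        for r in range(15):
            tree = sim.simulate_bd_tree(1.0, 0.0, 50, seed=900 + r)
            painted, _ = sim.simulate_mk_history(tree, np.zeros((2, 2)),
                                                 ["0", "1"], "0", seed=r)
            C = tr.cophenetic_matrix(tree).to_numpy()
            for name, params in (("BM1", {"x0": 0.0, "sigma2": 1.0}),
                                 ("OU1", {"alpha": 5.0, "sigma2": 1.0,
                                          "theta": 0.0})):
                y = sim.simulate_continuous_trait(painted, name, params,
                                                  seed=2000 + r)
                D, _ = sat.pairwise_disparity(dict(zip(tree.tip_labels, y)))
                curve = sat.saturation_curve(C, D, C.max(), D.max())
                labels[name].append(sat.classify_trajectory(curve)[0])
        bm_linear = labels["BM1"].count("linear")
        ou_linear = labels["OU1"].count("linear")
        assert bm_linear > ou_linear
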