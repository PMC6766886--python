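import numpy as np
import pytest

from islandrad import simulate as sim
from islandrad import trees as tr


@pytest.fixture
def three_tip_tree():
    return tr.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_map():
    return tr.parse_simmap_newick("((A:{0,1},B:{0,1}):{0,1},C:{0,2});")


@pytest.fixture(scope="session")
def yule50():
    """A 50-tip pure-birth tree reused across tests."""
    return sim.simulate_bd_tree(0.5, 0.0, 50, seed=42)


@pytest.fixture(scope="session")
def island_scenario():
    """Default island scenario (90 tips, island clade of 60)."""
    return sim.make_scenario(sim.ScenarioSpec(seed=11))


@pytest.fixture(scope="session")
def lrt_type_i_rate():
    """Rejection rate of the ER-vs-ARD LRT at alpha=0.05 over 200 histories
    simulated under ER truth (computed once per session)."""
    from islandrad import ancestral as anc

    tree = sim.simulate_bd_tree(1.0, 0.0, 80, seed=17)
    q = 0.4
    Q = np.array([[-q, q], [q, -q]])
    rejections = n_done = 0
    for r in range(200):
        _, tips = sim.simulate_mk_history(tree, Q, ["h", "w"], "h",
                                          seed=5000 + r)
        if len(set(tips.values())) < 2:
            continue
        er = anc.fit_mk(tree, tips, "ER")
        ard = anc.fit_mk(tree, tips, "ARD", n_restarts=1)
        _, _, p = anc.lrt_er_vs_ard(er, ard)
        n_done += 1
        rejections += p < 0.05
    return rejections / n_done


@pytest.fixture(scope="session")
def oum_recovery():
    """Model selection and optimum recovery under a two-optimum OU truth
    (theta = 0.5/2.0, alpha = 1, sigma2 = 1) on a 200-tip painted tree.

    Returns (fraction of replicates where the generating OUM model ranks in
    the AICc top 2 among the six models, median absolute error of the
    regime-1 optimum).  Computed once per session; reduced replicate count.
    """
    from islandrad import traitmodels as tm

    painted = random_painted(200, seed=0, q=0.15)
    pm = tm.PaintedModel(painted)
    truth = {"alpha": 1.0, "sigma2": 1.0, "theta": {"0": 0.5, "1": 2.0}}
    reps = 12
    top2 = 0
    theta_err = []
    for r in range(reps):
        y = sim.simulate_continuous_trait(painted, "OUM", truth, seed=100 + r)
        fits = [tm.fit_model(pm, y, name, n_restarts=2, compute_hessian=False,
                             seed=r)
                for name in tm.MODEL_NAMES]
        tm.aicc_weights(fits)
        ranked = sorted(fits, key=lambda f: f.aicc)
        top2 += any(f.name == "OUM" for f in ranked[:2])
        oum = next(f for f in fits if f.name == "OUM")
        theta_err.append(abs(oum.params["theta"]["1"] - 2.0))
    return top2 / reps, float(np.median(theta_err))


@pytest.fixture(scope="session")
def oum_coverage():
    """Parametric-bootstrap CI coverage of the regime optima under OUM truth
    (reduced replicates/boots).  Returns the fraction of replicates whose
    95% CI for the regime-1 optimum covers the truth."""
    from islandrad import traitmodels as tm

    painted = random_painted(150, seed=4, q=0.15)
    pm = tm.PaintedModel(painted)
    truth = {"alpha": 1.0, "sigma2": 1.0, "theta": {"0": 0.5, "1": 2.0}}
    reps, covered = 10, 0
    for r in range(reps):
        y = sim.simulate_continuous_trait(painted, "OUM", truth, seed=500 + r)
        fit = tm.fit_model(pm, y, "OUM", n_restarts=1, compute_hessian=False,
                           seed=r, start=truth)
        out = tm.parametric_bootstrap_ci(painted, fit, n_boot=40, seed=r,
                                         n_restarts=1)
        lo, hi = out["ci"]["theta[1]"]
        covered += lo <= 2.0 <= hi
    return covered / reps


def random_painted(n_tips: int, seed: int, q: float = 0.3):
    """Random tree with a random two-state painting (helper, not a fixture)."""
    tree = sim.simulate_bd_tree(1.0, 0.0, n_tips, seed=seed)
    Q = np.array([[-q, q], [q, -q]])
    painted, _ = sim.simulate_mk_history(tree, Q, ["0", "1"], "0", seed=seed + 1)
    return painted
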