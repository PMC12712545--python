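"""Planning units, the three-term objective, and the annealer vs an
exhaustive-enumeration oracle."""

import numpy as np
import pytest

from gapscape import prioritizer as pz
from gapscape.core_io import Grid


def toy_units(costs, amounts, boundary=None, outer=None, reserved=None,
              names=None):
    """Hand-built PlanningUnitSet from plain arrays."""
    costs = np.asarray(costs, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    n = len(costs)
    nbrs = [[] for _ in range(n)]
    lens = [[] for _ in range(n)]
    for (i, j), L in (boundary or {}).items():
        nbrs[i].append(j)
        lens[i].append(L)
        nbrs[j].append(i)
        lens[j].append(L)
    return pz.PlanningUnitSet(
        ids=np.arange(n), costs=costs,
        reserved=(np.zeros(n, bool) if reserved is None
                  else np.asarray(reserved, bool)),
        amounts=amounts,
        feature_names=names or [f"f{k}" for k in range(amounts.shape[1])],
        neighbors=[np.array(x, dtype=int) for x in nbrs],
        shared_lengths=[np.array(x, dtype=float) for x in lens],
        outer=(np.zeros(n) if outer is None else np.asarray(outer, float)))


def enumerate_optimum(pu, ft, blm):
    """Independent 2^N oracle: vectorized evaluation of every portfolio."""
    n = pu.n
    base = pz.base_penalties(pu, ft)
    bits = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
    bits[:, pu.reserved] = True
    bits = np.unique(bits, axis=0)
    cost = bits @ pu.costs
    held = bits @ pu.amounts
    short = np.maximum(0.0, (ft.targets - held) / np.where(ft.targets > 0,
                                                           ft.targets, 1.0))
    short[:, ft.targets <= 0] = 0.0
    penalty = short @ (ft.spf * base)
    boundary = bits @ pu.outer
    for i in range(n):
        for j, L in zip(pu.neighbors[i], pu.shared_lengths[i]):
            if i < j:
                boundary += L * (bits[:, i] != bits[:, j])
    values = cost + blm * boundary + penalty
    k = int(np.argmin(values))
    return float(values[k]), bits[k]


# ---------------------------------------------------------------------------
# build_units
# ---------------------------------------------------------------------------

def test_grid_block_units_geometry():
    hdi = Grid(values=np.zeros((4, 4)), cell_size_m=1000.0)
    reserves = hdi.like(np.zeros((4, 4), bool))
    pu = pz.build_units(hdi, {}, reserves, block_size=2)
    assert pu.n == 4
    bm = pu.boundary_matrix()
    # each orthogonal neighbour pair shares 2 km of boundary
    assert all(L == pytest.approx(2.0) for L in bm.values())
    assert len(bm) == 4
    # outer perimeter: each corner block exposes 2+2 km
    np.testing.assert_allclose(pu.outer, 4.0)


def test_unit_costs_are_mean_hdi():
    vals = np.arange(16, dtype=float).reshape(4, 4)
    hdi = Grid(values=vals)
    pu = pz.build_units(hdi, {}, hdi.like(np.zeros((4, 4), bool)), 2)
    assert pu.costs[0] == pytest.approx(vals[:2, :2].mean())


def test_feature_amounts_conserved():
    rng = np.random.default_rng(1)
    hdi = Grid(values=rng.random((10, 10)))
    mask = hdi.like(rng.random((10, 10)) < 0.4)
    reserves = hdi.like(np.zeros((10, 10), bool))
    pu = pz.build_units(hdi, {"f": mask}, reserves, block_size=5)
    assert pu.amounts.sum() == pytest.approx(mask.values.sum() * 1.0)
    full = hdi.like(np.zeros((10, 10), bool))
    full.values[:5, :5] = True
    pu2 = pz.build_units(hdi, {"f": full}, reserves, 5)
    np.testing.assert_allclose(pu2.amounts[:, 0], [25.0, 0, 0, 0])


def test_reserve_overlap_flags_units():
    hdi = Grid(values=np.zeros((4, 4)))
    res = hdi.like(np.zeros((4, 4), bool))
    res.values[:2, :2] = True  # unit 0 fully covered
    pu = pz.build_units(hdi, {}, res, 2)
    np.testing.assert_array_equal(pu.reserved, [True, False, False, False])


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def four_unit_toy():
    pu = toy_units(costs=[1.0, 2.0, 3.0, 4.0],
                   amounts=[[10.0], [5.0], [0.0], [20.0]],
                   boundary={(0, 1): 2.0, (1, 2): 1.0, (2, 3): 2.0},
                   outer=[4.0, 3.0, 3.0, 4.0])
    ft = pz.FeatureTargets(["f0"], targets=np.array([15.0]),
                           spf=np.array([10.0]))
    return pu, ft


def test_empty_selection_is_pure_penalty():
    pu, ft = four_unit_toy()
    base = pz.base_penalties(pu, ft)
    # greedy fill: unit 0 (cost/amount 0.1) then unit 3 (0.2) -> cost 1+4
    assert base[0] == pytest.approx(5.0)
    sol = pz.objective(np.zeros(4, bool), pu, ft, blm=1.0)
    assert sol.value == pytest.approx(10.0 * 5.0)
    assert sol.cost_term == 0 and sol.boundary_term == 0


def test_full_selection_no_penalty_outer_boundary():
    pu, ft = four_unit_toy()
    sol = pz.objective(np.ones(4, bool), pu, ft, blm=0.5)
    assert sol.penalty_term == 0
    assert sol.cost_term == pytest.approx(10.0)
    assert sol.boundary_term == pytest.approx(0.5 * 14.0)  # outer edges only


def test_hand_arithmetic_three_selections():
    pu, ft = four_unit_toy()
    base = pz.base_penalties(pu, ft)[0]
    # selection {0}: cost 1, boundary outer 4 + shared 2, shortfall (15-10)/15
    sol = pz.objective(np.array([1, 0, 0, 0], bool), pu, ft, blm=1.0)
    assert sol.value == pytest.approx(1 + 6 + 10 * base * (5 / 15))
    # selection {0,1}: cost 3, boundary 4+3+1(shared with 2), held 15 -> pen 0
    sol = pz.objective(np.array([1, 1, 0, 0], bool), pu, ft, blm=1.0)
    assert sol.value == pytest.approx(3 + 8)
    # selection {3}: cost 4, boundary 4+2, held 20 -> pen 0
    sol = pz.objective(np.array([0, 0, 0, 1], bool), pu, ft, blm=1.0)
    assert sol.value == pytest.approx(4 + 6)


def test_objective_terms_nonnegative_and_additive():
    rng = np.random.default_rng(2)
    pu, ft = four_unit_toy()
    for _ in range(20):
        sel = rng.random(4) < 0.5
        sol = pz.objective(sel, pu, ft, blm=0.7)
        assert sol.cost_term >= 0 and sol.boundary_term >= 0
        assert sol.penalty_term >= 0
        assert sol.value == pytest.approx(
            sol.cost_term + sol.boundary_term + sol.penalty_term)


def test_zero_target_has_no_penalty():
    pu = toy_units([1.0, 1.0], [[0.0], [0.0]])
    ft = pz.FeatureTargets(["f0"], np.array([0.0]), np.array([5.0]))
    sol = pz.objective(np.zeros(2, bool), pu, ft, 0.0)
    assert sol.penalty_term == 0


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------

def random_instance(rng, n_units=None, n_features=None, with_reserved=False):
    n = n_units or int(rng.integers(6, 16))
    F = n_features or int(rng.integers(2, 4))
    costs = rng.uniform(0.5, 3.0, n)
    amounts = np.where(rng.random((n, F)) < 0.5, 0.0,
                       rng.uniform(1.0, 10.0, (n, F)))
    boundary = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                boundary[(i, j)] = float(rng.uniform(0.5, 2.0))
    outer = rng.uniform(0.0, 2.0, n)
    reserved = (rng.random(n) < 0.15) if with_reserved else None
    pu = toy_units(costs, amounts, boundary, outer, reserved)
    ft = pz.FeatureTargets([f"f{k}" for k in range(F)],
                           targets=0.3 * amounts.sum(axis=0),
                           spf=rng.uniform(2.0, 8.0, F))
    return pu, ft


def test_single_cheap_unit_solution():
    """One feature coverable by one cheap unit: the annealer finds it."""
    pu = toy_units(costs=[0.5, 5.0, 5.0, 5.0],
                   amounts=[[10.0], [2.0], [2.0], [1.0]])
    ft = pz.FeatureTargets(["f0"], np.array([8.0]), np.array([50.0]))
    sol = pz.anneal(pu, ft, pz.SAParams(blm=0.0, iterations=500, seed=3))
    np.testing.assert_array_equal(sol.selected, [True, False, False, False])
    # exhaustive confirmation over all 16 portfolios
    best_val, best_sel = enumerate_optimum(pu, ft, 0.0)
    np.testing.assert_array_equal(sol.selected, best_sel)


def test_reserved_units_always_selected():
    rng = np.random.default_rng(5)
    pu, ft = random_instance(rng, with_reserved=True)
    pu.reserved[0] = True
    sol = pz.anneal(pu, ft, pz.SAParams(iterations=300, seed=1))
    assert sol.selected[pu.reserved].all()


def test_annealer_matches_enumeration_on_small_instances():
    """Best-of-multiple-seeds lands within 2% of the 2^N optimum."""
    rng = np.random.default_rng(7)
    hits = 0
    trials = 30
    for _ in range(trials):
        pu, ft = random_instance(rng, n_units=int(rng.integers(6, 13)))
        opt, _ = enumerate_optimum(pu, ft, blm=0.05)
        best = min(
            pz.anneal(pu, ft, pz.SAParams(blm=0.05, iterations=300, seed=s)).value
            for s in range(8))
        if best <= 1.02 * opt + 1e-9:
            hits += 1
    assert hits >= int(0.95 * trials)


def test_meeting_targets_zeroes_penalty():
    rng = np.random.default_rng(9)
    pu, ft = random_instance(rng)
    sol = pz.objective(np.ones(pu.n, bool), pu, ft, 0.0)
    assert sol.penalty_term == 0.0


def test_ssoln_irreplaceable_and_useless_units():
    # unit 0 holds all of the feature; unit 2 holds nothing and costs much
    pu = toy_units(costs=[1.0, 1.0, 5.0], amounts=[[10.0], [0.5], [0.0]])
    ft = pz.FeatureTargets(["f0"], np.array([9.0]), np.array([100.0]))
    sf = pz.ssoln(pu, ft, pz.SAParams(n_runs=20, iterations=200, seed=4))
    assert sf.ssoln[0] == pytest.approx(1.0)
    assert sf.ssoln[2] < 0.2
    assert np.all((sf.ssoln >= 0) & (sf.ssoln <= 1))


def test_ssoln_reserved_units_frequency_one():
    pu = toy_units(costs=[1.0, 1.0], amounts=[[1.0], [1.0]],
                   reserved=[True, False])
    ft = pz.FeatureTargets(["f0"], np.array([0.5]), np.array([3.0]))
    sf = pz.ssoln(pu, ft, pz.SAParams(n_runs=10, iterations=100, seed=5))
    assert sf.ssoln[0] == 1.0


def test_anneal_deterministic_under_seed():
    rng = np.random.default_rng(11)
    pu, ft = random_instance(rng)
    p = pz.SAParams(iterations=300, seed=21)
    a = pz.anneal(pu, ft, p)
    b = pz.anneal(pu, ft, p)
    np.testing.assert_array_equal(a.selected, b.selected)
    assert a.value == b.value


# ---------------------------------------------------------------------------
# BLM calibration and gap extraction
# ---------------------------------------------------------------------------

def test_blm_zero_minimizes_cost_term():
    rng = np.random.default_rng(13)
    pu, ft = random_instance(rng, n_units=10)
    ft.spf[:] = 1000.0  # targets always met; cost/boundary trade-off only
    df = pz.calibrate_blm(pu, ft, [0.0, 0.5, 2.0],
                          pz.SAParams(n_runs=8, iterations=300, seed=6))
    assert df.loc[df["blm"] == 0.0, "mean_cost"].iloc[0] == df["mean_cost"].min()
    assert df.attrs["suggested_blm"] in set(df["blm"])


def test_boundary_shrinks_with_blm():
    rng = np.random.default_rng(15)
    pu, ft = random_instance(rng, n_units=12)
    df = pz.calibrate_blm(pu, ft, [0.0, 5.0],
                          pz.SAParams(n_runs=10, iterations=400, seed=8))
    b = df.set_index("blm")["mean_boundary_km"]
    assert b[5.0] <= b[0.0] + 1e-9


def test_calibration_needs_two_values():
    rng = np.random.default_rng(16)
    pu, ft = random_instance(rng)
    with pytest.raises(ValueError, match="2 BLM"):
        pz.calibrate_blm(pu, ft, [0.1])


def test_gap_threshold_strictly_greater():
    pu = toy_units(costs=[1.0, 1.0, 1.0], amounts=[[1.0]] * 3,
                   reserved=[False, True, False])
    sf = pz.SelectionFrequency(
        ssoln=np.array([0.66, 0.66, 0.65]),
        best=pz.Solution(np.ones(3, bool), 0, 0, 0, 0), n_runs=100)
    gaps = pz.extract_gaps(sf, pu, threshold=0.65)
    assert gaps == {0}   # 0.66 available -> gap; reserved and 0.65 excluded


def test_marxan_flatfile_roundtrip(tmp_path):
    rng = np.random.default_rng(17)
    pu, ft = random_instance(rng, n_units=6)
    pz.write_marxan_inputs(pu, ft, str(tmp_path))
    import pandas as pd
    pu_df = pd.read_csv(tmp_path / "pu.csv")
    assert len(pu_df) == pu.n
    tg = pd.read_csv(tmp_path / "targets.csv")
    np.testing.assert_allclose(tg["target"], ft.targets)
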