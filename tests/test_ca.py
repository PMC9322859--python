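import numpy as np
import pytest

from flusim.ca import (
    NeighborhoodConfig,
    agreement,
    combined_probability,
    neighborhood_effect,
    roulette_allocate,
    simulate,
    update_inertia,
)
from flusim.grids import CategoricalRaster
from flusim.markov import ScenarioSpec
from flusim.suitability import SuitabilitySurface

from conftest import make_lu


def flat_surface(shape, cell_size=100.0):
    """Uninformative suitability: 1/6 everywhere."""
    return SuitabilitySurface(np.full((6,) + shape, 1.0 / 6), cell_size)


# --- neighbourhood factor ---------------------------------------------------

def test_neighborhood_full_window_of_construction():
    lu = make_lu(np.full((3, 3), 5))
    om = neighborhood_effect(lu, 5).values
    assert om[1, 1] == pytest.approx(1.0)  # 8/8 x weight 1


def test_neighborhood_half_window_grassland():
    values = np.full((3, 3), 1)
    values[0, :] = 3
    values[1, 0] = 3  # 4 of the centre's 8 neighbours are grassland
    lu = make_lu(values)
    om = neighborhood_effect(lu, 3).values
    assert om[1, 1] == pytest.approx(0.5 * 0.3)


def test_neighborhood_absent_class_zero_and_border_truncation():
    lu = make_lu(np.full((3, 3), 5))
    assert (neighborhood_effect(lu, 2).values == 0).all()
    # corner cell: 3 neighbours, all construction -> full share
    om = neighborhood_effect(lu, 5).values
    assert om[0, 0] == pytest.approx(1.0)


def test_neighborhood_rejects_bad_class():
    with pytest.raises(ValueError):
        neighborhood_effect(make_lu(np.ones((3, 3), int)), 7)


def test_neighborhood_config_validation():
    with pytest.raises(ValueError):
        NeighborhoodConfig(window=4)
    with pytest.raises(ValueError):
        NeighborhoodConfig(weights=np.full(6, 1.5))


# --- adaptive inertia --------------------------------------------------------

def test_inertia_unchanged_when_gap_not_growing():
    assert update_inertia(1.7, d_prev=-3, d_prev2=-4) == pytest.approx(1.7)
    assert update_inertia(0.5, d_prev=0, d_prev2=0) == pytest.approx(0.5)


def test_inertia_suppresses_worsening_overshoot():
    # over-allocated and getting worse: scale down by d2/d1
    assert update_inertia(1.0, d_prev=-8, d_prev2=-4) == pytest.approx(0.5)


def test_inertia_promotes_worsening_shortfall():
    # under-allocated and getting worse: scale up by d1/d2
    assert update_inertia(1.0, d_prev=8, d_prev2=4) == pytest.approx(2.0)
    # the printed-equation mode uses the reciprocal ratio
    assert update_inertia(1.0, 8, 4, strict_printed=True) == pytest.approx(0.5)


def test_inertia_clipped_to_bounds():
    assert update_inertia(8.0, d_prev=100, d_prev2=1) == pytest.approx(10.0)
    assert update_inertia(0.2, d_prev=-100, d_prev2=-1) == pytest.approx(0.1)


# --- combined probability -----------------------------------------------------

def test_combined_probability_product_and_masking():
    sp = np.array([0.1, 0.1, 0.5, 0.1, 0.1, 0.1])
    omega = np.full(6, 0.15)
    inertia = np.array([1.0, 1, 2, 1, 1, 1])
    cost_row = np.array([0, 0, 1, 0, 0, 0])
    tp = combined_probability(sp, omega, inertia, cost_row, current_class=1)
    assert tp[2] == pytest.approx(0.5 * 0.15 * 2)  # 0.15
    assert tp[0] == pytest.approx(0.1 * 0.15)      # keeping class 1 allowed
    assert (tp[[1, 3, 4, 5]] == 0).all()
    # doubling one inertia doubles exactly that class's score
    tp2 = combined_probability(sp, omega, inertia * [1, 1, 2, 1, 1, 1], cost_row, 1)
    assert tp2[2] == pytest.approx(2 * tp[2])
    np.testing.assert_allclose(tp2[[0, 1, 3, 4, 5]], tp[[0, 1, 3, 4, 5]])


# --- roulette allocation ------------------------------------------------------

def test_allocate_noop_when_demand_met(fixture100):
    lu = fixture100.lu_t0
    surf = flat_surface(lu.shape)
    res = roulette_allocate(lu, surf, lu.class_counts(), "natural", seed=0)
    assert res.converged and res.n_iter == 0
    np.testing.assert_array_equal(res.raster.values, lu.values)


def test_allocate_two_class_demand_shift():
    """Move 100 cells from cultivated to construction under flat sp."""
    rng = np.random.default_rng(30)
    values = np.where(rng.random((50, 50)) < 0.5, 1, 5).astype(np.int32)
    lu = CategoricalRaster(values, 100.0)
    counts = lu.class_counts()
    demand = counts.copy()
    demand[0] -= 100
    demand[4] += 100
    res = roulette_allocate(lu, flat_surface(lu.shape), demand, "natural", seed=1)
    out = res.raster.class_counts()
    tol = max(1, round(0.002 * counts.sum()))
    assert np.abs(out - demand).max() <= tol
    assert out.sum() == counts.sum()


def test_allocate_respects_cost_matrix(fixture100):
    """Cross-tabulating input vs output must show no forbidden transition."""
    lu = fixture100.lu_t1
    counts = lu.class_counts()
    demand = counts.copy()
    demand[0] -= 150
    demand[4] += 150
    spec = ScenarioSpec("locked", (), np.eye(6, dtype=int) | np.array(
        [[0, 0, 0, 0, 1, 0]] + [[0] * 6] * 5))
    res = roulette_allocate(lu, flat_surface(lu.shape), demand, spec, seed=2)
    a = lu.values.ravel() - 1
    b = res.raster.values.ravel() - 1
    moved = a != b
    assert spec.cost_matrix[a[moved], b[moved]].all()


def test_allocate_conserves_total_every_iteration(fixture100):
    lu = fixture100.lu_t1
    counts = lu.class_counts()
    demand = counts.copy()
    demand[0] -= 200
    demand[4] += 200
    res = roulette_allocate(lu, flat_surface(lu.shape), demand, "natural", seed=3)
    totals = res.history.sum(axis=1).to_numpy()
    assert (totals == counts.sum()).all()


def test_allocate_infeasible_demand_named():
    values = np.full((10, 10), 1, dtype=np.int32)
    lu = CategoricalRaster(values, 100.0)
    demand = np.array([80, 0, 0, 0, 0, 20])
    cost = np.eye(6, dtype=int)
    cost[0, 4] = 1
    with pytest.raises(ValueError, match="unused"):
        roulette_allocate(lu, flat_surface(lu.shape), demand,
                          ScenarioSpec("strict", (), cost), seed=4)


def test_allocate_rejects_wrong_demand_total(fixture100):
    lu = fixture100.lu_t0
    with pytest.raises(ValueError):
        roulette_allocate(lu, flat_surface(lu.shape),
                          lu.class_counts() + 1, "natural")


# --- full simulation ----------------------------------------------------------

def test_simulate_identity_transition_returns_base(fixture100):
    from flusim.markov import TransitionMatrix
    fx = fixture100
    res = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, "natural", steps=3, seed=5,
                   transition=TransitionMatrix(np.eye(6)), n_samples=2000)
    np.testing.assert_array_equal(res.raster.values, fx.lu_t1.values)


def test_simulate_deterministic_given_seed(fixture100):
    fx = fixture100
    r1 = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, "natural", seed=6, n_samples=2000)
    r2 = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, "natural", seed=6, n_samples=2000)
    np.testing.assert_array_equal(r1.raster.values, r2.raster.values)


def test_ecological_scenario_restrains_construction_growth(fixture100):
    """Cutting conversion probabilities toward construction must show up as
    slower simulated construction-land growth, seed by seed."""
    fx = fixture100
    base = fx.lu_t1.class_counts()[4]
    wins = 0
    for seed in range(10):
        nat = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, "natural",
                       seed=seed, n_samples=2000)
        eco = simulate(fx.lu_t0, fx.lu_t1, fx.drivers, "ecological_protection",
                       seed=seed, n_samples=2000)
        growth_nat = nat.raster.class_counts()[4] - base
        growth_eco = eco.raster.class_counts()[4] - base
        if growth_eco < growth_nat:
            wins += 1
    assert wins == 10


# --- agreement metrics ---------------------------------------------------------

def test_agreement_identical_maps(fixture100):
    rep = agreement(fixture100.lu_t0, fixture100.lu_t0)
    assert rep.overall_accuracy == 1.0 and rep.kappa == 1.0


def test_agreement_hand_confusion_case():
    """Confusion [[45,5],[15,35]] -> OA 0.80, p_e 0.50, kappa 0.60."""
    a = np.concatenate([np.full(50, 1), np.full(50, 2)])
    b = np.concatenate([np.full(45, 1), np.full(5, 2), np.full(15, 1), np.full(35, 2)])
    lu_a = CategoricalRaster(a.reshape(10, 10).astype(np.int32), 100.0)
    lu_b = CategoricalRaster(b.reshape(10, 10).astype(np.int32), 100.0)
    rep = agreement(lu_a, lu_b)
    assert rep.confusion[0, 0] == 45 and rep.confusion[1, 0] == 15
    assert rep.overall_accuracy == pytest.approx(0.80)
    assert rep.kappa == pytest.approx(0.60)


def test_agreement_permutation_null_kappa_zero():
    rng = np.random.default_rng(31)
    a = rng.integers(1, 3, size=(100, 100)).astype(np.int32)
    b = a.ravel().copy()
    rng.shuffle(b)  # matched marginals, no spatial association
    rep = agreement(CategoricalRaster(a, 100.0),
                    CategoricalRaster(b.reshape(a.shape), 100.0))
    assert abs(rep.kappa) < 0.05


def test_kappa_never_exceeds_overall_accuracy():
    rng = np.random.default_rng(32)
    for _ in range(20):
        a = rng.integers(1, 7, size=(20, 20)).astype(np.int32)
        b = rng.integers(1, 7, size=(20, 20)).astype(np.int32)
        rep = agreement(CategoricalRaster(a, 100.0), CategoricalRaster(b, 100.0))
        assert rep.kappa <= rep.overall_accuracy + 1e-12
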