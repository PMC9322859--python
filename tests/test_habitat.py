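import numpy as np
import pytest

from flusim.grids import ContinuousRaster
from flusim.habitat import (
    GRADE_LABELS,
    SensitivityTable,
    ThreatSource,
    assess,
    build_threat_masks,
    degradation,
    grade,
    load_sensitivity,
    load_threat_params,
    quality,
    summarize_quality,
    threat_impact,
)

from conftest import make_lu


def line_threat(shape=(5, 30), col=0, name="cultivated", d_max=3.0,
                weight=0.7, decay="linear"):
    mask = np.zeros(shape, dtype=bool)
    mask[:, col] = True
    return ThreatSource(name, mask, d_max, weight, decay)


def test_impact_is_one_on_source_cells():
    for decay in ("linear", "exponential"):
        t = line_threat(decay=decay)
        imp = threat_impact(t, cell_size=100.0).values
        assert (imp[:, 0] == 1.0).all()


def test_linear_impact_at_one_km():
    # cells are 100 m; column 10 is 1 km from the source line, d_max 3 km
    imp = threat_impact(line_threat(), cell_size=100.0).values
    assert imp[2, 10] == pytest.approx(2.0 / 3.0)


def test_impact_zero_beyond_max_distance():
    shape = (3, 120)
    lin = line_threat(shape, d_max=3.0, decay="linear")
    exp = line_threat(shape, d_max=3.0, decay="exponential", name="construction",
                      weight=1.0)
    for t in (lin, exp):
        imp = threat_impact(t, cell_size=100.0).values
        assert (imp[:, 31:] == 0.0).all()  # > 3 km away


def test_exponential_impact_small_at_max_distance():
    imp = threat_impact(line_threat(decay="exponential"), cell_size=100.0).values
    assert imp[2, 15] == pytest.approx(np.exp(-2.99 * 0.5))


def test_degradation_no_threats_is_zero():
    lu = make_lu(np.full((4, 4), 2))
    d = degradation([], [], load_sensitivity(), lu).values
    assert (d == 0).all()


def test_degradation_worked_woodland_example():
    """Woodland cell 1 km from a cultivated-land edge: D = (0.7/0.7) x 2/3 x 0.8."""
    values = np.full((5, 30), 2, dtype=int)
    values[:, 0] = 1
    lu = make_lu(values)
    threats = [line_threat()]
    impacts = [threat_impact(threats[0], 100.0)]
    d = degradation(impacts, threats, load_sensitivity(), lu).values
    assert d[2, 10] == pytest.approx(2.0 / 3.0 * 0.8, abs=1e-9)


def test_degradation_zero_sensitivity_class():
    values = np.full((5, 30), 5, dtype=int)  # construction: sensitivity row all 0
    values[:, 0] = 1
    lu = make_lu(values)
    threats = [line_threat()]
    impacts = [threat_impact(threats[0], 100.0)]
    d = degradation(impacts, threats, load_sensitivity(), lu).values
    assert (d[:, 1:] == 0).all()


def test_quality_closed_forms():
    sens = load_sensitivity()
    lu = make_lu(np.full((3, 3), 2))  # woodland, H = 1
    # D = 0 -> Q = H
    q0 = quality(ContinuousRaster(np.zeros((3, 3)), 100.0), sens, lu, k=0.5)
    np.testing.assert_allclose(q0.values, 1.0)
    # D = k -> Q = H/2
    qk = quality(ContinuousRaster(np.full((3, 3), 0.5), 100.0), sens, lu, k=0.5)
    np.testing.assert_allclose(qk.values, 0.5)
    # worked chain: D = 0.5333 -> Q = 0.4678
    d = np.full((3, 3), 2.0 / 3.0 * 0.8)
    qw = quality(ContinuousRaster(d, 100.0), sens, lu, k=0.5)
    assert qw.values[1, 1] == pytest.approx(0.4678, abs=1e-3)
    # H = 0 classes score 0 regardless of D
    lu_con = make_lu(np.full((3, 3), 5))
    qc = quality(ContinuousRaster(d, 100.0), sens, lu_con, k=0.5)
    np.testing.assert_allclose(qc.values, 0.0)


def test_quality_requires_positive_k():
    lu = make_lu(np.full((3, 3), 2))
    with pytest.raises(ValueError):
        quality(ContinuousRaster(np.zeros((3, 3)), 100.0), load_sensitivity(), lu, k=0.0)


def test_grade_bin_edges():
    q = ContinuousRaster(np.array([[0.35, 0.4, 0.59], [0.6, 0.8, 1.0],
                                   [0.0, 0.79, 0.99]]), 100.0)
    g = grade(q)
    expected = np.array([[0, 1, 1], [2, 3, 3], [0, 2, 3]])
    np.testing.assert_array_equal(g, expected)


def test_summaries_constant_and_checkerboard():
    const = ContinuousRaster(np.full((4, 4), 0.7), 100.0)
    s = summarize_quality(const, grade(const))
    assert s["mean_quality"][0] == pytest.approx(0.7)
    assert s["share_good"][0] == pytest.approx(100.0)
    board = np.indices((4, 4)).sum(axis=0) % 2
    check = ContinuousRaster(np.where(board == 0, 0.2, 0.9), 100.0)
    s2 = summarize_quality(check, grade(check))
    assert s2["mean_quality"][0] == pytest.approx(0.55)
    assert s2["share_poor"][0] == pytest.approx(50.0)
    assert s2["share_excellent"][0] == pytest.approx(50.0)
    shares = [s2[f"share_{g}"][0] for g in GRADE_LABELS]
    assert sum(shares) == pytest.approx(100.0, abs=1e-9)


def test_build_threat_masks_counts_match_histogram(fixture100):
    lu = fixture100.lu_t0
    threats = build_threat_masks(lu, roads=fixture100.roads)
    by_name = {t.name: t for t in threats}
    counts = lu.class_counts()
    assert by_name["cultivated"].mask.sum() == counts[0]
    assert by_name["construction"].mask.sum() == counts[4]


def test_build_threat_masks_missing_road_layer():
    lu = make_lu(np.full((4, 4), 1))
    with pytest.raises(KeyError):
        build_threat_masks(lu, roads={})


def test_empty_threat_skipped():
    lu = make_lu(np.full((4, 4), 2))  # no cultivated, no construction
    roads = {n: np.zeros((4, 4), bool) for n in
             ("national_road", "provincial_road", "railway")}
    roads["railway"][0, :] = True
    threats = build_threat_masks(lu, roads=roads)
    assert [t.name for t in threats] == ["railway"]


def test_growing_threat_source_never_raises_quality(fixture100):
    """With a fixed threat set, adding source cells to a threat can only move
    every cell closer to it, so quality is pointwise non-increasing.  (Adding
    a whole new threat is not monotone: the weights are renormalised.)"""
    fx = fixture100
    sparse = {n: m.copy() for n, m in fx.roads.items()}
    first = tuple(np.argwhere(fx.roads["railway"])[0])
    sparse["railway"] = np.zeros_like(fx.roads["railway"])
    sparse["railway"][first] = True  # subset of the full railway line
    r_sparse = assess(fx.lu_t0, roads=sparse)
    r_full = assess(fx.lu_t0, roads=fx.roads)
    m = fx.lu_t0.valid_mask
    assert (r_full.quality.values[m] <= r_sparse.quality.values[m] + 1e-12).all()


def test_quality_bounded_by_suitability(fixture100):
    res = assess(fixture100.lu_t0, roads=fixture100.roads)
    sens = load_sensitivity()
    h = sens.suitability[fixture100.lu_t0.values - 1]
    q = res.quality.values
    assert (q <= h + 1e-12).all()
    eq = np.isclose(q, h) & (h > 0)
    assert (res.degradation.values[eq] < 1e-12).all()


def test_halving_k_lowers_quality_where_degraded(fixture100):
    fx = fixture100
    r1 = assess(fx.lu_t0, roads=fx.roads, k=0.5)
    r2 = assess(fx.lu_t0, roads=fx.roads, k=0.25)
    d = r1.degradation.values
    sel = (d > 0) & (load_sensitivity().suitability[fx.lu_t0.values - 1] > 0)
    assert (r2.quality.values[sel] < r1.quality.values[sel]).all()


def test_more_construction_means_lower_mean_quality():
    """All else fixed, paving grassland must degrade the landscape score."""
    rng = np.random.default_rng(41)
    base = np.where(rng.random((40, 40)) < 0.5, 2, 3).astype(np.int32)
    paved = base.copy()
    paved[10:20, 10:20] = 5
    roads = {n: np.zeros((40, 40), bool) for n in
             ("national_road", "provincial_road", "railway")}
    roads["railway"][0, :] = True
    q_base = assess(make_lu(base), roads=roads).summary["mean_quality"][0]
    q_paved = assess(make_lu(paved), roads=roads).summary["mean_quality"][0]
    assert q_paved < q_base


def test_sensitivity_table_validation():
    with pytest.raises(ValueError):
        SensitivityTable(np.full(6, 1.5), np.zeros((6, 5)))
    with pytest.raises(ValueError):
        ThreatSource("x", np.ones((3, 3), bool), -1.0, 0.5, "linear")
    with pytest.raises(ValueError):
        ThreatSource("x", np.ones((3, 3), bool), 1.0, 0.5, "cubic")
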