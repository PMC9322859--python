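"""Cellular-automaton land allocator with adaptive inertia and roulette draws.

Each iteration combines, per cell and candidate class k, four factors into a
total conversion score

    TP[p, k] = sp(p, k) * Omega(p, k) * I_k * cost(orig(p) -> k)

where sp is the occurrence probability from the suitability network, Omega
the Moore-neighbourhood share of class k weighted by its expansion parameter,
I_k the adaptive inertia coefficient that steers class totals toward the
projected demand, and the binary cost term masks conversions a scenario
forbids (always relative to the cell's class in the base map, so the realised
cross-tabulation never violates the scenario's allowance).  Cells are visited
in seeded random order and draw their next class by roulette over TP; a class
whose count reaches its demand is frozen — its cells lock and it leaves every
candidate set.  Iteration stops when all class counts are within tolerance of
demand or an iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .grids import CLASS_LABELS, N_CLASSES, CategoricalRaster, ContinuousRaster, DriverStack
from .markov import (
    BUILTIN_SCENARIOS,
    ScenarioSpec,
    TransitionMatrix,
    apply_scenario,
    constrain_to_cost,
    estimate_transition,
    project_demand,
    round_demand,
)
from .suitability import (
    DEFAULT_HIDDEN_UNITS,
    SuitabilitySurface,
    fit_suitability,
    predict_suitability,
    sample_training,
)

__all__ = [
    "NeighborhoodConfig",
    "DEFAULT_NEIGHBORHOOD_WEIGHTS",
    "AllocationResult",
    "AccuracyReport",
    "neighborhood_effect",
    "update_inertia",
    "combined_probability",
    "roulette_allocate",
    "simulate",
    "agreement",
]

#: Expansion-capacity weights per class (cultivated, woodland, grassland,
#: waters, construction, unused): construction expands most readily (1),
#: woodland essentially not at all (0.01).
DEFAULT_NEIGHBORHOOD_WEIGHTS = np.array([0.2, 0.01, 0.3, 0.4, 1.0, 0.5])

INERTIA_BOUNDS = (0.1, 10.0)


@dataclass
class NeighborhoodConfig:
    """Moore window size and per-class expansion weights."""

    window: int = 3
    weights: np.ndarray = field(default_factory=lambda: DEFAULT_NEIGHBORHOOD_WEIGHTS.copy())

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_CLASSES,):
            raise ValueError(f"need {N_CLASSES} neighbourhood weights")
        if ((self.weights < 0) | (self.weights > 1)).any():
            raise ValueError("neighbourhood weights must lie in [0, 1]")


@dataclass
class AccuracyReport:
    """Cell-wise map agreement: confusion counts, overall accuracy, kappa."""

    confusion: np.ndarray
    overall_accuracy: float
    kappa: float


@dataclass
class AllocationResult:
    """Output of one allocation run."""

    raster: CategoricalRaster
    demand: np.ndarray
    history: pd.DataFrame  # per-iteration class counts
    converged: bool
    n_iter: int


def _window_counts(binary: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones((window, window))
    return ndimage.convolve(binary.astype(float), kernel, mode="constant", cval=0.0)


def neighborhood_effect(lu: CategoricalRaster, k: int,
                        cfg: NeighborhoodConfig | None = None) -> ContinuousRaster:
    """Weighted share of class-k cells in each cell's Moore window.

    The centre cell is excluded from the count; border cells use the
    truncated window with their actual neighbour count as denominator, so the
    unweighted share stays in [0, 1] everywhere.
    """
    cfg = cfg or NeighborhoodConfig()
    if not 1 <= k <= N_CLASSES:
        raise ValueError(f"unknown class code {k}")
    is_k = (lu.values == k) & lu.valid_mask
    count_k = _window_counts(is_k, cfg.window) - is_k
    count_all = _window_counts(lu.valid_mask, cfg.window) - lu.valid_mask
    omega = np.divide(count_k, count_all, out=np.zeros_like(count_k),
                      where=count_all > 0) * cfg.weights[k - 1]
    return ContinuousRaster(omega, lu.cell_size)


def _omega_stack(values: np.ndarray, valid: np.ndarray, cfg: NeighborhoodConfig) -> np.ndarray:
    """(6, n_cells) neighbourhood factors for the current map state."""
    count_all = _window_counts(valid, cfg.window) - valid
    out = np.empty((N_CLASSES, values.size))
    for k in range(N_CLASSES):
        is_k = (values == k + 1) & valid
        count_k = _window_counts(is_k, cfg.window) - is_k
        om = np.divide(count_k, count_all, out=np.zeros_like(count_k),
                       where=count_all > 0) * cfg.weights[k]
        out[k] = om.ravel()
    return out


def update_inertia(inertia: float, d_prev: float, d_prev2: float,
                   strict_printed: bool = False) -> float:
    """One adaptive-inertia update from the last two demand gaps.

    ``d_prev`` and ``d_prev2`` are demand minus current count at iterations
    t-1 and t-2.  If the absolute gap did not grow, inertia is unchanged.  A
    worsening negative gap (over-allocation) scales inertia by
    d_prev2/d_prev (< 1, suppressing the class); a worsening positive gap
    (under-allocation) scales by d_prev/d_prev2 (> 1, promoting it).
    ``strict_printed`` applies d_prev2/d_prev in both branches instead.
    The result is clipped to [0.1, 10].
    """
    if abs(d_prev) <= abs(d_prev2):
        out = inertia
    elif d_prev < d_prev2 < 0:
        out = inertia * (d_prev2 / d_prev)
    elif 0 < d_prev2 < d_prev:
        out = inertia * ((d_prev2 / d_prev) if strict_printed else (d_prev / d_prev2))
    else:
        # sign change with growing magnitude: leave unchanged
        out = inertia
    return float(np.clip(out, *INERTIA_BOUNDS))


def combined_probability(sp: np.ndarray, omega: np.ndarray, inertia: np.ndarray,
                         cost_row: np.ndarray, current_class: int) -> np.ndarray:
    """Per-class total conversion scores for one cell.

    ``current_class`` is a 1-based code; keeping the current class is always
    allowed regardless of the cost row.  An all-zero result means the cell
    retains its class (the allocator's documented fallback).
    """
    sp = np.asarray(sp, dtype=float)
    allowed = np.asarray(cost_row, dtype=float).copy()
    allowed[current_class - 1] = 1.0
    return sp * np.asarray(omega, dtype=float) * np.asarray(inertia, dtype=float) * allowed


@njit(cache=True)
def _sweep(order, cls0, cls, sp, omega, inertia, cost, counts, demand, frozen, rand):
    """One seeded-random-order roulette sweep; mutates cls/counts/frozen."""
    n_classes = sp.shape[0]
    tp = np.empty(n_classes)
    for idx in range(order.size):
        c = order[idx]
        cur = cls[c]
        if frozen[cur] == 1:
            continue
        orig = cls0[c]
        total = 0.0
        for k in range(n_classes):
            v = 0.0
            if k == cur or (frozen[k] == 0 and (cost[orig, k] == 1 or k == orig)):
                v = sp[k, c] * omega[k, c] * inertia[k]
                if v < 0.0:
                    v = 0.0
            tp[k] = v
            total += v
        if total <= 0.0:
            continue  # retain current class
        r = rand[idx] * total
        acc = 0.0
        new = cur
        for k in range(n_classes):
            if tp[k] <= 0.0:
                continue
            acc += tp[k]
            if r <= acc:
                new = k
                break
        if new != cur:
            counts[cur] -= 1
            counts[new] += 1
            cls[c] = new
            if counts[new] == demand[new]:
                frozen[new] = 1
            if counts[cur] == demand[cur]:
                frozen[cur] = 1


def roulette_allocate(lu_t: CategoricalRaster, surfaces: SuitabilitySurface,
                      demand: np.ndarray, scenario: ScenarioSpec | str = "natural",
                      cfg: NeighborhoodConfig | None = None, seed: int = 0,
                      max_iter: int = 300, tol: float = 0.002,
                      strict_printed_inertia: bool = False) -> AllocationResult:
    """Allocate projected demand onto the map by iterated roulette competition.

    ``demand`` must be integer per-class cell counts summing to the number of
    valid cells (see :func:`flusim.markov.round_demand`).  Convergence:
    every class count within ``tol`` (fraction of total cells) of its demand.
    """
    if isinstance(scenario, str):
        scenario = BUILTIN_SCENARIOS[scenario]
    cfg = cfg or NeighborhoodConfig()
    if surfaces.shape != lu_t.shape:
        raise ValueError("suitability surfaces and map shapes differ")
    valid = lu_t.valid_mask
    n_valid = int(valid.sum())
    demand = np.asarray(demand)
    if demand.shape != (N_CLASSES,) or demand.sum() != n_valid:
        raise ValueError(
            f"demand must be {N_CLASSES} integers summing to the valid cell count {n_valid}")
    demand = demand.astype(np.int64)

    counts = lu_t.class_counts()
    tol_cells = max(1, int(round(tol * n_valid)))
    cost = scenario.cost_matrix
    for j in range(N_CLASSES):
        gap = demand[j] - counts[j]
        donors = [i for i in range(N_CLASSES) if i != j and cost[i, j] == 1 and counts[i] > 0]
        if gap > tol_cells and not donors:
            raise ValueError(
                f"infeasible demand: class {CLASS_LABELS[j]!r} must grow by {gap} "
                "cells but no class may convert to it under this scenario")

    rng = np.random.default_rng(seed)
    flat_idx = np.flatnonzero(valid.ravel())
    cls0 = (lu_t.values.ravel()[flat_idx] - 1).astype(np.int64)
    cls = cls0.copy()
    sp = np.nan_to_num(surfaces.probs.reshape(N_CLASSES, -1)[:, flat_idx])
    inertia = np.ones(N_CLASSES)
    frozen = (counts == demand).astype(np.int64)
    gaps_hist: list[np.ndarray] = []
    rows = [counts.copy()]
    counts = counts.astype(np.int64)

    converged = bool(np.abs(demand - counts).max() <= tol_cells)
    it = 0
    work = np.zeros(lu_t.shape, dtype=np.int64).ravel()
    while not converged and it < max_iter:
        it += 1
        work[flat_idx] = cls + 1
        omega = _omega_stack(work.reshape(lu_t.shape), valid, cfg)[:, flat_idx]
        gaps = (demand - counts).astype(float)
        if len(gaps_hist) >= 2:
            for k in range(N_CLASSES):
                inertia[k] = update_inertia(inertia[k], gaps_hist[-1][k], gaps_hist[-2][k],
                                            strict_printed_inertia)
        gaps_hist.append(gaps)
        order = rng.permutation(cls.size)
        rand = rng.random(cls.size)
        _sweep(order, cls0, cls, sp, omega, inertia, cost, counts, demand, frozen, rand)
        rows.append(counts.copy())
        converged = bool(np.abs(demand - counts).max() <= tol_cells)

    out = np.full(lu_t.values.shape, lu_t.nodata_code, dtype=np.int32).ravel()
    out[flat_idx] = cls + 1
    raster = CategoricalRaster(out.reshape(lu_t.shape), lu_t.cell_size,
                               nodata_code=lu_t.nodata_code)
    history = pd.DataFrame(rows, columns=list(CLASS_LABELS))
    history.index.name = "iteration"
    return AllocationResult(raster, demand, history, converged, it)


def simulate(lu_prev: CategoricalRaster, lu_base: CategoricalRaster,
             drivers: DriverStack, scenario: ScenarioSpec | str = "natural",
             steps: int = 3, seed: int = 0,
             transition: TransitionMatrix | None = None,
             n_samples: int = 5000, hidden_units: int = DEFAULT_HIDDEN_UNITS,
             cfg: NeighborhoodConfig | None = None, max_iter: int = 300,
             tol: float = 0.002) -> AllocationResult:
    """Full scenario simulation from a pair of observed epochs.

    Composes transition estimation (``lu_prev`` to ``lu_base``), scenario
    probability edits, demand projection over ``steps`` periods, suitability
    training on the base epoch, and roulette allocation.  Pass ``transition``
    to skip the estimation stage.  Reproducible given ``seed``.
    """
    if isinstance(scenario, str):
        scenario = BUILTIN_SCENARIOS[scenario]
    if transition is None:
        transition = estimate_transition(lu_prev, lu_base)
    edited = constrain_to_cost(apply_scenario(transition, scenario), scenario)
    valid = lu_base.valid_mask & drivers.valid_mask
    counts = np.bincount(lu_base.values[valid], minlength=N_CLASSES + 1)[1:]
    demand = round_demand(project_demand(counts.astype(float), edited, steps=steps),
                          int(valid.sum()))
    ss = np.random.SeedSequence([seed, 3])
    s_train, s_fit, s_alloc = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3))
    n_samples = min(n_samples, int(valid.sum()))
    table = sample_training(lu_base, drivers, n_samples, seed=s_train)
    model = fit_suitability(table, hidden_units=hidden_units, seed=s_fit)
    surfaces = predict_suitability(model, drivers)
    base = CategoricalRaster(
        np.where(valid, lu_base.values, lu_base.nodata_code).astype(np.int32),
        lu_base.cell_size, nodata_code=lu_base.nodata_code)
    return roulette_allocate(base, surfaces, demand, scenario, cfg=cfg,
                             seed=s_alloc, max_iter=max_iter, tol=tol)


def agreement(map_a: CategoricalRaster, map_b: CategoricalRaster) -> AccuracyReport:
    """Cell-by-cell agreement of two maps: confusion, overall accuracy, kappa.

    Kappa uses the standard chance-corrected form with expected agreement
    p_e = sum_i row_i * col_i / n^2.
    """
    if map_a.shape != map_b.shape:
        raise ValueError(f"shape mismatch: {map_a.shape} vs {map_b.shape}")
    m = map_a.valid_mask & map_b.valid_mask
    a = map_a.values[m] - 1
    b = map_b.values[m] - 1
    conf = np.bincount(a * N_CLASSES + b, minlength=N_CLASSES ** 2)
    conf = conf.reshape(N_CLASSES, N_CLASSES).astype(np.int64)
    n = conf.sum()
    po = np.trace(conf) / n
    pe = float((conf.sum(axis=1) * conf.sum(axis=0)).sum()) / n ** 2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return AccuracyReport(conf, float(po), float(kappa))
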