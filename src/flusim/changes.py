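"""Cross-tabulation change accounting between land-use epochs.

An epoch pair collapses to a 6x6 area-flow matrix (km^2): entry (i, j) is the
area that moved from class i to class j over the period.  Row sums are the
t0 class areas, column sums the t1 areas, off-diagonal row/column sums the
per-class decreases/increases.  Derived statistics: net change, percent
change over the period, the annualised single-class dynamic degree
K = (A_t1 - A_t0) / A_t0 * (1/T) * 100%, and flow shares (the fraction of a
class's gain sourced from each donor class).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import CLASS_LABELS, N_CLASSES, CategoricalRaster
from .markov import load_reference_area_matrix

__all__ = [
    "cross_tabulate",
    "summarize_changes",
    "flow_shares",
    "compare_scenarios",
    "load_reference_area_matrix",
]


def cross_tabulate(lu_t0: CategoricalRaster, lu_t1: CategoricalRaster) -> pd.DataFrame:
    """Area-flow matrix (km^2) between two aligned epochs."""
    if lu_t0.shape != lu_t1.shape:
        raise ValueError(f"shape mismatch: {lu_t0.shape} vs {lu_t1.shape}")
    if lu_t0.cell_size != lu_t1.cell_size:
        raise ValueError("cell_size mismatch between epochs")
    m = lu_t0.valid_mask & lu_t1.valid_mask
    a = lu_t0.values[m] - 1
    b = lu_t1.values[m] - 1
    counts = np.bincount(a * N_CLASSES + b, minlength=N_CLASSES ** 2)
    area = counts.reshape(N_CLASSES, N_CLASSES) * (lu_t0.cell_size / 1000.0) ** 2
    return pd.DataFrame(area, index=list(CLASS_LABELS), columns=list(CLASS_LABELS))


def _check_margins(matrix: pd.DataFrame, summary: pd.DataFrame) -> None:
    # decrease(i) + diagonal(i) = t0 total(i); analogue for increases
    diag = np.diag(matrix.to_numpy())
    assert np.allclose(summary["area_decrease"] + diag, summary["area_t0"])
    assert np.allclose(summary["area_increase"] + diag, summary["area_t1"])


def summarize_changes(area_matrix: pd.DataFrame, period_years: int = 20) -> pd.DataFrame:
    """Per-class change accounting from an area-flow matrix.

    Columns: area_t0, area_t1, area_decrease, area_increase, net_change,
    percent_change (over the whole period), dynamic_degree (%/yr).  A class
    with zero t0 area reports NaN percent change.
    """
    m = area_matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or (m < 0).any():
        raise ValueError("area matrix must be square and non-negative")
    diag = np.diag(m)
    t0 = m.sum(axis=1)
    t1 = m.sum(axis=0)
    dec = t0 - diag
    inc = t1 - diag
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(t0 > 0, (t1 - t0) / t0 * 100.0, np.nan)
    out = pd.DataFrame(
        {
            "area_t0": t0,
            "area_t1": t1,
            "area_decrease": dec,
            "area_increase": inc,
            "net_change": t1 - t0,
            "percent_change": pct,
            "dynamic_degree": pct / period_years,
        },
        index=area_matrix.index,
    )
    _check_margins(area_matrix, out)
    return out


def flow_shares(area_matrix: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each class's gain sourced from each donor class.

    Entry (i, j) is off-diagonal flow i->j divided by class j's total
    increase; columns of classes with zero increase are NaN.
    """
    m = area_matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    inc = m.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(inc > 0, m / inc, np.nan)
    return pd.DataFrame(shares, index=area_matrix.index, columns=area_matrix.columns)


def compare_scenarios(base_lu: CategoricalRaster,
                      scenario_maps: dict[str, CategoricalRaster]) -> pd.DataFrame:
    """Per-scenario, per-class area deltas (km^2) and percent vs the base map."""
    base = base_lu.class_areas_km2()
    rows = []
    for name, lu in scenario_maps.items():
        if lu.shape != base_lu.shape:
            raise ValueError(f"scenario {name!r} map shape mismatch")
        areas = lu.class_areas_km2()
        for k in range(N_CLASSES):
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = (areas[k] - base[k]) / base[k] * 100.0 if base[k] > 0 else np.nan
            rows.append(
                {
                    "scenario": name,
                    "class": CLASS_LABELS[k],
                    "area_km2": areas[k],
                    "delta_km2": areas[k] - base[k],
                    "percent_change": pct,
                }
            )
    return pd.DataFrame(rows)
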