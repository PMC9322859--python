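"""Markov-chain land-use demand: transition estimation, scenario edits, projection.

The quantity side of the coupled model is a first-order Markov chain on the
six land classes.  A row-stochastic transition matrix P (rows = source class,
columns = destination class) is estimated from a pair of observed maps by
cross-tabulating cell transitions; per-class demand at a future epoch is the
repeated one-step map S_{t+1} = S_t P.  Policy scenarios edit individual
transfer probabilities multiplicatively before projection; the probability
mass removed from (or added to) an edited entry is absorbed by the row's
diagonal so the restricted land stays in place and rows remain stochastic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CLASS_LABELS, N_CLASSES, CategoricalRaster

__all__ = [
    "TransitionMatrix",
    "constrain_to_cost",
    "ScenarioSpec",
    "BUILTIN_SCENARIOS",
    "estimate_transition",
    "project_demand",
    "apply_scenario",
    "round_demand",
    "load_reference_area_matrix",
]

_CLASS_INDEX = {name: i for i, name in enumerate(CLASS_LABELS)}


def _as_class_index(c: int | str) -> int:
    """Accept a 1-based class code or a class name; return 0-based index."""
    if isinstance(c, str):
        try:
            return _CLASS_INDEX[c]
        except KeyError:
            raise ValueError(f"unknown class name {c!r}") from None
    if not 1 <= int(c) <= N_CLASSES:
        raise ValueError(f"class code {c} outside 1..{N_CLASSES}")
    return int(c) - 1


@dataclass
class TransitionMatrix:
    """Row-stochastic class-to-class transition probabilities.

    ``probs[i, j]`` is the probability that a cell of class i+1 becomes class
    j+1 over one period of ``period_years`` years.  ``counts`` holds the
    cell-count cross-tabulation the probabilities were estimated from, when
    available.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    period_years: int = 10

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected a {N_CLASSES}x{N_CLASSES} matrix")
        if (self.probs < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if (self.counts < 0).any():
                raise ValueError("transition counts must be non-negative")

    @classmethod
    def from_counts(cls, counts: np.ndarray, period_years: int = 10) -> "TransitionMatrix":
        counts = np.asarray(counts, dtype=float)
        probs = np.empty_like(counts)
        row_tot = counts.sum(axis=1)
        for i in range(N_CLASSES):
            if row_tot[i] > 0:
                probs[i] = counts[i] / row_tot[i]
            else:
                # class absent at t0: identity self-loop row
                probs[i] = 0.0
                probs[i, i] = 1.0
        return cls(probs, counts=counts, period_years=period_years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(CLASS_LABELS), columns=list(CLASS_LABELS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, period_years: int = 10) -> "TransitionMatrix":
        frame = frame.loc[list(CLASS_LABELS), list(CLASS_LABELS)]
        return cls(frame.to_numpy(dtype=float), period_years=period_years)


@dataclass
class ScenarioSpec:
    """A named policy scenario.

    ``prob_edits`` are multiplicative edits ``(from_class, to_class,
    multiplier)`` applied to off-diagonal transfer probabilities; classes may
    be 1-based codes or names.  ``cost_matrix`` is the binary conversion
    allowance (1 = class i may convert to class j); its diagonal must be 1.
    """

    name: str
    prob_edits: tuple[tuple[int | str, int | str, float], ...] = ()
    cost_matrix: np.ndarray = field(default_factory=lambda: np.ones((N_CLASSES, N_CLASSES), int))

    def __post_init__(self) -> None:
        self.cost_matrix = np.asarray(self.cost_matrix, dtype=int)
        if self.cost_matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("cost matrix must be 6x6")
        if not np.isin(self.cost_matrix, (0, 1)).all():
            raise ValueError("cost matrix entries must be 0 or 1")
        if not (np.diag(self.cost_matrix) == 1).all():
            raise ValueError("cost matrix diagonal must be all 1 (keeping a class is always allowed)")
        for frm, to, mult in self.prob_edits:
            i, j = _as_class_index(frm), _as_class_index(to)
            if i == j:
                raise ValueError("probability edits must reference off-diagonal entries")
            if mult < 0:
                raise ValueError("edit multipliers must be >= 0")


# Conversion allowances per scenario.  Rows = from, cols = to, class order
# cultivated, woodland, grassland, waters, construction, unused.  Construction
# land never converts away; unused land may convert to anything.
_COST_NATURAL = np.array([
    [1, 0, 0, 0, 1, 0],
    [1, 1, 0, 0, 1, 0],
    [1, 0, 1, 0, 1, 0],
    [1, 1, 1, 1, 1, 0],
    [0, 0, 0, 0, 1, 0],
    [1, 1, 1, 1, 1, 1],
])
_COST_CULTIVATED = np.array([
    [1, 0, 0, 0, 0, 0],
    [1, 1, 1, 0, 1, 1],
    [1, 1, 1, 1, 1, 1],
    [1, 0, 1, 1, 1, 1],
    [0, 0, 0, 0, 1, 0],
    [1, 1, 1, 1, 1, 1],
])
_COST_ECOLOGICAL = np.array([
    [1, 1, 1, 1, 1, 0],
    [0, 1, 0, 0, 0, 0],
    [0, 1, 1, 1, 0, 0],
    [0, 0, 1, 1, 0, 0],
    [0, 0, 0, 0, 1, 0],
    [1, 1, 1, 1, 1, 1],
])

#: The three built-in policy scenarios: unconstrained development, cultivated
#: land protection (transfer of cultivated land to construction cut 40% and to
#: woodland cut 30%), and ecological protection (woodland/grassland transfer
#: to construction cut 80% and to unused land cut 100%, waters to construction
#: cut 80%, cultivated-to-woodland raised 30%, cultivated-to-construction cut
#: 30%).
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "natural": ScenarioSpec("natural", (), _COST_NATURAL),
    "cultivated_protection": ScenarioSpec(
        "cultivated_protection",
        (("cultivated", "construction", 0.6), ("cultivated", "woodland", 0.7)),
        _COST_CULTIVATED,
    ),
    "ecological_protection": ScenarioSpec(
        "ecological_protection",
        (
            ("woodland", "construction", 0.2),
            ("grassland", "construction", 0.2),
            ("woodland", "unused", 0.0),
            ("grassland", "unused", 0.0),
            ("waters", "construction", 0.2),
            ("cultivated", "woodland", 1.3),
            ("cultivated", "construction", 0.7),
        ),
        _COST_ECOLOGICAL,
    ),
}


def estimate_transition(lu_t0: CategoricalRaster, lu_t1: CategoricalRaster,
                        period_years: int = 10) -> TransitionMatrix:
    """Cross-tabulate two aligned maps into a transition matrix.

    Only cells valid in both epochs contribute.  A class absent at t0 gets an
    identity self-loop row.
    """
    if lu_t0.shape != lu_t1.shape:
        raise ValueError(f"shape mismatch: {lu_t0.shape} vs {lu_t1.shape}")
    if lu_t0.cell_size != lu_t1.cell_size:
        raise ValueError("cell_size mismatch between epochs")
    m = lu_t0.valid_mask & lu_t1.valid_mask
    a = lu_t0.values[m] - 1
    b = lu_t1.values[m] - 1
    counts = np.bincount(a * N_CLASSES + b, minlength=N_CLASSES * N_CLASSES)
    counts = counts.reshape(N_CLASSES, N_CLASSES)
    return TransitionMatrix.from_counts(counts, period_years=period_years)


def project_demand(demand: np.ndarray, transition: TransitionMatrix,
                   steps: int = 1) -> np.ndarray:
    """Project per-class demand ``steps`` periods ahead: S_{t+1} = S_t P.

    Demand propagates as column sums of flows, so the one-step map is the
    row-vector product with P; the total is conserved by row-stochasticity.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    s = np.asarray(demand, dtype=float)
    if s.shape != (N_CLASSES,):
        raise ValueError(f"demand vector must have length {N_CLASSES}")
    if (s < 0).any():
        raise ValueError("demand entries must be non-negative")
    for _ in range(steps):
        s = s @ transition.probs
    return s


def apply_scenario(transition: TransitionMatrix, spec: ScenarioSpec) -> TransitionMatrix:
    """Apply a scenario's multiplicative transfer-probability edits.

    Each edited off-diagonal entry is multiplied by its factor and the row's
    mass change is absorbed by the diagonal (self-retention).  If the diagonal
    would go negative the row is clipped to >= 0 and re-normalized.
    """
    probs = transition.probs.copy()
    for frm, to, mult in spec.prob_edits:
        i, j = _as_class_index(frm), _as_class_index(to)
        old = probs[i, j]
        new = old * mult
        probs[i, j] = new
        probs[i, i] += old - new
    # repair any row whose diagonal went negative after an increase edit
    neg = probs < 0
    if neg.any():
        probs[neg] = 0.0
        probs /= probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs, counts=None, period_years=transition.period_years)


def constrain_to_cost(transition: TransitionMatrix, spec: ScenarioSpec) -> TransitionMatrix:
    """Zero out transitions the scenario's cost matrix forbids.

    The removed off-diagonal probability mass moves to the diagonal (the land
    stays put), keeping rows stochastic.  Projecting demand from the
    constrained matrix guarantees the demand is reachable through allowed
    conversions only, so the quantity side and the spatial allocation side of
    a scenario cannot contradict each other.
    """
    probs = transition.probs.copy()
    forbidden = (spec.cost_matrix == 0) & ~np.eye(N_CLASSES, dtype=bool)
    removed = np.where(forbidden, probs, 0.0).sum(axis=1)
    probs[forbidden] = 0.0
    probs[np.arange(N_CLASSES), np.arange(N_CLASSES)] += removed
    return TransitionMatrix(probs, counts=None, period_years=transition.period_years)


def round_demand(demand: np.ndarray, total: int) -> np.ndarray:
    """Round real-valued demand to integers summing exactly to ``total``.

    Largest-remainder apportionment: floor everything, then hand the leftover
    cells to the classes with the largest fractional parts.
    """
    s = np.asarray(demand, dtype=float)
    if s.sum() <= 0:
        raise ValueError("demand must have positive total")
    s = s * (total / s.sum())
    base = np.floor(s).astype(np.int64)
    rem = total - int(base.sum())
    order = np.argsort(-(s - base))
    base[order[:rem]] += 1
    return base


def load_reference_area_matrix() -> pd.DataFrame:
    """The packaged 2000-2020 study-region area-flow matrix (km^2)."""
    ref = importlib.resources.files("flusim.data") / "transition_area_2000_2020_km2.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)
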