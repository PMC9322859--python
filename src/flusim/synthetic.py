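"""Synthetic landscapes with the statistical structure the pipeline assumes.

The study region's rasters are not redistributable, so every downstream stage
is exercised on generated data instead: a spatially autocorrelated six-class
land-use map whose classes follow the driver surfaces (construction clusters
around an urban core, woodland on steep high ground, waters along a river),
plus an epoch-to-epoch change process governed by a known transition matrix.
Because the generating matrix is known, the Markov estimation stage has a
ground truth to recover, and scenario experiments have controlled conditions.

Defaults are desk-scale study conditions: a 200x200 grid at 100 m cells with
the true transition matrix and class prevalences taken from the packaged
2000-2020 reference area matrix (row-normalised probabilities and epoch-2000
area shares respectively), i.e. a decade of change statistically similar to
the study region's.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .grids import (
    CLASS_LABELS,
    N_CLASSES,
    CategoricalRaster,
    ContinuousRaster,
    DriverStack,
    distance_transform,
)
from .markov import TransitionMatrix, load_reference_area_matrix

__all__ = [
    "SyntheticConfig",
    "SyntheticFixture",
    "default_transition",
    "default_prevalence",
    "gen_drivers",
    "gen_landuse",
    "gen_next_epoch",
    "gen_roads",
    "generate_fixture",
]

#: Road/railway line counts used for the accessibility and threat layers.
ROAD_LINE_COUNTS = {"national_road": 2, "provincial_road": 3, "railway": 2}


def default_transition() -> TransitionMatrix:
    """Row-normalised packaged reference area matrix as the true transition."""
    area = load_reference_area_matrix().to_numpy()
    probs = area / area.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs, period_years=10)


def default_prevalence() -> np.ndarray:
    """Epoch-2000 class shares of the packaged reference area matrix."""
    area = load_reference_area_matrix().to_numpy()
    row = area.sum(axis=1)
    return row / row.sum()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape generator."""

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 100.0
    seed: int = 42
    true_transition: TransitionMatrix = field(default_factory=default_transition)
    smoothness: float = 4.0
    class_prevalence: np.ndarray = field(default_factory=default_prevalence)

    def __post_init__(self) -> None:
        self.class_prevalence = np.asarray(self.class_prevalence, dtype=float)
        if self.class_prevalence.shape != (N_CLASSES,):
            raise ValueError(f"class_prevalence must have length {N_CLASSES}")
        if (self.class_prevalence < 0).any():
            raise ValueError("class prevalences must be non-negative")
        if abs(self.class_prevalence.sum() - 1.0) > 1e-9:
            raise ValueError("class prevalences must sum to 1")
        if min(self.shape) < 3:
            raise ValueError("grid must be at least 3x3")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


@dataclass
class SyntheticFixture:
    """A complete generated input set for one pipeline run."""

    lu_t0: CategoricalRaster
    lu_t1: CategoricalRaster
    drivers: DriverStack
    roads: dict[str, np.ndarray]
    config: SyntheticConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardised Gaussian random field with correlation length ~sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _random_border_point(rng: np.random.Generator, shape: tuple[int, int],
                         border: int) -> tuple[int, int]:
    rows, cols = shape
    if border == 0:   # top
        return 0, int(rng.integers(cols))
    if border == 1:   # bottom
        return rows - 1, int(rng.integers(cols))
    if border == 2:   # left
        return int(rng.integers(rows)), 0
    return int(rng.integers(rows)), cols - 1  # right


def gen_roads(shape: tuple[int, int], n_lines: int, seed: int) -> np.ndarray:
    """Rasterize ``n_lines`` random polylines, each crossing the grid.

    Every line starts and ends on two distinct grid borders, with one
    interior waypoint so the lines bend.  Returns a boolean mask.
    """
    if n_lines < 0:
        raise ValueError("n_lines must be >= 0")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for _ in range(n_lines):
        b0, b1 = rng.choice(4, size=2, replace=False)
        p0 = _random_border_point(rng, shape, int(b0))
        p1 = _random_border_point(rng, shape, int(b1))
        mid = (int(rng.integers(rows // 4, max(rows * 3 // 4, rows // 4 + 1))),
               int(rng.integers(cols // 4, max(cols * 3 // 4, cols // 4 + 1))))
        for a, b in ((p0, mid), (mid, p1)):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            mask[rr, cc] = True
    return mask


def _river_mask(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """A single meandering polyline crossing the grid (the river course)."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    n_way = 6
    ways = [(0, int(rng.integers(cols)))]
    for k in range(1, n_way):
        r = int(round(k * (rows - 1) / (n_way - 1)))
        c = int(np.clip(ways[-1][1] + rng.integers(-cols // 4, cols // 4 + 1), 0, cols - 1))
        ways.append((r, c))
    for a, b in zip(ways[:-1], ways[1:]):
        rr, cc = draw_line(a[0], a[1], b[0], b[1])
        mask[rr, cc] = True
    return mask


def gen_drivers(config: SyntheticConfig,
                return_roads: bool = False) -> DriverStack | tuple[DriverStack, dict[str, np.ndarray]]:
    """Generate the nine driver layers.

    Elevation is a smoothed Gaussian random field; slope its gradient
    magnitude; GDP and population densities are distinct smooth fields
    sharing a common urban-core hotspot; the accessibility layers are
    Euclidean distances to generated towns, a river, and road/railway lines.
    Deterministic given ``config.seed``.
    """
    rows, cols = config.shape
    if min(rows, cols) < 3:
        raise ValueError("grid must be at least 3x3")
    rng = np.random.default_rng(config.seed)
    sig = config.smoothness
    cs = config.cell_size

    dem_field = _smooth_field(rng, config.shape, sig * 2)
    dem = 900.0 + 450.0 * dem_field
    gy, gx = np.gradient(dem, cs)
    slope = np.hypot(gy, gx)

    # one urban core shared by the socio-economic surfaces
    core = (int(rng.integers(rows // 4, rows * 3 // 4)),
            int(rng.integers(cols // 4, cols * 3 // 4)))
    rr, cc = np.mgrid[0:rows, 0:cols]
    core_d2 = (rr - core[0]) ** 2 + (cc - core[1]) ** 2
    bump = np.exp(-core_d2 / (2.0 * (0.12 * min(rows, cols)) ** 2))
    gdp = np.exp(0.7 * _smooth_field(rng, config.shape, sig) + 3.0 * bump)
    pop = np.exp(0.7 * _smooth_field(rng, config.shape, sig) + 2.6 * bump)

    # towns: the core plus a handful of secondary centres
    towns = np.zeros(config.shape, dtype=bool)
    towns[core] = True
    n_towns = max(3, (rows * cols) // 8000)
    towns[rng.integers(rows, size=n_towns), rng.integers(cols, size=n_towns)] = True

    river = _river_mask(rng, config.shape)
    roads = {
        name: gen_roads(config.shape, n, int(rng.integers(2 ** 31)))
        for name, n in ROAD_LINE_COUNTS.items()
    }

    layers = {
        "dem": ContinuousRaster(dem, cs),
        "slope": ContinuousRaster(slope, cs),
        "gdp_density": ContinuousRaster(gdp, cs),
        "pop_density": ContinuousRaster(pop, cs),
        "dist_town": distance_transform(towns, cs),
        "dist_river": distance_transform(river, cs),
        "dist_national_road": distance_transform(roads["national_road"], cs),
        "dist_provincial_road": distance_transform(roads["provincial_road"], cs),
        "dist_railway": distance_transform(roads["railway"], cs),
    }
    stack = DriverStack(layers)
    if return_roads:
        return stack, roads
    return stack


def _class_scores(norm: DriverStack, rng: np.random.Generator,
                  smoothness: float) -> np.ndarray:
    """(6, rows, cols) affine class scores over normalised drivers + noise.

    The signs encode the designed-in structure: construction rises with
    GDP/population density and falls with distance to towns; woodland rises
    with slope and elevation; waters hug the river; cultivated land prefers
    flat low ground.
    """
    z = {k: norm[k].values for k in norm.names}
    shape = norm.shape
    scores = np.empty((N_CLASSES,) + shape)
    scores[0] = 0.9 * (1 - z["slope"]) + 0.4 * (1 - z["dem"]) + 0.2 * (1 - z["dist_town"])
    scores[1] = 1.1 * z["slope"] + 0.7 * z["dem"]
    scores[2] = 0.6 * z["dem"] + 0.3 * z["slope"] + 0.3 * z["dist_town"]
    scores[3] = 2.5 * (1 - z["dist_river"]) ** 8
    scores[4] = 1.0 * z["gdp_density"] + 1.0 * z["pop_density"] + 0.9 * (1 - z["dist_town"])
    scores[5] = 0.8 * z["dem"] + 0.5 * z["dist_town"] + 0.3 * z["slope"]
    for k in range(N_CLASSES):
        scores[k] += 0.25 * _smooth_field(rng, shape, smoothness)
    return scores


def gen_landuse(drivers: DriverStack, config: SyntheticConfig) -> CategoricalRaster:
    """Assign each cell the argmax class of driver-derived scores.

    Per-class intercepts are calibrated iteratively so realised class
    fractions track ``config.class_prevalence``; classes with zero target
    prevalence are excluded outright.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    norm = drivers.normalized()
    scores = _class_scores(norm, rng, config.smoothness)
    target = config.class_prevalence
    n_cells = scores[0].size

    offsets = np.zeros(N_CLASSES)
    offsets[target == 0] = -np.inf
    flat = scores.reshape(N_CLASSES, -1)
    best_off, best_err = offsets.copy(), np.inf
    for it in range(150):
        labels = np.argmax(flat + offsets[:, None], axis=0)
        frac = np.bincount(labels, minlength=N_CLASSES) / n_cells
        err = np.abs(frac - target).max()
        if err < best_err:
            best_err, best_off = err, offsets.copy()
        if err < 0.005:
            break
        lr = 2.0 / (1.0 + it / 30.0)
        adj = lr * (target - frac)
        adj[target == 0] = 0.0
        offsets = offsets + adj
    labels = np.argmax(flat + best_off[:, None], axis=0)
    values = (labels + 1).reshape(config.shape).astype(np.int32)
    return CategoricalRaster(values, config.cell_size)


def gen_next_epoch(lu_t0: CategoricalRaster,
                   true_transition: TransitionMatrix | np.ndarray,
                   seed: int) -> CategoricalRaster:
    """Resample each cell's class from its row of the true transition matrix.

    Per source class the destination counts are the expected counts under
    the matrix row, rounded by largest remainder, so marginal transition
    frequencies match the matrix to O(1/n) — the randomness lies in which
    cells change, not how many.  Which cells move is decided by
    neighbourhood affinity (cells adjacent to existing cells of the target
    class move first, with Gumbel noise), giving the change spatial
    coherence without distorting the marginals.
    """
    if not isinstance(true_transition, TransitionMatrix):
        true_transition = TransitionMatrix(np.asarray(true_transition, dtype=float))
    P = true_transition.probs
    rng = np.random.default_rng(seed)
    out = lu_t0.values.copy()
    valid = lu_t0.valid_mask

    # 8-neighbour counts of each class in the base map
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neigh = np.stack([
        ndimage.convolve((lu_t0.values == k + 1).astype(float), kernel,
                         mode="constant", cval=0.0).ravel()
        for k in range(N_CLASSES)
    ])

    flat = lu_t0.values.ravel()
    flat_valid = valid.ravel()
    for i in range(N_CLASSES):
        idx = np.flatnonzero((flat == i + 1) & flat_valid)
        if idx.size == 0:
            continue
        expected = idx.size * P[i]
        dest_counts = np.floor(expected).astype(np.int64)
        short = idx.size - int(dest_counts.sum())
        order = np.argsort(-(expected - dest_counts))
        dest_counts[order[:short]] += 1
        available = np.ones(idx.size, dtype=bool)
        for j in rng.permutation(N_CLASSES):
            if j == i or dest_counts[j] == 0:
                continue
            # neighbourhood affinity + Gumbel noise = noisy top-k selection
            score = neigh[j][idx] + rng.gumbel(scale=0.5, size=idx.size)
            score[~available] = -np.inf
            take = int(dest_counts[j])
            pick = np.argpartition(-score, take - 1)[:take]
            out.ravel()[idx[pick]] = j + 1
            available[pick] = False
    return CategoricalRaster(out, lu_t0.cell_size, nodata_code=lu_t0.nodata_code)


def generate_fixture(config: SyntheticConfig | None = None) -> SyntheticFixture:
    """Generate a complete input set: two land-use epochs, drivers, roads."""
    config = config or SyntheticConfig()
    drivers, roads = gen_drivers(config, return_roads=True)
    lu_t0 = gen_landuse(drivers, config)
    epoch_seed = int(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2 ** 31))
    lu_t1 = gen_next_epoch(lu_t0, config.true_transition, epoch_seed)
    return SyntheticFixture(lu_t0, lu_t1, drivers, roads, config)
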