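"""Habitat degradation and quality from threat proximity.

Habitat quality is scored per cell in [0, 1] from the land-use map alone.
Five threat sources stress habitat: cultivated land, construction land, and
the national-road / provincial-road / railway networks.  Each threat decays
with Euclidean distance from its source cells — linearly or exponentially —
up to a maximum stress distance.  Degradation aggregates the threats,
weighted by their relative importance and by each land class's sensitivity:

    D(x) = sum_r (w_r / sum w_r) * i_r(x) * beta(x) * S(class(x), r)

and quality applies a half-saturation transform of degradation to the
class's intrinsic habitat suitability H:

    Q(x) = H(class(x)) * (1 - D^2 / (D^2 + k^2))

so Q = H where D = 0 and Q = H/2 where D equals the half-saturation
constant k.  Construction and unused land have H = 0 and score 0 regardless
of threats.  Quality is graded poor [0, 0.4), moderate [0.4, 0.6),
good [0.6, 0.8), excellent [0.8, 1].
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import CLASS_LABELS, N_CLASSES, CategoricalRaster, ContinuousRaster, distance_transform

__all__ = [
    "ThreatSource",
    "SensitivityTable",
    "HabitatResult",
    "THREAT_NAMES",
    "GRADE_LABELS",
    "GRADE_EDGES",
    "EXP_DECAY_CONSTANT",
    "DEFAULT_HALF_SATURATION",
    "load_threat_params",
    "load_sensitivity",
    "build_threat_masks",
    "threat_impact",
    "degradation",
    "quality",
    "grade",
    "summarize_quality",
    "assess",
]

THREAT_NAMES = ("cultivated", "construction", "national_road", "provincial_road", "railway")
GRADE_LABELS = ("poor", "moderate", "good", "excellent")
GRADE_EDGES = (0.4, 0.6, 0.8)
#: Exponential kernels reach ~0.05 at the maximum stress distance.
EXP_DECAY_CONSTANT = 2.99
DEFAULT_HALF_SATURATION = 0.5


@dataclass
class ThreatSource:
    """One threat: its source mask and decay parameters."""

    name: str
    mask: np.ndarray
    max_distance_km: float
    weight: float
    decay: str  # "linear" | "exponential"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.max_distance_km <= 0:
            raise ValueError("max_distance_km must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("threat weight must lie in (0, 1]")
        if self.decay not in {"linear", "exponential"}:
            raise ValueError(f"unknown decay type {self.decay!r}")


@dataclass
class SensitivityTable:
    """Per-class habitat suitability H and per-class-per-threat sensitivity S."""

    suitability: np.ndarray          # (6,)
    sensitivity: np.ndarray          # (6, n_threats)
    threat_names: tuple[str, ...] = THREAT_NAMES

    def __post_init__(self) -> None:
        self.suitability = np.asarray(self.suitability, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.suitability.shape != (N_CLASSES,):
            raise ValueError("suitability must have one entry per class")
        if self.sensitivity.shape != (N_CLASSES, len(self.threat_names)):
            raise ValueError("sensitivity must be (classes x threats)")
        for arr, what in ((self.suitability, "suitability"), (self.sensitivity, "sensitivity")):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{what} values must lie in [0, 1]")

    def threat_column(self, name: str) -> np.ndarray:
        try:
            return self.sensitivity[:, self.threat_names.index(name)]
        except ValueError:
            raise KeyError(f"no sensitivity column for threat {name!r}") from None


@dataclass
class HabitatResult:
    """Degradation, quality and grade rasters plus the parameters used."""

    degradation: ContinuousRaster
    quality: ContinuousRaster
    grades: np.ndarray  # integer grade codes 0..3, -1 for nodata
    half_saturation: float
    summary: pd.DataFrame = field(repr=False, default=None)


def _data_csv(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("flusim.data") / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_threat_params() -> pd.DataFrame:
    """Packaged default threat parameters (distance, weight, decay)."""
    return _data_csv("threats.csv").set_index("threat")


def load_sensitivity() -> SensitivityTable:
    """Packaged default habitat suitability / sensitivity table."""
    tab = _data_csv("sensitivity.csv").set_index("class").loc[list(CLASS_LABELS)]
    return SensitivityTable(
        tab["habitat_suitability"].to_numpy(),
        tab[list(THREAT_NAMES)].to_numpy(),
    )


def build_threat_masks(lu: CategoricalRaster,
                       roads: dict[str, np.ndarray] | None = None,
                       params: pd.DataFrame | None = None) -> list[ThreatSource]:
    """Assemble the threat list for a map.

    Cultivated and construction masks come from the map itself; road and
    railway masks are passed in.  Threats whose mask is empty on this map are
    skipped; a configured road threat without a layer raises.
    """
    params = params if params is not None else load_threat_params()
    roads = roads or {}
    threats: list[ThreatSource] = []
    for name, row in params.iterrows():
        if name == "cultivated":
            mask = (lu.values == 1) & lu.valid_mask
        elif name == "construction":
            mask = (lu.values == 5) & lu.valid_mask
        else:
            if name not in roads:
                raise KeyError(f"threat {name!r} configured but no road layer given")
            mask = np.asarray(roads[name], dtype=bool)
            if mask.shape != lu.shape:
                raise ValueError(f"road layer {name!r} shape mismatch")
        if not mask.any():
            continue
        threats.append(ThreatSource(str(name), mask, float(row["max_distance_km"]),
                                    float(row["weight"]), str(row["decay"])))
    return threats


def threat_impact(threat: ThreatSource, cell_size: float) -> ContinuousRaster:
    """Distance-decayed impact surface i_r in [0, 1]; 1 on source cells.

    Linear decay: i = max(0, 1 - d/d_max).  Exponential decay:
    i = exp(-2.99 d/d_max) inside d_max, 0 beyond.
    """
    d_km = distance_transform(threat.mask, cell_size).values / 1000.0
    rel = d_km / threat.max_distance_km
    if threat.decay == "linear":
        i = np.maximum(0.0, 1.0 - rel)
    else:
        i = np.where(rel < 1.0, np.exp(-EXP_DECAY_CONSTANT * rel), 0.0)
    return ContinuousRaster(i, cell_size)


def degradation(impacts: list[ContinuousRaster], threats: list[ThreatSource],
                sens: SensitivityTable, lu: CategoricalRaster,
                beta: np.ndarray | float = 1.0) -> ContinuousRaster:
    """Weighted threat aggregation into the degradation surface D in [0, 1].

    ``beta`` is the per-cell accessibility (anti-interference) level,
    scalar 1 by default.
    """
    if len(impacts) != len(threats):
        raise ValueError("impacts and threats must pair up")
    total_w = sum(t.weight for t in threats)
    d = np.zeros(lu.shape)
    cls = np.clip(lu.values, 1, N_CLASSES) - 1
    for imp, thr in zip(impacts, threats):
        if imp.shape != lu.shape:
            raise ValueError("impact surface shape mismatch")
        s = sens.threat_column(thr.name)[cls]
        d += (thr.weight / total_w) * imp.values * s
    d = np.clip(d * beta, 0.0, 1.0)
    d[~lu.valid_mask] = np.nan
    return ContinuousRaster(d, lu.cell_size)


def quality(degr: ContinuousRaster, sens: SensitivityTable, lu: CategoricalRaster,
            k: float = DEFAULT_HALF_SATURATION) -> ContinuousRaster:
    """Half-saturation quality transform Q = H * (1 - D^2/(D^2 + k^2))."""
    if k <= 0:
        raise ValueError("half-saturation constant k must be positive")
    cls = np.clip(lu.values, 1, N_CLASSES) - 1
    h = sens.suitability[cls]
    d = degr.values
    q = h * (1.0 - d ** 2 / (d ** 2 + k ** 2))
    q[~lu.valid_mask] = np.nan
    return ContinuousRaster(q, lu.cell_size)


def grade(q: ContinuousRaster) -> np.ndarray:
    """Grade codes 0..3 (poor/moderate/good/excellent); -1 on nodata.

    Bins are left-closed, right-open, except the top bin which includes 1.
    """
    codes = np.digitize(np.nan_to_num(q.values, nan=-1.0), GRADE_EDGES, right=False)
    codes[~q.valid_mask] = -1
    return codes.astype(np.int8)


def summarize_quality(q: ContinuousRaster, grades: np.ndarray,
                      lu: CategoricalRaster | None = None) -> pd.DataFrame:
    """Mean quality, grade shares (%) and optional per-class mean quality.

    Returns a single-row frame; grade-share columns are ``share_<grade>``.
    """
    m = q.valid_mask
    out = {"mean_quality": float(np.nanmean(q.values))}
    n = int(m.sum())
    for gi, label in enumerate(GRADE_LABELS):
        out[f"share_{label}"] = 100.0 * float((grades[m] == gi).sum()) / n
    if lu is not None:
        for k in range(N_CLASSES):
            sel = m & (lu.values == k + 1)
            out[f"mean_q_{CLASS_LABELS[k]}"] = (
                float(q.values[sel].mean()) if sel.any() else np.nan)
    return pd.DataFrame([out])


def assess(lu: CategoricalRaster, roads: dict[str, np.ndarray] | None = None,
           sens: SensitivityTable | None = None,
           params: pd.DataFrame | None = None,
           k: float = DEFAULT_HALF_SATURATION,
           beta: np.ndarray | float = 1.0) -> HabitatResult:
    """End-to-end habitat scoring of one land-use map."""
    sens = sens or load_sensitivity()
    threats = build_threat_masks(lu, roads, params)
    impacts = [threat_impact(t, lu.cell_size) for t in threats]
    d = degradation(impacts, threats, sens, lu, beta)
    q = quality(d, sens, lu, k)
    g = grade(q)
    summary = summarize_quality(q, g, lu)
    return HabitatResult(d, q, g, k, summary)
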