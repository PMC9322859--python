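"""Per-class land suitability surfaces from a single-hidden-layer network.

The CA allocator needs, for every cell, the probability that local conditions
favour each of the six land classes.  These occurrence probabilities are
learned from the base-epoch map: cells are sampled (stratified by class so
rare classes such as waters and unused land are represented), the normalised
driver values are the features, the observed class the label, and a
single-hidden-layer perceptron with sigmoid hidden units maps drivers to
per-class probabilities.  Per cell the six probabilities are normalised to a
simplex, which the roulette competition downstream requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .grids import CLASS_LABELS, DRIVER_NAMES, N_CLASSES, CategoricalRaster, DriverStack

__all__ = [
    "SuitabilityModel",
    "SuitabilitySurface",
    "sample_training",
    "fit_suitability",
    "predict_suitability",
    "save_model",
    "load_model",
]

#: Minimum training cells per present class under stratified sampling.
MIN_PER_CLASS = 10
DEFAULT_HIDDEN_UNITS = 12
DEFAULT_SEED = 42


@dataclass
class SuitabilityModel:
    """A fitted occurrence-probability network.

    Wraps the perceptron together with the driver-name order it was trained
    on and the class codes present in training, so prediction is invariant to
    the caller's layer ordering and absent classes get probability zero.
    """

    network: MLPClassifier
    feature_names: tuple[str, ...]
    classes: np.ndarray  # 1-based class codes present in training
    hidden_units: int

    @property
    def hidden_weights(self) -> np.ndarray:
        """Input-to-hidden weight matrix (n_features, hidden_units)."""
        return self.network.coefs_[0]

    @property
    def output_weights(self) -> np.ndarray:
        """Hidden-to-output weight matrix (hidden_units, n_classes)."""
        return self.network.coefs_[1]


@dataclass
class SuitabilitySurface:
    """Per-class occurrence probabilities, shape (6, rows, cols).

    Invalid cells are NaN; per valid cell the six probabilities sum to 1.
    """

    probs: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[0] != N_CLASSES:
            raise ValueError("expected (6, rows, cols) probability stack")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[1:]


def sample_training(lu: CategoricalRaster, drivers: DriverStack, n: int,
                    seed: int = DEFAULT_SEED, stratified: bool = True) -> pd.DataFrame:
    """Sample ``n`` cells into a training table.

    Stratified mode allocates samples proportionally to class prevalence with
    a floor of ``MIN_PER_CLASS`` per present class; a class with fewer cells
    than its quota contributes all its cells (with a warning).  Features are
    the min-max normalised drivers; the label column holds the class code.
    """
    if lu.shape != drivers.shape:
        raise ValueError("land-use map and driver stack shapes differ")
    valid = lu.valid_mask & drivers.valid_mask
    n_valid = int(valid.sum())
    if n > n_valid:
        raise ValueError(f"requested {n} samples but only {n_valid} valid cells")
    rng = np.random.default_rng(seed)
    norm = drivers.normalized()
    feats = norm.as_matrix(norm.names)
    flat_lu = lu.values.ravel()
    flat_valid = valid.ravel()

    if not stratified:
        chosen = rng.choice(np.flatnonzero(flat_valid), size=n, replace=False)
    else:
        counts = lu.class_counts()
        present = np.flatnonzero(counts > 0)
        quota = np.zeros(N_CLASSES, dtype=np.int64)
        quota[present] = np.maximum(
            np.round(n * counts[present] / n_valid).astype(np.int64), MIN_PER_CLASS
        )
        picks = []
        for k in present:
            idx = np.flatnonzero(flat_valid & (flat_lu == k + 1))
            take = int(quota[k])
            if take >= idx.size:
                if take > idx.size:
                    warnings.warn(
                        f"class {CLASS_LABELS[k]!r} has only {idx.size} cells "
                        f"(< quota {take}); taking all", stacklevel=2)
                picks.append(idx)
            else:
                picks.append(rng.choice(idx, size=take, replace=False))
        chosen = np.concatenate(picks)

    table = pd.DataFrame(feats[chosen], columns=list(norm.names))
    table["label"] = flat_lu[chosen]
    return table


def fit_suitability(training: pd.DataFrame, hidden_units: int = DEFAULT_HIDDEN_UNITS,
                    seed: int = DEFAULT_SEED, max_iter: int = 400) -> SuitabilityModel:
    """Train the single-hidden-layer network on a training table.

    Hidden activation is the logistic sigmoid; the output layer is softmax
    over the classes present in training.  Deterministic given ``seed``
    (L-BFGS optimisation from a seeded initialisation).
    """
    labels = training["label"].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain at least 2 classes")
    feature_names = tuple(c for c in training.columns if c != "label")
    X = training[list(feature_names)].to_numpy(dtype=float)
    net = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")
        net.fit(X, labels)
    return SuitabilityModel(net, feature_names, np.asarray(net.classes_), hidden_units)


def predict_suitability(model: SuitabilityModel, drivers: DriverStack) -> SuitabilitySurface:
    """Evaluate the network over a driver stack.

    Layers are looked up by name (order-invariant); classes absent from
    training get probability 0, and each valid cell's six probabilities are
    renormalised to sum to 1.
    """
    missing = [n for n in model.feature_names if n not in drivers.names]
    if missing:
        raise KeyError(f"missing driver layer(s): {missing}")
    norm = drivers.normalized()
    X = norm.as_matrix(model.feature_names)
    valid = drivers.valid_mask.ravel()
    rows, cols = drivers.shape
    probs = np.full((N_CLASSES, rows * cols), np.nan)
    p = model.network.predict_proba(X[valid])
    full = np.zeros((valid.sum(), N_CLASSES))
    full[:, model.classes - 1] = p
    full /= full.sum(axis=1, keepdims=True)
    probs[:, valid] = full.T
    return SuitabilitySurface(probs.reshape(N_CLASSES, rows, cols), drivers.cell_size)


def save_model(model: SuitabilityModel, path) -> None:
    """Serialise layer sizes and weight arrays to a single ``.npz`` file."""
    np.savez(
        path,
        feature_names=np.array(model.feature_names),
        classes=model.classes,
        hidden_units=np.array([model.hidden_units]),
        coef0=model.network.coefs_[0],
        coef1=model.network.coefs_[1],
        intercept0=model.network.intercepts_[0],
        intercept1=model.network.intercepts_[1],
    )


def load_model(path) -> SuitabilityModel:
    """Rebuild a :class:`SuitabilityModel` from :func:`save_model` output."""
    dat = np.load(path, allow_pickle=False)
    classes = dat["classes"]
    hidden_units = int(dat["hidden_units"][0])
    n_features = dat["coef0"].shape[0]
    net = MLPClassifier(hidden_layer_sizes=(hidden_units,), activation="logistic")
    # minimal fitted-state reconstruction: weights, classes, output layout
    net.coefs_ = [dat["coef0"], dat["coef1"]]
    net.intercepts_ = [dat["intercept0"], dat["intercept1"]]
    net.classes_ = classes
    net.n_layers_ = 3
    # output layer width: 1 unit for binary models, one per class otherwise
    net.n_outputs_ = dat["coef1"].shape[1]
    net.out_activation_ = "softmax" if len(classes) > 2 else "logistic"
    feature_names = tuple(str(s) for s in dat["feature_names"])
    model = SuitabilityModel(net, feature_names, classes, hidden_units)
    model.network.n_features_in_ = n_features
    return model
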