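"""Multilayer extreme learning machine (ELM) classifier.

An ELM is a feedforward network whose hidden weights are drawn at random
and *frozen*; only the output weights are learned, in closed form, via the
Moore–Penrose pseudoinverse.  The multilayer variant here draws L
independent hidden layers, applies each one to the (standardized,
bias-augmented) input

    H_l = g_l([X, 1] @ W_l),        W_l ~ Uniform[-1, 1]

concatenates the hidden outputs column-wise, H = [H_1 | ... | H_L], and
solves

    beta = pinv(H) @ Y              (ridge_lambda = 0)
    beta = (H'H + lambda I)^-1 H'Y  (ridge_lambda > 0)

for one-hot targets Y.  Every layer sees the raw input X; the conventional
stacked composition (each layer fed the previous layer's output) is
available as ``layer_mode='stacked'``.  Training is one-shot — a single
matrix factorization, no epochs, no backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ACTIVATIONS = {
    # clip keeps exp() in range; sigmoid saturates identically either way
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class MELMConfig:
    n_layers: int = 3
    neurons_per_layer: tuple[int, ...] = (334, 333, 333)
    activation: str = "sigmoid"
    ridge_lambda: float = 1e-6
    layer_mode: str = "parallel"  # each layer sees X; 'stacked' chains layers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValidationError("n_layers must be >= 1")
        self.neurons_per_layer = tuple(int(n) for n in self.neurons_per_layer)
        if len(self.neurons_per_layer) != self.n_layers:
            raise ValidationError("neurons_per_layer length must equal n_layers")
        if any(n < 1 for n in self.neurons_per_layer):
            raise ValidationError("every layer needs >= 1 neuron")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.ridge_lambda < 0:
            raise ValidationError("ridge_lambda must be >= 0")
        if self.layer_mode not in ("parallel", "stacked"):
            raise ValidationError("layer_mode must be 'parallel' or 'stacked'")

    @property
    def total_hidden(self) -> int:
        return sum(self.neurons_per_layer)


def one_hot(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """n x K binary indicator matrix, exactly one 1 per row."""
    index = {c: k for k, c in enumerate(class_order)}
    out = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValidationError(f"label {lab!r} not in class_order {list(class_order)}")
        out[i, index[lab]] = 1.0
    return out


@dataclass
class MELMModel:
    config: MELMConfig
    layer_weights: list[np.ndarray]
    output_weights: np.ndarray
    class_order: list[str]
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def __post_init__(self) -> None:
        if self.output_weights.shape[1] != len(self.class_order):
            raise ValidationError("output weight columns must match class count")
        for w in self.layer_weights + [self.output_weights]:
            if not np.all(np.isfinite(w)):
                raise ValidationError("non-finite model weights")


def _augment(x: np.ndarray) -> np.ndarray:
    return np.hstack([x, np.ones((x.shape[0], 1))])


def _hidden(x_std: np.ndarray, cfg: MELMConfig,
            layer_weights: list[np.ndarray]) -> np.ndarray:
    g = ACTIVATIONS[cfg.activation]
    outputs = []
    current = x_std
    for w in layer_weights:
        h = g(_augment(current) @ w)
        outputs.append(h)
        if cfg.layer_mode == "stacked":
            current = h
    return np.hstack(outputs)


def fit(x: np.ndarray, labels: Sequence[str], cfg: MELMConfig,
        class_order: Sequence[str] | None = None) -> MELMModel:
    """Fit the multilayer ELM on features ``x`` and string labels."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("x must be a 2-D feature matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("x contains non-finite features")
    if len(labels) != x.shape[0]:
        raise ValidationError("label count must match row count")
    if class_order is None:
        class_order = sorted(set(labels))
    if len(set(labels)) < 2:
        raise ValidationError("need at least 2 classes in training labels")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"feature {bad} has zero variance in training data")
    x_std = (x - mean) / sd
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    layer_weights = []
    in_dim = x.shape[1]
    for n_l in cfg.neurons_per_layer:
        layer_weights.append(rng.uniform(-1.0, 1.0, size=(in_dim + 1, n_l)))
        if cfg.layer_mode == "stacked":
            in_dim = n_l
    h = _hidden(x_std, cfg, layer_weights)
    y = one_hot(labels, class_order)
    if cfg.ridge_lambda == 0:
        beta = np.linalg.pinv(h) @ y
    else:
        k = h.shape[1]
        beta = np.linalg.solve(h.T @ h + cfg.ridge_lambda * np.eye(k), h.T @ y)
    return MELMModel(config=cfg, layer_weights=layer_weights, output_weights=beta,
                     class_order=list(class_order), feature_mean=mean, feature_sd=sd)


def decision_scores(model: MELMModel, x_new: np.ndarray) -> np.ndarray:
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim == 1:
        x_new = x_new[None, :]
    if x_new.shape[1] != model.feature_mean.shape[0]:
        raise ValidationError(
            f"feature dimension {x_new.shape[1]} does not match training "
            f"dimension {model.feature_mean.shape[0]}"
        )
    x_std = (x_new - model.feature_mean) / model.feature_sd
    h = _hidden(x_std, model.config, model.layer_weights)
    return h @ model.output_weights


def predict(model: MELMModel, x_new: np.ndarray) -> list[str]:
    """Argmax over class scores; exact ties resolve to the lowest class index."""
    scores = decision_scores(model, x_new)
    idx = np.argmax(scores, axis=1)  # first maximum wins on ties
    return [model.class_order[k] for k in idx]


# ---------------------------------------------------------------------------
# persistence: directory of TSV weight matrices + flat metadata


def save_model(model: MELMModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(model.layer_weights):
        pd.DataFrame(w).to_csv(directory / f"W{i}.tsv", sep="\t", index=False,
                               header=False, float_format="%.17g")
    pd.DataFrame(model.output_weights).to_csv(
        directory / "beta.tsv", sep="\t", index=False, header=False,
        float_format="%.17g")
    pd.DataFrame({"mean": model.feature_mean, "sd": model.feature_sd}).to_csv(
        directory / "standardization.tsv", sep="\t", index=False,
        float_format="%.17g")
    cfg = model.config
    meta = [
        f"n_layers = {cfg.n_layers}",
        f"neurons_per_layer = {','.join(map(str, cfg.neurons_per_layer))}",
        f"activation = {cfg.activation}",
        f"ridge_lambda = {cfg.ridge_lambda!r}",
        f"layer_mode = {cfg.layer_mode}",
        f"seed = {cfg.seed}",
        f"class_order = {','.join(model.class_order)}",
    ]
    (directory / "metadata.txt").write_text("\n".join(meta) + "\n")


def load_model(directory: str | Path) -> MELMModel:
    directory = Path(directory)
    meta = {}
    for line in (directory / "metadata.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            meta[k.strip()] = v.strip()
    cfg = MELMConfig(
        n_layers=int(meta["n_layers"]),
        neurons_per_layer=tuple(int(v) for v in meta["neurons_per_layer"].split(",")),
        activation=meta["activation"],
        ridge_lambda=float(meta["ridge_lambda"]),
        layer_mode=meta["layer_mode"],
        seed=int(meta["seed"]),
    )
    layer_weights = [
        pd.read_csv(directory / f"W{i}.tsv", sep="\t", header=None,
                    float_precision="round_trip").to_numpy(float)
        for i in range(cfg.n_layers)
    ]
    beta = pd.read_csv(directory / "beta.tsv", sep="\t", header=None,
                       float_precision="round_trip").to_numpy(float)
    std = pd.read_csv(directory / "standardization.tsv", sep="\t",
                      float_precision="round_trip")
    return MELMModel(config=cfg, layer_weights=layer_weights, output_weights=beta,
                     class_order=meta["class_order"].split(","),
                     feature_mean=std["mean"].to_numpy(float),
                     feature_sd=std["sd"].to_numpy(float))
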