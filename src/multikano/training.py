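"""Training harness: minibatch Adam on softmax cross-entropy.

Fits either the KAN or the MLP baseline on (augmented) feature rows and
exposes per-cell class probabilities. Also provides the random-guessing
baseline that assigns a training-set cell type at random.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .kan import KANNetwork, SplineGrid, init_network
from .mlp import MLP, init_mlp, matched_mlp_widths


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, no early stopping).

    ``hidden`` lists hidden-layer widths; the network is
    [n_features, *hidden, n_classes]. For ``model_kind="mlp"`` the hidden
    width is re-derived to match the KAN's parameter count within 10%
    unless ``match_mlp_params`` is disabled.
    """

    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    seed: int = 0
    model_kind: str = "kan"
    hidden: Tuple[int, ...] = (64,)
    grid_intervals: int = 5
    spline_order: int = 3
    domain: Tuple[float, float] = (-1.0, 1.0)
    use_base: bool = True
    match_mlp_params: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.model_kind not in ("kan", "mlp"):
            raise ValueError("model_kind must be 'kan' or 'mlp'")

    def make_grid(self) -> SplineGrid:
        return SplineGrid(
            a=self.domain[0],
            b=self.domain[1],
            num_intervals=self.grid_intervals,
            order=self.spline_order,
        )


@dataclass
class PredictionResult:
    """Row-stochastic class probabilities plus argmax labels."""

    barcodes: Optional[np.ndarray]
    prob: np.ndarray
    labels: np.ndarray
    class_names: List[str]

    def to_frame(self):
        import pandas as pd

        data = {"barcode": self.barcodes if self.barcodes is not None
                else np.arange(len(self.labels)).astype(str)}
        data["predicted_type"] = self.labels
        for j, name in enumerate(self.class_names):
            data[f"prob_{name}"] = self.prob[:, j]
        return pd.DataFrame(data)


class _Adam:
    """Adam with decoupled-free L2 (weight decay added to the gradient)."""

    def __init__(self, params: List[np.ndarray], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_and_grad(
    logits: np.ndarray, y_index: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and dL/dlogits for integer targets."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), y_index] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), y_index] -= 1.0
    return loss, dlogits / n


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to apply it."""

    model: Union[KANNetwork, MLP]
    class_names: List[str]
    config: TrainConfig
    epoch_losses: List[float] = field(default_factory=list)
    manifest_hash: Optional[str] = None

    @property
    def n_features(self) -> int:
        return self.model.widths[0]

    def predict_proba(self, features: np.ndarray,
                      barcodes: Optional[np.ndarray] = None) -> PredictionResult:
        return predict_proba(self, features, barcodes)


def _build_model(config: TrainConfig, n_features: int, class_names: Sequence[str]):
    widths = [n_features, *config.hidden, len(class_names)]
    if config.model_kind == "kan":
        return init_network(
            widths,
            grid=config.make_grid(),
            seed=config.seed,
            class_names=class_names,
            use_base=config.use_base,
        )
    if config.match_mlp_params:
        widths = matched_mlp_widths(widths, config.make_grid())
    return init_mlp(widths, seed=config.seed, class_names=class_names)


def fit(
    features: np.ndarray,
    labels: Sequence[str],
    config: TrainConfig = TrainConfig(),
    manifest_hash: Optional[str] = None,
) -> FittedModel:
    """Train a classifier on feature rows with string labels.

    Minibatch Adam on softmax cross-entropy; the class list is the sorted
    set of distinct labels. Deterministic given (data, config): one RNG
    stream seeded from ``config.seed`` drives initialization and epoch
    shuffles.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=str)
    if features.ndim != 2 or features.shape[0] != len(labels):
        raise ValueError("features rows must match labels")
    class_names = sorted(set(labels))
    if len(class_names) < 2:
        raise ValueError("training needs at least 2 classes present")
    class_index = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_index[l] for l in labels])

    model = _build_model(config, features.shape[1], class_names)
    opt = _Adam(
        [arr for *_, arr in model.parameters()],
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    n = features.shape[0]
    epoch_losses: List[float] = []
    for _epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model.forward(features[idx], need_grad=True)
            loss, dlogits = cross_entropy_and_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/Inf training loss at epoch {_epoch}; "
                    "check input scaling and learning rate"
                )
            model.backward(dlogits)
            opt.step([g for *_, g in model.gradients()])
            total += loss * len(idx)
            seen += len(idx)
        epoch_losses.append(total / seen)
    return FittedModel(
        model=model,
        class_names=class_names,
        config=config,
        epoch_losses=epoch_losses,
        manifest_hash=manifest_hash,
    )


def predict_proba(
    fitted: FittedModel,
    features: np.ndarray,
    barcodes: Optional[np.ndarray] = None,
) -> PredictionResult:
    """Softmax class probabilities; argmax labels (lowest index on ties)."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != fitted.n_features:
        raise ValueError(
            f"feature width {features.shape[1]} does not match the model's "
            f"expected {fitted.n_features}"
            + (f" (preprocessing manifest {fitted.manifest_hash[:12]})"
               if fitted.manifest_hash else "")
        )
    prob = softmax(fitted.model.forward(features))
    pred = np.argmax(prob, axis=1)  # np.argmax takes the lowest index on ties
    labels = np.array(fitted.class_names, dtype=object)[pred].astype(str)
    return PredictionResult(
        barcodes=None if barcodes is None else np.asarray(barcodes, dtype=str),
        prob=prob,
        labels=labels,
        class_names=fitted.class_names,
    )


def random_guess_baseline(
    train_labels: Sequence[str],
    n_test: int,
    seed: int = 0,
    empirical: bool = False,
) -> np.ndarray:
    """Random-guessing baseline: each test cell gets an i.i.d. draw over
    the training cell types — uniform over distinct types by default, or
    over the empirical label frequencies with ``empirical=True``."""
    train_labels = np.asarray(train_labels, dtype=str)
    if len(train_labels) == 0:
        raise ValueError("training labels are empty")
    rng = np.random.default_rng(seed)
    if empirical:
        return rng.choice(train_labels, size=n_test, replace=True)
    classes = np.array(sorted(set(train_labels)))
    return classes[rng.integers(0, len(classes), size=n_test)]


# -- single-file model serialization ---------------------------------------

_FORMAT_VERSION = 1


def save_model(fitted: FittedModel, path: Union[str, Path]) -> None:
    """Single-file archive: JSON header + npz parameter payload."""
    cfg = fitted.config
    header = {
        "format_version": _FORMAT_VERSION,
        "model_kind": cfg.model_kind,
        "widths": fitted.model.widths,
        "class_names": fitted.class_names,
        "manifest_hash": fitted.manifest_hash,
        "epoch_losses": fitted.epoch_losses,
        "config": {
            "epochs": cfg.epochs,
            "batch_size": cfg.batch_size,
            "learning_rate": cfg.learning_rate,
            "weight_decay": cfg.weight_decay,
            "seed": cfg.seed,
            "model_kind": cfg.model_kind,
            "hidden": list(cfg.hidden),
            "grid_intervals": cfg.grid_intervals,
            "spline_order": cfg.spline_order,
            "domain": list(cfg.domain),
            "use_base": cfg.use_base,
            "match_mlp_params": cfg.match_mlp_params,
        },
    }
    arrays = {
        f"{i}__{name}": arr for i, name, arr in fitted.model.parameters()
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    payload = buf.getvalue()
    header_bytes = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(len(header_bytes).to_bytes(8, "little"))
        fh.write(header_bytes)
        fh.write(payload)


def load_model(path: Union[str, Path]) -> FittedModel:
    with open(path, "rb") as fh:
        header_len = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(header_len).decode())
        payload = fh.read()
    if header["format_version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {header['format_version']}")
    c = header["config"]
    config = TrainConfig(
        epochs=c["epochs"],
        batch_size=c["batch_size"],
        learning_rate=c["learning_rate"],
        weight_decay=c["weight_decay"],
        seed=c["seed"],
        model_kind=c["model_kind"],
        hidden=tuple(c["hidden"]),
        grid_intervals=c["grid_intervals"],
        spline_order=c["spline_order"],
        domain=tuple(c["domain"]),
        use_base=c["use_base"],
        match_mlp_params=c["match_mlp_params"],
    )
    widths = header["widths"]
    class_names = header["class_names"]
    if config.model_kind == "kan":
        model = init_network(
            widths, grid=config.make_grid(), seed=config.seed,
            class_names=class_names, use_base=config.use_base,
        )
    else:
        model = init_mlp(widths, seed=config.seed, class_names=class_names)
    arrays = np.load(io.BytesIO(payload))
    for i, name, arr in model.parameters():
        arr[...] = arrays[f"{i}__{name}"]
    return FittedModel(
        model=model,
        class_names=class_names,
        config=config,
        epoch_losses=list(header.get("epoch_losses", [])),
        manifest_hash=header.get("manifest_hash"),
    )
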