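"""MLP ablation baseline with the same training harness as the KAN.

A plain multilayer perceptron — affine layers with a fixed ReLU node
nonlinearity — sized to match the KAN's parameter count within 10% by
widening its hidden layer, so the KAN-vs-MLP ablation compares
architectures at comparable capacity rather than comparable widths.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kan import SplineGrid, kan_parameter_count


class MLP:
    """ReLU MLP with manual forward/backward, mirroring KANNetwork's API."""

    def __init__(
        self,
        widths: Sequence[int],
        rng: Optional[np.random.Generator] = None,
        class_names: Optional[Sequence[str]] = None,
    ) -> None:
        widths = list(widths)
        if len(widths) < 2 or any(w < 1 for w in widths):
            raise ValueError("widths must list >= 2 positive integers")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.widths_list = widths
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i + 1], widths[i]))
            for i in range(len(widths) - 1)
        ]
        self.biases = [np.zeros(widths[i + 1]) for i in range(len(widths) - 1)]
        n_classes = widths[-1]
        if class_names is None:
            class_names = [str(i) for i in range(n_classes)]
        if len(class_names) != n_classes:
            raise ValueError(f"{len(class_names)} class names for {n_classes} outputs")
        self.class_names = list(class_names)
        self.grads: dict = {}
        self._cache: Optional[list] = None

    @property
    def widths(self) -> List[int]:
        return list(self.widths_list)

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.widths_list[0]:
            raise ValueError(
                f"expected input of width {self.widths_list[0]}, got shape {x.shape}"
            )
        activations = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w.T + b
            h = z if i == last else np.maximum(z, 0.0)  # ReLU on hidden layers only
            activations.append(h)
        if need_grad:
            self._cache = activations
        return h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("forward(need_grad=True) must precede backward")
        activations = self._cache
        d = dlogits
        self.grads = {}
        for i in reversed(range(len(self.weights))):
            if i != len(self.weights) - 1:
                d = d * (activations[i + 1] > 0)  # ReLU mask
            self.grads[(i, "w")] = d.T @ activations[i]
            self.grads[(i, "b")] = d.sum(axis=0)
            d = d @ self.weights[i]
        return d

    def parameters(self) -> List[Tuple[int, str, np.ndarray]]:
        out = []
        for i in range(len(self.weights)):
            out.append((i, "w", self.weights[i]))
            out.append((i, "b", self.biases[i]))
        return out

    def gradients(self) -> List[Tuple[int, str, np.ndarray]]:
        return [(i, name, self.grads[(i, name)]) for i, name, _ in self.parameters()]

    def n_parameters(self) -> int:
        return int(sum(arr.size for _, _, arr in self.parameters()))


def mlp_forward(x: np.ndarray, mlp: MLP) -> np.ndarray:
    return mlp.forward(x)


def matched_mlp_widths(
    kan_widths: Sequence[int], grid: SplineGrid = SplineGrid()
) -> List[int]:
    """Hidden width giving an MLP a parameter count within 10% of the KAN.

    For a single hidden layer, KAN params ≈ (G + k + 2)(d·h + h·K) while
    the MLP has d·h' + h' + h'·K + K, so h' ≈ (G + k + 2)·h matches.
    """
    kan_widths = list(kan_widths)
    target = kan_parameter_count(kan_widths, grid)
    d, k_out = kan_widths[0], kan_widths[-1]
    hidden = max(1, round((target - k_out) / (d + 1 + k_out)))
    return [d, hidden, k_out]


def init_mlp(
    widths: Sequence[int],
    seed: int = 0,
    class_names: Optional[Sequence[str]] = None,
) -> MLP:
    return MLP(widths, rng=np.random.default_rng(seed), class_names=class_names)
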