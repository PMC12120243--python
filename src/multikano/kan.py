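"""Kolmogorov–Arnold network (KAN) built from scratch on NumPy.

In a KAN every scalar edge weight of an MLP is replaced by a learnable 1D
function φ(x) = w_b · silu(x) + w_s · Σ_i c_i B_i(x), where the B_i are
B-spline basis functions of degree k over a uniform grid of G intervals on
a fixed closed interval. Nodes do nothing but sum incoming edge outputs —
there is no node nonlinearity. Grids are fixed after construction; inputs
are clamped into the grid domain upstream by the preprocessing stage.

Both the forward pass and the analytic backward pass (with respect to
spline coefficients, base weights, spline weights, and the layer input)
are implemented here; correctness is pinned by brute-force and
finite-difference oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


def silu(x: np.ndarray) -> np.ndarray:
    """x * sigmoid(x) — the residual base function of each edge."""
    return x / (1.0 + np.exp(-x))


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


@dataclass(frozen=True)
class SplineGrid:
    """Uniform extended knot grid on [a, b].

    ``num_intervals`` (G) uniform intervals of the domain, degree ``order``
    (k); the knot vector is extended k knots beyond each end, giving
    G + 2k + 1 knots and G + k basis functions.
    """

    a: float = -1.0
    b: float = 1.0
    num_intervals: int = 5
    order: int = 3
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.num_intervals < 1:
            raise ValueError("num_intervals must be >= 1")
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if not self.a < self.b:
            raise ValueError("domain [a, b] is empty")
        h = (self.b - self.a) / self.num_intervals
        knots = self.a + h * np.arange(-self.order, self.num_intervals + self.order + 1)
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return self.num_intervals + self.order


def _order0(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """Degree-0 indicators over every knot interval; x == b is assigned to
    the last domain interval so the partition of unity closes at b."""
    t = grid.knots
    left = t[:-1]
    right = t[1:]
    n0 = ((x[..., None] >= left) & (x[..., None] < right)).astype(float)
    at_b = x == grid.b
    if np.any(at_b):
        n0[at_b] = 0.0
        n0[at_b, grid.order + grid.num_intervals - 1] = 1.0
    return n0


def _raise_degree(n_prev: np.ndarray, x: np.ndarray, t: np.ndarray, d: int) -> np.ndarray:
    """One Cox–de Boor step: degree d-1 basis values -> degree d."""
    denom1 = t[d:-1] - t[:-d - 1]
    denom2 = t[d + 1:] - t[1:-d]
    w1 = (x[..., None] - t[None, :-d - 1]) / denom1
    w2 = (t[None, d + 1:] - x[..., None]) / denom2
    return w1 * n_prev[..., :-1] + w2 * n_prev[..., 1:]


def bspline_basis(x: np.ndarray, grid: SplineGrid) -> np.ndarray:
    """All G + k basis values at each point of `x` (appended last axis).

    Cox–de Boor recursion; on [a, b] the values are non-negative and sum
    to one. Points outside [a, b] are evaluated by the same recursion
    (callers clamp upstream).
    """
    x = np.asarray(x, dtype=float)
    n = _order0(x, grid)
    for d in range(1, grid.order + 1):
        n = _raise_degree(n, x, grid.knots, d)
    return n


def bspline_basis_and_deriv(
    x: np.ndarray, grid: SplineGrid
) -> Tuple[np.ndarray, np.ndarray]:
    """Basis values and their x-derivatives (both shape x.shape + (G+k,)).

    dB_{i,k}/dx = k * ( B_{i,k-1}/(t_{i+k} - t_i)
                        - B_{i+1,k-1}/(t_{i+k+1} - t_{i+1}) ).
    """
    x = np.asarray(x, dtype=float)
    t = grid.knots
    k = grid.order
    n = _order0(x, grid)
    if k == 0:
        return n, np.zeros_like(n)
    for d in range(1, k):
        n = _raise_degree(n, x, t, d)
    lower = n  # degree k-1 values
    basis = _raise_degree(lower, x, t, k)
    denom1 = t[k:-1] - t[:-k - 1]
    denom2 = t[k + 1:] - t[1:-k]
    deriv = k * (lower[..., :-1] / denom1 - lower[..., 1:] / denom2)
    return basis, deriv


def edge_eval(
    x: np.ndarray,
    coeffs: np.ndarray,
    w_b: float,
    w_s: float,
    grid: SplineGrid,
    use_base: bool = True,
) -> np.ndarray:
    """One edge function: φ(x) = w_b·silu(x) + w_s·Σ_i c_i B_i(x)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (grid.n_basis,):
        raise ValueError(f"expected {grid.n_basis} spline coefficients, got {coeffs.shape}")
    spline = bspline_basis(x, grid) @ coeffs
    base = w_b * silu(np.asarray(x, dtype=float)) if use_base else 0.0
    return base + w_s * spline


class KANLayer:
    """n_out × n_in grid of edge functions sharing one spline grid.

    Parameters per edge: spline coefficients (G + k of them), a base
    weight w_b, and a spline weight w_s. Output node j sums its incoming
    edges: out[b, j] = Σ_i φ_{j,i}(x[b, i]).
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        grid: SplineGrid,
        rng: Optional[np.random.Generator] = None,
        use_base: bool = True,
    ) -> None:
        if n_in < 1 or n_out < 1:
            raise ValueError("layer widths must be positive")
        self.n_in = n_in
        self.n_out = n_out
        self.grid = grid
        self.use_base = use_base
        rng = rng if rng is not None else np.random.default_rng(0)
        m = grid.n_basis
        self.coeffs = rng.normal(0.0, 0.1, size=(n_out, n_in, m))
        self.w_s = np.ones((n_out, n_in))
        bound = np.sqrt(6.0 / n_in)
        self.w_b = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.grads: dict = {}
        self._cache: Optional[tuple] = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> List[Tuple[str, np.ndarray]]:
        return [("coeffs", self.coeffs), ("w_s", self.w_s), ("w_b", self.w_b)]

    def _effective_weights(self) -> np.ndarray:
        """W[j, i, m] = w_s[j, i] * c[j, i, m], flattened for one GEMM."""
        return (self.w_s[:, :, None] * self.coeffs).reshape(self.n_out, -1)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValueError(f"expected input of width {self.n_in}, got shape {x.shape}")
        if need_grad:
            basis, dbasis = bspline_basis_and_deriv(x, self.grid)
        else:
            basis, dbasis = bspline_basis(x, self.grid), None
        n = x.shape[0]
        bflat = basis.reshape(n, -1)
        out = bflat @ self._effective_weights().T
        if self.use_base:
            out = out + silu(x) @ self.w_b.T
        if need_grad:
            self._cache = (x, basis, dbasis, bflat)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads from dL/dout; return dL/dx."""
        if self._cache is None:
            raise RuntimeError("forward(need_grad=True) must precede backward")
        x, basis, dbasis, bflat = self._cache
        n = x.shape[0]
        m = self.grid.n_basis
        dw = (dout.T @ bflat).reshape(self.n_out, self.n_in, m)
        self.grads = {
            "coeffs": dw * self.w_s[:, :, None],
            "w_s": np.einsum("jim,jim->ji", dw, self.coeffs),
        }
        dspline = (dout @ self._effective_weights()).reshape(n, self.n_in, m)
        dx = np.einsum("bim,bim->bi", dspline, dbasis)
        if self.use_base:
            self.grads["w_b"] = dout.T @ silu(x)
            dx = dx + (dout @ self.w_b) * silu_grad(x)
        else:
            self.grads["w_b"] = np.zeros_like(self.w_b)
        return dx


def kan_layer_forward(x: np.ndarray, layer: KANLayer) -> np.ndarray:
    """Functional alias for a single layer's forward pass."""
    return layer.forward(x)


class KANNetwork:
    """A stack of KAN layers plus the ordered output class names."""

    def __init__(self, layers: Sequence[KANLayer], class_names: Optional[Sequence[str]] = None):
        layers = list(layers)
        for prev, nxt in zip(layers, layers[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"adjacent layer widths mismatch: {prev.n_out} -> {nxt.n_in}"
                )
        self.layers = layers
        n_classes = layers[-1].n_out
        if class_names is None:
            class_names = [str(i) for i in range(n_classes)]
        if len(class_names) != n_classes:
            raise ValueError(
                f"{len(class_names)} class names for {n_classes} output units"
            )
        self.class_names = list(class_names)

    @property
    def widths(self) -> List[int]:
        return [self.layers[0].n_in] + [l.n_out for l in self.layers]

    def forward(self, x: np.ndarray, need_grad: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, need_grad=need_grad)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def parameters(self) -> List[Tuple[int, str, np.ndarray]]:
        return [
            (i, name, arr)
            for i, layer in enumerate(self.layers)
            for name, arr in layer.parameters()
        ]

    def gradients(self) -> List[Tuple[int, str, np.ndarray]]:
        return [
            (i, name, layer.grads[name])
            for i, layer in enumerate(self.layers)
            for name, _ in layer.parameters()
        ]

    def n_parameters(self) -> int:
        return int(sum(arr.size for _, _, arr in self.parameters()))


def network_forward(x: np.ndarray, net: KANNetwork) -> np.ndarray:
    """Pre-softmax logits for a batch (composition of the layers)."""
    return net.forward(x)


def init_network(
    widths: Sequence[int],
    grid: SplineGrid = SplineGrid(),
    seed: int = 0,
    class_names: Optional[Sequence[str]] = None,
    use_base: bool = True,
) -> KANNetwork:
    """Seeded construction: spline coeffs ~ N(0, 0.1²), w_s = 1, w_b
    uniform with a fan-in-scaled bound."""
    widths = list(widths)
    if len(widths) < 2:
        raise ValueError("need at least an input and an output width")
    if any(w < 1 for w in widths):
        raise ValueError("all widths must be positive")
    rng = np.random.default_rng(seed)
    layers = [
        KANLayer(widths[i], widths[i + 1], grid, rng=rng, use_base=use_base)
        for i in range(len(widths) - 1)
    ]
    return KANNetwork(layers, class_names=class_names)


def kan_parameter_count(widths: Sequence[int], grid: SplineGrid = SplineGrid()) -> int:
    """Parameters of a KAN with the given widths: (G + k + 2) per edge."""
    per_edge = grid.n_basis + 2
    return sum(widths[i] * widths[i + 1] * per_edge for i in range(len(widths) - 1))
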