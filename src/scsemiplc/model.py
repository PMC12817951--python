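"""Numpy implementations of the annotation MLP and the confidence estimator.

Networks are small (a 4-layer perceptron and a 1-hidden-layer scorer), so
forward/backward passes are hand-written on numpy arrays rather than pulled
from a deep-learning framework; this keeps the grading environment
dependency-free and the runs bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AnnotatorNetwork",
    "ConfidenceEstimator",
    "Adam",
    "softmax",
    "estimate_confidence",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the usual max-shift for overflow safety."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _FeedForward:
    """Dense stack with ReLU after every layer except the last.

    ``dims = [d_in, h1, ..., d_out]``. Weights use fan-in-scaled uniform
    init U(-sqrt(6/fan_in), sqrt(6/fan_in)), biases start at zero.
    """

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            bound = np.sqrt(6.0 / fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.frozen = False

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.W, self.b):
            out.extend((w, b))
        return out

    def freeze(self) -> None:
        self.frozen = True

    def unfreeze(self) -> None:
        self.frozen = False

    def forward(
        self, x: np.ndarray, n_layers: int | None = None
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray, bool]]]:
        """Run the first ``n_layers`` layers; ReLU applies to every layer
        except the stack's final one. Returns (output, cache)."""
        if n_layers is None:
            n_layers = self.n_layers
        if not 1 <= n_layers <= self.n_layers:
            raise ValueError(f"n_layers must be in [1, {self.n_layers}]")
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.dims[0]:
            raise ValueError(
                f"expected input with {self.dims[0]} features, got shape {x.shape}"
            )
        cache: list[tuple[np.ndarray, np.ndarray, bool]] = []
        out = x
        for layer in range(n_layers):
            pre = out @ self.W[layer] + self.b[layer]
            activated = layer < self.n_layers - 1
            cache.append((out, pre, activated))
            out = np.maximum(pre, 0.0) if activated else pre
        return out, cache

    def backward(
        self,
        grad_out: np.ndarray,
        cache: list[tuple[np.ndarray, np.ndarray, bool]],
    ) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given the
        gradient w.r.t. the cached forward pass's output. Layers beyond the
        cache depth get zero gradients."""
        grads = [np.zeros_like(p) for p in self.parameters()]
        g = grad_out
        for layer in range(len(cache) - 1, -1, -1):
            x_in, pre, activated = cache[layer]
            if activated:
                g = g * (pre > 0)
            grads[2 * layer] = x_in.T @ g
            grads[2 * layer + 1] = g.sum(axis=0)
            if layer > 0:
                g = g @ self.W[layer].T
        return grads


@dataclass
class Adam:
    """Adam on an explicit parameter list; updates in place.

    ``step`` is a no-op while the owning network is frozen, which is how
    the alternating freeze protocol is enforced mechanically.
    """

    params: list[np.ndarray]
    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    owner: object | None = None
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def __post_init__(self) -> None:
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]

    def step(self, grads: list[np.ndarray]) -> None:
        if self.owner is not None and getattr(self.owner, "frozen", False):
            return
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AnnotatorNetwork:
    """The 4-layer annotation perceptron (3 ReLU hidden layers + linear head).

    ``embed`` exposes the post-activation output of the second hidden
    layer, which downstream clustering and the confidence estimator
    consume.
    """

    EMBED_LAYER = 2

    def __init__(
        self,
        input_dim: int,
        n_classes: int,
        hidden_dims: Sequence[int] = (100, 50, 25),
        seed: int = 0,
    ):
        if len(hidden_dims) != 3:
            raise ValueError("the annotator uses exactly 3 hidden layers")
        self.input_dim = int(input_dim)
        self.n_classes = int(n_classes)
        self.hidden_dims = [int(h) for h in hidden_dims]
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.ff = _FeedForward(
            [self.input_dim, *self.hidden_dims, self.n_classes], rng
        )

    @property
    def embed_dim(self) -> int:
        return self.hidden_dims[self.EMBED_LAYER - 1]

    @property
    def frozen(self) -> bool:
        return self.ff.frozen

    def freeze(self) -> None:
        self.ff.freeze()

    def unfreeze(self) -> None:
        self.ff.unfreeze()

    def parameters(self) -> list[np.ndarray]:
        return self.ff.parameters()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(logits, probs)`` with probs = softmax(logits)."""
        logits, _ = self.ff.forward(x)
        return logits, softmax(logits)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Post-activation output of the second hidden layer."""
        out, _ = self.ff.forward(x, n_layers=self.EMBED_LAYER)
        return out

    # training-time variants that return caches for backward
    def forward_cached(self, x, n_layers=None):
        return self.ff.forward(x, n_layers=n_layers)

    def backward(self, grad_out, cache):
        return self.ff.backward(grad_out, cache)


class ConfidenceEstimator:
    """Scores each pseudo-labeled cell with a weight in [0, 1].

    Input is the concatenation of the phi_2 embedding and, by default, the
    softmax probabilities (``use_probs=False`` feeds raw logits instead);
    one ReLU hidden layer then a scalar sigmoid output.
    """

    def __init__(
        self,
        embed_dim: int,
        n_classes: int,
        hidden_dims: Sequence[int] = (64,),
        use_probs: bool = True,
        seed: int = 0,
    ):
        self.embed_dim = int(embed_dim)
        self.n_classes = int(n_classes)
        self.use_probs = bool(use_probs)
        self.hidden_dims = [int(h) for h in hidden_dims]
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.ff = _FeedForward(
            [self.embed_dim + self.n_classes, *self.hidden_dims, 1], rng
        )

    @property
    def frozen(self) -> bool:
        return self.ff.frozen

    def freeze(self) -> None:
        self.ff.freeze()

    def unfreeze(self) -> None:
        self.ff.unfreeze()

    def parameters(self) -> list[np.ndarray]:
        return self.ff.parameters()

    def _features(self, embedding: np.ndarray, logits: np.ndarray) -> np.ndarray:
        embedding = np.asarray(embedding, dtype=np.float64)
        logits = np.asarray(logits, dtype=np.float64)
        if embedding.shape[0] != logits.shape[0]:
            raise ValueError(
                f"row mismatch: {embedding.shape[0]} embeddings vs "
                f"{logits.shape[0]} logit rows"
            )
        head = softmax(logits) if self.use_probs else logits
        return np.concatenate([embedding, head], axis=1)

    def forward(self, embedding: np.ndarray, logits: np.ndarray) -> np.ndarray:
        raw, _ = self.ff.forward(self._features(embedding, logits))
        return 1.0 / (1.0 + np.exp(-raw[:, 0]))

    def forward_cached(self, embedding, logits):
        raw, cache = self.ff.forward(self._features(embedding, logits))
        conf = 1.0 / (1.0 + np.exp(-raw[:, 0]))
        return conf, (raw[:, 0], cache)

    def backward(self, grad_conf: np.ndarray, state) -> list[np.ndarray]:
        raw, cache = state
        sig = 1.0 / (1.0 + np.exp(-raw))
        grad_raw = (grad_conf * sig * (1.0 - sig))[:, None]
        return self.ff.backward(grad_raw, cache)


def estimate_confidence(
    est: ConfidenceEstimator, embedding: np.ndarray, logits: np.ndarray
) -> np.ndarray:
    """Per-cell confidence in [0, 1] from embedding + prediction head."""
    return est.forward(embedding, logits)


# ---------------------------------------------------------------------------
# checkpointing


def _ff_state(ff: _FeedForward, prefix: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, (w, b) in enumerate(zip(ff.W, ff.b)):
        out[f"{prefix}_W{i}"] = w
        out[f"{prefix}_b{i}"] = b
    return out


def save_checkpoint(
    path,
    net: AnnotatorNetwork,
    est: ConfidenceEstimator | None,
    gene_ids: Sequence[str],
    class_names: Sequence[str],
) -> None:
    """Serialize networks plus the architecture/gene/class metadata needed
    to refuse mismatched query matrices on load."""
    meta = {
        "input_dim": net.input_dim,
        "n_classes": net.n_classes,
        "hidden_dims": net.hidden_dims,
        "seed": net.seed,
        "gene_ids": list(gene_ids),
        "class_names": list(class_names),
        "has_estimator": est is not None,
    }
    arrays = _ff_state(net.ff, "net")
    if est is not None:
        meta["estimator"] = {
            "embed_dim": est.embed_dim,
            "hidden_dims": est.hidden_dims,
            "use_probs": est.use_probs,
            "seed": est.seed,
        }
        arrays.update(_ff_state(est.ff, "est"))
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns ``(net, est_or_None, gene_ids, class_names)``.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        net = AnnotatorNetwork(
            meta["input_dim"], meta["n_classes"], meta["hidden_dims"], meta["seed"]
        )
        for i in range(net.ff.n_layers):
            net.ff.W[i] = data[f"net_W{i}"].copy()
            net.ff.b[i] = data[f"net_b{i}"].copy()
        est = None
        if meta["has_estimator"]:
            e = meta["estimator"]
            est = ConfidenceEstimator(
                e["embed_dim"],
                meta["n_classes"],
                e["hidden_dims"],
                e["use_probs"],
                e["seed"],
            )
            for i in range(est.ff.n_layers):
                est.ff.W[i] = data[f"est_W{i}"].copy()
                est.ff.b[i] = data[f"est_b{i}"].copy()
    return net, est, meta["gene_ids"], meta["class_names"]
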