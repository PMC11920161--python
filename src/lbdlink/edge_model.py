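"""Linking-concept prediction: (A, C) edge representations and the MLP.

The closed-discovery model receives the embeddings of a starting concept A
and a target concept C, combines them into a single edge representation
(average, concatenation, or Hadamard product, optionally pre-scaled by a
constant factor to sharpen early gradients), and regresses the embedding of
the linking concept B through a compact feed-forward network. The output
layer is tanh so predictions stay inside the [-1, 1] hypercube that the
normalized concept embeddings occupy, and training minimizes cosine distance
1 - cos(prediction, B embedding) with Adam over the positive training
triplets only — negatives carry no gradient signal under a similarity
objective.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .graph_data import ConceptId, DiscoveryDataset
from .line_embed import EmbeddingTable

__all__ = [
    "EdgeReprConfig",
    "ModelConfig",
    "TrainedModel",
    "combine",
    "cosine_similarity",
    "train_model",
    "predict_b",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class EdgeReprConfig:
    """How the A and C vectors become one model input.

    ``scale`` multiplies each input vector before combination (1 disables it;
    10 is the inductive-bias setting). Average and Hadamard are symmetric in
    (A, C); concatenation is order-sensitive.
    """

    mode: str = "concat"
    scale: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("average", "concat", "hadamard"):
            raise ValueError(f"mode must be average|concat|hadamard, got {self.mode!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def input_dim(self, emb_dim: int) -> int:
        return 2 * emb_dim if self.mode == "concat" else emb_dim


@dataclass(frozen=True)
class ModelConfig:
    """MLP and optimizer settings.

    ``hidden_units=None`` resolves to the concept-embedding dimension. The
    default depth of two hidden layers gives a four-layer network counting the
    input-combination and output layers. ``loss`` selects ``one_minus_cos``
    (bounded in [0, 2], easier to monitor) or ``neg_cos``; the optima are
    identical.
    """

    hidden_layers: int = 2
    hidden_units: int | None = None
    hidden_activation: str = "relu"
    dropout: float = 0.10
    learning_rate: float = 1e-4
    batch_size: int = 256
    epochs: int = 400
    loss: str = "one_minus_cos"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("hidden_layers, batch_size and epochs must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_activation not in ("relu", "tanh"):
            raise ValueError(f"unsupported hidden activation {self.hidden_activation!r}")
        if self.loss not in ("one_minus_cos", "neg_cos"):
            raise ValueError(f"unsupported loss {self.loss!r}")


def combine(a_vec: np.ndarray, c_vec: np.ndarray, config: EdgeReprConfig) -> np.ndarray:
    """Combine (batches of) A and C vectors into edge representations."""
    a = np.asarray(a_vec, dtype=np.float64) * config.scale
    c = np.asarray(c_vec, dtype=np.float64) * config.scale
    if a.shape != c.shape:
        raise ValueError(f"input shapes differ: {a.shape} vs {c.shape}")
    if config.mode == "average":
        return (a + c) / 2.0
    if config.mode == "concat":
        return np.concatenate([a, c], axis=-1)
    return a * c  # hadamard


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-zero vectors, in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


class _MLP:
    """Dense ReLU/tanh network with tanh output, inverted dropout, and Adam."""

    def __init__(self, input_dim: int, hidden_units: int, hidden_layers: int,
                 output_dim: int, hidden_activation: str, seed: int):
        rng = np.random.default_rng(seed)
        dims = [input_dim] + [hidden_units] * hidden_layers + [output_dim]
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in) if hidden_activation == "relu" else np.sqrt(1.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.hidden_activation = hidden_activation
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, list]:
        cache = []
        h = x
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            last = layer == len(self.weights) - 1
            if last:
                out = np.tanh(z)
                cache.append((h, z, out, None))
                return out, cache
            a = np.maximum(z, 0.0) if self.hidden_activation == "relu" else np.tanh(z)
            mask = None
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
            cache.append((h, z, a, mask))
            h = a
        raise AssertionError("unreachable")

    def backward(self, cache: list, grad_out: np.ndarray) -> list:
        grads = []
        delta = grad_out
        for layer in reversed(range(len(self.weights))):
            h, z, a, mask = cache[layer]
            if layer == len(self.weights) - 1:
                delta = delta * (1.0 - a ** 2)  # tanh'
            else:
                if mask is not None:
                    delta = delta * mask
                if self.hidden_activation == "relu":
                    delta = delta * (z > 0.0)
                else:
                    delta = delta * (1.0 - np.tanh(z) ** 2)
            grads.append((h.T @ delta, delta.sum(axis=0)))
            delta = delta @ self.weights[layer].T
        grads.reverse()
        return grads

    def adam_step(self, grads: list, lr: float, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        params = self.weights + self.biases
        flat = [g for g, _ in grads] + [g for _, g in grads]
        for i, (p, g) in enumerate(zip(params, flat)):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g ** 2
            m_hat = self._adam_m[i] / (1 - beta1 ** self._adam_t)
            v_hat = self._adam_v[i] / (1 - beta2 ** self._adam_t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


def _cosine_loss_grad(pred: np.ndarray, target: np.ndarray,
                      loss: str) -> tuple[float, np.ndarray]:
    """Mean cosine-distance loss over a batch and its gradient wrt pred."""
    pn = np.linalg.norm(pred, axis=1, keepdims=True)
    tn = np.linalg.norm(target, axis=1, keepdims=True)
    pn = np.maximum(pn, 1e-12)
    tn = np.maximum(tn, 1e-12)
    cos = np.sum(pred * target, axis=1, keepdims=True) / (pn * tn)
    base = 1.0 if loss == "one_minus_cos" else 0.0
    value = float(np.mean(base - cos))
    # d(-cos)/dpred = -(t/(|p||t|) - cos * p/|p|^2)
    grad = -(target / (pn * tn) - cos * pred / pn ** 2) / pred.shape[0]
    return value, grad


@dataclass
class TrainedModel:
    """A trained linking-concept predictor plus its configs and history."""

    mlp: _MLP
    repr_cfg: EdgeReprConfig
    model_cfg: ModelConfig
    emb_dim: int
    history: dict = field(default_factory=dict)
    n_skipped: int = 0


def _build_training_arrays(dataset: DiscoveryDataset, embeddings: EmbeddingTable,
                           repr_cfg: EdgeReprConfig, missing: str) -> tuple[np.ndarray, np.ndarray, int]:
    xs, ys, skipped = [], [], 0
    for rec in dataset.train:
        if not rec.positive:
            continue
        if rec.a not in embeddings or rec.b not in embeddings or rec.c not in embeddings:
            if missing == "skip":
                skipped += 1
                continue
            absent = [str(x) for x in (rec.a, rec.b, rec.c) if x not in embeddings]
            raise KeyError(f"triplet concepts without embeddings: {', '.join(absent)}")
        xs.append(combine(embeddings[rec.a], embeddings[rec.c], repr_cfg))
        ys.append(embeddings[rec.b])
    if not xs:
        raise ValueError("no positive training triplets with embeddings")
    return np.vstack(xs), np.vstack(ys), skipped


def train_model(dataset: DiscoveryDataset, embeddings: EmbeddingTable,
                repr_cfg: EdgeReprConfig = EdgeReprConfig(),
                model_cfg: ModelConfig = ModelConfig(),
                eval_hook: Callable[["TrainedModel"], float] | None = None,
                missing: str = "error") -> TrainedModel:
    """Train the linking-concept predictor on the dataset's positive triplets.

    ``eval_hook``, when given, is called with the in-progress model after
    every epoch and its return value (typically the gold concept's rank) is
    appended to ``history["gold_rank"]``. ``missing`` selects hard failure or
    skip-with-count for triplets lacking embeddings.
    """
    if missing not in ("error", "skip"):
        raise ValueError("missing must be 'error' or 'skip'")
    X, Y, skipped = _build_training_arrays(dataset, embeddings, repr_cfg, missing)
    emb_dim = embeddings.dim
    hidden = model_cfg.hidden_units if model_cfg.hidden_units is not None else emb_dim
    mlp = _MLP(repr_cfg.input_dim(emb_dim), hidden, model_cfg.hidden_layers,
               emb_dim, model_cfg.hidden_activation, model_cfg.seed)
    model = TrainedModel(mlp=mlp, repr_cfg=repr_cfg, model_cfg=model_cfg,
                         emb_dim=emb_dim, history={"loss": []}, n_skipped=skipped)
    if eval_hook is not None:
        model.history["gold_rank"] = []

    rng = np.random.default_rng(model_cfg.seed + 1)
    n = X.shape[0]
    for _ in range(model_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, model_cfg.batch_size):
            idx = order[start:start + model_cfg.batch_size]
            pred, cache = mlp.forward(X[idx], dropout=model_cfg.dropout, rng=rng)
            value, grad = _cosine_loss_grad(pred, Y[idx], model_cfg.loss)
            mlp.adam_step(mlp.backward(cache, grad), model_cfg.learning_rate)
            losses.append(value)
        model.history["loss"].append(float(np.mean(losses)))
        if eval_hook is not None:
            model.history["gold_rank"].append(eval_hook(model))
    return model


def predict_batch(model: TrainedModel, inputs: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off); outputs lie in [-1, 1]."""
    out, _ = model.mlp.forward(np.atleast_2d(inputs), dropout=0.0, rng=None)
    return out


def predict_b(model: TrainedModel, a: ConceptId, c: ConceptId,
              embeddings: EmbeddingTable,
              repr_cfg: EdgeReprConfig | None = None) -> np.ndarray:
    """Predict the linking-concept embedding for the pair (a, c)."""
    for cid in (a, c):
        if cid not in embeddings:
            raise KeyError(f"concept {cid} has no embedding")
    cfg = repr_cfg if repr_cfg is not None else model.repr_cfg
    x = combine(embeddings[a], embeddings[c], cfg)
    return predict_batch(model, x)[0]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Self-describing checkpoint: configs as JSON plus the weight arrays."""
    meta = {
        "repr_cfg": asdict(model.repr_cfg),
        "model_cfg": asdict(model.model_cfg),
        "emb_dim": model.emb_dim,
        "history": model.history,
        "n_skipped": model.n_skipped,
        "n_layers": len(model.mlp.weights),
        "hidden_activation": model.mlp.hidden_activation,
    }
    arrays = {}
    for i, (w, b) in enumerate(zip(model.mlp.weights, model.mlp.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        repr_cfg = EdgeReprConfig(**meta["repr_cfg"])
        model_cfg = ModelConfig(**meta["model_cfg"])
        hidden = model_cfg.hidden_units if model_cfg.hidden_units is not None else meta["emb_dim"]
        mlp = _MLP(repr_cfg.input_dim(meta["emb_dim"]), hidden, model_cfg.hidden_layers,
                   meta["emb_dim"], meta["hidden_activation"], model_cfg.seed)
        mlp.weights = [np.array(data[f"w{i}"]) for i in range(meta["n_layers"])]
        mlp.biases = [np.array(data[f"b{i}"]) for i in range(meta["n_layers"])]
    return TrainedModel(mlp=mlp, repr_cfg=repr_cfg, model_cfg=model_cfg,
                        emb_dim=meta["emb_dim"], history=meta["history"],
                        n_skipped=meta["n_skipped"])
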