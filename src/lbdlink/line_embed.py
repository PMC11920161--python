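"""First- and second-order LINE vertex embeddings for co-occurrence graphs.

LINE learns low-dimensional vertex vectors by edge sampling with negative
sampling: edges are drawn with probability proportional to their weight, and
for each drawn edge the model pushes the endpoint vectors together while
pushing the source away from noise vertices drawn from a degree^(3/4)
distribution. First-order proximity ties directly connected vertices
(symmetric objective, one vector per vertex: maximize
w_ij · log σ(u_i·u_j) plus negative terms, the KL match between the model
joint and the edge-weight empirical distribution); second-order proximity
ties vertices with shared neighborhoods through separate context vectors
(maximize log σ(u'_j·u_i) plus negatives). The two orders are trained
separately, per-half L2-normalized, and concatenated into the final concept
representation.

Updates are applied in small vectorized mini-batches of sampled edges, the
numpy analogue of LINE's asynchronous SGD; with a fixed seed the run is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import numpy as np

from .graph_data import ConceptId

__all__ = [
    "LineConfig",
    "EmbeddingTable",
    "train_line",
    "concat_reweight",
    "write_embeddings",
    "read_embeddings",
]


class EmbeddingTable:
    """Concept → vector map backed by a dense matrix.

    ``order_tag`` records provenance: ``"first"``, ``"second"``, or
    ``"concatenated"``. All vectors share length ``dim``.
    """

    def __init__(self, concepts: list[ConceptId], matrix: np.ndarray, order_tag: str):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[0] != len(concepts):
            raise ValueError("matrix shape does not match the concept list")
        if len(set(concepts)) != len(concepts):
            raise ValueError("duplicate concepts in embedding table")
        self.concepts = list(concepts)
        self.matrix = matrix
        self.order_tag = order_tag
        self._index = {cid: i for i, cid in enumerate(self.concepts)}

    @classmethod
    def from_dict(cls, vectors: Mapping[ConceptId, np.ndarray], order_tag: str) -> "EmbeddingTable":
        concepts = list(vectors)
        matrix = np.vstack([np.asarray(vectors[c], dtype=np.float64) for c in concepts])
        return cls(concepts, matrix, order_tag)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept: ConceptId) -> bool:
        return concept in self._index

    def __getitem__(self, concept: ConceptId) -> np.ndarray:
        try:
            return self.matrix[self._index[concept]]
        except KeyError:
            raise KeyError(f"concept {concept} has no embedding") from None

    def items(self) -> Iterator[tuple[ConceptId, np.ndarray]]:
        for cid in self.concepts:
            yield cid, self.matrix[self._index[cid]]

    def submatrix(self, concepts: list[ConceptId]) -> np.ndarray:
        """Rows for ``concepts`` in order; raises naming any missing concept."""
        missing = [str(c) for c in concepts if c not in self._index]
        if missing:
            raise KeyError(f"concepts without embeddings: {', '.join(missing[:10])}")
        idx = np.fromiter((self._index[c] for c in concepts), dtype=np.int64, count=len(concepts))
        return self.matrix[idx]


@dataclass(frozen=True)
class LineConfig:
    """Training settings for one LINE order.

    ``n_samples`` counts drawn edges (one SGD update each); one million is the
    desk-scale default. ``n_negative`` noise vertices per edge and the linearly
    decayed ``initial_lr`` follow the original algorithm's conventions.
    """

    dim_per_order: int = 50
    n_samples: int = 1_000_000
    n_negative: int = 5
    initial_lr: float = 0.025
    batch_size: int = 1024
    seed: int = 0

    def validate(self) -> None:
        for name in ("dim_per_order", "n_samples", "n_negative", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_line(graph: nx.Graph, order: int, config: LineConfig = LineConfig()) -> EmbeddingTable:
    """Train LINE embeddings of the given proximity order over ``graph``.

    Every vertex receives a vector; isolated vertices keep their uniform
    (-0.5/dim, 0.5/dim) initialization since no edge sample can update them.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    config.validate()
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges to sample")

    vertices = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(vertices)}
    n = len(vertices)
    dim = config.dim_per_order

    edges = np.array([[index[u], index[v]] for u, v in graph.edges], dtype=np.int64)
    weights = np.array([graph[u][v].get("weight", 1.0) for u, v in graph.edges], dtype=np.float64)
    edge_p = weights / weights.sum()

    degree = np.zeros(n)
    for (u, v), w in zip(edges, weights):
        degree[u] += w
        degree[v] += w
    noise = degree ** 0.75
    if noise.sum() == 0:
        raise ValueError("graph has no weighted edges")
    noise_p = noise / noise.sum()

    rng = np.random.default_rng(config.seed)
    emb = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim))
    ctx = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n, dim)) if order == 2 else None

    total = config.n_samples
    done = 0
    while done < total:
        bs = min(config.batch_size, total - done)
        lr = config.initial_lr * max(1.0 - done / total, 1e-4)
        batch = edges[rng.choice(len(edges), size=bs, p=edge_p)]
        # undirected graph: random orientation of each sampled edge
        flip = rng.random(bs) < 0.5
        src = np.where(flip, batch[:, 1], batch[:, 0])
        dst = np.where(flip, batch[:, 0], batch[:, 1])
        neg = rng.choice(n, size=(bs, config.n_negative), p=noise_p)

        target = ctx if order == 2 else emb
        u = emb[src]                       # (bs, dim)
        t_pos = target[dst]                # (bs, dim)
        t_neg = target[neg]                # (bs, K, dim)

        g_pos = 1.0 - _sigmoid(np.einsum("bd,bd->b", u, t_pos))       # (bs,)
        g_neg = -_sigmoid(np.einsum("bd,bkd->bk", u, t_neg))          # (bs, K)
        # noise draws colliding with either endpoint carry no gradient
        g_neg *= (neg != src[:, None]) & (neg != dst[:, None])

        grad_u = g_pos[:, None] * t_pos + np.einsum("bk,bkd->bd", g_neg, t_neg)
        np.add.at(emb, src, lr * grad_u)
        np.add.at(target, dst, lr * g_pos[:, None] * u)
        np.add.at(target, neg.ravel(),
                  lr * (g_neg[:, :, None] * u[:, None, :]).reshape(-1, dim))
        done += bs

    return EmbeddingTable(vertices, emb, "first" if order == 1 else "second")


def concat_reweight(first: EmbeddingTable, second: EmbeddingTable) -> EmbeddingTable:
    """Concatenate two embedding tables after per-half L2 normalization.

    Normalizing each half independently balances the two orders without any
    tunable parameter; the result has dim = first.dim + second.dim.
    """
    missing_in_second = [str(c) for c in first.concepts if c not in second]
    missing_in_first = [str(c) for c in second.concepts if c not in first]
    if missing_in_second or missing_in_first:
        raise ValueError(
            "embedding coverage mismatch; missing from second: "
            f"{missing_in_second[:10]}; missing from first: {missing_in_first[:10]}")

    def normalized(mat: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return mat / norms

    concepts = list(first.concepts)
    left = normalized(first.matrix)
    right = normalized(second.submatrix(concepts))
    return EmbeddingTable(concepts, np.hstack([left, right]), "concatenated")


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write a word2vec-style text file: header "count dim", one concept per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for cid, vec in table.items():
            fh.write(str(cid) + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def read_embeddings(path: str | Path, order_tag: str = "concatenated") -> EmbeddingTable:
    """Read a word2vec-style text embedding file; values round-trip to >=6
    significant digits. Raises on header/line mismatches or duplicate tokens."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path.name}: malformed header {header!r}")
        count, dim = int(header[0]), int(header[1])
        concepts: list[ConceptId] = []
        seen: set[str] = set()
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != dim + 1:
                raise ValueError(f"{path.name}:{lineno}: expected {dim + 1} fields, got {len(fields)}")
            token = fields[0]
            if token in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate token {token!r}")
            seen.add(token)
            concepts.append(ConceptId.parse(token))
            rows.append(np.array(fields[1:], dtype=np.float64))
    if len(rows) != count:
        raise ValueError(f"{path.name}: header promised {count} rows, found {len(rows)}")
    return EmbeddingTable(concepts, np.vstack(rows), order_tag)
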