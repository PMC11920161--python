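"""Synthetic discovery-replication datasets with a planted implicit A-B-C link.

The generator emulates the shape of the Hallmarks-of-Cancer style closed
discovery benchmarks: grounded-concept triplets over an undirected
co-occurrence graph, Jaccard-scored positives and score-zero negatives mixed
50/50 in the training split, a positive-only evaluation split sharing a single
gold A and C concept, occasional multi-B links for one (A, C) pair, and —
crucially — a planted "discovery": a gold triplet (A*, B*, C*) whose A*–B* and
B*–C* edges are present in the training graph while no training triplet or
edge links A* and C* directly. Recovering B* from (A*, C*) is therefore a
genuine implicit-link inference.

Jaccard substrate
-----------------
Real benchmark scores express the overlap of the A→B and B→C co-occurrence
paths. Here every edge carries a synthetic *document support set* (a subset of
a document-id pool); a triplet's score is the Jaccard coefficient of its two
edge supports. Positive triplets share a core document set between both edges
(score > 0 by construction); negative triplets use edges with disjoint
supports (score exactly 0).

Community structure
-------------------
Concepts are assigned to latent clusters and positive triplets are drawn
within a cluster (with a small mixing rate), so graph embeddings carry signal
that the downstream model can exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import yaml

from .graph_data import (
    ConceptId,
    DiscoveryDataset,
    TripletRecord,
    build_graph,
    validate_dataset,
    write_triplets,
)

__all__ = ["SynthConfig", "SyntheticData", "generate_dataset", "jaccard_score", "edge_key"]

EdgeKey = tuple[ConceptId, ConceptId]


def edge_key(u: ConceptId, v: ConceptId) -> EdgeKey:
    """Canonical unordered key for an edge's support set."""
    return (u, v) if u <= v else (v, u)


def jaccard_score(edge_ab: Iterable[int], edge_bc: Iterable[int]) -> float:
    """Jaccard coefficient |S_ab ∩ S_bc| / |S_ab ∪ S_bc| of two edge supports."""
    s_ab, s_bc = set(edge_ab), set(edge_bc)
    union = s_ab | s_bc
    if not union:
        raise ValueError("both support sets are empty")
    return len(s_ab & s_bc) / len(union)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the desk-scale study conditions.

    Roughly 2,000 concepts and 20,000 training triplets at the benchmark's
    50/50 positive:negative balance. ``docs_per_edge`` bounds the size of each
    edge's synthetic document-support set, drawn from a pool of ``doc_pool``
    document ids. ``multi_b_fraction`` of positive (A, C) pairs receive 2–3
    distinct linking B concepts. ``n_clusters``/``mixing`` control the latent
    community structure (fraction of positives whose B is drawn outside the
    cluster of its A and C partners).
    """

    n_concepts_a: int = 700
    n_concepts_b: int = 600
    n_concepts_c: int = 700
    n_train_pos: int = 10_000
    n_train_neg: int = 10_000
    n_eval: int = 150
    docs_per_edge: tuple[int, int] = (3, 12)
    doc_pool: int = 40_000
    multi_b_fraction: float = 0.01
    n_clusters: int = 20
    mixing: float = 0.05
    gold_support: int = 3
    seed: int = 7

    def validate(self) -> None:
        for name in ("n_concepts_a", "n_concepts_b", "n_concepts_c",
                     "n_train_pos", "n_train_neg", "n_eval", "doc_pool",
                     "n_clusters", "gold_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.docs_per_edge
        if not (0 < lo <= hi):
            raise ValueError(f"docs_per_edge range {self.docs_per_edge} invalid")
        if not (0.0 <= self.multi_b_fraction <= 1.0):
            raise ValueError("multi_b_fraction must lie in [0, 1]")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError("mixing must lie in [0, 1]")
        if self.n_eval > self.n_concepts_b:
            raise ValueError("n_eval exceeds the number of B concepts")
        if self.n_train_pos < 2:
            raise ValueError("n_train_pos must be >= 2 to support the planted discovery")
        if self.n_clusters > min(self.n_concepts_a, self.n_concepts_b, self.n_concepts_c):
            raise ValueError("more clusters than concepts in some role pool")
        # unique (a, c) pairs must fit comfortably inside the per-cluster pair capacity
        pair_capacity = (self.n_concepts_a // self.n_clusters) * (self.n_concepts_c // self.n_clusters) * self.n_clusters
        if self.n_train_pos > 0.7 * pair_capacity:
            raise ValueError(
                f"n_train_pos={self.n_train_pos} exceeds 70% of the per-cluster "
                f"(A, C) pair capacity {pair_capacity}; add concepts or clusters")
        if self.doc_pool < 4 * self.n_clusters * hi:
            raise ValueError("doc_pool too small for the requested support-set sizes")


@dataclass
class SyntheticData:
    """Bundle returned by :func:`generate_dataset`."""

    dataset: DiscoveryDataset
    graph: nx.Graph
    supports: dict[EdgeKey, set[int]]
    config: SynthConfig
    gold_cluster_b: list[ConceptId] = field(default_factory=list)


def _make_pool(namespace: str, n: int) -> list[ConceptId]:
    width = len(str(n - 1))
    return [ConceptId(namespace, str(i).zfill(width)) for i in range(n)]


def generate_dataset(config: SynthConfig) -> SyntheticData:
    """Generate a discovery dataset, its training co-occurrence graph, and the
    per-edge document-support sets. Deterministic for a fixed config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    pool_a = _make_pool("syna", config.n_concepts_a)
    pool_b = _make_pool("synb", config.n_concepts_b)
    pool_c = _make_pool("sync", config.n_concepts_c)
    kc = config.n_clusters
    clusters_a = [[cid for i, cid in enumerate(pool_a) if i % kc == z] for z in range(kc)]
    clusters_b = [[cid for i, cid in enumerate(pool_b) if i % kc == z] for z in range(kc)]
    clusters_c = [[cid for i, cid in enumerate(pool_c) if i % kc == z] for z in range(kc)]

    # Document pool: first half partitioned per cluster (positive supports);
    # second half split by parity between the two edges of each negative, so a
    # negative's A-B and B-C supports are disjoint by construction.
    half = config.doc_pool // 2
    cluster_docs = [np.arange(z * half // kc, (z + 1) * half // kc) for z in range(kc)]
    neg_docs_ab = np.arange(half, config.doc_pool, 2)
    neg_docs_bc = np.arange(half + 1, config.doc_pool, 2)
    lo, hi = config.docs_per_edge

    gold_cluster = 0
    gold_a = clusters_a[gold_cluster][0]
    gold_b = clusters_b[gold_cluster][0]
    gold_c = clusters_c[gold_cluster][0]
    gold = TripletRecord(gold_a, gold_b, gold_c, 1.0)

    supports: dict[EdgeKey, set[int]] = {}
    used_edges: set[EdgeKey] = set()
    used_ac: set[tuple[ConceptId, ConceptId]] = set()
    # raw positives as (a, b, c, cluster); scores computed once supports are final
    raw_pos: list[tuple[ConceptId, ConceptId, ConceptId, int]] = []

    def add_support(u: ConceptId, v: ConceptId, docs: np.ndarray) -> None:
        key = edge_key(u, v)
        supports.setdefault(key, set()).update(int(d) for d in docs)
        used_edges.add(key)

    def add_positive(a: ConceptId, b: ConceptId, c: ConceptId, z: int) -> None:
        docs = cluster_docs[z]
        core = rng.choice(docs, size=int(rng.integers(1, min(3, lo) + 1)), replace=False)
        extra_ab = rng.choice(docs, size=int(rng.integers(lo, hi + 1)), replace=False)
        extra_bc = rng.choice(docs, size=int(rng.integers(lo, hi + 1)), replace=False)
        add_support(a, b, np.concatenate([core, extra_ab]))
        add_support(b, c, np.concatenate([core, extra_bc]))
        raw_pos.append((a, b, c, z))

    def draw_b(z: int, exclude: set[ConceptId] = frozenset()) -> ConceptId:
        for _ in range(1000):
            if rng.random() < config.mixing:
                b = pool_b[int(rng.integers(config.n_concepts_b))]
            else:
                members = clusters_b[z]
                b = members[int(rng.integers(len(members)))]
            if b not in exclude:
                return b
        raise RuntimeError("could not draw a fresh B concept")

    # --- planted discovery: support A*-B* and B*-C* without ever pairing (A*, C*)
    alt_c = [c for c in clusters_c[gold_cluster] if c != gold_c]
    alt_a = [a for a in clusters_a[gold_cluster] if a != gold_a]
    n_sup = max(1, min(config.gold_support, len(alt_c), len(alt_a), config.n_train_pos // 2))
    for i in range(n_sup):
        x = alt_c[int(rng.integers(len(alt_c)))]
        add_positive(gold_a, gold_b, x, gold_cluster)
        used_ac.add((gold_a, x))
    for i in range(n_sup):
        y = alt_a[int(rng.integers(len(alt_a)))]
        add_positive(y, gold_b, gold_c, gold_cluster)
        used_ac.add((y, gold_c))

    # --- bulk positives, unique (a, c) pairs, occasional multi-B links
    while len(raw_pos) < config.n_train_pos:
        z = int(rng.integers(kc))
        for _ in range(200):
            a = clusters_a[z][int(rng.integers(len(clusters_a[z])))]
            c = clusters_c[z][int(rng.integers(len(clusters_c[z])))]
            if (a, c) not in used_ac and not (a == gold_a and c == gold_c):
                break
        else:
            continue
        used_ac.add((a, c))
        b = draw_b(z)
        add_positive(a, b, c, z)
        if rng.random() < config.multi_b_fraction:
            extra = int(rng.integers(1, 3))  # 1-2 extra links -> multi-B size 2-3
            seen = {b}
            for _ in range(extra):
                if len(raw_pos) >= config.n_train_pos:
                    break
                b2 = draw_b(z, exclude=seen)
                seen.add(b2)
                add_positive(a, b2, c, z)

    train_pos = [
        TripletRecord(a, b, c, jaccard_score(supports[edge_key(a, b)], supports[edge_key(b, c)]))
        for a, b, c, _ in raw_pos
    ]

    # --- negatives: fresh edges with disjoint supports, score exactly zero
    train_neg: list[TripletRecord] = []
    while len(train_neg) < config.n_train_neg:
        a = pool_a[int(rng.integers(config.n_concepts_a))]
        b = pool_b[int(rng.integers(config.n_concepts_b))]
        c = pool_c[int(rng.integers(config.n_concepts_c))]
        if a == gold_a and c == gold_c:
            continue
        k_ab, k_bc = edge_key(a, b), edge_key(b, c)
        if k_ab in used_edges or k_bc in used_edges or k_ab == k_bc:
            continue
        add_support(a, b, rng.choice(neg_docs_ab, size=int(rng.integers(lo, hi + 1)), replace=False))
        add_support(b, c, rng.choice(neg_docs_bc, size=int(rng.integers(lo, hi + 1)), replace=False))
        score = jaccard_score(supports[k_ab], supports[k_bc])
        assert score == 0.0
        train_neg.append(TripletRecord(a, b, c, score))

    train = train_pos + train_neg
    order = rng.permutation(len(train))
    train = [train[i] for i in order]

    # --- evaluation split: (A*, b, C*) positives; gold cluster B's plus fillers
    eval_b = [gold_b] + [b for b in clusters_b[gold_cluster] if b != gold_b]
    if len(eval_b) > config.n_eval:
        eval_b = eval_b[: config.n_eval]
    else:
        others = [b for b in pool_b if b not in set(eval_b)]
        idx = rng.choice(len(others), size=config.n_eval - len(eval_b), replace=False)
        eval_b += [others[int(i)] for i in sorted(idx)]
    eval_records = [TripletRecord(gold_a, b, gold_c, 1.0) for b in eval_b]

    dataset = DiscoveryDataset(train=train, eval_records=eval_records, gold=gold,
                               name=f"synthetic-seed{config.seed}")
    validate_dataset(dataset, pos_neg_ratio=config.n_train_pos / config.n_train_neg,
                     ratio_tol=1e-9)
    graph = build_graph(train, positives_only=True)
    _check_planted(dataset, graph)
    return SyntheticData(dataset=dataset, graph=graph, supports=supports, config=config,
                         gold_cluster_b=list(clusters_b[gold_cluster]))


def _check_planted(dataset: DiscoveryDataset, graph: nx.Graph) -> None:
    """Planted-implicitness: the gold A and C are never linked in training."""
    g = dataset.gold
    if graph.has_edge(g.a, g.c):
        raise AssertionError("training graph contains the gold A-C edge")
    if not (graph.has_edge(g.a, g.b) and graph.has_edge(g.b, g.c)):
        raise AssertionError("gold A-B / B-C support edges missing from the training graph")
    for rec in dataset.train:
        if {rec.a, rec.c} == {g.a, g.c} or {rec.a, rec.b} == {g.a, g.c} or {rec.b, rec.c} == {g.a, g.c}:
            raise AssertionError("a training triplet directly links the gold A and C")


def write_dataset(data: SyntheticData, outdir: str | Path) -> dict[str, str]:
    """Write train/eval triplet files plus a flat manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_triplets(data.dataset.train, outdir / "train.tsv")
    write_triplets(data.dataset.eval_records, outdir / "eval.tsv")
    manifest = {
        "name": data.dataset.name,
        "train": "train.tsv",
        "eval": "eval.tsv",
        "gold_a": str(data.dataset.gold.a),
        "gold_b": str(data.dataset.gold.b),
        "gold_c": str(data.dataset.gold.c),
        "seed": data.config.seed,
    }
    with (outdir / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_manifest(path: str | Path) -> DiscoveryDataset:
    """Load a dataset written by :func:`write_dataset`."""
    from .graph_data import dataset_from_files

    path = Path(path)
    with path.open() as fh:
        manifest = yaml.safe_load(fh)
    gold = TripletRecord(
        ConceptId.parse(manifest["gold_a"]),
        ConceptId.parse(manifest["gold_b"]),
        ConceptId.parse(manifest["gold_c"]),
        1.0,
    )
    base = path.parent
    return dataset_from_files(base / manifest["train"], base / manifest["eval"], gold,
                              name=manifest.get("name", "dataset"))
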