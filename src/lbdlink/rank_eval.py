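"""Candidate ranking, discovery replication, and the random-relationship baseline.

Single-relationship discovery replication queries the trained model with the
gold (A, C) pair, compares the predicted linking-concept embedding against
every candidate B in a vocabulary by cosine similarity, sorts descending, and
reports the 1-based rank of the gold B — high similarity means a numerically
low rank. The random baseline draws unique random (a, b, c) triplets absent
from the data and ranks their b the same way; on a model that has learned
real structure those ranks sit near the middle of the vocabulary while the
planted discovery ranks near the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .edge_model import TrainedModel, predict_b
from .graph_data import ConceptId, DiscoveryDataset, vocabulary
from .line_embed import EmbeddingTable

__all__ = ["RankResult", "RandomBaselineResult", "rank_candidates",
           "replicate_discovery", "random_baseline"]


@dataclass
class RankResult:
    """Descending-cosine candidate list with the gold concept's rank."""

    candidates: list[tuple[ConceptId, float]]
    gold_rank: int
    vocab_size: int
    vocab_mode: str = "evaluation"

    def __post_init__(self) -> None:
        if not (1 <= self.gold_rank <= self.vocab_size):
            raise ValueError(f"gold_rank {self.gold_rank} outside [1, {self.vocab_size}]")


def rank_candidates(pred: np.ndarray, vocab: list[ConceptId],
                    embeddings: EmbeddingTable, gold: ConceptId,
                    ties: str = "optimistic", vocab_mode: str = "evaluation") -> RankResult:
    """Rank every vocabulary concept against the predicted embedding.

    Competition ranking: with ``ties="optimistic"`` the gold rank is 1 plus
    the number of candidates with strictly greater cosine; ``"pessimistic"``
    counts ties against the gold concept. The displayed order breaks exact
    cosine ties lexicographically.
    """
    if ties not in ("optimistic", "pessimistic"):
        raise ValueError("ties must be 'optimistic' or 'pessimistic'")
    if gold not in set(vocab):
        raise ValueError(f"gold concept {gold} not in the candidate vocabulary")
    pred = np.asarray(pred, dtype=np.float64).ravel()
    if np.linalg.norm(pred) == 0:
        raise ValueError("cosine ranking is undefined for a zero prediction vector")
    mat = embeddings.submatrix(vocab)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        bad = [str(v) for v, nz in zip(vocab, norms == 0) if nz]
        raise ValueError(f"zero-vector candidate embeddings: {', '.join(bad[:10])}")
    cos = mat @ pred / (norms * np.linalg.norm(pred))

    gold_idx = vocab.index(gold)
    gold_cos = cos[gold_idx]
    if ties == "optimistic":
        gold_rank = 1 + int(np.sum(cos > gold_cos))
    else:
        gold_rank = int(np.sum(cos >= gold_cos))
    order = sorted(range(len(vocab)), key=lambda i: (-cos[i], str(vocab[i])))
    candidates = [(vocab[i], float(cos[i])) for i in order]
    return RankResult(candidates=candidates, gold_rank=gold_rank,
                      vocab_size=len(vocab), vocab_mode=vocab_mode)


def replicate_discovery(model: TrainedModel, dataset: DiscoveryDataset,
                        embeddings: EmbeddingTable,
                        vocab_mode: str = "evaluation",
                        ties: str = "optimistic") -> RankResult:
    """Re-discover the dataset's gold relationship: predict from (gold A,
    gold C) and rank the gold B within the chosen vocabulary."""
    pred = predict_b(model, dataset.gold.a, dataset.gold.c, embeddings)
    vocab = vocabulary(dataset, vocab_mode)
    return rank_candidates(pred, vocab, embeddings, dataset.gold.b,
                           ties=ties, vocab_mode=vocab_mode)


@dataclass
class RandomBaselineResult:
    mean_rank: float
    ranks: list[int]
    triplets: list[tuple[ConceptId, ConceptId, ConceptId]]
    vocab_size: int
    vocab_mode: str = "comprehensive"


def random_baseline(model: TrainedModel, dataset: DiscoveryDataset,
                    embeddings: EmbeddingTable, n: int = 10, seed: int = 0,
                    vocab_mode: str = "comprehensive",
                    max_attempts: int = 100_000) -> RandomBaselineResult:
    """Rank ``n`` unique random (a, b, c) relationships absent from the data.

    Concepts are drawn from the dataset's unique A/B/C role pools (b from the
    ranking vocabulary so its rank is defined); sampled triplets are mutually
    unique, use three distinct concepts, and never coincide with a known
    training or evaluation triplet.
    """
    records = dataset.train + dataset.eval_records
    pool_a = sorted({r.a for r in records})
    pool_c = sorted({r.c for r in records})
    vocab = vocabulary(dataset, vocab_mode)
    known = {(r.a, r.b, r.c) for r in records}
    known.add((dataset.gold.a, dataset.gold.b, dataset.gold.c))

    rng = np.random.default_rng(seed)
    drawn: list[tuple[ConceptId, ConceptId, ConceptId]] = []
    seen: set[tuple[ConceptId, ConceptId, ConceptId]] = set()
    attempts = 0
    while len(drawn) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not draw {n} unique random triplets")
        a = pool_a[int(rng.integers(len(pool_a)))]
        b = vocab[int(rng.integers(len(vocab)))]
        c = pool_c[int(rng.integers(len(pool_c)))]
        trip = (a, b, c)
        if len({a, b, c}) < 3 or trip in known or trip in seen:
            continue
        if a not in embeddings or b not in embeddings or c not in embeddings:
            continue
        seen.add(trip)
        drawn.append(trip)

    ranks = []
    for a, b, c in drawn:
        pred = predict_b(model, a, c, embeddings)
        ranks.append(rank_candidates(pred, vocab, embeddings, b,
                                     vocab_mode=vocab_mode).gold_rank)
    return RandomBaselineResult(mean_rank=float(np.mean(ranks)), ranks=ranks,
                                triplets=drawn, vocab_size=len(vocab),
                                vocab_mode=vocab_mode)
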