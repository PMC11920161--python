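"""Data model and I/O for grounded concepts, A-B-C triplets, and co-occurrence graphs.

Closed literature-based discovery works over triplets of *grounded* biomedical
concepts (e.g. ``PR:000001754`` for a protein, ``MESH:D000236`` for a MeSH
descriptor): an explicit A–B relation and an explicit B–C relation jointly
suggest an implicit A–C relation mediated by the linking concept B. This module
provides the concept/triplet containers, the tab-separated triplet file
dialect, construction of the undirected co-occurrence knowledge graph, and the
time-sliced discovery dataset bundle used by the training and ranking stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

__all__ = [
    "ConceptId",
    "TripletRecord",
    "TripletDialect",
    "DiscoveryDataset",
    "load_triplets",
    "write_triplets",
    "build_graph",
    "vocabulary",
    "validate_dataset",
]


@dataclass(frozen=True, order=True, slots=True)
class ConceptId:
    """A namespaced grounded-concept identifier, rendered ``namespace:local_id``.

    All text is lowercased on ingest so that inputs differing only by case map
    to the same vertex. Concepts without a namespace carry ``namespace=None``.
    """

    namespace: str | None
    local_id: str

    def __post_init__(self) -> None:
        if not self.local_id:
            raise ValueError("concept local_id must be non-empty")
        if self.namespace is not None and not self.namespace:
            raise ValueError("concept namespace must be non-empty when present")

    @classmethod
    def parse(cls, text: str) -> "ConceptId":
        text = text.strip().lower()
        if not text:
            raise ValueError("empty concept identifier")
        if ":" in text:
            ns, local = text.split(":", 1)
            if not ns or not local:
                raise ValueError(f"malformed concept identifier {text!r}")
            return cls(ns, local)
        return cls(None, text)

    def __str__(self) -> str:
        if self.namespace is None:
            return self.local_id
        return f"{self.namespace}:{self.local_id}"


@dataclass(frozen=True, slots=True)
class TripletRecord:
    """One explicit A-B-C relation with its Jaccard path-similarity score.

    The label is derived, never stored: a score of zero marks a negative
    sample, any positive score marks a positive sample.
    """

    a: ConceptId
    b: ConceptId
    c: ConceptId
    jaccard: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.jaccard <= 1.0):
            raise ValueError(f"jaccard score {self.jaccard} outside [0, 1]")

    @property
    def positive(self) -> bool:
        return self.jaccard > 0.0

    @property
    def label(self) -> str:
        return "positive" if self.positive else "negative"


@dataclass(frozen=True)
class TripletDialect:
    """Column layout of a delimited triplet file.

    ``delimiter=None`` splits on any whitespace (covers the default
    tab-separated layout). ``columns`` names the role of each field in order;
    recognised roles are ``a``, ``b``, ``c``, ``score``. A missing score
    column falls back to ``default_score`` (evaluation files carry positive
    records only, hence the 1.0 default).
    """

    delimiter: str | None = None
    columns: tuple[str, ...] = ("a", "b", "c", "score")
    comment: str = "#"
    default_score: float = 1.0

    def __post_init__(self) -> None:
        required = {"a", "b", "c"}
        if not required <= set(self.columns):
            raise ValueError(f"dialect columns {self.columns} must include a, b, c")


DEFAULT_DIALECT = TripletDialect()


def load_triplets(path: str | Path, dialect: TripletDialect = DEFAULT_DIALECT) -> list[TripletRecord]:
    """Read a delimited triplet file into :class:`TripletRecord` objects.

    Raises :class:`ValueError` naming the offending line on malformed input or
    on a score outside [0, 1].
    """
    path = Path(path)
    records: list[TripletRecord] = []
    roles = dialect.columns
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(dialect.comment):
                continue
            fields = line.split(dialect.delimiter)
            if len(fields) < 3:
                raise ValueError(f"{path.name}:{lineno}: expected >=3 fields, got {len(fields)}")
            values: dict[str, str] = {}
            for role, value in zip(roles, fields):
                values[role] = value
            try:
                a = ConceptId.parse(values["a"])
                b = ConceptId.parse(values["b"])
                c = ConceptId.parse(values["c"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path.name}:{lineno}: {exc}") from exc
            score_text = values.get("score")
            if score_text is None:
                score = dialect.default_score
            else:
                try:
                    score = float(score_text)
                except ValueError as exc:
                    raise ValueError(f"{path.name}:{lineno}: unparseable score {score_text!r}") from exc
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"{path.name}:{lineno}: score {score} outside [0, 1]")
            records.append(TripletRecord(a, b, c, score))
    return records


def write_triplets(records: Iterable[TripletRecord], path: str | Path,
                   dialect: TripletDialect = DEFAULT_DIALECT) -> None:
    """Write records in the dialect's column order; round-trips with load_triplets."""
    path = Path(path)
    sep = dialect.delimiter if dialect.delimiter is not None else "\t"
    with path.open("w") as fh:
        for rec in records:
            parts = []
            for role in dialect.columns:
                if role == "score":
                    parts.append(repr(rec.jaccard))
                else:
                    parts.append(str(getattr(rec, role)))
            fh.write(sep.join(parts) + "\n")


def build_graph(triplets: Sequence[TripletRecord], positives_only: bool = True) -> nx.Graph:
    """Build the undirected co-occurrence knowledge graph from A-B-C triplets.

    Each included triplet contributes the edges (a, b) and (b, c); edge weight
    accumulates the number of supporting triplets (co-occurrence strength).
    The A–C edge is deliberately never added — that implicit link is what the
    downstream model must infer. Self-pairs (a == b or b == c) contribute no
    edge: the graph carries no self-loops.
    """
    if not triplets:
        raise ValueError("cannot build a graph from an empty triplet list")
    graph: nx.Graph = nx.Graph()
    for rec in triplets:
        if positives_only and not rec.positive:
            continue
        for node in (rec.a, rec.b, rec.c):
            graph.add_node(node)
        for u, v in ((rec.a, rec.b), (rec.b, rec.c)):
            if u == v:
                continue
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += 1.0
            else:
                graph.add_edge(u, v, weight=1.0)
    return graph


@dataclass
class DiscoveryDataset:
    """A time-sliced discovery-replication dataset.

    ``train`` holds the pre-cutoff triplets (positives and negatives at the
    configured ratio); ``eval_records`` the post-cutoff positives, all sharing
    the gold A and C concepts; ``gold`` is the known discovery the system must
    re-rank first. Vocabularies are ordered (lexicographic) lists of unique B
    concepts: the evaluation vocabulary from the evaluation split alone, the
    comprehensive vocabulary from train and evaluation together.
    """

    train: list[TripletRecord]
    eval_records: list[TripletRecord]
    gold: TripletRecord
    eval_vocab: list[ConceptId] = field(default_factory=list)
    comprehensive_vocab: list[ConceptId] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not self.eval_vocab:
            self.eval_vocab = _unique_b(self.eval_records)
        if not self.comprehensive_vocab:
            self.comprehensive_vocab = _unique_b(self.train + self.eval_records)


def _unique_b(records: Iterable[TripletRecord]) -> list[ConceptId]:
    return sorted({rec.b for rec in records})


def vocabulary(dataset: DiscoveryDataset,
               mode: Literal["evaluation", "comprehensive"]) -> list[ConceptId]:
    """Return the ordered candidate-B vocabulary for ranking.

    ``evaluation``: unique B concepts of the evaluation split; this is the
    vocabulary prior closed-discovery systems report against.
    ``comprehensive``: all known unique B concepts (train plus evaluation).
    """
    if mode == "evaluation":
        return list(dataset.eval_vocab)
    if mode == "comprehensive":
        return list(dataset.comprehensive_vocab)
    raise ValueError(f"unknown vocabulary mode {mode!r}")


def validate_dataset(dataset: DiscoveryDataset, pos_neg_ratio: float | None = 1.0,
                     ratio_tol: float = 0.0) -> None:
    """Assert the discovery-dataset invariants; raise ValueError on violation.

    ``pos_neg_ratio`` is the expected positive:negative training ratio (1.0
    for the standard 50/50 split); pass None to skip the balance check.
    """
    if not dataset.eval_records:
        raise ValueError("evaluation split is empty")
    for rec in dataset.eval_records:
        if not rec.positive:
            raise ValueError(f"evaluation record {rec} is not positive")
        if rec.a != dataset.gold.a or rec.c != dataset.gold.c:
            raise ValueError("evaluation records must share the gold A and C concepts")
    if dataset.gold.b not in set(dataset.eval_vocab):
        raise ValueError("gold B concept missing from the evaluation vocabulary")
    if not set(dataset.eval_vocab) <= set(dataset.comprehensive_vocab):
        raise ValueError("evaluation vocabulary is not contained in the comprehensive vocabulary")
    if pos_neg_ratio is not None:
        n_pos = sum(1 for r in dataset.train if r.positive)
        n_neg = len(dataset.train) - n_pos
        if n_neg == 0:
            if pos_neg_ratio is not None and n_pos and pos_neg_ratio != float("inf"):
                raise ValueError("training split has no negative samples")
        else:
            observed = n_pos / n_neg
            if abs(observed - pos_neg_ratio) > ratio_tol:
                raise ValueError(
                    f"training positive:negative ratio {observed:.3f} differs from "
                    f"expected {pos_neg_ratio:.3f}")


def dataset_from_files(train_path: str | Path, eval_path: str | Path,
                       gold: TripletRecord,
                       train_dialect: TripletDialect = DEFAULT_DIALECT,
                       eval_dialect: TripletDialect | None = None,
                       name: str = "dataset") -> DiscoveryDataset:
    """Assemble a DiscoveryDataset from on-disk triplet files."""
    if eval_dialect is None:
        eval_dialect = replace(train_dialect, default_score=1.0)
    return DiscoveryDataset(
        train=load_triplets(train_path, train_dialect),
        eval_records=load_triplets(eval_path, eval_dialect),
        gold=gold,
        name=name,
    )
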