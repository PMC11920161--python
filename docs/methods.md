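# Methods

## Problem setting

Closed literature-based discovery starts from a known (A, C) concept pair
and asks which linking concepts B bridge them. The package frames this as
predicting the *embedding* of the linking vertex in a co-occurrence
knowledge graph: a model that regresses B's vector from the (A, C) pair can
be compared, by cosine similarity, against every known concept at once,
yielding a full ranked hypothesis list instead of a per-query likelihood.

Discovery replication is the evaluation: the data are time-sliced at the
year of a known discovery, the model trains on the pre-cutoff graph, and
success is the 1-based rank of the gold B concept when predicting from the
gold (A, C) pair — ideally near 1, with random relationships ranking near
the middle of the vocabulary.

## Graph and embeddings

Triplets (a, b, c) contribute undirected edges a–b and b–c whose weight
accumulates the number of supporting triplets; the a–c edge is never
materialized, since that implicit link is the prediction target. Duplicate
triplets are kept deliberately — co-occurrence strength is the edge weight
the embedding sampler consumes.

Vertex embeddings use the LINE objective: edges are drawn with probability
proportional to weight; for each draw the source vector is pulled toward the
target (first order: the vertex's own vector; second order: a separate
context vector) and pushed from `n_negative = 5` noise vertices drawn from a
degree^(3/4) distribution. Noise draws that collide with either endpoint of
the sampled edge are dropped — without this, degenerate graphs (e.g. a
single edge) receive systematically contradictory updates. The learning rate
decays linearly from 0.025 with a floor of 10⁻⁴ of its initial value.
Updates are applied in vectorized mini-batches of 1,024 sampled edges, the
deterministic numpy analogue of the reference implementation's asynchronous
multi-threaded SGD; a fixed seed therefore reproduces runs exactly, which is
the test default. One million edge samples per order is the desk-scale
default (the reference tool counts samples in millions; the figure is
configurable). Isolated vertices keep their uniform(−0.5/dim, 0.5/dim)
initialization: no gradient ever reaches them, and dropping them would break
the coverage invariant that every graph vertex has a vector.

The two orders (50 dimensions each by default) are combined by L2-normalizing
each half independently and concatenating — a scale-free, parameter-free
reading of "balance by re-weighting" — giving 100-dimensional concept
vectors written in the word2vec text format.

## Edge representation and model

The A and C vectors are each multiplied by a scale factor (default 10, an
inductive-bias device inherited from earlier closed-discovery work; 1
disables it) and combined by averaging, concatenation, or Hadamard product.
Average and Hadamard are symmetric in (A, C) and the model's predictions
commute accordingly; concatenation is order-sensitive.

The predictor is a compact MLP: the combined input, two hidden layers whose
width defaults to the concept-embedding dimension (a four-layer network
counting input combination and output), and a tanh output bounding every
component in [−1, 1]. The hidden activation is not pinned by the
architecture's description; the rectifier is the default and tanh is
available. Dropout (10%) follows each hidden layer. Training minimizes the
mean cosine distance `1 − cos(prediction, B embedding)` with Adam
(learning rate 10⁻⁴, batch 256, 400 epochs by default); the `1 − cos` form
is preferred over `−cos` because it is non-negative and bounded in [0, 2],
which eases monitoring — the optima are identical and the alternative is a
config knob. Only positive triplets are trained on: under a similarity
objective, score-zero negatives carry no meaningful target. Multi-B (A, C)
pairs contribute one independent sample per linking concept; their gradient
targets conflict by construction, which is the honest reading of the data
rather than a defect. An evaluation hook can record the gold rank after
every epoch, so both final-epoch and best-epoch summaries are available
(reported training protocols are ambiguous between the two).

## Ranking

Candidates are scored by cosine similarity to the predicted vector and
sorted descending; rank and similarity are inversely related. The gold rank
uses competition ranking — 1 plus the number of candidates with strictly
greater cosine — which is optimistic for the gold concept among exact ties;
a pessimistic variant (ties count against) is available. Exact ties in the
displayed list break lexicographically. Zero vectors (prediction or
candidate) raise rather than defaulting to similarity 0, which would
silently corrupt rankings.

Two vocabularies are supported: *evaluation* (unique B concepts of the
evaluation split) and *comprehensive* (all known unique B concepts). The
published per-dataset vocabulary sizes do not reconcile with the published
unique-B training counts, and the derivation is not recoverable; the
comprehensive vocabulary here is therefore defined as the unique B concepts
over train ∪ eval, and the source is configurable at the dataset level.

The random-relationship baseline draws n (default 10) mutually unique
(a, b, c) triplets — three distinct concepts, none matching any known
training or evaluation triplet — from the dataset's own A/B/C role pools,
ranks each b given (a, c), and reports the arithmetic mean rank. On a model
that has learned real structure this mean sits near vocab/2 while the
planted discovery ranks far better.

## Synthetic data generator

The generator produces benchmark-shaped datasets at desk scale. Defaults:
700 A, 600 B, and 700 C concepts (2,000 total), 10,000 positive and 10,000
negative training triplets (the 50/50 benchmark balance), 150 evaluation
records, 20 latent clusters with 5% mixing, 1% multi-B fraction, edge
support sets of 3–12 documents from a 40,000-document pool. The full
benchmarks are roughly 200,000 triplets over 150,000 concepts; the 10×–75×
reduction keeps a complete pipeline run (embeddings + 100 training epochs)
around half a minute while preserving every structural property the tests
exercise.

Mechanics and assumptions:

- **Jaccard substrate.** The real benchmarks score each triplet by the
  Jaccard coefficient between its A→B and B→C paths without publishing the
  underlying sets. Here every edge carries a synthetic document-support set;
  a positive triplet's two edges share a core document set (score > 0 by
  construction, recomputable from the supports), while negatives use fresh
  edges with supports drawn from disjoint document ranges (score exactly 0).
  Negatives exist to emulate file shape and the labeling rule; they are not
  trained against.
- **Community structure.** Concepts are assigned round-robin to latent
  clusters; positives draw A, C, and (with probability 1 − mixing) B from
  one cluster. This is what gives the graph embeddings their signal; real
  literature graphs have hubs, degree heavy tails, and overlapping topics
  that this deliberately clean structure does not reproduce — passing the
  recovery tests demonstrates the pipeline's correctness, not its field
  performance on real corpora.
- **Planted discovery.** The gold triplet's A*–B* and B*–C* edges enter the
  training graph through support triplets (A*, B*, x) and (y, B*, C*) with
  cluster-mates x ≠ C*, y ≠ A*; no training triplet ever pairs A* with C*,
  and the generator asserts this. Base positives use unique (A, C) pairs, so
  multi-B links arise only at the configured rate (2–3 B's for a fraction of
  pairs, matching the benchmarks' small multi-B counts and max size 3).
- **Determinism.** A single seeded generator drives all sampling; identical
  config + seed reproduces the dataset byte-for-byte on disk.

## Statistical comparison

Methods are compared across datasets by mean rank: within-dataset ranks
(best = 1, average on ties), the Friedman chi-square, and the
Iman–Davenport F form, tested against the F(k−1, (k−1)(N−1)) quantile. A
perfectly consistent ordering makes the F form's denominator vanish; the
omnibus report treats that extreme as a rejection, while the bare statistic
raises. When the omnibus test rejects, the Nemenyi post-hoc compares all
pairwise mean-rank gaps against CD = q_α √(k(k+1)/6N) and reports maximal
groups of methods whose pairwise gaps all fall below CD.

Numerical choices worth noting:

- Critical F values come from the numeric quantile, not printed tables; for
  df (8, 32) this gives 2.2444 where a coarse table row (df₂ = 30) reads
  2.27. Decisions in the shipped benchmark reproductions are unaffected.
- The Nemenyi q constants are stored as two-tailed studentized-range values
  at infinite df (k = 2–10, α ∈ {0.05, 0.10}) and divided by √2 at full
  float precision: for k = 6 this yields q = 2.850 (3 d.p.) and
  CD = 3.3717 for N = 5 — using the rounded q directly would give 3.3722.
  Other k or α require a user-supplied q.
- The shipped comprehensive-vocabulary mean-rank table does not reproduce
  its published omnibus statistic under average-tie ranking (the per-run
  data behind that figure are not public); the table is provided for
  exploration, and only the evaluation-vocabulary statistic is treated as a
  reproducible quantity.

## Limitations

- The embedding trainer is single-process numpy; it is deterministic and
  adequate at desk scale but not tuned for million-node graphs.
- The generator's clean cluster structure makes recovery easier than real
  literature graphs; absolute ranks on synthetic data do not transfer.
- Out-of-vocabulary concepts are not handled: a concept absent from the
  training graph has no embedding and cannot be ranked or queried.
- Directed relation graphs (subject–predicate–object triples) are out of
  scope; the pipeline assumes undirected co-occurrence.
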