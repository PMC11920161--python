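"""Shared fixtures: a tiny synthetic dataset for cheap checks and the
default desk-scale pipeline (dataset -> embeddings -> trained model) reused
by the end-to-end evaluation tests."""

from __future__ import annotations

from dataclasses import replace
from types import SimpleNamespace

import numpy as np
import pytest

from lbdlink import (
    EdgeReprConfig,
    LineConfig,
    ModelConfig,
    SynthConfig,
    concat_reweight,
    generate_dataset,
    train_line,
    train_model,
)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small but non-degenerate synthetic dataset (~160 concepts)."""
    cfg = SynthConfig(
        n_concepts_a=60, n_concepts_b=50, n_concepts_c=60,
        n_train_pos=400, n_train_neg=400, n_eval=25,
        docs_per_edge=(3, 8), doc_pool=4000,
        n_clusters=5, multi_b_fraction=0.02, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_pipeline():
    """The default study conditions run end to end once per session:
    ~2,000 concepts / 20,000 training triplets, 100-d concatenated LINE
    embeddings, concatenated inputs scaled by 10, 100 training epochs."""
    data = generate_dataset(SynthConfig())
    line_cfg = LineConfig(seed=1)
    first = train_line(data.graph, 1, line_cfg)
    second = train_line(data.graph, 2, replace(line_cfg, seed=2))
    embeddings = concat_reweight(first, second)
    model = train_model(
        data.dataset, embeddings,
        EdgeReprConfig(mode="concat", scale=10.0),
        ModelConfig(epochs=100, seed=3),
        missing="error",
    )
    return SimpleNamespace(data=data, dataset=data.dataset,
                           embeddings=embeddings, model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
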