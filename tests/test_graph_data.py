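"""Concept/triplet data model, file dialect, and co-occurrence graph tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbdlink.graph_data import (
    ConceptId,
    DiscoveryDataset,
    TripletDialect,
    TripletRecord,
    build_graph,
    load_triplets,
    validate_dataset,
    vocabulary,
    write_triplets,
)


def cid(text: str) -> ConceptId:
    return ConceptId.parse(text)


def trip(a, b, c, score=1.0) -> TripletRecord:
    return TripletRecord(cid(a), cid(b), cid(c), score)


class TestConceptId:
    def test_parse_lowercases_and_splits_namespace(self):
        c = ConceptId.parse("PR:000001754")
        assert (c.namespace, c.local_id) == ("pr", "000001754")
        assert str(c) == "pr:000001754"

    def test_case_insensitive_identity(self):
        assert ConceptId.parse("MESH:D000236") == ConceptId.parse("mesh:d000236")

    def test_namespace_free_identifier(self):
        c = ConceptId.parse("senescence")
        assert c.namespace is None and str(c) == "senescence"

    @pytest.mark.parametrize("bad", ["", ":x", "x:", ":"])
    def test_malformed_identifiers_rejected(self, bad):
        with pytest.raises(ValueError):
            ConceptId.parse(bad)


class TestTripletRecord:
    def test_label_follows_jaccard_sign(self):
        assert trip("x:1", "x:2", "x:3", 0.12).label == "positive"
        assert trip("x:1", "x:2", "x:3", 0.0).label == "negative"

    def test_score_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            trip("x:1", "x:2", "x:3", 1.2)


class TestLoadTriplets:
    def test_known_discovery_row(self, tmp_path):
        # the NF-kB / Bcl-2 / adenoma triplet in its grounded-concept form
        f = tmp_path / "t.tsv"
        f.write_text("PR:000001754\tPR:000002307\tMESH:D000236\t0.12\n")
        (rec,) = load_triplets(f)
        assert rec.a == cid("pr:000001754")
        assert rec.b == cid("pr:000002307")
        assert rec.c == cid("mesh:d000236")
        assert rec.jaccard == 0.12 and rec.positive

    def test_zero_score_yields_negative(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("x:1 x:2 x:3 0.0\n")
        (rec,) = load_triplets(f)
        assert not rec.positive

    def test_comment_lines_skipped(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a:1 b:1 c:1 0.5\n# comment line\na:2 b:2 c:2 0.5\na:3 b:3 c:3 0\n")
        assert len(load_triplets(f)) == 3

    def test_missing_score_uses_dialect_default(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a:1 b:1 c:1\n")
        (rec,) = load_triplets(f, TripletDialect(default_score=1.0))
        assert rec.jaccard == 1.0

    def test_malformed_line_error_names_line_number(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a:1 b:1 c:1 0.5\na:2 b:2\n")
        with pytest.raises(ValueError, match=":2"):
            load_triplets(f)

    def test_out_of_range_score_rejected(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("a:1 b:1 c:1 1.5\n")
        with pytest.raises(ValueError, match="outside"):
            load_triplets(f)


concept_ids = st.builds(
    lambda ns, loc: ConceptId(ns, loc),
    st.sampled_from(["pr", "mesh", "chebi", "hoc"]),
    st.text(alphabet="abcdefghij0123456789", min_size=1, max_size=8),
)
triplets = st.builds(
    TripletRecord, concept_ids, concept_ids, concept_ids,
    st.one_of(st.just(0.0), st.floats(0.001, 1.0, allow_nan=False)),
)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(triplets, min_size=1, max_size=30))
def test_triplet_file_round_trip(tmp_path_factory, records):
    """write_triplets(load_triplets(f)) reproduces every field."""
    path = tmp_path_factory.mktemp("rt") / "t.tsv"
    write_triplets(records, path)
    loaded = load_triplets(path)
    assert loaded == records


class TestBuildGraph:
    def test_single_positive_triplet(self):
        g = build_graph([trip("x:a", "x:b", "x:c", 0.5)])
        assert set(g.nodes) == {cid("x:a"), cid("x:b"), cid("x:c")}
        assert g.has_edge(cid("x:a"), cid("x:b")) and g.has_edge(cid("x:b"), cid("x:c"))
        assert not g.has_edge(cid("x:a"), cid("x:c"))
        assert g[cid("x:a")][cid("x:b")]["weight"] == 1.0

    def test_duplicate_triplets_accumulate_weight(self):
        t = trip("x:a", "x:b", "x:c", 0.5)
        g = build_graph([t, t])
        assert g[cid("x:a")][cid("x:b")]["weight"] == 2.0

    def test_negatives_excluded_by_default(self):
        g = build_graph([trip("x:a", "x:b", "x:c", 0.5), trip("y:a", "y:b", "y:c", 0.0)])
        assert cid("y:a") not in g
        g_all = build_graph([trip("x:a", "x:b", "x:c", 0.5), trip("y:a", "y:b", "y:c", 0.0)],
                            positives_only=False)
        assert cid("y:a") in g_all

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_graph([])

    def test_permutation_invariance(self, tiny_synth, rng):
        records = tiny_synth.dataset.train
        g1 = build_graph(records)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        g2 = build_graph(shuffled)
        assert set(g1.nodes) == set(g2.nodes)
        assert {frozenset(e) for e in g1.edges} == {frozenset(e) for e in g2.edges}
        for u, v in g1.edges:
            assert g1[u][v]["weight"] == g2[u][v]["weight"]

    def test_vertex_set_matches_bruteforce_union(self, tiny_synth):
        positives = [r for r in tiny_synth.dataset.train if r.positive]
        expected = set()
        for r in positives:
            expected |= {r.a, r.b, r.c}
        g = build_graph(tiny_synth.dataset.train)
        assert set(g.nodes) == expected


class TestVocabulary:
    def test_eval_vocab_deduplicates(self):
        recs = [trip("g:a", "x:x", "g:c"), trip("g:a", "x:y", "g:c"), trip("g:a", "x:x", "g:c")]
        ds = DiscoveryDataset(train=[trip("g:a", "x:x", "g:c", 0.5)],
                              eval_records=recs, gold=recs[0])
        assert vocabulary(ds, "evaluation") == sorted({cid("x:x"), cid("x:y")})

    def test_eval_vocab_contained_in_comprehensive(self, tiny_synth):
        ds = tiny_synth.dataset
        assert set(vocabulary(ds, "evaluation")) <= set(vocabulary(ds, "comprehensive"))

    def test_eval_vocab_size_matches_generator_config(self, tiny_synth):
        assert len(vocabulary(tiny_synth.dataset, "evaluation")) == tiny_synth.config.n_eval

    def test_unknown_mode_rejected(self, tiny_synth):
        with pytest.raises(ValueError):
            vocabulary(tiny_synth.dataset, "everything")


class TestValidateDataset:
    def test_generated_dataset_passes(self, tiny_synth):
        validate_dataset(tiny_synth.dataset, pos_neg_ratio=1.0)

    def test_negative_eval_record_rejected(self, tiny_synth):
        ds = tiny_synth.dataset
        bad = DiscoveryDataset(
            train=ds.train,
            eval_records=ds.eval_records + [TripletRecord(ds.gold.a, cid("z:z"), ds.gold.c, 0.0)],
            gold=ds.gold)
        with pytest.raises(ValueError, match="not positive"):
            validate_dataset(bad)

    def test_mismatched_eval_anchor_rejected(self, tiny_synth):
        ds = tiny_synth.dataset
        stray = TripletRecord(cid("q:q"), ds.gold.b, ds.gold.c, 1.0)
        bad = DiscoveryDataset(train=ds.train, eval_records=ds.eval_records + [stray],
                               gold=ds.gold)
        with pytest.raises(ValueError, match="share the gold"):
            validate_dataset(bad)

    def test_unbalanced_training_split_rejected(self, tiny_synth):
        ds = tiny_synth.dataset
        positives = [r for r in ds.train if r.positive]
        bad = DiscoveryDataset(train=positives + [r for r in ds.train if not r.positive][:10],
                               eval_records=ds.eval_records, gold=ds.gold)
        with pytest.raises(ValueError, match="ratio"):
            validate_dataset(bad, pos_neg_ratio=1.0)
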