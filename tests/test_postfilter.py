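"""Disambiguation postfilter: features, training, θ heuristic, semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lexitag as lt
from lexitag.io_formats import Document, Section
from lexitag.matcher import Annotation
from lexitag.postfilter import (
    NOT_ENTITY,
    STOP_WORDS,
    FeatureConfig,
    iter_words,
    vocabulary_coverage_report,
    vowel_consonant_ratio,
)
from lexitag.terminology import TermEntry


@pytest.fixture(scope="module")
def tiny_table():
    return lt.EmbeddingTable(
        {"kala": np.array([1.0, 2.0]), "bodo": np.array([3.0, 4.0])}, 2
    )


class TestFeatures:
    @pytest.mark.parametrize(
        "surface,expected",
        [
            ("protein", 3 / 4),   # vowels o, e, i against p, r, t, n
            ("12345", 0.0),       # no letters at all
            ("eau", 3.0),         # no consonants: divide by one
            ("rhythm", 0.0),      # y is not a vowel
        ],
    )
    def test_vowel_consonant_ratio(self, surface, expected):
        assert vowel_consonant_ratio(surface) == pytest.approx(expected)

    def test_stopword_flag(self, tiny_table):
        fv = lt.featurize("the", tiny_table, common_vocab=frozenset())
        assert fv.is_stopword == 1
        assert "the" in STOP_WORDS

    def test_common_vocab_whole_term_no_breakup(self, tiny_table):
        vocab = frozenset({"kala", "bodo"})
        assert lt.featurize("Kala", tiny_table, vocab).in_common_vocab == 1
        # multi-word surfaces are looked up as a whole and never found
        assert (
            lt.featurize("kala bodo", tiny_table, vocab).in_common_vocab
            == 0
        )

    def test_embedding_mean_of_two_tokens(self, tiny_table):
        fv = lt.featurize("kala bodo", tiny_table, frozenset())
        np.testing.assert_allclose(fv.embedding, [2.0, 3.0])

    def test_unknown_tokens_contribute_zero_vector(self, tiny_table):
        fv = lt.featurize("kala xyz", tiny_table, frozenset())
        np.testing.assert_allclose(fv.embedding, [0.5, 1.0])
        all_unknown = lt.featurize("xyz qrs", tiny_table, frozenset())
        np.testing.assert_allclose(all_unknown.embedding, [0.0, 0.0])

    def test_mean_pooling_matches_independent_average(self, small_fixture):
        """Mean-pooled term embeddings equal a manually accumulated
        average over individual token look-ups."""
        emb = small_fixture["embeddings"]
        for entry in small_fixture["terms"][:50]:
            fv = lt.featurize(entry.term, emb, frozenset())
            toks = [t.norm for t in lt.tokenize(entry.term)]
            total = np.zeros(emb.dim)
            for tok in toks:
                v = emb.get(tok)
                if v is not None:
                    total = total + v
            np.testing.assert_allclose(fv.embedding, total / len(toks))

    def test_feature_presets(self, tiny_table):
        full = lt.FeatureExtractor(tiny_table, frozenset()).vector("kala")
        three = lt.FeatureExtractor(
            tiny_table, frozenset(),
            config=FeatureConfig.preset("service3"),
        ).vector("kala")
        assert full.shape[0] == 1 + 1 + 1 + 2 + 7
        assert three.shape[0] == 1 + 1 + 2
        with pytest.raises(ValueError):
            FeatureConfig.preset("nope")


class TestTrainingSet:
    def test_toy_document(self):
        text = "p53 binds DNA"
        doc = Document(
            "d1", text, [Section("text", 0, len(text))],
            [Annotation(0, 3, "protein", "PR:1", surface="p53")],
        )
        examples = lt.build_training_set([doc])
        assert ("p53", "protein") in examples
        negatives = {s for s, y in examples if y == NOT_ENTITY}
        assert negatives == {"binds", "DNA"}

    def test_punctuation_stripped_from_negative_words(self):
        text = "kala (rose)."
        doc = Document("d1", text, [Section("text", 0, len(text))], [])
        negatives = {s for s, _ in lt.build_training_set([doc])}
        assert negatives == {"kala", "rose"}

    def test_empty_document_skipped(self):
        doc = Document("empty", "", [], [])
        assert lt.build_training_set([doc]) == []

    def test_negative_count_matches_independent_scan(self, small_fixture):
        """The number of NOT_ENTITY examples equals an independently
        counted tally of uncovered word occurrences."""
        docs = small_fixture["docs"]
        examples = lt.build_training_set(docs)
        n_neg = sum(1 for _, y in examples if y == NOT_ENTITY)
        n_pos = sum(1 for _, y in examples if y != NOT_ENTITY)
        expected = 0
        for doc in docs:
            spans = [(a.start, a.end) for a in doc.annotations]
            for _, start, end in iter_words(doc.text):
                if not any(start < e and s < end for s, e in spans):
                    expected += 1
        assert n_neg == expected
        assert n_pos == sum(len(d.annotations) for d in docs)


class TestTrain:
    def test_separable_two_type_set(self, separable_embeddings):
        """On linearly separable embedding clusters, held-out accuracy
        reaches at least 0.95."""
        tokens = sorted(separable_embeddings.vectors)
        examples = [
            (t, "protein" if t.startswith("ka") else "chemical")
            for t in tokens
        ]
        train_ex = examples[:160]
        held = examples[160:]
        extractor = lt.FeatureExtractor(
            separable_embeddings, frozenset(),
            config=FeatureConfig.preset("service3"),
        )
        model = lt.train(train_ex, extractor, seed=3)
        correct = 0
        for surface, label in held:
            dist = model.predict_distribution(surface)
            correct += max(dist, key=dist.get) == label
        assert correct / len(held) >= 0.95

    def test_single_label_rejected(self, tiny_table):
        extractor = lt.FeatureExtractor(tiny_table, frozenset())
        with pytest.raises(ValueError, match="2 distinct labels"):
            lt.train([("kala", "protein")] * 5, extractor, seed=0)

    def test_same_seed_identical_predictions(self, separable_embeddings):
        all_tokens = sorted(separable_embeddings.vectors)
        tokens = all_tokens[:30] + all_tokens[100:130]
        examples = [
            (t, "protein" if t.startswith("ka") else "chemical")
            for t in tokens
        ]
        extractor = lt.FeatureExtractor(
            separable_embeddings, frozenset(),
            config=FeatureConfig.preset("service3"),
        )
        m1 = lt.train(examples, extractor, seed=5)
        m2 = lt.train(examples, extractor, seed=5)
        assert m1.predict_distributions(tokens) == m2.predict_distributions(
            tokens
        )

    def test_save_load_round_trip(self, small_model, tmp_path):
        path = tmp_path / "model.pkl"
        small_model.save(path)
        loaded = lt.PostfilterModel.load(path)
        surfaces = ["kala", "bodo gafa", "x1"]
        assert loaded.predict_distributions(
            surfaces
        ) == small_model.predict_distributions(surfaces)
        assert loaded.theta == small_model.theta
        assert loaded.labels == small_model.labels


class TestDecideLabels:
    def test_not_entity_majority_yields_empty(self):
        dist = {NOT_ENTITY: 0.9, "chemical": 0.1}
        assert lt.decide_labels(dist, 0.3) == frozenset()

    def test_close_runner_up_added(self):
        dist = {"cell": 0.50, "protein": 0.30, NOT_ENTITY: 0.20}
        assert lt.decide_labels(dist, 0.3) == {"cell", "protein"}

    def test_wide_gap_keeps_top_only(self):
        dist = {"cell": 0.70, "protein": 0.30}
        assert lt.decide_labels(dist, 0.3) == {"cell"}

    def test_gap_exactly_theta_is_not_close(self):
        dist = {"cell": 0.65, "protein": 0.35}
        assert lt.decide_labels(dist, 0.3) == {"cell"}

    def test_not_entity_removed_after_selection(self):
        # NOT_ENTITY occupies the runner-up slot and is then dropped,
        # leaving a single label even though the gap is small.
        dist = {"cell": 0.4, NOT_ENTITY: 0.35, "protein": 0.25}
        assert lt.decide_labels(dist, 0.3) == {"cell"}

    @given(
        st.lists(
            st.floats(min_value=0.001, max_value=1.0),
            min_size=4, max_size=4,
        ),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_contract_and_monotonicity(self, raw, t1, t2):
        total = sum(raw)
        labels = ["chemical", "protein", "cell", NOT_ENTITY]
        dist = {k: v / total for k, v in zip(labels, raw)}
        out = lt.decide_labels(dist, t1)
        assert len(out) <= 2
        assert NOT_ENTITY not in out
        ranked = sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))
        expected_second = ranked[0][1] - ranked[1][1] < t1
        selected = {ranked[0][0]} | (
            {ranked[1][0]} if expected_second else set()
        )
        assert out == frozenset(selected - {NOT_ENTITY})
        lo, hi = sorted((t1, t2))
        assert lt.decide_labels(dist, lo) <= lt.decide_labels(dist, hi)


@pytest.fixture(scope="module")
def typed_model(separable_embeddings):
    """Model that maps ka*-tokens to protein, bo*-tokens to chemical."""
    tokens = sorted(separable_embeddings.vectors)
    examples = [
        (t, "protein" if t.startswith("ka") else "chemical")
        for t in tokens
    ] + [("filler", NOT_ENTITY)] * 40
    extractor = lt.FeatureExtractor(
        separable_embeddings, frozenset(),
        config=FeatureConfig.preset("service3"),
    )
    return lt.train(examples, extractor, seed=4)


class TestOutputSemantics:
    def _ann(self, start, end, etype, cid, surface):
        return Annotation(start, end, etype, cid, surface=surface)

    def test_ner_reclassification_drops_identifier(self, typed_model):
        """A span upstream-typed chemical but decided protein is emitted
        as protein with no concept identifier."""
        surface = sorted(typed_model.extractor.embeddings.vectors)[100]
        assert surface.startswith("ka")  # protein cluster
        upstream = [self._ann(0, len(surface), "chemical", "CHEBI:9",
                              surface)]
        out = lt.apply_ner(upstream, typed_model)
        assert [(a.entity_type, a.concept_id) for a in out] == [
            ("protein", None)
        ]

    def test_ner_keeps_identifier_for_confirmed_type(self, typed_model):
        surface = sorted(typed_model.extractor.embeddings.vectors)[100]
        upstream = [self._ann(0, len(surface), "protein", "PR:1", surface)]
        out = lt.apply_ner(upstream, typed_model)
        assert [(a.entity_type, a.concept_id) for a in out] == [
            ("protein", "PR:1")
        ]

    def test_cr_loses_reclassified_annotation(self, typed_model):
        surface = sorted(typed_model.extractor.embeddings.vectors)[100]
        upstream = [self._ann(0, len(surface), "chemical", "CHEBI:9",
                              surface)]
        assert lt.apply_cr(upstream, typed_model) == []

    def test_cr_keeps_confirmed_annotation_verbatim(self, typed_model):
        surface = sorted(typed_model.extractor.embeddings.vectors)[0]
        assert surface.startswith("bo")  # chemical cluster
        upstream = [self._ann(0, len(surface), "chemical", "CHEBI:9",
                              surface)]
        assert lt.apply_cr(upstream, typed_model) == upstream

    def test_cr_subset_and_ner_span_subset(self, small_fixture,
                                           small_model):
        idx = small_fixture["index"]
        for doc in small_fixture["docs"][7:]:
            upstream = lt.annotate(doc.text, idx)
            cr = lt.apply_cr(upstream, small_model)
            ner = lt.apply_ner(upstream, small_model)
            assert set(cr) <= set(upstream)
            spans = {(a.start, a.end) for a in upstream}
            assert {(a.start, a.end) for a in ner} <= spans
            assert len(ner) <= len(upstream)

    def test_ner_equals_per_span_decision_oracle(self, small_fixture,
                                                 small_model):
        """apply_ner agrees with applying decide_labels span by span."""
        idx = small_fixture["index"]
        doc = small_fixture["docs"][8]
        upstream = lt.annotate(doc.text, idx)
        ner = lt.apply_ner(upstream, small_model)
        by_span = {}
        for a in upstream:
            by_span.setdefault((a.start, a.end), []).append(a)
        expected = []
        for (start, end), group in by_span.items():
            dist = small_model.predict_distribution(group[0].surface)
            for label in lt.decide_labels(dist, small_model.theta):
                matching = [a for a in group if a.entity_type == label]
                if matching:
                    expected.extend(matching)
                else:
                    expected.append(
                        Annotation(start, end, label, None,
                                   surface=group[0].surface)
                    )
        assert ner == sorted(expected, key=Annotation.sort_key)

    def test_multiword_spurious_match_not_removed(self, small_model):
        """The network never sees multi-word negatives, so a spurious
        multi-word match whose tokens carry no entity-like signal is
        kept rather than rejected — a documented limitation."""
        upstream = [
            self._ann(0, 9, "chemical", "CHE:0", "cwyx jqwc"),
        ]
        assert lt.apply_ner(upstream, small_model) != []


class TestCoverageReport:
    def test_percentages_both_ways(self):
        entries = [
            TermEntry("R", "C:1", "lead", "lead", "chemical"),
            TermEntry("R", "C:2", "zinc oxide", "zinc oxide", "chemical"),
            TermEntry("R", "C:3", "p53", "p53", "protein"),
        ]
        vocab = frozenset({"lead", "zinc", "oxide"})
        report = vocabulary_coverage_report(entries, vocab)
        assert report["chemical"]["no_breakup_pct"] == pytest.approx(50.0)
        assert report["chemical"]["breakup_pct"] == pytest.approx(100.0)
        assert report["protein"]["no_breakup_pct"] == 0.0
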