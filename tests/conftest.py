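"""Shared fixtures: worked-example terminology and small synthetic sets."""

import warnings

import numpy as np
import pytest

import lexitag as lt
from lexitag.terminology import TermEntry

warnings.filterwarnings(
    "ignore", category=UserWarning, module="sklearn"
)
warnings.filterwarnings(
    "ignore", message=".*Stochastic Optimizer.*"
)


@pytest.fixture(scope="session")
def worked_entries() -> list[TermEntry]:
    """Dictionary entries behind the documented matcher examples."""
    return [
        TermEntry("SRC", "ID:1", "IOP1", "IOP1", "chemical"),
        TermEntry("SRC", "ID:2", "AT-1", "AT-1", "protein"),
        TermEntry("SRC", "ID:3", "Thr", "threonine", "chemical"),
        TermEntry("SRC", "ID:4", "Ala-", "alanine", "chemical"),
        TermEntry("SRC", "ID:5", "water", "water", "chemical"),
        TermEntry("CHEBI", "CHEBI:25016", "lead", "lead", "chemical"),
    ]


@pytest.fixture(scope="session")
def worked_index(worked_entries):
    return lt.build_index(worked_entries)


@pytest.fixture(scope="session")
def small_cfg() -> lt.FixtureConfig:
    """Down-scaled fixture for fast unit tests."""
    return lt.FixtureConfig(
        seed=11, n_concepts_per_type=12, n_docs=10, tokens_per_doc=80,
        filler_lexicon_size=120,
    )


@pytest.fixture(scope="session")
def small_fixture(small_cfg):
    terms = lt.make_terminology(small_cfg)
    docs = lt.make_corpus(small_cfg, terms)
    emb = lt.make_embeddings(small_cfg, terms)
    vocab, stops = lt.make_wordlists(small_cfg, terms)
    return {
        "cfg": small_cfg,
        "terms": terms,
        "docs": docs,
        "embeddings": emb,
        "vocab": vocab,
        "stops": stops,
        "index": lt.build_index(terms),
    }


@pytest.fixture(scope="session")
def small_model(small_fixture):
    """Postfilter trained on the small fixture's training half."""
    train_docs = small_fixture["docs"][:7]
    examples = lt.build_training_set(train_docs)
    extractor = lt.FeatureExtractor(
        embeddings=small_fixture["embeddings"],
        common_vocab=small_fixture["vocab"],
        stop_words=small_fixture["stops"],
    )
    return lt.train(examples, extractor, seed=11)


@pytest.fixture(scope="session")
def separable_embeddings():
    """Two well-separated clusters of letter-only token vectors."""
    rng = np.random.default_rng(0)
    names = {}
    for i in range(100):
        suffix = "".join(
            "abcdefghij"[int(d)] for d in f"{i:02d}"
        )
        names[f"ka{suffix}"] = np.r_[np.ones(5) * 3.0, rng.normal(size=5)]
        names[f"bo{suffix}"] = np.r_[-np.ones(5) * 3.0, rng.normal(size=5)]
    return lt.EmbeddingTable(names, 10)
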