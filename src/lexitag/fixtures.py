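"""Deterministic synthetic fixtures for every pipeline stage.

The generator emulates the inputs a real deployment would download:

* a flat terminology with spelling variants, cross-type name sharing
  (ambiguity) and planted common-word terms — the mechanism behind
  dictionary false positives such as "lead";
* a gold-annotated corpus of documents mixing entity mentions (with
  surface-variant spelling) and common-word filler;
* a word-embedding table with one Gaussian cluster per entity type and a
  separate cluster for common words, so that embeddings carry the type
  signal the disambiguation network relies on;
* common-vocabulary and stop-word lists.

Construction guarantees worth knowing:

* Filler words and entity names are built from disjoint consonant
  inventories, and entity letter-stems are unique, so a planted mention
  can only match its own dictionary key (matcher recall on gold is 1.0
  by construction) — except for the deliberate collisions introduced by
  ``ambiguity_rate`` and ``common_word_fp_rate``.
* Surface variants are generated only at letter–digit boundaries
  (hyphen/space insertion) plus case changes, exactly the variation the
  lossy normalization collapses.
* A share of entity terms is also placed into the common-vocabulary
  list, mirroring the real-world overlap between terminologies and a
  common-language dictionary.

Everything is a pure function of :class:`FixtureConfig`; regenerating
with the same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import Document, Section, write_document
from .matcher import Annotation
from .normalize import norm_sequence
from .postfilter import EmbeddingTable
from .terminology import TermEntry, write_terminology

__all__ = [
    "FixtureConfig",
    "make_terminology",
    "make_corpus",
    "make_embeddings",
    "make_wordlists",
    "split_corpus",
    "write_fixture",
]

_VOWELS = "aeiou"
_FILLER_CONSONANTS = "bdfgh"
_ENTITY_CONSONANTS = "klmnprstvz"

#: Default entity-type vocabulary; cycled/extended for other n_types.
TYPE_NAMES = ("chemical", "protein", "cell", "disease", "organism",
              "sequence")


@dataclass(frozen=True, slots=True)
class FixtureConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    ``ambiguity_rate`` is the fraction of entity names shared across
    types; ``common_word_fp_rate`` the fraction of dictionary terms that
    are planted common words; ``cluster_separation`` the distance of each
    type centroid from the common-word centroid, in units of the
    within-cluster standard deviation.
    """

    seed: int = 0
    n_types: int = 4
    n_concepts_per_type: int = 50
    synonyms_per_concept: int = 2
    ambiguity_rate: float = 0.1
    common_word_fp_rate: float = 0.2
    n_docs: int = 67
    tokens_per_doc: int = 120
    embedding_dim: int = 25
    cluster_separation: float = 4.0
    mention_rate: float = 0.08
    filler_lexicon_size: int = 400
    noise_pool_size: int = 16
    n_stop_words: int = 20
    common_vocab_entity_share: float = 0.3
    resource: str = "SYNTH"

    def __post_init__(self) -> None:
        for name in ("ambiguity_rate", "common_word_fp_rate",
                     "mention_rate", "common_vocab_entity_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_types > 1 or self.ambiguity_rate == 0:
            return
        raise ValueError("ambiguity requires at least two entity types")

    def type_names(self) -> list[str]:
        return [
            TYPE_NAMES[i] if i < len(TYPE_NAMES) else f"type{i}"
            for i in range(self.n_types)
        ]


def _rng(cfg: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _word(rng: np.random.Generator, consonants: str, syllables: int) -> str:
    return "".join(
        consonants[rng.integers(len(consonants))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(syllables)
    )


def _filler_lexicon(cfg: FixtureConfig) -> list[str]:
    """Common-word lexicon; shared stream so every stage agrees on it.

    Filler words follow the *same* shape process as entity names
    (syllables plus an optional digit suffix) so that surface-shape
    features carry no class signal by themselves and the embedding
    clusters remain the decisive, separation-controlled feature.
    """
    rng = _rng(cfg, 0)
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < cfg.filler_lexicon_size:
        w = _word(rng, _FILLER_CONSONANTS, int(rng.integers(2, 4)))
        if rng.random() < 0.5:
            w += str(rng.integers(1, 100))
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _perturb(rng: np.random.Generator, name: str) -> str:
    """A spelling variant at a letter–digit boundary, or a case variant."""
    boundaries = [
        i
        for i in range(1, len(name))
        if name[i - 1].isalpha() != name[i].isalpha()
    ]
    choices = ["upper", "title"]
    if boundaries:
        choices += ["hyphen", "space"]
    kind = choices[rng.integers(len(choices))]
    if kind == "upper":
        return name.upper()
    if kind == "title":
        return name[0].upper() + name[1:]
    b = boundaries[rng.integers(len(boundaries))]
    sep = "-" if kind == "hyphen" else " "
    return name[:b] + sep + name[b:]


def make_terminology(cfg: FixtureConfig) -> list[TermEntry]:
    """Generate the synthetic terminology.

    Each concept gets a unique primary name (letter stem unique across
    the whole terminology, optionally with a digit suffix) and
    ``synonyms_per_concept - 1`` spelling variants.  Then exactly
    ``round(ambiguity_rate * n_names)`` donor names are re-used as terms
    of a concept of a *different* type, and common words are appended as
    terms of random concepts until they make up ``common_word_fp_rate``
    of all dictionary terms.
    """
    rng = _rng(cfg, 1)
    types = cfg.type_names()
    entries: list[TermEntry] = []
    concepts: list[tuple[str, str, str]] = []  # (concept_id, type, name)
    stems: set[str] = set()
    for t_i, etype in enumerate(types):
        for c_i in range(cfg.n_concepts_per_type):
            while True:
                stem = _word(rng, _ENTITY_CONSONANTS,
                             int(rng.integers(2, 4)))
                if stem not in stems:
                    break
            stems.add(stem)
            name = stem
            if rng.random() < 0.5:
                name += str(rng.integers(1, 100))
            concept_id = f"{etype[:3].upper()}:{t_i * 1000 + c_i:04d}"
            concepts.append((concept_id, etype, name))
            terms = {name}
            while len(terms) < cfg.synonyms_per_concept:
                terms.add(_perturb(rng, name))
            for term in sorted(terms):
                entries.append(
                    TermEntry(cfg.resource, concept_id, term, name, etype)
                )

    # cross-type name sharing (ambiguity)
    n_shared = round(cfg.ambiguity_rate * len(concepts))
    donor_idx = rng.choice(len(concepts), size=n_shared, replace=False)
    for i in sorted(donor_idx):
        donor_id, donor_type, donor_name = concepts[i]
        others = [c for c in concepts if c[1] != donor_type]
        acc_id, acc_type, acc_name = others[int(rng.integers(len(others)))]
        entries.append(
            TermEntry(cfg.resource, acc_id, donor_name, acc_name, acc_type)
        )

    # planted common-word terms ("lead"-style false-positive sources)
    rate = cfg.common_word_fp_rate
    n_common = round(rate * len(entries) / (1.0 - rate)) if rate < 1 else 0
    fillers = _filler_lexicon(cfg)
    if n_common > len(fillers):
        raise ValueError(
            "filler_lexicon_size too small for common_word_fp_rate"
        )
    chosen = rng.choice(len(fillers), size=n_common, replace=False)
    for j in sorted(chosen):
        word = fillers[j]
        cid, etype, name = concepts[int(rng.integers(len(concepts)))]
        entries.append(TermEntry(cfg.resource, cid, word, name, etype))
    return entries


def _mentionable(cfg: FixtureConfig,
                 entries: Sequence[TermEntry]) -> list[TermEntry]:
    """Entries whose term is a genuine entity name (not a planted common
    word): the population mentions are drawn from."""
    fillers = set(_filler_lexicon(cfg))
    return [e for e in entries if e.term.casefold() not in fillers]


def make_corpus(
    cfg: FixtureConfig, terminology: Sequence[TermEntry]
) -> list[Document]:
    """Documents of filler sentences with planted, gold-annotated
    mentions.

    Each document holds ~``tokens_per_doc`` whitespace-separated words in
    sentences of 8–14 words; a word position becomes an entity mention
    with probability ``mention_rate``.  The mention surface is one of the
    concept's dictionary terms, optionally perturbed once more at a
    letter–digit boundary.  Gold spans, types and identifiers are
    recorded exactly.
    """
    rng = _rng(cfg, 2)
    fillers = _filler_lexicon(cfg)
    pool = _mentionable(cfg, terminology)
    docs: list[Document] = []
    for d in range(cfg.n_docs):
        words: list[tuple[str, TermEntry | None]] = []
        for _ in range(cfg.tokens_per_doc):
            if pool and rng.random() < cfg.mention_rate:
                e = pool[int(rng.integers(len(pool)))]
                surface = e.term
                if rng.random() < 0.5:
                    surface = _perturb(rng, surface)
                words.append((surface, e))
            else:
                # same case-variation process as mention surfaces, so
                # capitalization carries no class signal
                surface = fillers[int(rng.integers(len(fillers)))]
                r = rng.random()
                if r < 0.125:
                    surface = surface.upper()
                elif r < 0.25:
                    surface = surface[0].upper() + surface[1:]
                words.append((surface, None))
        # assemble sentences, tracking character offsets
        text_parts: list[str] = []
        gold: list[Annotation] = []
        offset = 0
        sentence_len = int(rng.integers(8, 15))
        in_sentence = 0
        for i, (surface, entry) in enumerate(words):
            if in_sentence == 0:
                surface = surface[0].upper() + surface[1:]
            start = offset
            text_parts.append(surface)
            offset += len(surface)
            if entry is not None:
                gold.append(
                    Annotation(
                        start=start,
                        end=offset,
                        entity_type=entry.entity_type,
                        concept_id=entry.concept_id,
                        surface=surface,
                        preferred_name=entry.preferred_name,
                        resource=entry.resource,
                    )
                )
            in_sentence += 1
            last = i == len(words) - 1
            if in_sentence >= sentence_len or last:
                text_parts.append(".")
                offset += 1
                if not last:
                    text_parts.append(" ")
                    offset += 1
                in_sentence = 0
                sentence_len = int(rng.integers(8, 15))
            elif not last:
                text_parts.append(" ")
                offset += 1
        text = "".join(text_parts)
        doc = Document(
            doc_id=f"doc{d:04d}",
            text=text,
            sections=[Section("text", 0, len(text))],
            annotations=sorted(gold, key=Annotation.sort_key),
        )
        doc.validate()
        docs.append(doc)
    return docs


def make_embeddings(
    cfg: FixtureConfig, terminology: Sequence[TermEntry]
) -> EmbeddingTable:
    """Per-type Gaussian embedding clusters plus a common-word cluster.

    Type centroids sit at distance ``cluster_separation`` from the
    origin in random directions; common (filler) words cluster around
    the origin.  Within-cluster offsets are unit-Gaussian draws taken
    from one *global* pool of ``noise_pool_size`` vectors shared by all
    clusters, so a token's vector carries cluster identity but no usable
    token identity: at ``cluster_separation = 0`` the table is entirely
    uninformative about entity types, by construction.  Letter tokens of
    entity terms are assigned to the cluster of the first type they
    occur with; digit tokens are left out of the table (they fall back
    to the zero vector at feature time).
    """
    rng = _rng(cfg, 3)
    types = cfg.type_names()
    centroids: dict[str, np.ndarray] = {}
    for etype in types:
        direction = rng.standard_normal(cfg.embedding_dim)
        direction /= np.linalg.norm(direction)
        centroids[etype] = direction * cfg.cluster_separation
    common_centroid = np.zeros(cfg.embedding_dim)
    pool = rng.standard_normal((cfg.noise_pool_size, cfg.embedding_dim))

    fillers = set(_filler_lexicon(cfg))
    token_cluster: dict[str, np.ndarray] = {}
    for e in sorted(terminology,
                    key=lambda e: (e.resource, e.concept_id, e.term)):
        target = (
            common_centroid
            if e.term.casefold() in fillers
            else centroids[e.entity_type]
        )
        for tok in norm_sequence(e.term):
            if tok.isdigit() or tok in token_cluster:
                continue
            token_cluster[tok] = target
    for w in sorted(fillers):
        for tok in norm_sequence(w):
            if not tok.isdigit():
                token_cluster.setdefault(tok, common_centroid)

    vectors = {
        tok: centroid + pool[int(rng.integers(cfg.noise_pool_size))]
        for tok, centroid in sorted(token_cluster.items())
    }
    return EmbeddingTable(vectors, cfg.embedding_dim)


def make_wordlists(
    cfg: FixtureConfig, terminology: Sequence[TermEntry]
) -> tuple[frozenset[str], frozenset[str]]:
    """(common_vocab, stop_words) for the postfilter features.

    The common vocabulary is the filler lexicon plus a
    ``common_vocab_entity_share`` sample of entity terms (single-token
    ones, lower-cased), emulating terminology/common-dictionary overlap.
    Stop words are a small subset of the filler lexicon.
    """
    rng = _rng(cfg, 4)
    fillers = _filler_lexicon(cfg)
    vocab = set(fillers)
    entity_terms = sorted(
        {
            e.term.casefold()
            for e in _mentionable(cfg, terminology)
            if " " not in e.term
        }
    )
    n_extra = round(cfg.common_vocab_entity_share * len(entity_terms))
    if n_extra:
        chosen = rng.choice(len(entity_terms), size=n_extra, replace=False)
        vocab.update(entity_terms[i] for i in sorted(chosen))
    letter_fillers = [w for w in fillers if w.isalpha()]
    stops = frozenset(letter_fillers[: cfg.n_stop_words])
    return frozenset(vocab), stops


def split_corpus(
    docs: Sequence[Document], n_train: int = 47
) -> tuple[list[Document], list[Document]]:
    """Deterministic train/test split (first ``n_train`` documents)."""
    return list(docs[:n_train]), list(docs[n_train:])


def write_fixture(cfg: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize all fixture artifacts in the pipeline's own dialects.

    Writes terminology TSV, word2vec-text embeddings, one BioC JSON file
    per document, and the two word lists; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    terminology = make_terminology(cfg)
    docs = make_corpus(cfg, terminology)
    embeddings = make_embeddings(cfg, terminology)
    vocab, stops = make_wordlists(cfg, terminology)

    paths = {
        "terminology": outdir / "terminology.tsv",
        "embeddings": outdir / "embeddings.txt",
        "common_vocab": outdir / "common_vocab.txt",
        "stop_words": outdir / "stop_words.txt",
        "corpus": outdir / "corpus",
    }
    write_terminology(terminology, paths["terminology"])
    embeddings.save(paths["embeddings"])
    paths["common_vocab"].write_text(
        "\n".join(sorted(vocab)) + "\n", encoding="utf-8"
    )
    paths["stop_words"].write_text(
        "\n".join(sorted(stops)) + "\n", encoding="utf-8"
    )
    paths["corpus"].mkdir(exist_ok=True)
    for doc in docs:
        (paths["corpus"] / f"{doc.doc_id}.bioc.json").write_bytes(
            write_document(doc, "bioc_json")
        )
    return paths
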