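"""Corpus-based disambiguation postfilter.

The dictionary matcher is deliberately exhaustive and therefore produces
many spurious annotations: common-language words that happen to be
dictionary terms (such as "lead"), and spans linked to identifiers of
several entity types at once.  The postfilter is a feed-forward network
with a softmax output over all entity types plus a "not an entity" label.
For each annotated span it predicts a label distribution; a simple
heuristic then turns the distribution into zero, one or two entity-type
labels per span:

1. take the highest-ranked entity type;
2. if the probability gap between the two top-ranked types is less than
   a threshold θ (default 0.3), take the second-ranked type as well;
3. remove "not an entity" from the selection.

In NER mode the decided labels are emitted directly, so a span can be
*re-classified* to a type the dictionary never proposed (such an
annotation carries no concept identifier).  In CR mode the original
dictionary annotations are kept, restricted to the decided types — a
re-classified span is lost because no identifier can be provided.

Features are computed from the annotated surface string only (no
sentence context): vowel:consonant ratio, membership in a common
vocabulary (whole term, no break-up), stop-word membership, the mean of
the per-token word embeddings, and a configurable set of additional
surface descriptors (length, token count, digit fraction, capitalization
pattern) standing in for the legacy feature set, which is not canonical.

Negative training examples are the *single* words of the training corpus
not covered by any gold annotation.  A consequence — reproduced here as
a documented limitation — is that the network never sees multi-word
negatives and so cannot reliably remove spurious multi-word matches.
"""

from __future__ import annotations

import logging
import pickle
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .matcher import Annotation, strip_concept
from .normalize import tokenize

__all__ = [
    "NOT_ENTITY",
    "STOP_WORDS",
    "EmbeddingTable",
    "FeatureConfig",
    "FeatureExtractor",
    "FeatureVector",
    "PostfilterModel",
    "featurize",
    "build_training_set",
    "train",
    "decide_labels",
    "apply_ner",
    "apply_cr",
]

logger = logging.getLogger(__name__)

#: The extra softmax label that lets the classifier reject a span.
NOT_ENTITY = "NOT_ENTITY"

VOWELS = frozenset("aeiou")

#: Standard English stop-word list (the usual NLP toolkit inventory);
#: used as the default when no stop-word file is supplied.
STOP_WORDS = frozenset("""
a about above after again against all am an and any are aren as at be
because been before being below between both but by can cannot could
couldn did didn do does doesn doing don down during each few for from
further had hadn has hasn have haven having he her here hers herself him
himself his how i if in into is isn it its itself just me mightn more
most mustn my myself no nor not now o of off on once only or other our
ours ourselves out over own re s same shan she should shouldn so some
such t than that the their theirs them themselves then there these they
this those through to too under until up very was wasn we were weren
what when where which while who whom why will with won wouldn you your
yours yourself yourselves
""".split())


# ---------------------------------------------------------------------------
# word embeddings (plain-text word2vec dialect)

class EmbeddingTable:
    """Token → fixed-width vector map in text word2vec format.

    The file starts with a header line ``"<count> <dim>"`` followed by
    one line per token: ``"<token> <v1> ... <vdim>"``.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray], dim: int):
        self.vectors = {k: np.asarray(v, dtype=float) for k, v in
                        vectors.items()}
        self.dim = int(dim)
        for k, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(
                    f"vector for {k!r} has shape {v.shape}, expected "
                    f"({self.dim},)"
                )

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token)

    @classmethod
    def load(cls, source: str | Path | TextIO) -> "EmbeddingTable":
        if isinstance(source, (str, Path)):
            with open(source, encoding="utf-8") as handle:
                return cls.load(handle)
        header = source.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad word2vec header: {header!r}")
        count, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in source:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"embedding row for {parts[0]!r} has {len(parts) - 1} "
                    f"values, expected {dim}"
                )
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
        if len(vectors) != count:
            logger.warning(
                "embedding header announced %d rows, read %d", count,
                len(vectors)
            )
        return cls(vectors, dim)

    def save(self, target: str | Path | TextIO) -> None:
        if isinstance(target, (str, Path)):
            with open(target, "w", encoding="utf-8") as handle:
                self.save(handle)
            return
        target.write(f"{len(self.vectors)} {self.dim}\n")
        for token in sorted(self.vectors):
            values = " ".join(repr(float(x)) for x in self.vectors[token])
            target.write(f"{token} {values}\n")


def load_wordlist(source: str | Path | TextIO) -> frozenset[str]:
    """One word per line, UTF-8; case-folded on load."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as handle:
            return load_wordlist(handle)
    return frozenset(
        line.strip().casefold() for line in source if line.strip()
    )


# ---------------------------------------------------------------------------
# features

@dataclass(frozen=True, slots=True)
class FeatureConfig:
    """Which feature groups enter the network input.

    Presets: ``craft17`` enables everything; ``service3`` uses only the
    common-vocabulary, stop-word and embedding features (the public
    service configuration).
    """

    vowel_consonant: bool = True
    common_vocab: bool = True
    stop_word: bool = True
    embedding: bool = True
    surface_extras: bool = True

    @classmethod
    def preset(cls, name: str) -> "FeatureConfig":
        if name == "craft17":
            return cls()
        if name == "service3":
            return cls(vowel_consonant=False, surface_extras=False)
        raise ValueError(f"unknown feature preset {name!r}")


@dataclass(slots=True)
class FeatureVector:
    """The per-span feature groups, before concatenation."""

    vowel_consonant: float
    in_common_vocab: int
    is_stopword: int
    embedding: np.ndarray
    surface_extras: np.ndarray


def vowel_consonant_ratio(surface: str) -> float:
    """#vowels / #consonants over the letters of ``surface``.

    The vowel set is a, e, i, o, u (y counts as a consonant); non-letter
    characters are ignored.  A surface with no consonants (including
    digit-only surfaces) divides by one instead.
    """
    letters = [c for c in surface.casefold() if c.isalpha()]
    vowels = sum(1 for c in letters if c in VOWELS)
    consonants = len(letters) - vowels
    return vowels / (consonants if consonants else 1)


_CAP_PATTERNS = ("all_upper", "all_lower", "init_cap", "mixed")


def _cap_pattern(surface: str) -> np.ndarray:
    letters = [c for c in surface if c.isalpha()]
    onehot = np.zeros(len(_CAP_PATTERNS))
    if not letters:
        onehot[3] = 1.0
    elif all(c.isupper() for c in letters):
        onehot[0] = 1.0
    elif all(c.islower() for c in letters):
        onehot[1] = 1.0
    elif letters[0].isupper() and all(c.islower() for c in letters[1:]):
        onehot[2] = 1.0
    else:
        onehot[3] = 1.0
    return onehot


def featurize(
    surface: str,
    embeddings: EmbeddingTable,
    common_vocab: frozenset[str] | set[str],
    stop_words: frozenset[str] | set[str] = STOP_WORDS,
) -> FeatureVector:
    """Compute the feature groups for one annotated surface string.

    The common-vocabulary look-up uses the whole term, case-insensitively
    and without break-up, so multi-word surfaces are never "common".
    The embedding is the arithmetic mean over the per-token vectors;
    unknown tokens contribute the zero vector, and a surface whose tokens
    are all unknown gets the zero vector.
    """
    tokens = tokenize(surface)
    vecs = []
    for t in tokens:
        v = embeddings.get(t.norm)
        vecs.append(v if v is not None else np.zeros(embeddings.dim))
    embedding = (
        np.mean(vecs, axis=0) if vecs else np.zeros(embeddings.dim)
    )
    folded = surface.casefold()
    n_digits = sum(1 for c in surface if c.isdigit())
    extras = np.concatenate(
        [
            [float(len(surface))],
            [float(len(tokens))],
            [n_digits / len(surface) if surface else 0.0],
            _cap_pattern(surface),
        ]
    )
    return FeatureVector(
        vowel_consonant=vowel_consonant_ratio(surface),
        in_common_vocab=int(folded in common_vocab),
        is_stopword=int(folded in stop_words),
        embedding=embedding,
        surface_extras=extras,
    )


@dataclass(slots=True)
class FeatureExtractor:
    """Binds the feature resources and flattens feature vectors."""

    embeddings: EmbeddingTable
    common_vocab: frozenset[str]
    stop_words: frozenset[str] = STOP_WORDS
    config: FeatureConfig = field(default_factory=FeatureConfig)

    def vector(self, surface: str) -> np.ndarray:
        fv = featurize(
            surface, self.embeddings, self.common_vocab, self.stop_words
        )
        parts: list[np.ndarray] = []
        cfg = self.config
        if cfg.vowel_consonant:
            parts.append(np.array([fv.vowel_consonant]))
        if cfg.common_vocab:
            parts.append(np.array([float(fv.in_common_vocab)]))
        if cfg.stop_word:
            parts.append(np.array([float(fv.is_stopword)]))
        if cfg.embedding:
            parts.append(fv.embedding)
        if cfg.surface_extras:
            parts.append(fv.surface_extras)
        out = np.concatenate(parts)
        if not np.all(np.isfinite(out)):
            raise ValueError(f"non-finite features for surface {surface!r}")
        return out

    def matrix(self, surfaces: Sequence[str]) -> np.ndarray:
        return np.vstack([self.vector(s) for s in surfaces])


# ---------------------------------------------------------------------------
# training-set construction

_WORD_RE = re.compile(r"\S+")


def iter_words(text: str):
    """Whitespace-delimited word occurrences, stripped of surrounding
    punctuation; yields (surface, start, end)."""
    for m in _WORD_RE.finditer(text):
        word, start = m.group(), m.start()
        lead = len(word) - len(word.lstrip(_PUNCT))
        word = word.strip(_PUNCT)
        if word:
            yield word, start + lead, start + lead + len(word)


_PUNCT = "".join(
    chr(c) for c in range(0x21, 0x7F) if not chr(c).isalnum()
)


def build_training_set(
    docs: Iterable["Document"],  # noqa: F821 - structural typing
) -> list[tuple[str, str]]:
    """Labeled (surface, label) examples from a gold-annotated corpus.

    One positive example per gold annotation (multi-word surfaces
    allowed, labeled with the gold entity type); one NOT_ENTITY example
    per *single word* occurrence not covered by any gold span.  A word is
    a whitespace-delimited run stripped of surrounding punctuation — the
    network sees multi-word inputs only as gold entities, never as
    negatives.  Documents without text are skipped with a warning.
    """
    examples: list[tuple[str, str]] = []
    for doc in docs:
        if not doc.text:
            logger.warning("document %r has no text; skipped", doc.doc_id)
            continue
        covered: list[tuple[int, int]] = []
        for a in doc.annotations:
            surface = a.surface or doc.text[a.start : a.end]
            examples.append((surface, a.entity_type))
            covered.append((a.start, a.end))
        for word, start, end in iter_words(doc.text):
            if any(start < e and s < end for s, e in covered):
                continue
            examples.append((word, NOT_ENTITY))
    return examples


# ---------------------------------------------------------------------------
# the network

@dataclass(frozen=True, slots=True)
class PostfilterConfig:
    """Network hyperparameters (sizes are not canonical; configurable)."""

    hidden_layers: tuple[int, ...] = (100, 100)
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    validation_fraction: float = 0.1
    theta: float = 0.3


@dataclass(slots=True)
class PostfilterModel:
    """A trained joint softmax classifier over entity types + NOT_ENTITY.

    The serialized model carries the network weights, the fixed label
    order, the feature configuration and resources, θ and the training
    seed in one file.
    """

    pipeline: Pipeline
    labels: tuple[str, ...]
    extractor: FeatureExtractor
    theta: float
    seed: int

    def predict_distributions(
        self, surfaces: Sequence[str]
    ) -> list[dict[str, float]]:
        if not surfaces:
            return []
        probs = self.pipeline.predict_proba(self.extractor.matrix(surfaces))
        return [dict(zip(self.labels, row)) for row in probs]

    def predict_distribution(self, surface: str) -> dict[str, float]:
        return self.predict_distributions([surface])[0]

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as handle:
            pickle.dump(self, handle)

    @classmethod
    def load(cls, path: str | Path) -> "PostfilterModel":
        with open(path, "rb") as handle:
            model = pickle.load(handle)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a postfilter model")
        return model


def train(
    examples: Sequence[tuple[str, str]],
    extractor: FeatureExtractor,
    config: PostfilterConfig | None = None,
    seed: int = 0,
) -> PostfilterModel:
    """Fit the feed-forward softmax network on labeled surfaces.

    Rectifier hidden layers, adaptive-gradient optimizer, cross-entropy
    loss, early stopping on a held-out split; fully deterministic for a
    given seed.  At least two distinct labels must be present.
    """
    config = config or PostfilterConfig()
    labels = sorted({label for _, label in examples})
    if len(labels) < 2:
        raise ValueError(
            f"training requires >= 2 distinct labels, got {labels}"
        )
    X = extractor.matrix([surface for surface, _ in examples])
    y = np.array([label for _, label in examples])
    net = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation="relu",
        solver="adam",
        max_iter=config.max_epochs,
        batch_size=min(config.batch_size, max(1, len(examples) - 1)),
        early_stopping=True,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
        random_state=seed,
    )
    pipeline = Pipeline([("scale", StandardScaler()), ("net", net)])
    pipeline.fit(X, y)
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            f"training diverged: final loss {net.loss_!r} is not finite"
        )
    return PostfilterModel(
        pipeline=pipeline,
        labels=tuple(net.classes_),
        extractor=extractor,
        theta=config.theta,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# label decision and output semantics

def decide_labels(
    dist: Mapping[str, float], theta: float
) -> frozenset[str]:
    """Turn a label distribution into 0–2 entity-type labels.

    Labels are ranked by probability (ties broken alphabetically for
    determinism); the top label is taken, the runner-up is added only if
    the probability gap is strictly below θ, and NOT_ENTITY is removed
    from the result afterwards.
    """
    ranked = sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = [ranked[0][0]]
    if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < theta:
        selected.append(ranked[1][0])
    return frozenset(label for label in selected if label != NOT_ENTITY)


def _group_by_span(
    annotations: Sequence[Annotation],
) -> dict[tuple[int, int], list[Annotation]]:
    groups: dict[tuple[int, int], list[Annotation]] = defaultdict(list)
    for a in annotations:
        groups[(a.start, a.end)].append(a)
    return dict(groups)


def _decisions(
    annotations: Sequence[Annotation],
    model: PostfilterModel,
    theta: float | None,
) -> list[tuple[tuple[int, int], list[Annotation], frozenset[str]]]:
    theta = model.theta if theta is None else theta
    groups = _group_by_span(annotations)
    spans = sorted(groups)
    surfaces = [groups[span][0].surface for span in spans]
    dists = model.predict_distributions(surfaces)
    return [
        (span, groups[span], decide_labels(dist, theta))
        for span, dist in zip(spans, dists)
    ]


def apply_ner(
    annotations: Sequence[Annotation],
    model: PostfilterModel,
    theta: float | None = None,
) -> list[Annotation]:
    """Emit the decided labels directly (NER semantics).

    A decided label present among the upstream annotations of the span
    keeps those annotations (identifiers included); a re-classified label
    yields one annotation without a concept identifier.  A span whose
    decision is empty is removed.
    """
    out: list[Annotation] = []
    for (start, end), group, labels in _decisions(annotations, model, theta):
        upstream_types = {a.entity_type for a in group}
        for label in sorted(labels):
            if label in upstream_types:
                out.extend(a for a in group if a.entity_type == label)
            else:
                out.append(
                    strip_concept(
                        Annotation(
                            start=start,
                            end=end,
                            entity_type=label,
                            concept_id=None,
                            surface=group[0].surface,
                        )
                    )
                )
    return sorted(out, key=Annotation.sort_key)


def apply_cr(
    annotations: Sequence[Annotation],
    model: PostfilterModel,
    theta: float | None = None,
) -> list[Annotation]:
    """Restrict upstream annotations to the decided types (CR semantics).

    Re-classified labels contribute nothing, since no identifier can be
    provided; hence CR output is always a subset of the matcher output.
    """
    out: list[Annotation] = []
    for _, group, labels in _decisions(annotations, model, theta):
        out.extend(a for a in group if a.entity_type in labels)
    return sorted(out, key=Annotation.sort_key)


# ---------------------------------------------------------------------------
# descriptive report

def vocabulary_coverage_report(
    entries: Sequence["TermEntry"],  # noqa: F821
    common_vocab: frozenset[str] | set[str],
) -> dict[str, dict[str, float]]:
    """Per-type percentage of dictionary terms found in the common
    vocabulary, computed both ways: whole-term look-up ("no break-up")
    and per-word look-up requiring every word to be known ("break-up").
    """
    by_type: dict[str, list[str]] = defaultdict(list)
    for e in entries:
        by_type[e.entity_type].append(e.term)
    report: dict[str, dict[str, float]] = {}
    for etype, terms in sorted(by_type.items()):
        whole = sum(1 for t in terms if t.casefold() in common_vocab)
        broken = sum(
            1
            for t in terms
            if all(w.casefold() in common_vocab for w in t.split())
        )
        report[etype] = {
            "no_breakup_pct": 100.0 * whole / len(terms),
            "breakup_pct": 100.0 * broken / len(terms),
            "n_terms": float(len(terms)),
        }
    return report
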