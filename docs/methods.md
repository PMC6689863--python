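# Methods

This note documents the models and procedures implemented in `lexitag`,
the design choices made where the design was genuinely open, and what
the synthetic study does and does not demonstrate.

## Lossy normalization

Both dictionary terms and document text pass through the same
tokenization: the text is case-folded and split into maximal runs of
Unicode letters and maximal runs of decimal digits; every other
character separates tokens and is discarded. A letter–digit transition
splits a token even without a separator, so `SRC1`, `SRC 1` and `SRC-1`
all normalize to `(src, 1)`. Each token keeps its character span
(0-based, half-open) in the *original* text, which is what all
downstream offsets refer to. Greek letters are ordinary letters (no
transliteration); there is no stemming or morphological expansion —
mentions that differ morphologically from every dictionary term
(`carbonic` vs. `carbon`) are out of reach by design and are the
dominant source of false negatives in this family of systems.

Sentence splitting is a deliberately simple rule: a boundary after
sentence-final punctuation (`.!?`, optional closing quote/bracket) plus
whitespace, only when the next character is an upper-case letter or a
digit. The digit clause makes enumerations like "rose to 5. 6 mice
died" split correctly but over-splits abbreviation-before-number
patterns ("Fig. 1b"); this is an accepted limitation of the rule.
Sentence segmentation only matters when `sentence_mode` is on, in which
case candidate matches may not cross a boundary; by default the whole
text is one matching window.

## Two-hash-table matching

Terms are indexed under their normalized token sequence (the *main
index*); a second table (the *trigger index*) maps the first token of
every term to the set of term lengths beginning with it, and `t_max` is
the longest indexed term in tokens. Scanning looks each text token up
in the trigger index (one look-up per token); only on a hit are the
windows of admissible lengths extracted and looked up in the main
index, bounding main look-ups by `tokens x t_max`. The scanner is
provably equivalent to the exhaustive all-subsequences matcher — the
test suite checks this equivalence on hundreds of generated documents —
while doing a small fraction of its look-ups.

All matches are emitted, including nested and overlapping spans,
because pruning is the postfilter's job. A matched span runs from the
first to the last matched token in the original text and therefore may
contain intervening punctuation (surface `IOP) [1` for normalized
`(iop, 1)`). Exact (span, type, concept) duplicates arising from
distinct synonym spellings are collapsed.

## Disambiguation postfilter

A feed-forward network with a softmax output over the configured entity
types plus a NOT_ENTITY label scores each annotated span from its
surface string alone (no sentence context). Features:

| feature | definition | default |
|---|---|---|
| vowel:consonant | #vowels / #consonants over letters (vowels a,e,i,o,u; zero consonants → divide by 1) | on |
| common vocabulary | whole-surface, case-insensitive membership in a word list; multi-word surfaces are never members (no break-up) | on |
| stop word | membership in a stop-word list (default: the standard English list) | on |
| embeddings | arithmetic mean of per-token vectors from a word2vec-text table; unknown tokens contribute the zero vector | on |
| surface extras | length, token count, digit fraction, capitalization pattern (4-way one-hot) | on |

The `craft17` preset enables everything; `service3` keeps only common
vocabulary, stop words and embeddings. The surface extras are a
configurable stand-in for a legacy feature set that is not canonically
defined; they are labelled non-canonical on purpose.

Training data comes from a gold-annotated corpus: one positive example
per gold annotation (multi-word surfaces allowed), one NOT_ENTITY
example per whitespace-delimited word occurrence (surrounding
punctuation stripped) not covered by any gold span. Because negatives
are always single words, the network never observes a multi-word
non-entity and systematically keeps spurious multi-word matches — a
known limitation that the test suite reproduces rather than hides.

The network defaults are two ReLU hidden layers of width 100, adam,
cross-entropy, at most 100 epochs, early stopping with patience 10 on a
10% held-out split, batch size 32 (capped at the dataset size so small
corpora still take many gradient steps per epoch), fixed seed. Training
is deterministic for a given seed; the serialized model carries
weights, label order, feature configuration, θ and the seed in one
file.

**Label heuristic.** For each span, rank labels by probability; take
the top label; add the runner-up iff `p1 − p2 < θ` (strict, so a gap of
exactly θ does not add it); remove NOT_ENTITY afterwards — NOT_ENTITY
can occupy a rank before removal but is never emitted. θ defaults to
0.3 and the heuristic yields 0–2 labels per span, monotone in θ.

**Output semantics.** NER: the decided labels are emitted; a label the
dictionary also proposed keeps those annotations (with identifiers), a
re-classified label yields an annotation with no concept identifier,
and an empty decision removes the span. CR: the upstream annotations
are restricted to the decided types, so CR output is always a subset of
matcher output and re-classified spans are lost (no identifier can be
provided).

## Evaluation

Strict-span micro-averaged scoring: a prediction is correct only when
its (document, start, end) and its entity type (NER) or concept
identifier (CR) equal a gold annotation's exactly; partial overlap gets
no credit. Matching on exact keys makes the maximum bipartite matching
degenerate to per-key count intersection; duplicate identical
predictions are collapsed first so they cannot double-count as false
positives. Predictions referencing a document absent from gold are a
hard error (documents with empty gold can be declared explicitly). The
entity-type overlap matrix reports, for undisambiguated multi-type
output, the percentage of mentions of row type r also annotated with
column type c at the same span; raw co-occurrence counts are symmetric,
the row-normalized percentages are not.

## Interchange formats

BioC XML and JSON carry type/identifier in annotation infons `type` and
`identifier`; section labels in the passage infon `type`; all
document-level infons round-trip as metadata. PubAnnotation denotations
carry the entity type in `obj` and the identifier in an `identifier`
attribute; preferred name and source resource are outside that format's
data model and are dropped. All formats share one document-level
0-based coordinate system; passage offsets are honored on read, with
gaps padded by spaces so offsets remain valid verbatim. Round-trip
identity holds per format on the data-model subset it supports.

## Synthetic study design

The generator (`lexitag.fixtures`) emulates the inputs of a real
deployment, with every quantity a pure function of the config (default
values in parentheses):

* **Terminology** — `n_types` (4) × `n_concepts_per_type` (50)
  concepts; each has a unique letter stem (2–3 syllables), half carry a
  digit suffix, and `synonyms_per_concept` (2) spelling variants
  generated only by hyphen/space insertion at letter–digit boundaries
  and case changes — exactly the variation the normalization collapses.
  `ambiguity_rate` (0.1) of names are re-used as terms of a concept of
  another type; common words are appended as extra terms until they are
  `common_word_fp_rate` (0.2) of all entries — the `lead`-style
  false-positive mechanism.
* **Corpus** — `n_docs` (67) documents of `tokens_per_doc` (120) words
  in 8–14-word sentences; each position is an entity mention with
  probability `mention_rate` (0.08), drawn from the non-common-word
  entries with a possible extra surface perturbation; gold spans, types
  and identifiers are recorded exactly. The first 47 documents train,
  the last 20 test, mirroring the usual corpus split convention.
* **Embeddings** — `embedding_dim` (25); each entity type's centroid
  sits at distance `cluster_separation` (4.0) from the origin in a
  random direction, common words at the origin. Within-cluster offsets
  are drawn from a single global pool of `noise_pool_size` (16) unit
  Gaussians shared by all clusters, so a token's vector identifies its
  *cluster* but not the token itself: at separation 0 the table carries
  no type information whatsoever, which is what makes the
  zero-separation control meaningful (with per-token i.i.d. noise a
  network simply memorizes token identity).
* **Shape parity** — filler (common) words follow the same shape
  process as entity names (syllable structure, digit-suffix rate,
  matched case variation, sentence-initial capitalization for every
  word), and `common_vocab_entity_share` (0.3) of entity terms are also
  placed in the common-vocabulary list. This keeps the surface features
  weakly informative — matching the empirical situation in which
  embeddings are the salient feature — so that the benefit of the
  postfilter is controlled by `cluster_separation`, not by giveaway
  surface cues.
* **Recall guarantee** — filler and entity lexicons use disjoint
  consonant inventories and entity stems are unique, so a planted
  mention always matches its own dictionary key: dictionary recall on
  gold is 1.0 by construction, and every measured difference is about
  precision.

What the study shows: under separable clusters the hybrid pipeline
recovers most of the precision the exhaustive matcher gives away
(seed 0: dictionary-only P 0.23 / R 1.00 / F1 0.37 → hybrid
P ≈ R ≈ F1 ≈ 0.91), and the gain collapses when the clusters coincide.
What it does not show: performance on real corpora — real synonymy,
morphology, abbreviation ambiguity, multi-word negatives and
distributional embedding noise are all absent, and the reported numbers
characterize the synthetic conditions only.

## Numerical and degenerate-input choices

* Ties in the label heuristic break alphabetically for determinism; a
  probability gap of exactly θ does not admit the runner-up.
* Digit-only surfaces get vowel:consonant 0; surfaces with no known
  embedding tokens get the zero vector.
* Empty text tokenizes to an empty sequence; an empty document is
  skipped at training time with a warning; a single-label training set
  is rejected.
* Precision/recall are 0 when their denominators are 0; F1 is 0 when
  P + R = 0.
* Problem sizes in the default study (67 × 120-word documents, ~5 600
  training examples, 200 oracle-comparison documents, 10 000 heuristic
  samples) were chosen so the full study runs in seconds on one CPU
  while keeping per-document annotation counts realistic.
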