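# lexitag

Hybrid dictionary-based named-entity recognition (NER) and concept
recognition (CR) for biomedical text, with a neural disambiguation
postfilter.

Terminology-driven taggers are the workhorse of biomedical text mining:
given a curated dictionary of names connected to ontology identifiers
(chemicals, proteins, cell types, diseases, …), they locate mentions in
running text and link each mention to a concept. Pure dictionary lookup
is fast but noisy — ordinary words such as *lead* are also dictionary
terms, and the aggressive normalization needed to catch spelling
variants creates cross-type collisions. `lexitag` therefore runs a
four-step pipeline:

1. **Parse** — plain text, BioC XML/JSON or PubAnnotation JSON into a
   common document model with standoff annotations.
2. **Match** — lossy, offset-preserving tokenization (case folded,
   punctuation dropped, letter–digit boundaries split, so
   `SRC1` ≡ `SRC 1` ≡ `SRC-1`) feeds a two-hash-table index: a *trigger
   index* maps the first token of any term to the admissible term
   lengths, and a *main index* maps full token sequences to dictionary
   entries. Matching costs one trigger look-up per token and at most
   O(s · t_max) main look-ups per sentence of s tokens, instead of the
   O(s²) of naive subsequence lookup. All matches are emitted, nested
   and overlapping ones included.
3. **Disambiguate** — a feed-forward softmax network predicts, for each
   annotated span, a probability distribution over entity types plus a
   *not-an-entity* label, from surface features only: vowel:consonant
   ratio, common-vocabulary membership, stop-word membership, the mean
   of per-token word embeddings, and simple surface descriptors. The
   label heuristic takes the top-ranked type, adds the runner-up when
   the probability gap is below θ (default 0.3), and removes
   *not-an-entity* — yielding 0–2 labels per span. In NER mode decided
   labels are emitted directly (a span may be re-classified, losing its
   identifier); in CR mode the original annotations are kept, restricted
   to the decided types.
4. **Serialize** — back to any supported format, or annotation TSV.

Evaluation is strict-span and micro-averaged: a prediction counts only
if its character offsets (and type, for NER, or concept identifier, for
CR) exactly match a gold annotation.

A deterministic synthetic-fixture generator (`lexitag.fixtures`)
produces terminologies with planted spelling variants, cross-type
ambiguity and common-word terms, gold-annotated corpora, and
type-clustered word embeddings, so the whole pipeline is testable
without downloading any corpus or ontology.

## Worked example

```python
import lexitag as lt

# a synthetic study: 4 entity types, 20% common-word dictionary terms,
# well-separated embedding clusters, 67 documents (47 train / 20 test)
cfg = lt.FixtureConfig()                      # seed=0
terms = lt.make_terminology(cfg)
docs = lt.make_corpus(cfg, terms)
index = lt.build_index(terms)
vocab, stops = lt.make_wordlists(cfg, terms)

train_docs, test_docs = lt.split_corpus(docs)
extractor = lt.FeatureExtractor(
    embeddings=lt.make_embeddings(cfg, terms),
    common_vocab=vocab, stop_words=stops,
)
model = lt.train(lt.build_training_set(train_docs), extractor, seed=0)

gold = [(d.doc_id, a) for d in test_docs for a in d.annotations]
ids = [d.doc_id for d in test_docs]
upstream = {d.doc_id: lt.annotate(d.text, index) for d in test_docs}
dict_out = [(i, a) for i, anns in upstream.items() for a in anns]
ner_out = [(i, a) for i, anns in upstream.items()
           for a in lt.apply_ner(anns, model)]

print("dict-only:", lt.eval_ner(gold, dict_out, documents=ids).overall)
print("hybrid:   ", lt.eval_ner(gold, ner_out, documents=ids).overall)
```

prints

```
dict-only: Scores(tp=185, fp=620, fn=0)
hybrid:    Scores(tp=168, fp=17, fn=17)
```

i.e. the dictionary matcher finds every planted mention (recall 1.00)
but drowns it in common-word and ambiguity false positives (precision
0.23); the postfilter removes almost all of them, lifting precision to
0.91 at recall 0.91 (F1 0.91 versus 0.37 dictionary-only).

The same pipeline is available from the shell:

```sh
lexitag fixture --outdir fx --seed 0
lexitag index -t fx/terminology.tsv
lexitag train fx/corpus/doc00*.json --embeddings fx/embeddings.txt \
    --common-vocab fx/common_vocab.txt --out model.pkl
lexitag annotate paper.txt -t fx/terminology.tsv --model model.pkl \
    --out-format bioc_json --outdir out/
lexitag eval --gold gold.json --predicted out/paper.bioc.json --level ner
```

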