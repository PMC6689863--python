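"""Trigger-indexed dictionary matching.

Every token of the (lossily normalized) text is looked up in the trigger
index; on a hit, the candidate token windows of every admissible length
are looked up in the main index, and each dictionary entry in a matching
bucket yields one annotation.  All matches are emitted — nested and
overlapping ones included — because pruning is the postfilter's job.

A matched span runs from the first token's start to the last token's end
in the *original* text, so it may include intervening punctuation or
whitespace (e.g. the surface ``"IOP) [1"`` for a term whose normalized
form is ``("iop", "1")``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, TextIO

from .normalize import Token, iter_sentence_tokens, tokenize
from .terminology import TermIndex

__all__ = ["Annotation", "annotate", "lookup_stats", "write_annotations_tsv"]


@dataclass(frozen=True, slots=True)
class Annotation:
    """A text span linked to an entity type and (usually) a concept.

    Offsets are 0-based half-open over the original text.  Several
    annotations may share one span with different types or concept
    identifiers.  ``concept_id`` is ``None`` only for spans re-classified
    by the postfilter in NER mode, where no identifier can be provided.
    """

    start: int
    end: int
    entity_type: str
    concept_id: str | None
    surface: str = ""
    preferred_name: str = ""
    resource: str = ""

    def sort_key(self) -> tuple:
        return (self.start, self.end, self.entity_type, self.concept_id or "")


def annotate(
    text: str, index: TermIndex, sentence_mode: bool = False
) -> list[Annotation]:
    """Emit every dictionary match in ``text``.

    With ``sentence_mode`` on, candidate token sequences never cross a
    sentence boundary.  Exact (span, type, concept) duplicates that arise
    from distinct dictionary terms normalizing identically are collapsed.
    Output is sorted by (start, end, entity_type, concept_id).
    """
    out: dict[tuple, Annotation] = {}
    for tokens in iter_sentence_tokens(text, sentence_mode):
        _scan(text, tokens, index, out)
    return sorted(out.values(), key=Annotation.sort_key)


def _scan(
    text: str,
    tokens: Sequence[Token],
    index: TermIndex,
    out: dict[tuple, Annotation],
) -> None:
    n = len(tokens)
    for p in range(n):
        lengths = index.trigger_index.get(tokens[p].norm)
        if not lengths:
            continue
        for length in lengths:
            if p + length > n:
                continue
            window = tokens[p : p + length]
            entries = index.main_index.get(tuple(t.norm for t in window))
            if not entries:
                continue
            start, end = window[0].start, window[-1].end
            for e in entries:
                dedup = (start, end, e.entity_type, e.concept_id)
                if dedup not in out:
                    out[dedup] = Annotation(
                        start=start,
                        end=end,
                        entity_type=e.entity_type,
                        concept_id=e.concept_id,
                        surface=text[start:end],
                        preferred_name=e.preferred_name,
                        resource=e.resource,
                    )


def lookup_stats(
    text: str, index: TermIndex, sentence_mode: bool = False
) -> tuple[int, int]:
    """Count hash-table look-ups performed while scanning ``text``.

    Returns ``(trigger_lookups, main_lookups)``: one trigger look-up per
    token, and one main-index look-up per (trigger hit, admissible
    length) pair — at most ``token_count * t_max`` in total.
    """
    trigger_lookups = 0
    main_lookups = 0
    for tokens in iter_sentence_tokens(text, sentence_mode):
        n = len(tokens)
        trigger_lookups += n
        for p in range(n):
            lengths = index.trigger_index.get(tokens[p].norm)
            if not lengths:
                continue
            main_lookups += sum(1 for length in lengths if p + length <= n)
    return trigger_lookups, main_lookups


def brute_force_annotate(text: str, index: TermIndex) -> list[Annotation]:
    """Exhaustive O(s²) reference matcher: look up *every* contiguous
    token subsequence of length ≤ t_max in the main index.

    Used as the independence oracle for the trigger-based scanner; it
    never consults the trigger index.
    """
    tokens = tokenize(text)
    out: dict[tuple, Annotation] = {}
    n = len(tokens)
    for p in range(n):
        for q in range(p + 1, min(p + index.t_max, n) + 1):
            window = tokens[p:q]
            entries = index.main_index.get(tuple(t.norm for t in window))
            if not entries:
                continue
            start, end = window[0].start, window[-1].end
            for e in entries:
                dedup = (start, end, e.entity_type, e.concept_id)
                out.setdefault(
                    dedup,
                    Annotation(
                        start=start,
                        end=end,
                        entity_type=e.entity_type,
                        concept_id=e.concept_id,
                        surface=text[start:end],
                        preferred_name=e.preferred_name,
                        resource=e.resource,
                    ),
                )
    return sorted(out.values(), key=Annotation.sort_key)


def write_annotations_tsv(
    docs: Sequence[tuple[str, Sequence[Annotation]]],
    target: str | Path | TextIO,
) -> None:
    """Annotation TSV export: one row per annotation per document."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            write_annotations_tsv(docs, handle)
        return
    target.write(
        "document_id\tstart\tend\tsurface\tentity_type\tconcept_id\t"
        "preferred_name\tresource\n"
    )
    for doc_id, annotations in docs:
        for a in annotations:
            target.write(
                f"{doc_id}\t{a.start}\t{a.end}\t{a.surface}\t"
                f"{a.entity_type}\t{a.concept_id or ''}\t"
                f"{a.preferred_name}\t{a.resource}\n"
            )


def strip_concept(annotation: Annotation) -> Annotation:
    """A copy of ``annotation`` with the concept identifier removed."""
    return replace(annotation, concept_id=None, preferred_name="",
                   resource="")
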