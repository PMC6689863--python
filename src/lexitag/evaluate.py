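"""Strict-span evaluation and the entity-type overlap matrix.

A prediction is a true positive only when its character offsets match a
gold annotation *exactly* — no credit for partial overlap — and, at the
NER level, the entity type matches; at the CR level, the concept
identifier matches.  Each gold annotation can absorb at most one
prediction and vice versa.  Precision, recall and F1 are micro-averaged
over summed TP/FP/FN counts.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence, TextIO

from .matcher import Annotation

__all__ = ["Scores", "EvalReport", "eval_ner", "eval_cr",
           "type_overlap_matrix"]

#: (doc_id, annotation) pairs are the evaluation currency.
DocAnnotation = tuple[str, Annotation]


@dataclass(slots=True)
class Scores:
    """TP/FP/FN counts with the derived micro metrics."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(slots=True)
class EvalReport:
    """Per-type and overall strict-span scores."""

    per_type: dict[str, Scores] = field(default_factory=dict)
    overall: Scores = field(default_factory=Scores)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for name, s in [*sorted(self.per_type.items()),
                        ("All", self.overall)]:
            rows.append(
                {
                    "entity_type": name,
                    "precision": round(s.precision, 4),
                    "recall": round(s.recall, 4),
                    "f1": round(s.f1, 4),
                    "tp": s.tp,
                    "fp": s.fp,
                    "fn": s.fn,
                }
            )
        return rows

    def write_tsv(self, target: str | Path | TextIO) -> None:
        if isinstance(target, (str, Path)):
            with open(target, "w", encoding="utf-8") as handle:
                self.write_tsv(handle)
            return
        cols = ("entity_type", "precision", "recall", "f1", "tp", "fp", "fn")
        target.write("\t".join(cols) + "\n")
        for row in self.to_rows():
            target.write("\t".join(str(row[c]) for c in cols) + "\n")

    def write_json(self, target: str | Path | TextIO) -> None:
        if isinstance(target, (str, Path)):
            with open(target, "w", encoding="utf-8") as handle:
                self.write_json(handle)
            return
        json.dump(self.to_rows(), target, indent=1)


def _score(
    gold: Iterable[DocAnnotation],
    predicted: Iterable[DocAnnotation],
    key,
    type_of,
    documents: Iterable[str] | None,
) -> EvalReport:
    # Duplicate identical predictions would double-count FPs; collapse them.
    gold_keys = Counter(key(d, a) for d, a in gold)
    pred_keys = set(key(d, a) for d, a in predicted)

    gold_docs = {k[0] for k in gold_keys}
    if documents is not None:
        gold_docs |= set(documents)
    stray = {k[0] for k in pred_keys} - gold_docs
    if stray:
        raise ValueError(
            f"predictions reference documents absent from gold: "
            f"{sorted(stray)}"
        )

    report = EvalReport()

    def scores_for(k: Hashable) -> Scores:
        etype = type_of(k)
        if etype not in report.per_type:
            report.per_type[etype] = Scores()
        return report.per_type[etype]

    for k, n_gold in gold_keys.items():
        # exact-key matching: a maximum bipartite matching degenerates to
        # min(count) per identical key; predictions are already collapsed.
        n_pred = 1 if k in pred_keys else 0
        tp = min(n_gold, n_pred)
        s = scores_for(k)
        s.tp += tp
        s.fn += n_gold - tp
    for k in pred_keys:
        if k not in gold_keys:
            scores_for(k).fp += 1

    report.overall = Scores(
        tp=sum(s.tp for s in report.per_type.values()),
        fp=sum(s.fp for s in report.per_type.values()),
        fn=sum(s.fn for s in report.per_type.values()),
    )
    return report


def eval_ner(
    gold: Iterable[DocAnnotation],
    predicted: Iterable[DocAnnotation],
    documents: Iterable[str] | None = None,
) -> EvalReport:
    """Strict-span, exact-type scoring.

    ``documents`` may list gold document ids explicitly (needed when a
    gold document has no annotations at all); predictions for a document
    not present in gold raise a ValueError.
    """
    return _score(
        gold,
        predicted,
        key=lambda d, a: (d, a.start, a.end, a.entity_type),
        type_of=lambda k: k[3],
        documents=documents,
    )


def eval_cr(
    gold: Iterable[DocAnnotation],
    predicted: Iterable[DocAnnotation],
    documents: Iterable[str] | None = None,
) -> EvalReport:
    """Strict-span, exact-identifier scoring.

    Per-type breakdown uses the annotation's entity type; matching is on
    (document, span, concept_id).
    """
    by_key_type: dict[tuple, str] = {}

    def key(d: str, a: Annotation) -> tuple:
        k = (d, a.start, a.end, a.concept_id)
        by_key_type.setdefault(k, a.entity_type)
        return k

    return _score(
        gold,
        predicted,
        key=key,
        type_of=lambda k: by_key_type.get(k, ""),
        documents=documents,
    )


def type_overlap_matrix(
    annotations: Iterable[DocAnnotation],
    types: Sequence[str] | None = None,
) -> tuple[list[str], list[list[float]]]:
    """Row-normalized co-annotation percentages between entity types.

    Input is multi-type matcher output with disambiguation disabled.
    Cell (r, c) is the percentage of mentions (distinct document spans)
    carrying type r that also carry type c at the same span; the diagonal
    is 100 for every type that occurs.  Raw co-occurrence counts are
    symmetric; the row-normalized percentages generally are not.
    """
    span_types: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    for doc_id, a in annotations:
        span_types[(doc_id, a.start, a.end)].add(a.entity_type)

    co: Counter[tuple[str, str]] = Counter()
    for ts in span_types.values():
        for r in ts:
            for c in ts:
                co[(r, c)] += 1

    labels = list(types) if types is not None else sorted(
        {t for ts in span_types.values() for t in ts}
    )
    matrix = []
    for r in labels:
        denom = co[(r, r)]
        matrix.append(
            [100.0 * co[(r, c)] / denom if denom else 0.0 for c in labels]
        )
    return labels, matrix
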