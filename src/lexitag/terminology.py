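"""Terminology loading and the two-hash-table term index.

Terminologies are flat 5-column TSV files (header ``resource``,
``concept_id``, ``term``, ``preferred_name``, ``entity_type``; extra
columns are carried opaquely).  Every term is converted to its normalized
token sequence and indexed in two hash tables:

* the *main index* maps a full normalized token sequence to its dictionary
  entries (ambiguous sequences hold several entries; synonyms of one
  concept occupy several keys);
* the *trigger index* maps the first normalized token of any term to the
  set of term lengths (in tokens) starting with it, so that document
  matching needs a single look-up per token in the common case.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .normalize import norm_sequence

__all__ = [
    "TermEntry",
    "TermIndex",
    "TerminologyError",
    "load_terminology",
    "write_terminology",
    "build_index",
    "index_stats",
]

logger = logging.getLogger(__name__)

#: Required header of the terminology TSV dialect, in column order.
COLUMNS = ("resource", "concept_id", "term", "preferred_name", "entity_type")


class TerminologyError(ValueError):
    """Malformed terminology input (wrong header / field count)."""


@dataclass(frozen=True, slots=True)
class TermEntry:
    """One dictionary record: a name connected to a concept identifier."""

    resource: str
    concept_id: str
    term: str
    preferred_name: str
    entity_type: str
    extras: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, ...]:
        return norm_sequence(self.term)


@dataclass(slots=True)
class LoadReport:
    """Per-file tally of accepted and rejected terminology lines."""

    accepted: int = 0
    duplicates: int = 0
    empty_terms: int = 0
    rejected_types: dict[str, int] = field(default_factory=dict)


def load_terminology(
    source: str | Path | TextIO,
    type_vocabulary: Iterable[str] | None = None,
    *,
    report: LoadReport | None = None,
) -> list[TermEntry]:
    """Read a terminology TSV and return deduplicated entries.

    Entries whose ``entity_type`` is outside ``type_vocabulary`` (when
    given) are rejected and counted in ``report.rejected_types``.
    Duplicate ``(concept_id, entity_type, term)`` triples are collapsed.
    A line with fewer than 5 fields raises :class:`TerminologyError`
    naming the line number; an empty term is skipped with a warning count.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8", newline="") as handle:
            return load_terminology(handle, type_vocabulary, report=report)

    vocab = set(type_vocabulary) if type_vocabulary is not None else None
    report = report if report is not None else LoadReport()
    reader = csv.reader(source, delimiter="\t", quoting=csv.QUOTE_NONE)

    header = next(reader, None)
    if header is None or tuple(h.strip() for h in header[:5]) != COLUMNS:
        raise TerminologyError(
            f"terminology header must start with {COLUMNS}, got {header!r}"
        )

    entries: list[TermEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) < 5:
            raise TerminologyError(
                f"line {lineno}: expected at least 5 tab-separated fields, "
                f"got {len(row)}"
            )
        resource, concept_id, term, preferred, etype = (
            f.strip() for f in row[:5]
        )
        if not term or not norm_sequence(term):
            report.empty_terms += 1
            logger.warning("line %d: empty term skipped", lineno)
            continue
        if vocab is not None and etype not in vocab:
            report.rejected_types[etype] = (
                report.rejected_types.get(etype, 0) + 1
            )
            continue
        triple = (concept_id, etype, term)
        if triple in seen:
            report.duplicates += 1
            continue
        seen.add(triple)
        entries.append(
            TermEntry(resource, concept_id, term, preferred, etype,
                      tuple(row[5:]))
        )
    report.accepted = len(entries)
    return entries


def write_terminology(
    entries: Sequence[TermEntry], target: str | Path | TextIO
) -> None:
    """Serialize entries back to the 5-column TSV dialect."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8", newline="") as handle:
            write_terminology(entries, handle)
        return
    writer = csv.writer(target, delimiter="\t", lineterminator="\n",
                        quoting=csv.QUOTE_NONE)
    writer.writerow(COLUMNS)
    for e in entries:
        writer.writerow(
            [e.resource, e.concept_id, e.term, e.preferred_name,
             e.entity_type, *e.extras]
        )


@dataclass(slots=True)
class TermIndex:
    """The two-hash-table structure for trigger-based term look-up.

    ``t_max`` is the token count of the longest indexed term; it bounds
    the number of main-index look-ups per token (O(s × t_max) over a
    sentence of s tokens, versus O(s²) without the trigger table).
    """

    main_index: dict[tuple[str, ...], list[TermEntry]]
    trigger_index: dict[str, set[int]]
    t_max: int

    def __contains__(self, key: tuple[str, ...]) -> bool:
        return key in self.main_index


def build_index(entries: Sequence[TermEntry]) -> TermIndex:
    """Index terms by normalized token sequence plus the trigger table.

    Entries are sorted by (resource, concept_id, term) first so bucket
    order — and hence annotation output order — is reproducible.
    """
    if not entries:
        raise ValueError("cannot build an index from zero entries")
    main: dict[tuple[str, ...], list[TermEntry]] = {}
    trigger: dict[str, set[int]] = {}
    t_max = 0
    for entry in sorted(
        entries, key=lambda e: (e.resource, e.concept_id, e.term)
    ):
        key = entry.key
        if not key:
            continue
        main.setdefault(key, []).append(entry)
        trigger.setdefault(key[0], set()).add(len(key))
        t_max = max(t_max, len(key))
    return TermIndex(main, trigger, t_max)


def index_stats(index: TermIndex) -> dict[str, int]:
    """Entry/key counts for the index statistics report."""
    return {
        "entries": sum(len(v) for v in index.main_index.values()),
        "keys": len(index.main_index),
        "ambiguous_keys": sum(
            1
            for v in index.main_index.values()
            if len({(e.entity_type, e.concept_id) for e in v}) > 1
        ),
        "t_max": index.t_max,
    }


def write_index_stats(index: TermIndex, target: str | Path | TextIO) -> None:
    """Write the statistics report as two-column TSV."""
    stats = index_stats(index)
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as handle:
            write_index_stats(index, handle)
        return
    for k, v in stats.items():
        target.write(f"{k}\t{v}\n")
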