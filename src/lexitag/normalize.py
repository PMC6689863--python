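"""Lossy, offset-preserving tokenization.

The tokenizer deliberately discards case, punctuation and letter–digit
boundaries so that spelling variants of the same term ("SRC1", "SRC 1",
"SRC-1") collapse onto a single normalized token sequence ("src", "1").
The same function is applied to dictionary terms at indexing time and to
document text at matching time, which guarantees that every collapsible
variant pair meets on an identical key.

Character classes are Unicode letters and decimal digits; every other
character is a separator and is dropped.  Greek letters are kept as
letters (no transliteration).  Offsets are 0-based half-open over the
original, unmodified text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = ["Token", "tokenize", "norm_sequence", "split_sentences"]

# Maximal runs of letters, or maximal runs of decimal digits.  ``\w`` minus
# digits minus underscore leaves exactly the Unicode letter class (plus
# combining marks, which behave as letters for our purposes).
_TOKEN_RE = re.compile(r"[^\W\d_]+|\d+")

# Sentence-final punctuation followed by whitespace; a split is made only
# when the next character is an upper-case letter or a digit, which keeps
# abbreviations like "e.g. the" unsplit.
_SENT_BREAK_RE = re.compile(r"[.!?]+[\"')\]]*\s+")


@dataclass(frozen=True, slots=True)
class Token:
    """A normalized token plus its character span in the original text.

    ``norm`` is the case-folded surface: only lower-case letters, or only
    digits — never a mix, never punctuation.  ``text[start:end]`` is the
    original substring the token was derived from.
    """

    norm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span ({self.start}, {self.end})")


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into lossily normalized tokens.

    Case is folded; maximal runs of letters and maximal runs of digits
    become tokens; a transition between a letter and a digit splits
    tokens; whitespace and punctuation separate tokens and are dropped.

    >>> [t.norm for t in tokenize("SRC-1")]
    ['src', '1']
    >>> [t.norm for t in tokenize("Thr164Ala")]
    ['thr', '164', 'ala']
    """
    return [
        Token(m.group().casefold(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def norm_sequence(text: str) -> tuple[str, ...]:
    """The normalized token sequence of ``text`` — the dictionary key."""
    return tuple(t.norm for t in tokenize(text))


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence segmentation.

    Returns ordered, non-overlapping ``(start, end)`` character spans that
    cover all non-whitespace text.  A boundary is placed after
    sentence-final punctuation (``.!?``, optionally followed by closing
    quotes/brackets) plus whitespace, provided the next character is an
    upper-case letter or a digit.
    """
    spans: list[tuple[int, int]] = []
    cursor = 0
    for m in _SENT_BREAK_RE.finditer(text):
        nxt = m.end()
        if nxt >= len(text):
            continue
        c = text[nxt]
        if not (c.isupper() or c.isdigit()):
            continue
        spans.append((cursor, m.end()))
        cursor = nxt
    if cursor < len(text):
        spans.append((cursor, len(text)))
    return [_trim(text, s, e) for s, e in spans if text[s:e].strip()]


def _trim(text: str, start: int, end: int) -> tuple[int, int]:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return start, end


def iter_sentence_tokens(
    text: str, sentence_mode: bool
) -> Iterator[Sequence[Token]]:
    """Token windows for matching: one per sentence, or one for the text."""
    if not sentence_mode:
        yield tokenize(text)
        return
    for start, end in split_sentences(text):
        window = [
            Token(t.norm, t.start + start, t.end + start)
            for t in tokenize(text[start:end])
        ]
        yield window
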