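"""Readers and writers for standoff-annotation interchange formats.

Supported formats: plain text (``txt``), BioC XML (``bioc_xml``), BioC
JSON (``bioc_json``) and PubAnnotation JSON (``pubanno_json``), plus the
annotation TSV dialect of the matcher.  All offsets use one
document-level, 0-based half-open coordinate system; they are never
re-based per section.

Dialect notes
-------------
* BioC: the entity type and concept identifier are carried in the
  annotation infons ``type`` and ``identifier`` (common BioC practice);
  section labels in the passage infon ``type``.  All document-level
  infons round-trip as metadata.
* PubAnnotation: each annotation becomes a denotation whose ``obj`` is
  the entity type; the concept identifier travels in an attribute with
  predicate ``identifier``.  Preferred name and resource are outside this
  format's data model and are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Sequence

from lxml import etree

from .matcher import Annotation

__all__ = ["Document", "Section", "FormatError", "read_document",
           "write_document", "FORMATS"]

FORMATS = ("txt", "bioc_xml", "bioc_json", "pubanno_json")


class FormatError(ValueError):
    """Malformed input or an annotation violating document bounds."""


@dataclass(frozen=True, slots=True)
class Section:
    """A labelled region of the document text (document coordinates)."""

    label: str
    start: int
    end: int


@dataclass(slots=True)
class Document:
    """Text with sections and standoff annotations.

    ``text`` is the full document string; sections are ordered,
    non-overlapping spans into it.  Reading a format whose passages carry
    explicit offsets preserves those offsets; any gap between passages is
    padded with spaces so annotation offsets stay valid verbatim.
    """

    doc_id: str
    text: str = ""
    sections: list[Section] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_sections(
        cls,
        doc_id: str,
        sections: Sequence[tuple[str, str, int]],
        **kwargs,
    ) -> "Document":
        """Build a document from ``(label, text, start_offset)`` triples."""
        if not sections:
            return cls(doc_id, "", [], **kwargs)
        length = max(off + len(txt) for _, txt, off in sections)
        buf = [" "] * length
        secs = []
        for label, txt, off in sorted(sections, key=lambda s: s[2]):
            buf[off : off + len(txt)] = txt
            secs.append(Section(label, off, off + len(txt)))
        return cls(doc_id, "".join(buf), secs, **kwargs)

    def validate(self) -> None:
        for a in self.annotations:
            if not (0 <= a.start < a.end <= len(self.text)):
                raise FormatError(
                    f"annotation ({a.start}, {a.end}) outside text bounds "
                    f"of document {self.doc_id!r} (length {len(self.text)})"
                )


# ---------------------------------------------------------------------------
# dispatch

def read_document(
    source: str | Path | BinaryIO, fmt: str, doc_id: str | None = None
) -> Document:
    """Parse one document from ``source`` in format ``fmt``."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format tag {fmt!r}; expected {FORMATS}")
    if isinstance(source, (str, Path)):
        path = Path(source)
        data = path.read_bytes()
        doc_id = doc_id or path.stem
    else:
        data = source.read()
        doc_id = doc_id or "document"
    if fmt == "txt":
        return _read_txt(data, doc_id)
    if fmt == "bioc_xml":
        return _read_bioc_xml(data)
    if fmt == "bioc_json":
        return _read_bioc_json(data)
    return _read_pubanno(data, doc_id)


def write_document(doc: Document, fmt: str) -> bytes:
    """Serialize ``doc`` to ``fmt``; raises on out-of-bounds annotations."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format tag {fmt!r}; expected {FORMATS}")
    doc.validate()
    if fmt == "txt":
        return doc.text.encode("utf-8")
    if fmt == "bioc_xml":
        return _write_bioc_xml(doc)
    if fmt == "bioc_json":
        return json.dumps(_bioc_dict(doc), ensure_ascii=False,
                          indent=1).encode("utf-8")
    return json.dumps(_pubanno_dict(doc), ensure_ascii=False,
                      indent=1).encode("utf-8")


# ---------------------------------------------------------------------------
# plain text

def _read_txt(data: bytes, doc_id: str) -> Document:
    text = data.decode("utf-8")
    sections = [Section("text", 0, len(text))] if text else []
    return Document(doc_id, text, sections)


# ---------------------------------------------------------------------------
# BioC (XML and JSON share one intermediate dict shape)

def _sections_or_whole(doc: Document) -> list[Section]:
    if doc.sections:
        return doc.sections
    return [Section("text", 0, len(doc.text))] if doc.text else []


def _bioc_dict(doc: Document) -> dict:
    passages = []
    aid = 0
    covered: set[int] = set()
    secs = _sections_or_whole(doc)
    for i, sec in enumerate(secs):
        anns = []
        for j, a in enumerate(doc.annotations):
            if j in covered or not (sec.start <= a.start and a.end <= sec.end):
                continue
            covered.add(j)
            aid += 1
            infons = {"type": a.entity_type}
            if a.concept_id is not None:
                infons["identifier"] = a.concept_id
            if a.preferred_name:
                infons["preferred_name"] = a.preferred_name
            if a.resource:
                infons["resource"] = a.resource
            anns.append(
                {
                    "id": f"A{aid}",
                    "infons": infons,
                    "text": a.surface or doc.text[a.start : a.end],
                    "locations": [
                        {"offset": a.start, "length": a.end - a.start}
                    ],
                }
            )
        passages.append(
            {
                "infons": {"type": sec.label},
                "offset": sec.start,
                "text": doc.text[sec.start : sec.end],
                "annotations": anns,
            }
        )
    return {
        "source": "lexitag",
        "date": "",
        "key": "",
        "documents": [
            {"id": doc.doc_id, "infons": dict(doc.metadata),
             "passages": passages}
        ],
    }


def _doc_from_bioc_dict(d: dict) -> Document:
    try:
        bdoc = d["documents"][0]
    except (KeyError, IndexError) as exc:
        raise FormatError("BioC collection contains no document") from exc
    sections = []
    annotations = []
    for passage in bdoc.get("passages", []):
        offset = int(passage.get("offset", 0))
        text = passage.get("text", "") or ""
        label = (passage.get("infons") or {}).get("type", "")
        sections.append((label, text, offset))
        for ann in passage.get("annotations", []):
            infons = ann.get("infons") or {}
            locs = ann.get("locations") or []
            if not locs:
                continue
            start = int(locs[0]["offset"])
            end = start + int(locs[0]["length"])
            annotations.append(
                Annotation(
                    start=start,
                    end=end,
                    entity_type=infons.get("type", ""),
                    concept_id=infons.get("identifier"),
                    surface=ann.get("text", ""),
                    preferred_name=infons.get("preferred_name", ""),
                    resource=infons.get("resource", ""),
                )
            )
    doc = Document.from_sections(
        bdoc.get("id", "document"),
        sections,
        metadata={str(k): str(v) for k, v in (bdoc.get("infons") or {}).items()},
    )
    doc.annotations = sorted(annotations, key=Annotation.sort_key)
    doc.validate()
    return doc


def _read_bioc_json(data: bytes) -> Document:
    try:
        d = json.loads(data.decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed BioC JSON: {exc}") from exc
    return _doc_from_bioc_dict(d)


def _write_bioc_xml(doc: Document) -> bytes:
    d = _bioc_dict(doc)
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = d["source"]
    etree.SubElement(root, "date").text = d["date"]
    etree.SubElement(root, "key").text = d["key"]
    bdoc = d["documents"][0]
    xdoc = etree.SubElement(root, "document")
    etree.SubElement(xdoc, "id").text = bdoc["id"]
    for k, v in bdoc["infons"].items():
        inf = etree.SubElement(xdoc, "infon", key=k)
        inf.text = v
    for passage in bdoc["passages"]:
        xp = etree.SubElement(xdoc, "passage")
        for k, v in passage["infons"].items():
            inf = etree.SubElement(xp, "infon", key=k)
            inf.text = v
        etree.SubElement(xp, "offset").text = str(passage["offset"])
        etree.SubElement(xp, "text").text = passage["text"]
        for ann in passage["annotations"]:
            xa = etree.SubElement(xp, "annotation", id=ann["id"])
            for k, v in ann["infons"].items():
                inf = etree.SubElement(xa, "infon", key=k)
                inf.text = v
            loc = ann["locations"][0]
            etree.SubElement(
                xa,
                "location",
                offset=str(loc["offset"]),
                length=str(loc["length"]),
            )
            etree.SubElement(xa, "text").text = ann["text"]
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _read_bioc_xml(data: bytes) -> Document:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed BioC XML: {exc}") from exc
    xdoc = root.find("document")
    if xdoc is None:
        raise FormatError("BioC collection contains no document")
    passages = []
    for xp in xdoc.findall("passage"):
        anns = []
        for xa in xp.findall("annotation"):
            loc = xa.find("location")
            anns.append(
                {
                    "id": xa.get("id", ""),
                    "infons": {
                        inf.get("key"): inf.text or ""
                        for inf in xa.findall("infon")
                    },
                    "text": (xa.findtext("text") or ""),
                    "locations": [
                        {
                            "offset": int(loc.get("offset")),
                            "length": int(loc.get("length")),
                        }
                    ]
                    if loc is not None
                    else [],
                }
            )
        passages.append(
            {
                "infons": {
                    inf.get("key"): inf.text or ""
                    for inf in xp.findall("infon")
                },
                "offset": int(xp.findtext("offset") or 0),
                "text": xp.findtext("text") or "",
                "annotations": anns,
            }
        )
    d = {
        "documents": [
            {
                "id": xdoc.findtext("id") or "document",
                "infons": {
                    inf.get("key"): inf.text or ""
                    for inf in xdoc.findall("infon")
                },
                "passages": passages,
            }
        ]
    }
    return _doc_from_bioc_dict(d)


# ---------------------------------------------------------------------------
# PubAnnotation

def _pubanno_dict(doc: Document) -> dict:
    denotations = []
    attributes = []
    for i, a in enumerate(doc.annotations, start=1):
        denotations.append(
            {
                "id": f"T{i}",
                "span": {"begin": a.start, "end": a.end},
                "obj": a.entity_type,
            }
        )
        if a.concept_id is not None:
            attributes.append(
                {
                    "id": f"A{i}",
                    "subj": f"T{i}",
                    "pred": "identifier",
                    "obj": a.concept_id,
                }
            )
    out = {
        "sourcedb": doc.metadata.get("sourcedb", "lexitag"),
        "sourceid": doc.doc_id,
        "text": doc.text,
        "denotations": denotations,
    }
    if attributes:
        out["attributes"] = attributes
    return out


def _read_pubanno(data: bytes, doc_id: str) -> Document:
    try:
        d = json.loads(data.decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed PubAnnotation JSON: {exc}") from exc
    text = d.get("text", "")
    ids_to_concept = {
        attr.get("subj"): attr.get("obj")
        for attr in d.get("attributes", [])
        if attr.get("pred") == "identifier"
    }
    annotations = []
    for den in d.get("denotations", []):
        span = den.get("span") or {}
        start, end = int(span.get("begin")), int(span.get("end"))
        annotations.append(
            Annotation(
                start=start,
                end=end,
                entity_type=den.get("obj", ""),
                concept_id=ids_to_concept.get(den.get("id")),
                surface=text[start:end],
            )
        )
    doc = Document(
        str(d.get("sourceid") or doc_id),
        text,
        [Section("text", 0, len(text))] if text else [],
        sorted(annotations, key=Annotation.sort_key),
    )
    doc.validate()
    return doc
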