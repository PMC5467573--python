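"""Annotated-corpus model and XML I/O.

Corpora are exchanged in the unified PPI/DDI XML dialect: ``<corpus>`` (or a
bare ``<document>``) containing ``<document>`` elements, each with
``<sentence>`` children carrying ``<entity>`` mentions (character-offset
spans) and ``<pair>`` candidate relations with ``ddi``/``type`` attributes.

Character offsets are 0-based inclusive ranges ``start-end``; a discontinuous
mention lists several ranges separated by ``;``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from lxml import etree

PROVENANCES = ("drugbank", "medline", "synthetic")


class ClassLabel(enum.Enum):
    """The five relation classes; the value<->index bijection is fixed.

    ``OTHER`` marks a non-interacting candidate pair; the four remaining
    classes are the positive DDI types of the shared task.
    """

    ADVICE = "advice"
    EFFECT = "effect"
    INT = "int"
    MECHANISM = "mechanism"
    OTHER = "other"

    @property
    def index(self) -> int:
        return _LABEL_ORDER.index(self)

    @classmethod
    def from_index(cls, i: int) -> "ClassLabel":
        return _LABEL_ORDER[i]

    @classmethod
    def from_string(cls, s: str) -> "ClassLabel":
        try:
            return cls(s.lower())
        except ValueError:
            raise ValueError(f"unknown DDI class label: {s!r}") from None


_LABEL_ORDER = (
    ClassLabel.ADVICE,
    ClassLabel.EFFECT,
    ClassLabel.INT,
    ClassLabel.MECHANISM,
    ClassLabel.OTHER,
)

POSITIVE_LABELS = _LABEL_ORDER[:4]
N_CLASSES = len(_LABEL_ORDER)


@dataclass
class EntityMention:
    """A drug mention with one or more (start, end) inclusive char ranges."""

    id: str
    text: str
    spans: list[tuple[int, int]]
    type: str = "drug"

    @property
    def discontinuous(self) -> bool:
        return len(self.spans) > 1

    @property
    def start(self) -> int:
        return self.spans[0][0]

    def validate(self, sentence_text: str) -> None:
        if not self.spans:
            raise ValueError(f"entity {self.id}: empty span list")
        for s, e in self.spans:
            if s > e:
                raise ValueError(f"entity {self.id}: span start {s} > end {e}")
            if e >= len(sentence_text):
                raise ValueError(
                    f"entity {self.id}: span ({s},{e}) outside sentence of "
                    f"length {len(sentence_text)}"
                )


@dataclass
class CandidatePair:
    """One candidate relation instance: an ordered pair of mentions."""

    id: str
    e1: EntityMention
    e2: EntityMention
    label: ClassLabel


@dataclass
class Sentence:
    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    pairs: list[CandidatePair] = field(default_factory=list)

    def validate(self) -> None:
        ids = [e.id for e in self.entities]
        if len(ids) != len(set(ids)):
            raise ValueError(f"sentence {self.id}: duplicate entity ids")
        for e in self.entities:
            e.validate(self.text)
        known = set(ids)
        for p in self.pairs:
            if p.e1.id not in known or p.e2.id not in known:
                raise ValueError(
                    f"sentence {self.id}: pair {p.id} references an entity "
                    f"not present in the sentence"
                )


@dataclass
class Document:
    id: str
    provenance: str
    sentences: list[Sentence] = field(default_factory=list)

    def validate(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"document {self.id}: provenance {self.provenance!r} not in "
                f"{PROVENANCES}"
            )
        for s in self.sentences:
            s.validate()


def _parse_char_offset(offset: str, entity_id: str) -> list[tuple[int, int]]:
    spans = []
    for part in offset.split(";"):
        try:
            s, e = part.split("-")
            spans.append((int(s), int(e)))
        except ValueError:
            raise ValueError(
                f"entity {entity_id}: malformed charOffset {offset!r}"
            ) from None
    return spans


def _infer_provenance(elem, path: Union[str, Path, None], default: str | None) -> str:
    origin = elem.get("origin")
    if origin is not None:
        return origin.lower()
    if path is not None:
        parts = [p.lower() for p in Path(path).parts]
        for name in ("drugbank", "medline"):
            if any(name in p for p in parts):
                return name
    if default is not None:
        return default
    raise ValueError(
        f"document {elem.get('id')!r}: provenance cannot be determined "
        f"(no origin attribute, no drugbank/medline path component, no default)"
    )


def _parse_document(delem, path, default_provenance) -> Document:
    doc = Document(
        id=delem.get("id", ""),
        provenance=_infer_provenance(delem, path, default_provenance),
    )
    for selem in delem.findall("sentence"):
        sent = Sentence(id=selem.get("id", ""), text=selem.get("text", ""))
        by_id: dict[str, EntityMention] = {}
        for eelem in selem.findall("entity"):
            ent = EntityMention(
                id=eelem.get("id", ""),
                text=eelem.get("text", ""),
                spans=_parse_char_offset(eelem.get("charOffset", ""), eelem.get("id", "")),
                type=eelem.get("type", "drug"),
            )
            sent.entities.append(ent)
            by_id[ent.id] = ent
        for pelem in selem.findall("pair"):
            pid = pelem.get("id", "")
            e1_id, e2_id = pelem.get("e1"), pelem.get("e2")
            if e1_id not in by_id or e2_id not in by_id:
                raise ValueError(
                    f"pair {pid}: references missing entity "
                    f"({e1_id!r}, {e2_id!r}) in sentence {sent.id}"
                )
            ddi = (pelem.get("ddi") or "false").lower()
            if ddi == "false":
                label = ClassLabel.OTHER
            elif ddi == "true":
                type_attr = pelem.get("type")
                if type_attr is None:
                    raise ValueError(f"pair {pid}: ddi='true' but no type attribute")
                label = ClassLabel.from_string(type_attr)
                if label is ClassLabel.OTHER:
                    raise ValueError(f"pair {pid}: ddi='true' with type 'other'")
            else:
                raise ValueError(f"pair {pid}: ddi attribute must be true/false, got {ddi!r}")
            e1, e2 = by_id[e1_id], by_id[e2_id]
            # normalize so e1 is the leftmost mention
            if e2.start < e1.start:
                e1, e2 = e2, e1
            sent.pairs.append(CandidatePair(id=pid, e1=e1, e2=e2, label=label))
        doc.sentences.append(sent)
    return doc


def read_corpus(
    path: Union[str, Path],
    default_provenance: str | None = None,
) -> list[Document]:
    """Read a corpus file; returns one :class:`Document` per document element.

    Provenance is taken from the document's ``origin`` attribute, or inferred
    from a ``drugbank``/``medline`` path component, or ``default_provenance``.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed corpus XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag == "document":
        delems = [root]
    else:
        delems = root.findall("document")
    docs = [_parse_document(d, path, default_provenance) for d in delems]
    for d in docs:
        d.validate()
    return docs


def corpus_to_xml(docs: Sequence[Document]) -> etree._Element:
    root = etree.Element("corpus")
    for doc in docs:
        delem = etree.SubElement(root, "document", id=doc.id, origin=doc.provenance)
        for sent in doc.sentences:
            selem = etree.SubElement(delem, "sentence", id=sent.id, text=sent.text)
            for ent in sent.entities:
                etree.SubElement(
                    selem,
                    "entity",
                    id=ent.id,
                    charOffset=";".join(f"{s}-{e}" for s, e in ent.spans),
                    type=ent.type,
                    text=ent.text,
                )
            for pair in sent.pairs:
                attrs = {
                    "id": pair.id,
                    "e1": pair.e1.id,
                    "e2": pair.e2.id,
                    "ddi": "false" if pair.label is ClassLabel.OTHER else "true",
                }
                if pair.label is not ClassLabel.OTHER:
                    attrs["type"] = pair.label.value
                etree.SubElement(selem, "pair", **attrs)
    return root


def write_corpus(docs: Sequence[Document], path: Union[str, Path]) -> Path:
    """Write documents to ``path``; the output round-trips through read_corpus.

    Raises ``ValueError`` if any type invariant is violated (the violated
    invariant is named in the message); nothing is written in that case.
    """
    for d in docs:
        d.validate()
    root = corpus_to_xml(docs)
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return Path(path)


def iter_pairs(docs: Iterable[Document]):
    """Yield (document, sentence, pair) triples over a corpus."""
    for doc in docs:
        for sent in doc.sentences:
            for pair in sent.pairs:
                yield doc, sent, pair


def class_distribution(docs: Iterable[Document]) -> dict[str, dict[str, int]]:
    """Per-provenance and total counts of each relation class."""
    table: dict[str, dict[str, int]] = {}
    for doc, _, pair in iter_pairs(docs):
        row = table.setdefault(doc.provenance, {l.value: 0 for l in ClassLabel})
        row[pair.label.value] += 1
    total = {l.value: 0 for l in ClassLabel}
    for row in table.values():
        for k, v in row.items():
            total[k] += v
    table["total"] = total
    return table
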