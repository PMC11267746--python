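"""Domain types: documents, entity spans, annotated documents, corpora.

Offsets are 0-based half-open character intervals over Unicode code points.
A span caches its surface string; validation re-slices the text and compares,
so a stale or shifted annotation is always caught at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from .labels import (
    CLINICAL_LABELS,
    LABEL_LAYER,
    LAYER_CLINICAL,
    LAYER_PII,
    PII_LABELS,
    SUBCORPORA,
)


class ValidationError(ValueError):
    """An annotation violates a structural invariant."""


@dataclass(frozen=True)
class TextDocument:
    doc_id: str
    text: str
    subcorpus: str = "accident"

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be non-empty")
        if len(self.text) < 1:
            raise ValidationError(f"{self.doc_id}: text must be non-empty")
        if self.subcorpus not in SUBCORPORA:
            raise ValidationError(
                f"{self.doc_id}: subcorpus {self.subcorpus!r} not in {SUBCORPORA}"
            )


@dataclass(frozen=True, order=True)
class EntitySpan:
    start: int
    end: int
    label: str
    layer: str
    surface: str

    @classmethod
    def from_text(cls, text: str, start: int, end: int, label: str) -> "EntitySpan":
        """Build a span over ``text`` with the surface sliced and layer inferred."""
        layer = LABEL_LAYER.get(label)
        if layer is None:
            raise ValidationError(f"unknown label {label!r}")
        return cls(start=start, end=end, label=label, layer=layer,
                   surface=text[start:end])

    def validate(self, text: str, allow_unknown: bool = False) -> None:
        if not (0 <= self.start < self.end <= len(text)):
            raise ValidationError(
                f"span [{self.start},{self.end}) out of range for text of "
                f"length {len(text)}"
            )
        if text[self.start:self.end] != self.surface:
            raise ValidationError(
                f"surface mismatch at [{self.start},{self.end}): "
                f"annotation says {self.surface!r}, text has "
                f"{text[self.start:self.end]!r}"
            )
        known_layer = LABEL_LAYER.get(self.label)
        if known_layer is None:
            if not allow_unknown:
                raise ValidationError(f"unknown label {self.label!r}")
        elif known_layer != self.layer:
            raise ValidationError(
                f"label {self.label} belongs to layer {known_layer}, "
                f"span declares {self.layer}"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "EntitySpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shifted(self, delta: int, text: str) -> "EntitySpan":
        return replace(self, start=self.start + delta, end=self.end + delta,
                       surface=text[self.start + delta:self.end + delta])


def _overlapping_pairs(spans: list[EntitySpan]) -> list[tuple[EntitySpan, EntitySpan]]:
    srt = sorted(spans, key=lambda s: (s.start, s.end))
    out = []
    for a, b in zip(srt, srt[1:]):
        if a.overlaps(b):
            out.append((a, b))
    return out


def resolve_pii_overlaps(spans: Iterable[EntitySpan]) -> list[EntitySpan]:
    """Repair mode for overlapping PII spans: keep the longer span of each
    overlapping pair (ties: the earlier one)."""
    srt = sorted(spans, key=lambda s: (s.start, -(s.end - s.start)))
    kept: list[EntitySpan] = []
    for s in srt:
        if kept and kept[-1].overlaps(s):
            if (s.end - s.start) > (kept[-1].end - kept[-1].start):
                kept[-1] = s
            continue
        kept.append(s)
    return kept


@dataclass
class AnnotatedDocument:
    """A document plus its two annotation layers.

    PII spans are required to be pairwise non-overlapping (replacement is
    otherwise ill-defined); clinical spans may nest or overlap.  Cross-layer
    overlap is permitted.  Pass ``strict_pii_overlap=False`` to ``validate``
    for evaluation-only corpora (e.g. a noisy second annotator).
    """

    document: TextDocument
    pii_spans: list[EntitySpan] = field(default_factory=list)
    clinical_spans: list[EntitySpan] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.document.doc_id

    @property
    def text(self) -> str:
        return self.document.text

    def spans(self) -> Iterator[EntitySpan]:
        yield from self.pii_spans
        yield from self.clinical_spans

    def validate(self, strict_pii_overlap: bool = True,
                 allow_unknown: bool = False) -> "AnnotatedDocument":
        for span in self.spans():
            span.validate(self.text, allow_unknown=allow_unknown)
        for span in self.pii_spans:
            if span.layer != LAYER_PII:
                raise ValidationError(
                    f"{self.doc_id}: {span.label} in PII layer list but "
                    f"declares layer {span.layer}"
                )
        for span in self.clinical_spans:
            if span.layer != LAYER_CLINICAL:
                raise ValidationError(
                    f"{self.doc_id}: {span.label} in clinical layer list but "
                    f"declares layer {span.layer}"
                )
        if strict_pii_overlap:
            pairs = _overlapping_pairs(self.pii_spans)
            if pairs:
                a, b = pairs[0]
                raise ValidationError(
                    f"{self.doc_id}: overlapping PII spans "
                    f"[{a.start},{a.end}) {a.label} and [{b.start},{b.end}) {b.label}"
                )
        return self

    def sorted(self) -> "AnnotatedDocument":
        return AnnotatedDocument(
            document=self.document,
            pii_spans=sorted(self.pii_spans, key=lambda s: (s.start, s.end, s.label)),
            clinical_spans=sorted(self.clinical_spans,
                                  key=lambda s: (s.start, s.end, s.label)),
        )


@dataclass
class Corpus:
    documents: list[AnnotatedDocument] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __getitem__(self, i):
        return self.documents[i]

    def by_id(self) -> dict[str, AnnotatedDocument]:
        return {d.doc_id: d for d in self.documents}

    def validate(self, strict_pii_overlap: bool = True) -> "Corpus":
        for doc in self.documents:
            doc.validate(strict_pii_overlap=strict_pii_overlap)
        return self


__all__ = [
    "ValidationError",
    "TextDocument",
    "EntitySpan",
    "AnnotatedDocument",
    "Corpus",
    "resolve_pii_overlaps",
    "PII_LABELS",
    "CLINICAL_LABELS",
]
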