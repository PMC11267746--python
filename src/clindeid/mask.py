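"""Masking: replace each PII span by its bracketed class-name placeholder.

The same replacement engine drives pseudonymization (the only difference is
what string goes in).  Replacement rebuilds the text from untouched pieces
and replacement strings in one left-to-right pass over the spans sorted by
offset — a single edit script, so no offset ever moves under a later edit —
and returns an :class:`~clindeid.offsets.OffsetMap` for remapping.

Clinical spans that overlap a PII span are handled by policy: a span strictly
inside a replaced region is dropped (default) or raises; a partial overlap is
clipped to its longest contiguous non-PII residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import AnnotatedDocument, EntitySpan, TextDocument, ValidationError
from .labels import DEFAULT_PLACEHOLDERS
from .offsets import OffsetMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplacementRecord:
    """Audit trail of one substitution."""
    doc_id: str
    label: str
    start: int
    end: int
    surface: str
    surrogate: str
    rule: str
    draws: int = 0


@dataclass
class MaskedDocument:
    document: TextDocument
    pii_spans: list[EntitySpan]
    clinical_spans: list[EntitySpan]
    offset_map: OffsetMap
    replacement_records: list[ReplacementRecord]
    warnings: list[str] = field(default_factory=list)

    @property
    def doc_id(self) -> str:
        return self.document.doc_id

    @property
    def text(self) -> str:
        return self.document.text

    def to_annotated(self) -> AnnotatedDocument:
        return AnnotatedDocument(document=self.document,
                                 pii_spans=list(self.pii_spans),
                                 clinical_spans=list(self.clinical_spans))


def _residue_pieces(span: EntitySpan,
                    pii: list[EntitySpan]) -> list[tuple[int, int]]:
    """Sub-intervals of ``span`` not covered by any PII interval."""
    pieces = [(span.start, span.end)]
    for p in pii:
        nxt = []
        for s, e in pieces:
            if p.end <= s or e <= p.start:
                nxt.append((s, e))
                continue
            if s < p.start:
                nxt.append((s, p.start))
            if p.end < e:
                nxt.append((p.end, e))
        pieces = nxt
    return pieces


def apply_replacements(doc: AnnotatedDocument,
                       replacements: list[tuple[EntitySpan, str]],
                       records: list[ReplacementRecord],
                       *,
                       on_contained: str = "drop") -> MaskedDocument:
    """Replace each PII span by the paired string; remap everything else.

    ``replacements`` must cover exactly the document's PII spans.
    ``on_contained`` governs clinical spans strictly inside a PII span:
    ``"drop"`` (with a warning) or ``"error"``.
    """
    if on_contained not in ("drop", "error"):
        raise ValueError(f"on_contained must be drop|error, got {on_contained!r}")
    ordered = sorted(replacements, key=lambda r: (r[0].start, r[0].end))
    for (a, _), (b, _) in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValidationError(
                f"{doc.doc_id}: overlapping PII spans "
                f"[{a.start},{a.end}) and [{b.start},{b.end})"
            )
    text = doc.text
    pieces: list[str] = []
    pos = 0
    for span, new in ordered:
        pieces.append(text[pos:span.start])
        pieces.append(new)
        pos = span.end
    pieces.append(text[pos:])
    new_text = "".join(pieces)

    omap = OffsetMap.from_replacements(
        len(text), [(s.start, s.end, len(new)) for s, new in ordered])

    new_pii = [
        EntitySpan(start=omap.map(s.start), end=omap.map(s.start) + len(new),
                   label=s.label, layer=s.layer, surface=new)
        for s, new in ordered
    ]

    pii_sorted = [s for s, _ in ordered]
    warnings: list[str] = []
    new_clinical: list[EntitySpan] = []
    for span in doc.clinical_spans:
        overlapping = [p for p in pii_sorted if p.overlaps(span)]
        if not overlapping:
            a, b = omap.map(span.start), omap.map(span.end)
            new_clinical.append(EntitySpan(start=a, end=b, label=span.label,
                                           layer=span.layer,
                                           surface=new_text[a:b]))
            continue
        pieces_ = _residue_pieces(span, overlapping)
        if not pieces_:
            msg = (f"{doc.doc_id}: clinical span {span.label} "
                   f"[{span.start},{span.end}) inside a PII span")
            if on_contained == "error":
                raise ValidationError(msg)
            warnings.append(msg + " — dropped")
            logger.warning("%s", warnings[-1])
            continue
        # keep the longest contiguous residue (ties: earliest)
        s0, e0 = max(pieces_, key=lambda p: (p[1] - p[0], -p[0]))
        a, b = omap.map(s0), omap.map(e0)
        clipped = EntitySpan(start=a, end=b, label=span.label, layer=span.layer,
                             surface=new_text[a:b])
        warnings.append(
            f"{doc.doc_id}: clinical span {span.label} [{span.start},{span.end}) "
            f"clipped to [{s0},{e0}) around PII"
        )
        logger.warning("%s", warnings[-1])
        new_clinical.append(clipped)

    return MaskedDocument(
        document=TextDocument(doc_id=doc.doc_id, text=new_text,
                              subcorpus=doc.document.subcorpus),
        pii_spans=new_pii,
        clinical_spans=new_clinical,
        offset_map=omap,
        replacement_records=records,
        warnings=warnings,
    )


def mask_document(doc: AnnotatedDocument,
                  placeholder_style: dict[str, str] | None = None,
                  *,
                  on_contained: str = "drop") -> MaskedDocument:
    """Mask every PII span with its class placeholder, e.g. ``[Last Name]``."""
    style = dict(DEFAULT_PLACEHOLDERS)
    if placeholder_style:
        style.update(placeholder_style)
    replacements = []
    records = []
    for span in doc.pii_spans:
        try:
            placeholder = style[span.label]
        except KeyError:
            raise ValidationError(
                f"{doc.doc_id}: no placeholder configured for {span.label}")
        replacements.append((span, placeholder))
        records.append(ReplacementRecord(
            doc_id=doc.doc_id, label=span.label, start=span.start, end=span.end,
            surface=span.surface, surrogate=placeholder, rule="mask"))
    return apply_replacements(doc, replacements, records,
                              on_contained=on_contained)


def mask_corpus(corpus, placeholder_style=None, *, on_contained: str = "drop"):
    """Mask every document; returns (Corpus, records, warnings)."""
    from .corpus import Corpus
    docs, records, warns = [], [], []
    for doc in corpus:
        masked = mask_document(doc, placeholder_style, on_contained=on_contained)
        docs.append(masked.to_annotated())
        records.extend(masked.replacement_records)
        warns.extend(masked.warnings)
    return Corpus(documents=docs), records, warns


def write_audit(records: list[ReplacementRecord], path) -> None:
    """Tab-separated audit file: doc_id, class, offsets, surface, surrogate."""
    from pathlib import Path
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tclass\tstart\tend\tsurface\tsurrogate\trule\tdraws\n")
        for r in records:
            fh.write(f"{r.doc_id}\t{r.label}\t{r.start}\t{r.end}\t"
                     f"{r.surface}\t{r.surrogate}\t{r.rule}\t{r.draws}\n")
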