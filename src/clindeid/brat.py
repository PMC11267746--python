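"""BRAT standoff reader/writer (.txt + .ann, entity T-lines only).

T-line syntax::

    T1<TAB>Disease 25 31<TAB>cancer

Offsets are 0-based half-open over code points, matching the convention of
the rest of the toolkit.  Discontinuous annotations (``25 31;40 44``) are
rejected: neither layer of this corpus uses them and silently merging
fragments would corrupt offsets.
"""

from __future__ import annotations

import os
from pathlib import Path

from .corpus import AnnotatedDocument, EntitySpan, TextDocument, ValidationError
from .labels import LABEL_LAYER, LAYER_CLINICAL, LAYER_PII


def read_brat(
    text_file: str | os.PathLike,
    ann_file: str | os.PathLike,
    layer_map: dict[str, str] | None = None,
    *,
    subcorpus: str = "accident",
    allow_unknown: bool = False,
) -> AnnotatedDocument:
    """Load one annotated document from a BRAT ``.txt``/``.ann`` pair.

    ``layer_map`` assigns labels to layers; it defaults to the built-in
    label inventory.  Unknown labels raise unless ``allow_unknown`` is set,
    in which case they are placed in the PII layer map only if the caller's
    ``layer_map`` says so, otherwise rejected (a layerless span cannot be
    stored).
    """
    text_file, ann_file = Path(text_file), Path(ann_file)
    text = text_file.read_text(encoding="utf-8")
    doc = TextDocument(doc_id=text_file.stem, text=text)
    layers = dict(LABEL_LAYER)
    if layer_map:
        layers.update(layer_map)

    pii: list[EntitySpan] = []
    clinical: list[EntitySpan] = []
    for lineno, raw in enumerate(ann_file.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        if not raw.startswith("T"):
            raise ValidationError(
                f"{ann_file.name}:{lineno}: only entity (T) annotations are "
                f"supported, got {raw.split(chr(9))[0]!r}"
            )
        try:
            tid, meta, quoted = raw.split("\t")
            label, start_s, end_s = meta.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError:
            if ";" in raw.split("\t")[1]:
                raise ValidationError(
                    f"{ann_file.name}:{lineno}: discontinuous annotation "
                    f"{raw.split(chr(9))[0]} is not supported"
                ) from None
            raise ValidationError(
                f"{ann_file.name}:{lineno}: malformed T-line {raw!r}"
            ) from None
        if not (0 <= start < end <= len(text)):
            raise ValidationError(
                f"{ann_file.name}: {tid} offsets [{start},{end}) out of range "
                f"for text of length {len(text)}"
            )
        sliced = text[start:end]
        if sliced != quoted:
            raise ValidationError(
                f"{ann_file.name}: {tid} quoted surface {quoted!r} does not "
                f"match text slice {sliced!r}"
            )
        layer = layers.get(label)
        if layer is None:
            if allow_unknown:
                continue
            raise ValidationError(f"{ann_file.name}: {tid} unknown label {label!r}")
        span = EntitySpan(start=start, end=end, label=label, layer=layer,
                          surface=sliced)
        (pii if layer == LAYER_PII else clinical).append(span)

    return AnnotatedDocument(document=doc, pii_spans=pii,
                             clinical_spans=clinical).validate(
        allow_unknown=allow_unknown)


def write_brat(doc: AnnotatedDocument, out_dir: str | os.PathLike,
               *, overwrite: bool = False) -> tuple[Path, Path]:
    """Write ``doc`` as a ``.txt``/``.ann`` pair named after its doc_id.

    Spans are emitted sorted by (start, end, label) with ids T1..Tn, so
    writing is canonical: read→write→read is the identity and write→read→
    write is byte-stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt_path = out_dir / f"{doc.doc_id}.txt"
    ann_path = out_dir / f"{doc.doc_id}.ann"
    if not overwrite and (txt_path.exists() or ann_path.exists()):
        raise FileExistsError(f"refusing to overwrite {txt_path} / {ann_path}")
    txt_path.write_text(doc.text, encoding="utf-8")
    lines = []
    ordered = sorted(doc.spans(), key=lambda s: (s.start, s.end, s.label))
    for i, span in enumerate(ordered, 1):
        lines.append(f"T{i}\t{span.label} {span.start} {span.end}\t{span.surface}")
    ann_path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return txt_path, ann_path
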