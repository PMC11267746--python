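"""JSON-lines corpus interchange.

One document per line::

    {"doc_id": "...", "text": "...", "subcorpus": "accident",
     "pii": [[start, end, "Label"], ...], "clinical": [[start, end, "Label"], ...]}

Surfaces are not serialized (they are recomputed and re-validated on read),
which keeps the format minimal and makes tampered offsets detectable.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

from .corpus import AnnotatedDocument, Corpus, EntitySpan, TextDocument, ValidationError


def _doc_to_obj(doc: AnnotatedDocument) -> dict:
    doc = doc.sorted()
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "subcorpus": doc.document.subcorpus,
        "pii": [[s.start, s.end, s.label] for s in doc.pii_spans],
        "clinical": [[s.start, s.end, s.label] for s in doc.clinical_spans],
    }


def _doc_from_obj(obj: dict, *, strict_pii_overlap: bool = True) -> AnnotatedDocument:
    document = TextDocument(
        doc_id=obj["doc_id"], text=obj["text"],
        subcorpus=obj.get("subcorpus", "accident"),
    )
    text = document.text
    pii = [EntitySpan.from_text(text, int(s), int(e), str(lab))
           for s, e, lab in obj.get("pii", [])]
    clinical = [EntitySpan.from_text(text, int(s), int(e), str(lab))
                for s, e, lab in obj.get("clinical", [])]
    return AnnotatedDocument(document=document, pii_spans=pii,
                             clinical_spans=clinical).validate(
        strict_pii_overlap=strict_pii_overlap)


def read_jsonl(path: str | os.PathLike, *,
               strict_pii_overlap: bool = True) -> Corpus:
    docs: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed JSON ({exc})")
            try:
                docs.append(_doc_from_obj(obj, strict_pii_overlap=strict_pii_overlap))
            except (KeyError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return Corpus(documents=docs)


def write_jsonl(corpus: Corpus, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(_doc_to_obj(doc), ensure_ascii=False) + "\n")
    return path
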