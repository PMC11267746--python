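"""CoNLL BIO export, one entity class per file.

Flat BIO cannot encode nesting, so export is per class: spans of the chosen
class are reduced to maximal (outermost) intervals, tokens intersecting a
span get B-/I- tags, everything else O.  A span that ends or starts inside
a token extends its tag to the whole token.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

from .corpus import AnnotatedDocument, Corpus, EntitySpan
from .tokenize import Tokenizer, tokenize

logger = logging.getLogger(__name__)


def outermost_spans(spans: list[EntitySpan]) -> list[EntitySpan]:
    """Drop spans strictly contained in another span of the same list."""
    kept: list[EntitySpan] = []
    for s in spans:
        contained = any(o is not s and o.contains(s) and
                        (o.start, o.end) != (s.start, s.end) for o in spans)
        if not contained:
            kept.append(s)
    # identical duplicates collapse to one
    seen = set()
    uniq = []
    for s in sorted(kept, key=lambda x: (x.start, x.end)):
        if (s.start, s.end) not in seen:
            seen.add((s.start, s.end))
            uniq.append(s)
    return uniq


def document_bio(doc: AnnotatedDocument, label: str,
                 tokenizer: Tokenizer = tokenize) -> list[tuple[str, str]]:
    """(token, tag) pairs for one document and one entity class."""
    spans = [s for s in doc.spans() if s.label == label]
    maximal = outermost_spans(spans)
    if len(maximal) < len(spans):
        logger.warning("%s: %d nested %s span(s) collapsed to outermost",
                       doc.doc_id, len(spans) - len(maximal), label)
    tokens = tokenizer(doc.text)
    tags = ["O"] * len(tokens)
    for span in maximal:
        inside = [i for i, t in enumerate(tokens)
                  if t.start < span.end and span.start < t.end]
        for j, i in enumerate(inside):
            tags[i] = ("B-" if j == 0 else "I-") + label
    return [(t.surface, tag) for t, tag in zip(tokens, tags)]


def export_conll_bio(corpus: Corpus, label: str, path: str | os.PathLike,
                     tokenizer: Tokenizer = tokenize) -> Path:
    """Write two-column (token tag) CoNLL with blank lines between documents."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    blocks = []
    for doc in corpus:
        rows = document_bio(doc, label, tokenizer)
        blocks.append("".join(f"{tok} {tag}\n" for tok, tag in rows))
    path.write_text("\n".join(blocks), encoding="utf-8")
    return path
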