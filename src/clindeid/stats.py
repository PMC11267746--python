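"""Descriptive corpus statistics and per-class frequency tables.

Vocabulary is computed on case-folded token surfaces; mean ± sd summaries
use the population (n) denominator.  Annotated-token counts treat each
token once even when spans nest over it.  The tokenizer (word runs +
punctuation singletons) is a toolkit choice: absolute token and vocabulary
counts are tokenizer-dependent and therefore comparable only between
corpora processed with this same tokenizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .corpus import Corpus, ValidationError
from .labels import CLINICAL_LABELS, PII_LABELS
from .tokenize import Tokenizer, tokenize


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


@dataclass
class CorpusStatistics:
    documents: int
    tokens: int
    vocabulary: int
    lexical_diversity: float            # percent, 100·V/N
    tokens_per_doc: tuple[float, float]  # mean, population sd
    entities_per_doc: tuple[float, float]
    annotated_tokens: int
    pii_entities: int
    medical_entities: int
    per_class_frequency: dict[str, int] = field(default_factory=dict)
    tokens_per_entity: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            ("Documents", self.documents),
            ("Tokens", self.tokens),
            ("Vocabulary", self.vocabulary),
            ("Lexical diversity (%)", round(self.lexical_diversity, 1)),
            ("Tok. per doc. (mean)", round(self.tokens_per_doc[0], 1)),
            ("Tok. per doc. (sd)", round(self.tokens_per_doc[1], 1)),
            ("Ent. per doc. (mean)", round(self.entities_per_doc[0], 1)),
            ("Ent. per doc. (sd)", round(self.entities_per_doc[1], 1)),
            ("Annotated tokens", self.annotated_tokens),
            ("PII entities", self.pii_entities),
            ("Medical entities", self.medical_entities),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def compute_statistics(corpus: Corpus,
                       tokenizer: Tokenizer = tokenize) -> CorpusStatistics:
    if len(corpus) == 0:
        raise ValidationError("cannot compute statistics of an empty corpus")
    vocab: set[str] = set()
    n_tokens = 0
    tokens_per_doc: list[int] = []
    entities_per_doc: list[int] = []
    annotated = 0
    per_class: dict[str, int] = {lab: 0 for lab in (*PII_LABELS,
                                                    *CLINICAL_LABELS)}
    tok_per_ent: dict[str, list[int]] = {}
    for doc in corpus:
        toks = tokenizer(doc.text)
        n_tokens += len(toks)
        tokens_per_doc.append(len(toks))
        vocab.update(t.surface.casefold() for t in toks)
        spans = list(doc.spans())
        entities_per_doc.append(len(spans))
        annotated += sum(
            1 for t in toks
            if any(s.start < t.end and t.start < s.end for s in spans))
        for s in spans:
            per_class[s.label] = per_class.get(s.label, 0) + 1
            n_in = sum(1 for t in toks if s.start < t.end and t.start < s.end)
            tok_per_ent.setdefault(s.label, []).append(n_in)

    summaries = {}
    for label, counts in tok_per_ent.items():
        mean, sd = _mean_sd([float(c) for c in counts])
        summaries[label] = {"mean": mean, "sd": sd,
                            "min": float(min(counts)),
                            "max": float(max(counts))}
    return CorpusStatistics(
        documents=len(corpus),
        tokens=n_tokens,
        vocabulary=len(vocab),
        lexical_diversity=100.0 * len(vocab) / n_tokens,
        tokens_per_doc=_mean_sd([float(x) for x in tokens_per_doc]),
        entities_per_doc=_mean_sd([float(x) for x in entities_per_doc]),
        annotated_tokens=annotated,
        pii_entities=sum(per_class[lab] for lab in PII_LABELS),
        medical_entities=sum(per_class[lab] for lab in CLINICAL_LABELS),
        per_class_frequency=per_class,
        tokens_per_entity=summaries,
    )


def frequency_table(corpus: Corpus) -> pd.DataFrame:
    """One row per entity class with its annotation count, plus layer
    subtotal rows ("PII total", "Clinical total")."""
    counts: dict[str, int] = {lab: 0 for lab in (*PII_LABELS, *CLINICAL_LABELS)}
    for doc in corpus:
        for s in doc.spans():
            counts[s.label] = counts.get(s.label, 0) + 1
    rows = [{"class": lab, "layer": "pii", "frequency": counts[lab]}
            for lab in PII_LABELS]
    rows += [{"class": lab, "layer": "clinical", "frequency": counts[lab]}
             for lab in CLINICAL_LABELS]
    rows.append({"class": "PII total", "layer": "pii",
                 "frequency": sum(counts[lab] for lab in PII_LABELS)})
    rows.append({"class": "Clinical total", "layer": "clinical",
                 "frequency": sum(counts[lab] for lab in CLINICAL_LABELS)})
    return pd.DataFrame(rows)


def histogram_table(corpus: Corpus,
                    tokenizer: Tokenizer = tokenize) -> pd.DataFrame:
    """Long-format distributions: annotations per document and tokens per
    entity, by class and subcorpus (feeds frequency-distribution plots)."""
    rows = []
    for doc in corpus:
        toks = tokenizer(doc.text)
        per_class: dict[str, int] = {}
        for s in doc.spans():
            per_class[s.label] = per_class.get(s.label, 0) + 1
            n_in = sum(1 for t in toks if s.start < t.end and t.start < s.end)
            rows.append({"doc_id": doc.doc_id,
                         "subcorpus": doc.document.subcorpus,
                         "class": s.label, "measure": "tokens_per_entity",
                         "value": n_in})
        for label, n in per_class.items():
            rows.append({"doc_id": doc.doc_id,
                         "subcorpus": doc.document.subcorpus,
                         "class": label, "measure": "entities_per_doc",
                         "value": n})
    return pd.DataFrame(rows)
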