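"""Published reference statistics of the ACHS occupational-health corpus.

The toolkit was designed around a corpus of 1,787 Spanish anamneses of
work-related accidents and diseases (Zenodo record 10.5281/zenodo.10447555,
available on request), annotated with 13 PII classes and 3 clinical entity
classes.  The constants here are the corpus's published summary figures;
:func:`consistency_report` recomputes the derivable quantities from them,
and :func:`corpus_census` produces the same census from any loaded corpus
so the counts can be re-verified if the restricted data are obtained.

Raw token and vocabulary counts depend on the (unpublished) tokenizer that
produced them and are kept here only as context, not as quantities this
toolkit's tokenizer is expected to reproduce.
"""

from __future__ import annotations

from .corpus import Corpus
from .labels import CLINICAL_LABELS, PII_LABELS

CORPUS_REFERENCE = {
    "documents": 1787,
    "accident_documents": 1614,
    "disease_documents": 173,
    "tokens": 221_854,
    "vocabulary": 20_779,
    "lexical_diversity_pct": 9.4,
    "tokens_per_doc_mean": 124,
    "tokens_per_doc_sd": 93,
    "entities_per_doc_mean": 8.6,
    "entities_per_doc_sd": 5.7,
    "annotated_tokens": 27_036,
    "pii_entities": 5460,
    "medical_entities": 10_019,
}

PII_CLASS_FREQUENCIES = {
    "Occupation": 1960,
    "FullDate": 1105,
    "DatePart": 859,
    "HealthCareUnit": 604,
    "Company": 317,
    "Age": 280,
    "LastName": 136,
    "Location": 108,
    "FirstName": 65,
    "ID": 13,
    "PersonalID": 8,
    "PhoneNumber": 3,
    "Email": 2,
}

CLINICAL_CLASS_FREQUENCIES = {
    "BodyPart": 5061,
    "Disease": 3026,
    "Medication": 1932,
}


def lexical_diversity_pct(vocabulary: int, tokens: int) -> float:
    return 100.0 * vocabulary / tokens


def consistency_report() -> dict[str, float]:
    """Recompute every derivable reference quantity from the primitive ones.

    All four recomputations must agree with the published figures; this is
    the arithmetic self-consistency of the reference constants.
    """
    ref = CORPUS_REFERENCE
    return {
        "lexical_diversity_pct": round(
            lexical_diversity_pct(ref["vocabulary"], ref["tokens"]), 1),
        "tokens_per_doc_mean": round(ref["tokens"] / ref["documents"]),
        "pii_support_total": sum(PII_CLASS_FREQUENCIES.values()),
        "medical_entity_total": sum(CLINICAL_CLASS_FREQUENCIES.values()),
        "document_split_total": (ref["accident_documents"]
                                 + ref["disease_documents"]),
    }


def corpus_census(corpus: Corpus) -> dict:
    """Counts needed to verify a loaded corpus against the reference."""
    per_class = {lab: 0 for lab in (*PII_LABELS, *CLINICAL_LABELS)}
    accident = disease = 0
    for doc in corpus:
        if doc.document.subcorpus == "accident":
            accident += 1
        else:
            disease += 1
        for span in doc.spans():
            per_class[span.label] += 1
    return {
        "documents": len(corpus),
        "accident_documents": accident,
        "disease_documents": disease,
        "pii_annotations": sum(per_class[lab] for lab in PII_LABELS),
        "clinical_annotations": sum(per_class[lab] for lab in CLINICAL_LABELS),
        "per_class": per_class,
    }
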