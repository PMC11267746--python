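import pytest

from clindeid.corpus import AnnotatedDocument, Corpus, EntitySpan, TextDocument
from clindeid.synth import GeneratorConfig, generate_corpus


def make_doc(text, pii=(), clinical=(), doc_id="doc-1", subcorpus="accident"):
    """Build an annotated document from (start, end, label) triples."""
    document = TextDocument(doc_id=doc_id, text=text, subcorpus=subcorpus)
    return AnnotatedDocument(
        document=document,
        pii_spans=[EntitySpan.from_text(text, s, e, lab) for s, e, lab in pii],
        clinical_spans=[EntitySpan.from_text(text, s, e, lab)
                        for s, e, lab in clinical],
    ).validate()


@pytest.fixture
def figure_like_doc():
    """A short anamnesis-style document mixing PII and clinical entities,
    with a body part nested inside a disease phrase."""
    text = ("Paciente con Tu benigno trabaja como mecánico industrial. "
            "El día 01/03/2019 sufre esguince de tobillo. "
            "Atendido por Dr. Gonzalez en Hospital La Cisterna. "
            "Edad: 45 años. RUN 12.345.678-5.")
    pii = [
        (37, 56, "Occupation"),       # mecánico industrial
        (65, 75, "FullDate"),         # 01/03/2019
        (120, 128, "LastName"),       # Gonzalez
        (132, 152, "HealthCareUnit"),  # Hospital La Cisterna
        (160, 167, "Age"),            # 45 años
        (173, 185, "PersonalID"),     # 12.345.678-5
    ]
    clinical = [
        (13, 23, "Disease"),          # Tu benigno
        (82, 101, "Disease"),         # esguince de tobillo
        (94, 101, "BodyPart"),        # tobillo (nested)
    ]
    return make_doc(text, pii, clinical)


@pytest.fixture(scope="session")
def synth_corpus():
    """Medium synthetic corpus shared by read-only tests."""
    return generate_corpus(GeneratorConfig(seed=20240, n_documents=60))


@pytest.fixture
def small_corpus():
    return generate_corpus(GeneratorConfig(seed=7, n_documents=8))


def corpus_of(*docs):
    return Corpus(documents=list(docs))
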