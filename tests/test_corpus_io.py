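"""Domain types and standoff I/O: validation, BRAT/JSONL round trips,
CoNLL BIO export."""

import pytest

from clindeid.brat import read_brat, write_brat
from clindeid.conll import document_bio, export_conll_bio
from clindeid.corpus import (AnnotatedDocument, Corpus, EntitySpan,
                             TextDocument, ValidationError,
                             resolve_pii_overlaps)
from clindeid.jsonl import read_jsonl, write_jsonl
from clindeid.synth import GeneratorConfig, generate_corpus
from clindeid.tokenize import tokenize

from conftest import make_doc


class TestSpanValidation:
    def test_surface_must_match_slice(self):
        with pytest.raises(ValidationError, match="surface mismatch"):
            EntitySpan(0, 4, "Disease", "clinical", "XXXX").validate("tumor")

    def test_offsets_must_be_in_range(self):
        span = EntitySpan.from_text("tumor", 0, 5, "Disease")
        with pytest.raises(ValidationError, match="out of range"):
            span.validate("tum")

    def test_unknown_label_rejected_unless_allowed(self):
        with pytest.raises(ValidationError, match="unknown label"):
            EntitySpan.from_text("tumor", 0, 5, "Gadget")

    def test_empty_text_rejected(self):
        with pytest.raises(ValidationError):
            TextDocument(doc_id="d", text="")

    def test_pii_overlap_rejected_and_repairable(self):
        text = "Juan Pablo Rojas"
        spans = [EntitySpan.from_text(text, 0, 10, "FirstName"),
                 EntitySpan.from_text(text, 5, 16, "LastName")]
        doc = AnnotatedDocument(document=TextDocument(doc_id="d", text=text),
                                pii_spans=spans)
        with pytest.raises(ValidationError, match="overlapping PII"):
            doc.validate()
        repaired = resolve_pii_overlaps(spans)
        assert repaired == [spans[1]]  # longer span wins

    def test_clinical_nesting_is_legal(self, figure_like_doc):
        labels = [s.label for s in figure_like_doc.clinical_spans]
        assert labels.count("Disease") == 2 and "BodyPart" in labels


class TestBrat:
    def test_single_t_line_maps_to_span(self, tmp_path):
        text = "x" * 25 + "cancer y algo más"
        (tmp_path / "d.txt").write_text(text, encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tDisease 25 31\tcancer\n",
                                        encoding="utf-8")
        doc = read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        (span,) = doc.clinical_spans
        assert (span.start, span.end, span.label, span.surface) == \
            (25, 31, "Disease", "cancer")

    def test_empty_ann_gives_empty_layers(self, tmp_path):
        (tmp_path / "d.txt").write_text("hola", encoding="utf-8")
        (tmp_path / "d.ann").write_text("", encoding="utf-8")
        doc = read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        assert doc.pii_spans == [] and doc.clinical_spans == []

    @pytest.mark.parametrize("ann,err", [
        ("T1\tDisease 2 99\ttoolong", "out of range"),
        ("T1\tDisease 0 4\tWRNG", "surface"),
        ("T1\tGadget 0 4\thola", "unknown label"),
        ("T1\tDisease 0 2;3 4\tho a", "discontinuous|malformed"),
        ("R1\tRel Arg1:T1 Arg2:T2", "only entity"),
    ])
    def test_malformed_ann_rejected(self, tmp_path, ann, err):
        (tmp_path / "d.txt").write_text("hola mundo", encoding="utf-8")
        (tmp_path / "d.ann").write_text(ann + "\n", encoding="utf-8")
        with pytest.raises(ValidationError, match=err):
            read_brat(tmp_path / "d.txt", tmp_path / "d.ann")

    def test_round_trip_is_identity(self, tmp_path, small_corpus):
        for doc in small_corpus:
            txt, ann = write_brat(doc, tmp_path)
            again = read_brat(txt, ann, subcorpus=doc.document.subcorpus)
            assert again.text == doc.text
            assert sorted(again.spans()) == sorted(doc.spans())
            # write(read(x)) reproduces the files byte-for-byte
            txt2, ann2 = write_brat(again, tmp_path / "again")
            assert txt2.read_bytes() == txt.read_bytes()
            assert ann2.read_bytes() == ann.read_bytes()

    def test_refuses_overwrite(self, tmp_path, small_corpus):
        write_brat(small_corpus[0], tmp_path)
        with pytest.raises(FileExistsError):
            write_brat(small_corpus[0], tmp_path)


class TestJsonl:
    def test_empty_file_empty_corpus(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text("", encoding="utf-8")
        assert len(read_jsonl(p)) == 0

    def test_figure_like_record_round_trips(self, tmp_path, figure_like_doc):
        p = tmp_path / "c.jsonl"
        write_jsonl(Corpus(documents=[figure_like_doc]), p)
        corpus = read_jsonl(p)
        assert len(corpus) == 1
        assert sorted(corpus[0].spans()) == sorted(figure_like_doc.spans())

    def test_write_read_identity_on_synthetic(self, tmp_path, small_corpus):
        p1 = tmp_path / "a.jsonl"
        p2 = tmp_path / "b.jsonl"
        write_jsonl(small_corpus, p1)
        write_jsonl(read_jsonl(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text('{"doc_id": "a", "text": "x", "subcorpus": "accident"}\n'
                     "{not json}\n", encoding="utf-8")
        with pytest.raises(ValidationError, match=":2"):
            read_jsonl(p)

    def test_duplicate_doc_id_rejected(self, tmp_path):
        line = '{"doc_id": "a", "text": "x", "subcorpus": "accident"}\n'
        p = tmp_path / "c.jsonl"
        p.write_text(line + line, encoding="utf-8")
        with pytest.raises(ValidationError, match="duplicate"):
            read_jsonl(p)


def _bio_oracle(doc, label):
    """Independent tagging by character-interval intersection, outermost
    spans only."""
    spans = [s for s in doc.spans() if s.label == label]
    maximal = [s for s in spans
               if not any(o.contains(s) and (o.start, o.end) != (s.start, s.end)
                          for o in spans)]
    tags = []
    for t in tokenize(doc.text):
        hit = [s for s in maximal if s.start < t.end and t.start < s.end]
        if not hit:
            tags.append("O")
        else:
            s = min(hit, key=lambda x: x.start)
            first = min(tok.start for tok in tokenize(doc.text)
                        if s.start < tok.end and tok.start < s.end)
            tags.append(("B-" if t.start == first else "I-") + label)
    return tags


class TestConllBio:
    def test_no_spans_all_o(self):
        doc = make_doc("sin anotaciones aquí")
        assert all(tag == "O" for _, tag in document_bio(doc, "Disease"))

    def test_disease_span_over_three_tokens(self):
        doc = make_doc("tendinitis de hombro", clinical=[(0, 20, "Disease")])
        assert [t for _, t in document_bio(doc, "Disease")] == \
            ["B-Disease", "I-Disease", "I-Disease"]

    def test_same_class_nesting_outermost_wins(self):
        text = "cancer de colon avanzado"
        doc = make_doc(text, clinical=[(0, 15, "Disease"), (0, 6, "Disease")])
        tags = [t for _, t in document_bio(doc, "Disease")]
        assert tags == ["B-Disease", "I-Disease", "I-Disease", "O"]

    def test_tags_match_interval_intersection_oracle(self, small_corpus):
        for doc in small_corpus:
            for label in ("Disease", "BodyPart", "Occupation", "FullDate"):
                got = [t for _, t in document_bio(doc, label)]
                assert got == _bio_oracle(doc, label)

    def test_b_count_equals_maximal_span_count(self, small_corpus):
        for doc in small_corpus:
            rows = document_bio(doc, "BodyPart")
            n_b = sum(1 for _, t in rows if t == "B-BodyPart")
            spans = [s for s in doc.clinical_spans if s.label == "BodyPart"]
            maximal = [s for s in spans
                       if not any(o.contains(s)
                                  and (o.start, o.end) != (s.start, s.end)
                                  for o in spans)]
            assert n_b == len({(s.start, s.end) for s in maximal})

    def test_export_blank_line_between_documents(self, tmp_path, small_corpus):
        p = export_conll_bio(small_corpus, "Disease", tmp_path / "d.conll")
        blocks = p.read_text(encoding="utf-8").split("\n\n")
        assert len(blocks) == len(small_corpus)
        for block in blocks:
            for line in block.strip().splitlines():
                tok, tag = line.rsplit(" ", 1)
                assert tag == "O" or tag.startswith(("B-", "I-"))


def test_generated_corpora_are_valid_and_deterministic():
    a = generate_corpus(GeneratorConfig(seed=3, n_documents=6))
    b = generate_corpus(GeneratorConfig(seed=3, n_documents=6))
    assert [(d.text, sorted(d.spans())) for d in a] == \
        [(d.text, sorted(d.spans())) for d in b]
    for doc in a:
        doc.validate()
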