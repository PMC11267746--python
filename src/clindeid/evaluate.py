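"""Entity-level evaluation: pairwise span F1 (inter-annotator agreement)
and precision/recall/F1 for NER output against a gold standard.

The default matching criterion is *exact*: two spans match when they agree
on (start, end, label).  Under exact matching the pairwise score is
symmetric — P(A,B)=R(B,A) and F1(A,B)=F1(B,A) — which is what makes it
usable as an agreement measure.  An *overlap* mode (same label, intersecting
intervals, greedy one-to-one by maximal overlap, ties to the earlier start)
is provided for sensitivity analysis.

Zero-denominator convention: a precision or recall with an empty denominator
is reported as 0, the common convention in NER evaluation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .corpus import AnnotatedDocument, Corpus, EntitySpan, ValidationError

MICRO_LABEL = "Global (micro avg)"


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    support: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvaluationReport:
    rows: list[ClassMetrics]
    micro: ClassMetrics
    matching_mode: str

    def __post_init__(self) -> None:
        assert self.micro.tp == sum(r.tp for r in self.rows)
        assert self.micro.support == sum(r.support for r in self.rows)

    def row(self, label: str) -> ClassMetrics:
        if label == MICRO_LABEL:
            return self.micro
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [{"class": r.label, "support": r.support,
                 "P": r.precision, "R": r.recall, "F1": r.f1}
                for r in [self.micro] + self.rows]
        return pd.DataFrame.from_records(recs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.4f")

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [f"{'class':<22}{'support':>8}{'P':>8}{'R':>8}{'F1':>8}"]
        for _, row in df.iterrows():
            lines.append(f"{row['class']:<22}{row['support']:>8d}"
                         f"{row['P']:>8.2f}{row['R']:>8.2f}{row['F1']:>8.2f}")
        lines.append(f"[matching: {self.matching_mode}; empty-denominator "
                     f"P/R reported as 0]")
        return "\n".join(lines)


def _span_overlap(a: EntitySpan, b: EntitySpan) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_spans(reference: list[EntitySpan], hypothesis: list[EntitySpan],
                mode: str = "exact") -> dict[str, tuple[int, int, int]]:
    """Per-class (TP, FP, FN) between two span sets over one document."""
    if mode not in ("exact", "overlap"):
        raise ValueError(f"mode must be exact|overlap, got {mode!r}")
    labels = sorted({s.label for s in reference} | {s.label for s in hypothesis})
    out: dict[str, tuple[int, int, int]] = {}
    for label in labels:
        ref = [s for s in reference if s.label == label]
        hyp = [s for s in hypothesis if s.label == label]
        if mode == "exact":
            rc = Counter((s.start, s.end) for s in ref)
            hc = Counter((s.start, s.end) for s in hyp)
            tp = sum(min(rc[k], hc[k]) for k in rc)
        else:
            pairs = [(_span_overlap(r, h), r, h)
                     for r in ref for h in hyp if _span_overlap(r, h) > 0]
            pairs.sort(key=lambda x: (-x[0], x[1].start, x[2].start,
                                      x[1].end, x[2].end))
            used_r: set[int] = set()
            used_h: set[int] = set()
            tp = 0
            for _, r, h in pairs:
                if id(r) in used_r or id(h) in used_h:
                    continue
                used_r.add(id(r))
                used_h.add(id(h))
                tp += 1
        out[label] = (tp, len(hyp) - tp, len(ref) - tp)
    return out


def _corpus_counts(ref_corpus: Corpus, hyp_corpus: Corpus, mode: str,
                   layer: str) -> dict[str, list[int]]:
    ref_docs = ref_corpus.by_id()
    hyp_docs = hyp_corpus.by_id()
    only_ref = sorted(set(ref_docs) - set(hyp_docs))
    only_hyp = sorted(set(hyp_docs) - set(ref_docs))
    if only_ref or only_hyp:
        raise ValidationError(
            f"corpora do not cover the same documents; only in reference: "
            f"{only_ref}; only in hypothesis: {only_hyp}")
    totals: dict[str, list[int]] = {}
    for doc_id, ref_doc in ref_docs.items():
        hyp_doc = hyp_docs[doc_id]
        counts = match_spans(_layer(ref_doc, layer), _layer(hyp_doc, layer),
                             mode)
        for label, (tp, fp, fn) in counts.items():
            acc = totals.setdefault(label, [0, 0, 0])
            acc[0] += tp
            acc[1] += fp
            acc[2] += fn
    return totals


def _layer(doc: AnnotatedDocument, layer: str) -> list[EntitySpan]:
    if layer == "pii":
        return doc.pii_spans
    if layer == "clinical":
        return doc.clinical_spans
    if layer == "both":
        return list(doc.spans())
    raise ValueError(f"layer must be pii|clinical|both, got {layer!r}")


def _build_report(totals: dict[str, list[int]], mode: str) -> EvaluationReport:
    rows = []
    for label in sorted(totals):
        tp, fp, fn = totals[label]
        rows.append(ClassMetrics(label=label, support=tp + fn,
                                 tp=tp, fp=fp, fn=fn))
    rows.sort(key=lambda r: (-r.support, r.label))
    micro = ClassMetrics(label=MICRO_LABEL,
                         support=sum(r.support for r in rows),
                         tp=sum(r.tp for r in rows),
                         fp=sum(r.fp for r in rows),
                         fn=sum(r.fn for r in rows))
    return EvaluationReport(rows=rows, micro=micro, matching_mode=mode)


def pairwise_f1(ann_a: Corpus, ann_b: Corpus, mode: str = "exact",
                layer: str = "pii") -> EvaluationReport:
    """Pairwise span F1 between two annotators over the same documents.

    Support is counted on the first argument (the reference role).
    """
    return _build_report(_corpus_counts(ann_a, ann_b, mode, layer), mode)


def ner_eval(gold: Corpus, predicted: Corpus, mode: str = "exact",
             layer: str = "clinical") -> EvaluationReport:
    """Entity-level P/R/F1 of predictions against a gold standard."""
    return _build_report(_corpus_counts(gold, predicted, mode, layer), mode)
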