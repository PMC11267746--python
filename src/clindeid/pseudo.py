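"""Pseudonymization: replace PII spans with realistic surrogates.

Per-class rules (see :mod:`clindeid.dates` and :mod:`clindeid.idnum` for the
date/identifier arithmetic):

* first/last names — resampled from lists of common Chilean names, gender
  preserved when inferable from list membership, casing mirrored;
* occupations / companies / healthcare units — generalized via lookup
  tables to a category placeholder (``técnico``, ``un centro educativo``,
  ``un hospital`` ...) with total fallbacks (``trabajador``, ``una
  empresa``, ``un hospital``);
* locations — resampled from a word list for the location's type, fallback
  ``un lugar`` for unknown types;
* dates — per-document day shift, year-wrapped into a window; ages — small
  per-entity shift with clamping;
* RUN / ID / phone — random structurally valid replacements; emails — a
  random local part at a reserved example domain.

Randomness is scoped so output is reproducible and order-invariant: every
draw comes from a generator seeded by a stable hash of the master seed plus
the consistency key (document id, class, surface).  Identical surfaces
within the consistency scope therefore receive identical surrogates by
construction.
"""

from __future__ import annotations

import hashlib
import logging
from random import Random
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

from . import resources as res
from .corpus import AnnotatedDocument, Corpus, ValidationError
from .dates import DateParseError, shift_age, shift_date
from .idnum import surrogate_email, surrogate_id, surrogate_phone, surrogate_run
from .labels import DEFAULT_PLACEHOLDERS
from .mask import MaskedDocument, ReplacementRecord, apply_replacements

logger = logging.getLogger(__name__)


class CountingRandom(Random):
    """Random stream that counts how many primitive draws were consumed."""

    def __init__(self, seed=None):
        self.calls = 0
        super().__init__(seed)

    def random(self):
        self.calls += 1
        return super().random()

    def getrandbits(self, k):
        self.calls += 1
        return super().getrandbits(k)


def derive_seed(master: int, *parts: str) -> int:
    """Stable sub-seed from the master seed and a scope key (< 2^31)."""
    h = hashlib.sha256(("|".join([str(master), *parts])).encode("utf-8"))
    return int.from_bytes(h.digest()[:8], "big") % (2 ** 31)


class SurrogateConfig(BaseModel):
    """All knobs and resources of the pseudonymizer."""

    seed: int = 0
    first_names_female: list[str] = Field(default_factory=list)
    first_names_male: list[str] = Field(default_factory=list)
    last_names: list[str] = Field(default_factory=list)
    occupation_table: dict[str, str] = Field(default_factory=dict)
    company_table: dict[str, str] = Field(default_factory=dict)
    healthcare_table: dict[str, str] = Field(default_factory=dict)
    location_lists: dict[str, list[str]] = Field(default_factory=dict)
    location_types: dict[str, str] = Field(default_factory=dict)
    date_window: tuple[int, int] = (2017, 2023)
    day_offset_range: tuple[int, int] = (10, 300)
    age_shift_min: int = 1
    age_shift_max: int = 5
    age_clamp: tuple[int, int] = (18, 90)
    consistency_scope: Literal["document", "corpus"] = "document"
    dialect: Literal["dayfirst", "monthfirst", "auto"] = "dayfirst"
    occupation_fallback: str = "trabajador"
    company_fallback: str = "una empresa"
    healthcare_fallback: str = "un hospital"
    location_fallback: str = "un lugar"

    @field_validator("date_window")
    @classmethod
    def _window_nonempty(cls, v):
        if v[0] > v[1]:
            raise ValueError("date_window must be a non-empty year interval")
        return v

    @field_validator("age_shift_min")
    @classmethod
    def _shift_positive(cls, v):
        if v < 1:
            raise ValueError("age shift range must exclude 0")
        return v

    @classmethod
    def default(cls, seed: int = 0, resource_dir=None,
                **overrides) -> "SurrogateConfig":
        """Config backed by the shipped resource tables."""
        return cls(
            seed=seed,
            first_names_female=res.load_word_list("first_names_female", resource_dir),
            first_names_male=res.load_word_list("first_names_male", resource_dir),
            last_names=res.load_word_list("last_names", resource_dir),
            occupation_table=res.load_table("occupations", resource_dir),
            company_table=res.load_table("companies", resource_dir),
            healthcare_table=res.load_table("healthcare_units", resource_dir),
            location_lists=res.load_location_lists(resource_dir),
            location_types=res.load_table("location_types", resource_dir),
            **overrides,
        )


def _mirror_case(word: str, like: str) -> str:
    if like.isupper():
        return word.upper()
    if like.islower():
        return word.lower()
    return word


def surrogate_name(surface: str, kind: Literal["first", "last"],
                   config: SurrogateConfig, rng: Random) -> str:
    """Sample a replacement name; gender preserved for first names when the
    original appears in exactly one gendered list; casing mirrored."""
    if kind == "last":
        pool = config.last_names
    else:
        cf = surface.split()[0].casefold()
        in_f = any(n.casefold() == cf for n in config.first_names_female)
        in_m = any(n.casefold() == cf for n in config.first_names_male)
        if in_f and not in_m:
            pool = config.first_names_female
        elif in_m and not in_f:
            pool = config.first_names_male
        else:
            pool = config.first_names_female + config.first_names_male
    if not pool:
        raise ValidationError(f"name list for kind={kind!r} is empty")
    words = surface.split()
    originals = {w.casefold() for w in words}
    candidates = [n for n in pool if n.casefold() not in originals]
    if len(candidates) < len(words):
        raise ValidationError(
            f"candidate pool empty after excluding {surface!r}")
    picked = rng.sample(candidates, len(words))
    return " ".join(_mirror_case(p, w) for p, w in zip(picked, words))


def _table_lookup(surface: str, table: dict[str, str], fallback: str) -> str:
    hit = table.get(surface)
    if hit is not None:
        return hit
    cf = surface.casefold()
    for k, v in table.items():
        if k.casefold() == cf:
            return v
    return fallback


def surrogate_occupation(surface: str, config: SurrogateConfig) -> str:
    return _table_lookup(surface, config.occupation_table,
                         config.occupation_fallback)


def surrogate_company(surface: str, config: SurrogateConfig) -> str:
    return _table_lookup(surface, config.company_table, config.company_fallback)


def surrogate_healthcare_unit(surface: str, config: SurrogateConfig) -> str:
    return _table_lookup(surface, config.healthcare_table,
                         config.healthcare_fallback)


def surrogate_location(surface: str, location_type: Optional[str],
                       config: SurrogateConfig, rng: Random) -> str:
    """Sample from the word list of the location's type; unknown type →
    generic ``un lugar``."""
    if location_type is None or location_type not in config.location_lists:
        if location_type is not None:
            raise ValidationError(
                f"location type {location_type!r} has no configured list")
        return config.location_fallback
    pool = config.location_lists[location_type]
    if not pool:
        raise ValidationError(f"location list {location_type!r} is empty")
    candidates = [x for x in pool if x.casefold() != surface.casefold()]
    if not candidates:
        return config.location_fallback
    return _mirror_case(rng.choice(candidates), surface)


_MEMOIZED = {"FirstName", "LastName", "Location", "PersonalID", "ID",
             "PhoneNumber", "Email", "Occupation", "Company", "HealthCareUnit"}


def _scope_key(config: SurrogateConfig, doc_id: str, label: str,
               surface: str) -> tuple[str, ...]:
    if label in _MEMOIZED and config.consistency_scope == "corpus":
        return (label, surface.casefold())
    return (doc_id, label, surface.casefold())


def _forbidden_surfaces(doc: AnnotatedDocument, min_len: int = 4) -> list[str]:
    return [s.surface for s in doc.pii_spans if len(s.surface) >= min_len]


def pseudonymize_document(doc: AnnotatedDocument, config: SurrogateConfig,
                          *, on_contained: str = "drop",
                          _memo: dict | None = None) -> MaskedDocument:
    """Replace every PII span of ``doc`` with its class rule's surrogate.

    Deterministic given (seed, doc_id, input).  Spans whose rule cannot
    interpret the surface (e.g. an unparseable date) fall back to the
    class-name placeholder and are flagged in the audit records.
    """
    doc_rng = CountingRandom(derive_seed(config.seed, doc.doc_id, "doc"))
    lo, hi = config.day_offset_range
    forbidden = _forbidden_surfaces(doc)

    def draw_offset(r: Random, wide: bool = False) -> int:
        # wide draws move the calendar year, needed when a bare-year PII
        # surface elsewhere in the document pins the shifted dates' year
        a, b = (366, 720) if wide else (lo, hi)
        return r.choice((-1, 1)) * r.randint(a, b)

    # Per-document day offset, re-drawn (bounded) if any *offset-dependent*
    # date surrogate would contain an original PII surface of the document.
    # Offset-independent date parts (month/year/weekday resamples) are kept
    # out of this probe: their collisions are handled by per-span redraws.
    date_spans = [s for s in doc.pii_spans if s.label in ("FullDate", "DatePart")]

    def offset_dependent(span) -> bool:
        key = _scope_key(config, doc.doc_id, span.label, span.surface)
        outs = set()
        for off in (40, 70):
            probe = CountingRandom(derive_seed(config.seed, *key, ""))
            try:
                outs.add(shift_date(span.surface, config, probe, off))
            except (DateParseError, ValueError):
                return False
        return len(outs) == 2

    probed = [s for s in date_spans if offset_dependent(s)]
    doc_offset = draw_offset(doc_rng)
    for attempt in range(24):
        collision = False
        for span in probed:
            key = _scope_key(config, doc.doc_id, span.label, span.surface)
            probe = CountingRandom(derive_seed(config.seed, *key, ""))
            try:
                cand = shift_date(span.surface, config, probe, doc_offset)
            except (DateParseError, ValueError):
                continue
            if any(f in cand for f in forbidden):
                collision = True
                break
        if not collision:
            break
        doc_offset = draw_offset(doc_rng, wide=attempt >= 8)

    memo: dict[tuple[str, ...], str] = {} if _memo is None else _memo
    replacements = []
    records = []
    for span in sorted(doc.pii_spans, key=lambda s: (s.start, s.end)):
        key = _scope_key(config, doc.doc_id, span.label, span.surface)
        rng = CountingRandom(derive_seed(config.seed, *key,
                                         str(span.start)
                                         if span.label == "Age" else ""))
        rule = span.label
        # cross-document privacy guard is skipped for corpus-scope memoized
        # classes: one surface must map to one surrogate corpus-wide
        guarded = (config.consistency_scope == "document"
                   or span.label not in _MEMOIZED)
        try:
            if key in memo and span.label != "Age":
                surrogate = memo[key]
                rule += "/memo"
            else:
                surrogate = _apply_rule(span.label, span.surface, config, rng,
                                        doc_offset,
                                        forbidden if guarded else [])
                memo[key] = surrogate
        except (DateParseError, ValueError, ValidationError) as exc:
            if isinstance(exc, ValidationError):
                raise
            surrogate = DEFAULT_PLACEHOLDERS[span.label]
            rule = "mask_fallback"
            logger.warning("%s: %s span %r not interpretable (%s); masked",
                           doc.doc_id, span.label, span.surface, exc)
        replacements.append((span, surrogate))
        records.append(ReplacementRecord(
            doc_id=doc.doc_id, label=span.label, start=span.start,
            end=span.end, surface=span.surface, surrogate=surrogate,
            rule=rule, draws=rng.calls))
    return apply_replacements(doc, replacements, records,
                              on_contained=on_contained)


def _apply_rule(label: str, surface: str, config: SurrogateConfig,
                rng: Random, doc_offset: int, forbidden: list[str]) -> str:
    """Dispatch to the per-class rule; resampling (bounded) keeps surrogates
    clear of every other original PII surface of the document."""

    def clear(candidate: str, redraw) -> str:
        # no original surface of the document (the span's own included) may
        # occur inside the surrogate; bounded redraws from the same stream
        for _ in range(20):
            if not any(f in candidate for f in forbidden):
                return candidate
            candidate = redraw()
        return candidate

    if label == "FirstName":
        return clear(surrogate_name(surface, "first", config, rng),
                     lambda: surrogate_name(surface, "first", config, rng))
    if label == "LastName":
        return clear(surrogate_name(surface, "last", config, rng),
                     lambda: surrogate_name(surface, "last", config, rng))
    if label == "Occupation":
        return surrogate_occupation(surface, config)
    if label == "Company":
        return surrogate_company(surface, config)
    if label == "HealthCareUnit":
        return surrogate_healthcare_unit(surface, config)
    if label == "Location":
        ltype = config.location_types.get(surface)
        if ltype is None:
            cf = surface.casefold()
            ltype = next((v for k, v in config.location_types.items()
                          if k.casefold() == cf), None)
        return clear(surrogate_location(surface, ltype, config, rng),
                     lambda: surrogate_location(surface, ltype, config, rng))
    if label in ("FullDate", "DatePart"):
        return clear(shift_date(surface, config, rng, doc_offset),
                     lambda: shift_date(surface, config, rng, doc_offset))
    if label == "Age":
        return clear(shift_age(surface, config, rng),
                     lambda: shift_age(surface, config, rng))
    if label == "PersonalID":
        return clear(surrogate_run(surface, rng),
                     lambda: surrogate_run(surface, rng))
    if label == "ID":
        return clear(surrogate_id(surface, rng),
                     lambda: surrogate_id(surface, rng))
    if label == "PhoneNumber":
        return clear(surrogate_phone(surface, rng),
                     lambda: surrogate_phone(surface, rng))
    if label == "Email":
        return clear(surrogate_email(surface, rng),
                     lambda: surrogate_email(surface, rng))
    raise ValidationError(f"no surrogate rule registered for class {label!r}")


def pseudonymize_corpus(corpus: Corpus, config: SurrogateConfig,
                        *, on_contained: str = "drop"):
    """Pseudonymize every document; returns (Corpus, records, warnings)."""
    docs, records, warns = [], [], []
    shared_memo: dict | None = {} if config.consistency_scope == "corpus" else None
    for doc in corpus:
        out = pseudonymize_document(doc, config, on_contained=on_contained,
                                    _memo=shared_memo)
        docs.append(out.to_annotated())
        records.extend(out.replacement_records)
        warns.extend(out.warnings)
    return Corpus(documents=docs), records, warns
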