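"""Seeded generator of synthetic Spanish anamnesis documents.

Documents imitate the register of occupational-health admission notes: a
short narrative mixing PII (occupation, employer, dates, age, names, RUN,
phone, healthcare unit, locations, emails) with clinical entities (diseases,
body parts — sometimes nested inside a disease phrase — and medications),
all carrying gold span annotations.  The generator exists so every pipeline
stage is testable without the restricted corpus; its class mix defaults to
the published per-class frequencies and its documents carry 1–30 entities.

It also provides :func:`corrupt_annotations`, a noise model (span drops,
spurious spans, boundary jitter) that turns a gold corpus into a pseudo
second annotator or a pseudo NER prediction with analytically known
expected precision and recall.
"""

from __future__ import annotations

from collections import Counter
from random import Random
from typing import Union

from pydantic import BaseModel, Field, field_validator

from . import resources as res
from .corpus import AnnotatedDocument, Corpus, EntitySpan, TextDocument
from .idnum import format_run
from .labels import CLINICAL_LABELS, LAYER_CLINICAL, LAYER_PII, PII_LABELS
from .pseudo import derive_seed
from .reference import (CLINICAL_CLASS_FREQUENCIES, CORPUS_REFERENCE,
                        PII_CLASS_FREQUENCIES)

_DEFAULT_WEIGHTS = {**PII_CLASS_FREQUENCIES, **CLINICAL_CLASS_FREQUENCIES}


class GeneratorConfig(BaseModel):
    seed: int = 0
    n_documents: int = 100
    accident_fraction: float = (CORPUS_REFERENCE["accident_documents"]
                                / CORPUS_REFERENCE["documents"])
    class_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    nesting_rate: float = 0.35
    entities_per_doc_mean: float = CORPUS_REFERENCE["entities_per_doc_mean"]
    entities_per_doc_sd: float = CORPUS_REFERENCE["entities_per_doc_sd"]
    max_entities_per_doc: int = 30
    year_range: tuple[int, int] = (2017, 2023)
    #: fraction of occupation/company/unit/location surfaces drawn outside
    #: the shipped lookup tables, to exercise the fallback rules
    unknown_resource_rate: float = 0.12

    @field_validator("accident_fraction", "nesting_rate",
                     "unknown_resource_rate")
    @classmethod
    def _fraction(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @field_validator("class_weights")
    @classmethod
    def _weights(cls, v):
        if any(w < 0 for w in v.values()):
            raise ValueError("rates must be non-negative")
        return v

    @field_validator("n_documents")
    @classmethod
    def _ndocs(cls, v):
        if v < 1:
            raise ValueError("n_documents must be >= 1")
        return v


class _Builder:
    def __init__(self, doc_id: str, subcorpus: str):
        self.doc_id = doc_id
        self.subcorpus = subcorpus
        self.parts: list[str] = []
        self.pos = 0
        self.pii: list[EntitySpan] = []
        self.clinical: list[EntitySpan] = []

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.pos += len(text)

    def add_entity(self, surface: str, label: str) -> None:
        layer = LAYER_PII if label in PII_LABELS else LAYER_CLINICAL
        self.pii.append(EntitySpan(self.pos, self.pos + len(surface), label,
                                   layer, surface)) if layer == LAYER_PII \
            else self.clinical.append(EntitySpan(self.pos, self.pos + len(surface),
                                                 label, layer, surface))
        self.add(surface)

    def add_nested(self, prefix: str, inner_surface: str, suffix: str,
                   outer_label: str, inner_label: str) -> None:
        start = self.pos
        self.add(prefix)
        inner = EntitySpan(self.pos, self.pos + len(inner_surface),
                           inner_label, LAYER_CLINICAL, inner_surface)
        self.add(inner_surface)
        self.add(suffix)
        outer = EntitySpan(start, self.pos, outer_label, LAYER_CLINICAL,
                           prefix + inner_surface + suffix)
        self.clinical.extend([outer, inner])

    def build(self) -> AnnotatedDocument:
        return AnnotatedDocument(
            document=TextDocument(doc_id=self.doc_id,
                                  text="".join(self.parts),
                                  subcorpus=self.subcorpus),
            pii_spans=self.pii, clinical_spans=self.clinical)


_EXTRA_OCCUPATIONS = ["ayudante de maestranza", "clasificador de fruta",
                      "montajista de andamios", "operario de packing"]
_EXTRA_COMPANIES = ["Sociedad Agroexportadora del Valle",
                    "Comercializadora Austral SpA",
                    "Servicios Generales El Faro EIRL"]
_EXTRA_UNITS = ["Hospital Provincial del Este", "Clínica Cumbre",
                "Centro Médico del Estrecho"]
_EXTRA_LOCATIONS = ["el sector poniente", "la zona costera",
                    "el kilómetro 12 de la ruta interior"]

_DISEASES = ["lumbago agudo", "cervicalgia", "dermatitis de contacto",
             "síndrome de túnel carpiano", "epicondilitis", "hipoacusia",
             "neumonitis", "estrés laboral"]
_DISEASE_HEADS = ["fractura", "esguince", "tendinitis", "contusión",
                  "luxación", "herida cortante", "desgarro"]
_BODYPARTS = ["tobillo", "muñeca", "hombro", "rodilla", "codo", "cadera",
              "mano izquierda", "pie derecho", "columna lumbar",
              "dedo índice", "antebrazo", "tórax"]
_MEDICATIONS = ["paracetamol", "ibuprofeno", "ketorolaco", "diclofenaco",
                "tramadol", "celecoxib", "metamizol", "prednisona"]

_MONTH_NAMES = ("enero", "febrero", "marzo", "abril", "mayo", "junio",
                "julio", "agosto", "septiembre", "octubre", "noviembre",
                "diciembre")
_WEEKDAYS = ("lunes", "martes", "miércoles", "jueves", "viernes", "sábado",
             "domingo")
_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


class _Resources:
    """Lazily loaded shipped resource tables shared across documents."""
    _cache = None

    @classmethod
    def get(cls):
        if cls._cache is None:
            cls._cache = {
                "female": res.load_word_list("first_names_female"),
                "male": res.load_word_list("first_names_male"),
                "last": res.load_word_list("last_names"),
                "occ": sorted(res.load_table("occupations")),
                "comp": sorted(res.load_table("companies")),
                "unit": sorted(res.load_table("healthcare_units")),
                "loc": res.load_location_lists(),
            }
        return cls._cache


def _full_date(rng: Random, years: tuple[int, int]) -> str:
    y = rng.randint(*years)
    m = rng.randint(1, 12)
    d = rng.randint(1, _DAYS_IN_MONTH[m - 1])
    style = rng.randrange(4)
    if style == 0:
        return f"{d:02d}/{m:02d}/{y}"
    if style == 1:
        return f"{d}/{m}/{y}"
    if style == 2:
        return f"{d:02d}-{m:02d}-{y}"
    return f"{d} de {_MONTH_NAMES[m - 1]} de {y}"


def _date_part(rng: Random, years: tuple[int, int]) -> str:
    style = rng.randrange(4)
    if style == 0:
        return rng.choice(_MONTH_NAMES)
    if style == 1:
        return f"{rng.choice(_MONTH_NAMES)} de {rng.randint(*years)}"
    if style == 2:
        return rng.choice(_WEEKDAYS)
    return str(rng.randint(*years))


def _id_surface(rng: Random) -> str:
    style = rng.randrange(3)
    if style == 0:
        return (rng.choice("ABCDEFH") + rng.choice("ABCDEFH") + "-"
                + "".join(str(rng.randint(0, 9)) for _ in range(4)))
    if style == 1:
        return "F-" + "".join(str(rng.randint(0, 9)) for _ in range(5))
    return ("".join(str(rng.randint(0, 9)) for _ in range(2)) + "-"
            + "".join(str(rng.randint(0, 9)) for _ in range(5)))


def _phone_surface(rng: Random) -> str:
    style = rng.randrange(3)
    d = lambda n: " ".join("".join(str(rng.randint(0, 9)) for _ in range(k))
                           for k in n)
    if style == 0:
        return "+56 9 " + d((4, 4))
    if style == 1:
        return "9 " + d((4, 4))
    return "22 " + d((3, 4))


def _email_surface(rng: Random) -> str:
    letters = "abcdefghijlmnoprstuv"
    local = "".join(rng.choice(letters) for _ in range(rng.randint(5, 10)))
    return local + rng.choice(["@correo.cl", "@mail.com", "@trabajo.cl"])


def _pick(rng: Random, listed: list[str], extra: list[str],
          unknown_rate: float) -> str:
    if extra and rng.random() < unknown_rate:
        return rng.choice(extra)
    return rng.choice(listed)


def _realize(label: str, b: _Builder, rng: Random, cfg: GeneratorConfig,
             pool: dict, nested_credit: Counter) -> None:
    u = cfg.unknown_resource_rate
    if label == "Occupation":
        b.add(rng.choice(["Trabaja como ", "Se desempeña como ",
                          "De oficio "]))
        b.add_entity(_pick(rng, pool["occ"], _EXTRA_OCCUPATIONS, u), label)
        b.add(rng.choice([" desde hace 3 años. ", ". ",
                          " en jornada completa. "]))
    elif label == "Company":
        b.add(rng.choice(["Empleado de ", "Presta servicios en ",
                          "Contratado por "]))
        b.add_entity(_pick(rng, pool["comp"], _EXTRA_COMPANIES, u), label)
        b.add(". ")
    elif label == "HealthCareUnit":
        b.add(rng.choice(["Derivado a ", "Atendido inicialmente en ",
                          "Trasladado a "]))
        b.add_entity(_pick(rng, pool["unit"], _EXTRA_UNITS, u), label)
        b.add(". ")
    elif label == "Location":
        all_locs = [x for lst in pool["loc"].values() for x in lst]
        b.add(rng.choice(["Domicilio en ", "El hecho ocurre en ",
                          "Reside en "]))
        b.add_entity(_pick(rng, all_locs, _EXTRA_LOCATIONS, u), label)
        b.add(". ")
    elif label == "FirstName":
        b.add("Paciente de nombre ")
        b.add_entity(rng.choice(pool["female"] + pool["male"]), label)
        b.add(". ")
    elif label == "LastName":
        b.add(rng.choice(["Evaluado por Dr. ", "Evaluada por Dra. ",
                          "Paciente de apellido "]))
        b.add_entity(rng.choice(pool["last"]), label)
        b.add(". ")
    elif label == "FullDate":
        b.add(rng.choice(["El día ", "Con fecha ", "Accidente ocurrido el "]))
        b.add_entity(_full_date(rng, cfg.year_range), label)
        b.add(rng.choice([" sufre caída a nivel. ", " inicia los síntomas. ",
                          ". "]))
    elif label == "DatePart":
        # template wording must not reuse any annotatable surface (e.g. an
        # occupation word): text outside spans is never rewritten
        b.add(rng.choice(["Control agendado en ", "Sintomatología desde ",
                          "Próxima evaluación el "]))
        b.add_entity(_date_part(rng, cfg.year_range), label)
        b.add(". ")
    elif label == "Age":
        b.add(rng.choice(["Edad: ", "Paciente de "]))
        b.add_entity(f"{rng.randint(18, 90)} años", label)
        b.add(". ")
    elif label == "PersonalID":
        b.add("RUN ")
        b.add_entity(format_run(rng.randint(5_000_000, 26_999_999),
                                dots=rng.random() < 0.5), label)
        b.add(". ")
    elif label == "ID":
        b.add(rng.choice(["Ficha N° ", "Licencia folio "]))
        b.add_entity(_id_surface(rng), label)
        b.add(". ")
    elif label == "PhoneNumber":
        b.add("Teléfono de contacto ")
        b.add_entity(_phone_surface(rng), label)
        b.add(". ")
    elif label == "Email":
        b.add("Correo electrónico ")
        b.add_entity(_email_surface(rng), label)
        b.add(". ")
    elif label == "Disease":
        if nested_credit["BodyPart"] > 0 and rng.random() < cfg.nesting_rate:
            nested_credit["BodyPart"] -= 1
            b.add(rng.choice(["Se diagnostica ", "Presenta ",
                              "Cuadro compatible con "]))
            b.add_nested(rng.choice(_DISEASE_HEADS) + " de ",
                         rng.choice(_BODYPARTS), "", "Disease", "BodyPart")
            b.add(". ")
        else:
            b.add(rng.choice(["Presenta ", "Con antecedente de ",
                              "En estudio por "]))
            b.add_entity(rng.choice(_DISEASES), "Disease")
            b.add(". ")
    elif label == "BodyPart":
        b.add(rng.choice(["Refiere dolor en ", "Aumento de volumen en ",
                          "Impotencia funcional de "]))
        b.add_entity(rng.choice(_BODYPARTS), "BodyPart")
        b.add(". ")
    elif label == "Medication":
        b.add(rng.choice(["Se indica ", "En tratamiento con ",
                          "Recibe "]))
        b.add_entity(rng.choice(_MEDICATIONS), "Medication")
        b.add(rng.choice([" cada 8 horas. ", " según pauta. ", ". "]))
    else:
        raise ValueError(f"no template for label {label!r}")


def generate_document(index: int, config: GeneratorConfig) -> AnnotatedDocument:
    rng = Random(derive_seed(config.seed, "synth", str(index)))
    subcorpus = "accident" if rng.random() < config.accident_fraction \
        else "disease"
    b = _Builder(doc_id=f"synth-{index:05d}", subcorpus=subcorpus)
    b.add("Paciente consulta por accidente laboral. " if subcorpus == "accident"
          else "Paciente en estudio por enfermedad profesional. ")

    n = round(rng.gauss(config.entities_per_doc_mean,
                        config.entities_per_doc_sd))
    n = max(1, min(config.max_entities_per_doc, n))
    labels = sorted(config.class_weights)
    weights = [config.class_weights[lab] for lab in labels]
    drawn = rng.choices(labels, weights=weights, k=n)
    # nested disease phrases consume BodyPart allocations, keeping the
    # realized per-class counts exactly the multinomial draw
    credit = Counter(lab for lab in drawn if lab == "BodyPart")
    order = [lab for lab in drawn if lab != "BodyPart"]
    rng.shuffle(order)
    for lab in order:
        _realize(lab, b, rng, config, _Resources.get(), credit)
    for _ in range(credit["BodyPart"]):
        _realize("BodyPart", b, rng, config, _Resources.get(), credit)
    doc = b.build()
    return doc.validate()


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Deterministic gold-annotated corpus; per-document randomness is keyed
    by (seed, document index), so any sub-range regenerates identically."""
    return Corpus(documents=[generate_document(i, config)
                             for i in range(config.n_documents)])


Rate = Union[float, dict[str, float]]


class NoiseSpec(BaseModel):
    """Per-class (or global scalar) probabilities of annotation noise."""
    drop: Rate = 0.0
    spurious: Rate = 0.0
    jitter: Rate = 0.0

    @field_validator("drop", "spurious", "jitter")
    @classmethod
    def _prob(cls, v):
        vals = v.values() if isinstance(v, dict) else [v]
        if any(not 0.0 <= x <= 1.0 for x in vals):
            raise ValueError("noise probabilities must lie in [0, 1]")
        return v

    def rate(self, which: str, label: str) -> float:
        v = getattr(self, which)
        return v.get(label, 0.0) if isinstance(v, dict) else v


def _jittered(span: EntitySpan, text: str, rng: Random) -> EntitySpan:
    for _ in range(5):
        ds = rng.choice((-2, -1, 0, 1, 2))
        de = rng.choice((-2, -1, 0, 1, 2))
        if ds == de == 0:
            continue
        s, e = span.start + ds, span.end + de
        if 0 <= s < e <= len(text):
            return EntitySpan(s, e, span.label, span.layer, text[s:e])
    return span


def corrupt_annotations(corpus: Corpus, noise_spec: NoiseSpec,
                        rng: Random) -> Corpus:
    """Altered copy of ``corpus``: spans dropped, jittered, and spurious
    spans added per the noise spec.  With all rates 0 the output equals the
    input.  With drop-only noise at rate d, expected recall against the
    original is 1−d and precision stays 1."""
    out_docs = []
    for doc in corpus:
        text = doc.text
        new_layers: dict[str, list[EntitySpan]] = {"pii": [], "clinical": []}
        for span in doc.spans():
            if rng.random() < noise_spec.rate("drop", span.label):
                continue
            if rng.random() < noise_spec.rate("jitter", span.label):
                span = _jittered(span, text, rng)
            new_layers[span.layer].append(span)
        for span in doc.spans():
            if rng.random() < noise_spec.rate("spurious", span.label):
                length = rng.randint(3, 8)
                s = rng.randrange(0, max(1, len(text) - length))
                e = min(len(text), s + length)
                if s < e:
                    new_layers[span.layer].append(
                        EntitySpan(s, e, span.label, span.layer, text[s:e]))
        out_docs.append(AnnotatedDocument(
            document=doc.document,
            pii_spans=new_layers["pii"],
            clinical_spans=new_layers["clinical"]))
    return Corpus(documents=out_docs)
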