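"""Per-class surrogate rules and document-level pseudonymization."""

import random
import re
import string

import pytest
from scipy import stats as sps

from clindeid.corpus import ValidationError
from clindeid.dates import (DateParseError, parse_full_date, shift_age,
                            shift_date, wrap_year, MONTHS_ES, WEEKDAYS_ES)
from clindeid.idnum import (run_check_digit, surrogate_email, surrogate_id,
                            surrogate_phone, surrogate_run, validate_run,
                            format_run)
from clindeid.pseudo import (SurrogateConfig, pseudonymize_corpus,
                             pseudonymize_document, surrogate_company,
                             surrogate_healthcare_unit, surrogate_location,
                             surrogate_name, surrogate_occupation)
from clindeid.synth import GeneratorConfig, generate_corpus

from conftest import make_doc


@pytest.fixture(scope="module")
def config():
    return SurrogateConfig.default(seed=42)


class TestNames:
    def test_female_all_caps_stays_female_all_caps(self, config):
        rng = random.Random(0)
        out = surrogate_name("MARÍA", "first", config, rng)
        assert out.isupper() and out != "MARÍA"
        assert out.title() in config.first_names_female

    def test_unknown_gender_samples_from_union(self, config):
        rng = random.Random(0)
        union = set(config.first_names_female) | set(config.first_names_male)
        outs = {surrogate_name("Zyxo", "first", config, rng)
                for _ in range(300)}
        assert outs <= union
        # draws reach both gendered lists
        assert outs & set(config.first_names_female)
        assert outs & set(config.first_names_male)

    def test_last_name_never_equals_original(self, config):
        rng = random.Random(1)
        for _ in range(200):
            assert surrogate_name("Rojas", "last", config, rng) != "Rojas"

    def test_empty_pool_is_an_error(self, config):
        cfg = config.model_copy(update={"last_names": ["Rojas"]})
        with pytest.raises(ValidationError, match="pool empty"):
            surrogate_name("Rojas", "last", cfg, random.Random(0))

    def test_uniformity_over_name_list(self, config):
        """Empirical distribution over the 100-name last-name list is
        uniform (chi-square) over 10,000 draws."""
        rng = random.Random(123)
        counts = {}
        for _ in range(10_000):
            n = surrogate_name("Zzyzx", "last", config, rng)
            counts[n] = counts.get(n, 0) + 1
        observed = [counts.get(n, 0) for n in config.last_names]
        chi2, p = sps.chisquare(observed)
        assert p > 0.001


class TestTableRules:
    def test_occupation_worked_examples(self, config):
        assert surrogate_occupation("mecánico industrial", config) == "técnico"
        assert surrogate_occupation("xyz", config) == "trabajador"

    def test_occupation_empty_table_total_fallback(self):
        cfg = SurrogateConfig(seed=0)
        for s in ("a", "mecánico industrial", ""):
            assert surrogate_occupation(s, cfg) == "trabajador"

    def test_company_worked_examples(self, config):
        assert surrogate_company("Colegio Cumbres del Valle", config) == \
            "un centro educativo"
        assert surrogate_company("Empresa Fantasma SA", config) == "una empresa"
        assert surrogate_company("x", SurrogateConfig(seed=0)) == "una empresa"

    def test_healthcare_worked_examples(self, config):
        assert surrogate_healthcare_unit("Hospital La Cisterna", config) == \
            "un hospital"
        cfg = config.model_copy(
            update={"healthcare_table": {"Clínica Sur": "una clínica"}})
        assert surrogate_healthcare_unit("Clínica Sur", cfg) == "una clínica"
        assert surrogate_healthcare_unit("lo que sea",
                                         SurrogateConfig(seed=0)) == "un hospital"


class TestLocations:
    def test_unknown_type_generic_place(self, config):
        assert surrogate_location("Monte Perdido", None, config,
                                  random.Random(0)) == "un lugar"

    def test_singleton_list_is_deterministic(self, config):
        cfg = config.model_copy(
            update={"location_lists": {"city": ["Rancagua"]}})
        assert surrogate_location("Temuco", "city", cfg,
                                  random.Random(0)) == "Rancagua"

    def test_samples_stay_in_configured_list(self, config):
        rng = random.Random(9)
        pool = set(config.location_lists["region"])
        for _ in range(1000):
            out = surrogate_location("Región del Maule", "region", config, rng)
            assert out in pool and out != "Región del Maule"

    def test_empty_configured_list_is_error(self, config):
        cfg = config.model_copy(update={"location_lists": {"city": []}})
        with pytest.raises(ValidationError, match="empty"):
            surrogate_location("Temuco", "city", cfg, random.Random(0))


class TestAges:
    def test_forced_shift_arithmetic(self, config):
        assert shift_age("45 años", config, random.Random(0), shift=3) == \
            "48 años"

    def test_clamp_at_lower_bound(self, config):
        assert shift_age("18 años", config, random.Random(0), shift=-1) == \
            "18 años"

    def test_prefix_preserved(self, config):
        assert shift_age("Edad: 45", config, random.Random(0), shift=2) == \
            "Edad: 47"

    def test_random_draws_never_reproduce_original(self, config):
        rng = random.Random(4)
        for value in (18, 19, 45, 89, 90):
            for _ in range(50):
                assert shift_age(f"{value} años", config, rng) != f"{value} años"

    def test_two_age_entities_may_shift_differently(self, config):
        text = "Paciente de 45 años. Hijo de 21 años."
        doc = make_doc(text, pii=[(12, 19, "Age"), (29, 36, "Age")])
        out = pseudonymize_document(doc, config)
        a, b = [r for r in out.replacement_records if r.label == "Age"]
        shift_a = int(a.surrogate.split()[0]) - 45
        shift_b = int(b.surrogate.split()[0]) - 21
        assert shift_a != 0 and shift_b != 0  # per-entity draws are free


class TestDates:
    def test_day_shift_calendar_arithmetic(self, config):
        out = shift_date("01/03/2019", config, random.Random(0), 30)
        assert out == "31/03/2019"

    def test_year_wrap_into_window(self):
        import datetime as dt
        assert wrap_year(dt.date(2024, 5, 2), (2017, 2023)).year == 2017
        assert wrap_year(dt.date(2016, 2, 29), (2017, 2023)) == \
            dt.date(2023, 2, 28)

    @pytest.mark.parametrize("surface", [
        "05/07/2021", "5-7-2021", "05.07.21", "14 de mayo de 2020",
        "2021/07/05",
    ])
    def test_pattern_preserved_and_year_in_window(self, config, surface):
        out = shift_date(surface, config, random.Random(0), 45)
        d, _ = parse_full_date(out, config.dialect)
        assert 2017 <= d.year <= 2023
        # separator structure survives (digit-run widths may grow, e.g. 5→19)
        assert re.sub(r"\d+", "N", re.sub(r"[a-záéíóúñ]+", "w", out)) == \
            re.sub(r"\d+", "N", re.sub(r"[a-záéíóúñ]+", "w", surface))

    def test_weekday_resampled_to_different_weekday(self, config):
        for _ in range(30):
            out = shift_date("lunes", config, random.Random(_), 10)
            assert out in WEEKDAYS_ES and out != "lunes"
        assert shift_date("Lunes", config, random.Random(0), 10)[0].isupper()

    def test_month_part_resampled(self, config):
        out = shift_date("marzo de 2020", config, random.Random(2), 10)
        month, _, year = out.partition(" de ")
        assert month in MONTHS_ES and month != "marzo"
        assert 2017 <= int(year) <= 2023 and int(year) != 2020

    def test_unparseable_raises(self, config):
        with pytest.raises((DateParseError, ValueError)):
            shift_date("ayer por la tarde", config, random.Random(0), 10)

    def test_monthfirst_dialect(self, config):
        cfg = config.model_copy(update={"dialect": "monthfirst"})
        # 12/26/2023 is day 26 of month 12 under month-first reading
        out = shift_date("12/26/2023", cfg, random.Random(0), 5)
        assert out == "12/31/2023"


class TestRun:
    @pytest.mark.parametrize("body,check", [
        ("12345678", "5"), ("11111111", "1"),
    ])
    def test_check_digit_worked_cases(self, body, check):
        assert run_check_digit(body) == check
        assert validate_run(f"{body}-{check}")

    def test_layout_copied_from_input(self):
        rng = random.Random(0)
        assert "." not in surrogate_run("12345678-5", rng)
        assert surrogate_run("12.345.678-5", rng).count(".") == 2

    def test_surrogates_always_valid(self):
        rng = random.Random(1)
        for _ in range(500):
            assert validate_run(surrogate_run("12.345.678-5", rng))

    def test_non_run_rejected(self):
        with pytest.raises(ValueError):
            surrogate_run("no es un run", random.Random(0))

    def test_format_run_matches_validator(self):
        rng = random.Random(2)
        for _ in range(200):
            body = rng.randint(5_000_000, 26_999_999)
            assert validate_run(format_run(body, dots=bool(rng.getrandbits(1))))


def _signature(s: str) -> str:
    return "".join("9" if c.isdigit() else
                   "A" if c.isalpha() and c.isupper() else
                   "a" if c.isalpha() else c for c in s)


class TestIdPhoneEmail:
    def test_id_structure_preserved(self):
        out = surrogate_id("AB-1234", random.Random(0))
        assert re.fullmatch(r"[A-Z]{2}-\d{4}", out) and out != "AB-1234"

    def test_id_copy_through_without_alnum(self):
        assert surrogate_id("----", random.Random(0)) == "----"

    def test_id_signature_function_oracle(self):
        rng = random.Random(3)
        alphabet = string.ascii_letters + string.digits + "-./ #"
        for _ in range(1000):
            s = "".join(rng.choice(alphabet)
                        for _ in range(rng.randint(1, 12)))
            assert _signature(surrogate_id(s, rng)) == _signature(s)

    def test_phone_prefix_and_layout(self):
        out = surrogate_phone("+56 9 1234 5678", random.Random(0))
        assert re.fullmatch(r"\+56 9 \d{4} \d{4}", out)
        assert out != "+56 9 1234 5678"

    def test_phone_digit_count_preserved(self):
        rng = random.Random(5)
        for surface in ("+56 9 1234 5678", "221234567", "9-8765-4321"):
            out = surrogate_phone(surface, rng)
            assert sum(c.isdigit() for c in out) == \
                sum(c.isdigit() for c in surface)

    def test_phone_too_few_digits_rejected(self):
        with pytest.raises(ValueError):
            surrogate_phone("123", random.Random(0))

    def test_email_shape_and_determinism(self):
        out = surrogate_email("juan.perez@acme.cl", random.Random(7))
        assert re.fullmatch(r"[a-z]+@example\.com", out)
        assert "juan.perez" not in out
        assert out == surrogate_email("juan.perez@acme.cl", random.Random(7))

    def test_email_requires_at(self):
        with pytest.raises(ValueError):
            surrogate_email("sin arroba", random.Random(0))


class TestPseudonymizeDocument:
    def test_same_surface_same_surrogate(self, config):
        text = "Dr. Rojas y luego Dr. Rojas firman."
        doc = make_doc(text, pii=[(4, 9, "LastName"), (22, 27, "LastName")])
        out = pseudonymize_document(doc, config)
        a, b = out.replacement_records
        assert a.surrogate == b.surrogate

    def test_fixed_seed_byte_identical(self, figure_like_doc, config):
        t1 = pseudonymize_document(figure_like_doc, config)
        t2 = pseudonymize_document(figure_like_doc, config)
        assert t1.text == t2.text
        assert [r.surrogate for r in t1.replacement_records] == \
            [r.surrogate for r in t2.replacement_records]

    def test_output_order_invariant_across_corpus(self, config):
        corpus = generate_corpus(GeneratorConfig(seed=31, n_documents=6))
        fwd, _, _ = pseudonymize_corpus(corpus, config)
        from clindeid.corpus import Corpus
        rev, _, _ = pseudonymize_corpus(
            Corpus(documents=list(corpus)[::-1]), config)
        assert {d.doc_id: d.text for d in fwd} == \
            {d.doc_id: d.text for d in rev}

    def test_unparseable_surface_falls_back_to_mask(self, config):
        text = "Fecha estimada primavera pasada."
        doc = make_doc(text, pii=[(15, 31, "FullDate")])
        out = pseudonymize_document(doc, config)
        (rec,) = out.replacement_records
        assert rec.rule == "mask_fallback"
        assert "[Full Date]" in out.text

    def test_missing_resource_list_is_error(self):
        cfg = SurrogateConfig(seed=0)  # no name lists loaded
        doc = make_doc("Dr. Soto", pii=[(4, 8, "LastName")])
        with pytest.raises(ValidationError):
            pseudonymize_document(doc, cfg)

    def test_full_date_interval_preserved_without_wrap(self, config):
        text = "Ingresa el 03/04/2021 y controla el 17/04/2021."
        doc = make_doc(text, pii=[(11, 21, "FullDate"), (36, 46, "FullDate")])
        out = pseudonymize_document(doc, config)
        d1 = parse_full_date(out.replacement_records[0].surrogate, "dayfirst")[0]
        d2 = parse_full_date(out.replacement_records[1].surrogate, "dayfirst")[0]
        if 2017 <= d1.year <= 2023 and 2017 <= d2.year <= 2023:
            assert (d2 - d1).days == 14

    def test_surrogate_map_is_function_within_scope(self, config):
        corpus = generate_corpus(GeneratorConfig(seed=77, n_documents=25))
        _, records, _ = pseudonymize_corpus(corpus, config)
        seen = {}
        for r in records:
            key = (r.doc_id, r.label, r.surface)
            assert seen.setdefault(key, r.surrogate) == r.surrogate

    def test_corpus_scope_consistency(self):
        cfg = SurrogateConfig.default(seed=5, consistency_scope="corpus")
        corpus = generate_corpus(GeneratorConfig(seed=77, n_documents=25))
        _, records, _ = pseudonymize_corpus(corpus, cfg)
        seen = {}
        for r in records:
            if r.label in ("LastName", "FirstName", "Location", "Occupation"):
                key = (r.label, r.surface)
                assert seen.setdefault(key, r.surrogate) == r.surrogate
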