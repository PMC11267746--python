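"""Date and age surrogate rules.

Full dates are shifted by a per-document day offset and year-wrapped into a
configurable window (default 2017–2023) so that no document drifts outside
the plausible period of the corpus.  The rendering preserves the input's
surface pattern: separator, digit widths, 2- vs 4-digit years, Spanish month
names and their casing.  Date parts (a lone month, a year, a weekday, a
day/month pair) are resampled or shifted component-wise.  Ages are shifted
by a small per-entity amount and clamped to a plausible adult range.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from random import Random

MONTHS_ES = ("enero", "febrero", "marzo", "abril", "mayo", "junio",
             "julio", "agosto", "septiembre", "octubre", "noviembre",
             "diciembre")
WEEKDAYS_ES = ("lunes", "martes", "miércoles", "jueves", "viernes",
               "sábado", "domingo")

_NUMERIC_FULL = re.compile(r"^\s*(\d{1,4})([/.\-])(\d{1,2})\2(\d{1,4})\s*$")
_NUMERIC_DAYMONTH = re.compile(r"^\s*(\d{1,2})([/.\-])(\d{1,2})\s*$")
_TEXTUAL_FULL = re.compile(
    r"^\s*(\d{1,2})\s+de\s+([a-záéíóúñ]+)\s+(de(?:l)?\s+)?(\d{4})\s*$",
    re.IGNORECASE)
_MONTH_YEAR = re.compile(
    r"^\s*([a-záéíóúñ]+)\s+(?:de(?:l)?\s+)?(\d{4})\s*$", re.IGNORECASE)
_YEAR = re.compile(r"^\s*(\d{4})\s*$")
_DAYNUM = re.compile(r"^\s*(\d{1,2})\s*$")


class DateParseError(ValueError):
    """Surface could not be interpreted as a date expression."""


def _month_index(name: str) -> int | None:
    low = name.lower()
    if low in MONTHS_ES:
        return MONTHS_ES.index(low) + 1
    # common unaccented misspelling of septiembre
    if low == "setiembre":
        return 9
    return None


def _match_case(word: str, like: str) -> str:
    if like.isupper():
        return word.upper()
    if like[:1].isupper():
        return word[:1].upper() + word[1:]
    return word


def _order(a: int, b: int, dialect: str) -> tuple[int, int]:
    """Return (day, month) for the first two numeric fields."""
    if dialect == "monthfirst":
        return b, a
    if dialect == "auto":
        if a > 12 >= b:
            return a, b
        if b > 12 >= a:
            return b, a
        return a, b  # ambiguous → day-first (Chilean convention)
    return a, b


def parse_full_date(surface: str, dialect: str = "dayfirst"):
    """Parse a full date; returns ``(date, render)`` where ``render(date)``
    reproduces the input's surface pattern for a new date."""
    m = _NUMERIC_FULL.match(surface)
    if m:
        f1, sep, f2, f3 = m.group(1), m.group(2), m.group(3), m.group(4)
        if len(f1) == 4:  # ISO-like year first
            year, month, day = int(f1), int(f2), int(f3)
            widths = (len(f1), len(f2), len(f3))

            def render(d: dt.date, sep=sep, widths=widths) -> str:
                return sep.join([str(d.year).zfill(widths[0]),
                                 str(d.month).zfill(widths[1]),
                                 str(d.day).zfill(widths[2])])
        else:
            day, month = _order(int(f1), int(f2), dialect)
            swapped = (day, month) != (int(f1), int(f2))
            year = int(f3)
            ywidth = len(f3)
            if ywidth <= 2:
                year += 2000
            widths = (len(f1), len(f2))

            def render(d: dt.date, sep=sep, widths=widths, ywidth=ywidth,
                       swapped=swapped) -> str:
                a, b = (d.month, d.day) if swapped else (d.day, d.month)
                y = d.year % 100 if ywidth <= 2 else d.year
                return sep.join([str(a).zfill(widths[0]),
                                 str(b).zfill(widths[1]),
                                 str(y).zfill(ywidth)])
        try:
            return dt.date(year, month, day), render
        except ValueError as exc:
            raise DateParseError(f"{surface!r}: {exc}") from None

    m = _TEXTUAL_FULL.match(surface)
    if m:
        day_s, month_name, de, year_s = m.groups()
        month = _month_index(month_name)
        if month is None:
            raise DateParseError(f"unknown month name in {surface!r}")
        connective = (de or "").strip()

        def render(d: dt.date, month_name=month_name,
                   connective=connective) -> str:
            name = _match_case(MONTHS_ES[d.month - 1], month_name)
            middle = f"{connective} " if connective else ""
            return f"{d.day} de {name} {middle}{d.year}"
        try:
            return dt.date(int(year_s), month, int(day_s)), render
        except ValueError as exc:
            raise DateParseError(f"{surface!r}: {exc}") from None

    raise DateParseError(f"not a full date: {surface!r}")


def wrap_year(d: dt.date, window: tuple[int, int]) -> dt.date:
    """Map the date's year cyclically into ``window``; day clamped for the
    shorter February."""
    lo, hi = window
    if lo <= d.year <= hi:
        return d
    year = lo + (d.year - lo) % (hi - lo + 1)
    day = min(d.day, calendar.monthrange(year, d.month)[1])
    return dt.date(year, d.month, day)


def shift_full_date(surface: str, doc_offset: int, window: tuple[int, int],
                    dialect: str = "dayfirst") -> str:
    d, render = parse_full_date(surface, dialect)
    return render(wrap_year(d + dt.timedelta(days=doc_offset), window))


def shift_date(surface: str, config, rng: Random, doc_offset: int) -> str:
    """Surrogate for a FullDate or DatePart surface.

    Full dates shift by the per-document day offset then year-wrap into the
    window.  Weekday names become a uniformly random *different* weekday;
    months and years are resampled within the window; a bare day number is
    resampled in 1–28.  Raises :class:`DateParseError` when nothing applies
    (the caller falls back to masking).
    """
    window = tuple(config.date_window)
    dialect = config.dialect
    stripped = surface.strip()

    low = stripped.lower()
    if low in WEEKDAYS_ES:
        others = [w for w in WEEKDAYS_ES if w != low]
        return _match_case(rng.choice(others), stripped)

    try:
        return shift_full_date(surface, doc_offset, window, dialect)
    except DateParseError:
        pass

    m = _MONTH_YEAR.match(stripped)
    if m and _month_index(m.group(1)) is not None:
        month_name, year_s = m.group(1), m.group(2)
        month = _month_index(month_name)
        new_month = rng.choice([i for i in range(1, 13) if i != month])
        years = [y for y in range(window[0], window[1] + 1) if y != int(year_s)]
        new_year = rng.choice(years) if years else int(year_s)
        connective = stripped[len(month_name):len(stripped) - len(year_s)]
        name = _match_case(MONTHS_ES[new_month - 1], month_name)
        return f"{name}{connective}{new_year}"

    if _month_index(stripped) is not None:
        month = _month_index(stripped)
        new_month = rng.choice([i for i in range(1, 13) if i != month])
        return _match_case(MONTHS_ES[new_month - 1], stripped)

    m = _YEAR.match(stripped)
    if m:
        year = int(m.group(1))
        years = [y for y in range(window[0], window[1] + 1) if y != year]
        return str(rng.choice(years)) if years else str(year)

    m = _NUMERIC_DAYMONTH.match(stripped)
    if m:
        day, month = _order(int(m.group(1)), int(m.group(3)), dialect)
        sep = m.group(2)
        if 1 <= day <= 31 and 1 <= month <= 12:
            anchor = dt.date((window[0] + window[1]) // 2, month,
                             min(day, 28))
            moved = anchor + dt.timedelta(days=doc_offset)
            a = stripped.split(sep)
            w1, w2 = len(a[0]), len(a[1])
            d1, d2 = ((moved.month, moved.day)
                      if (day, month) != (int(m.group(1)), int(m.group(3)))
                      else (moved.day, moved.month))
            return f"{str(d1).zfill(w1)}{sep}{str(d2).zfill(w2)}"

    m = _DAYNUM.match(stripped)
    if m:
        day = int(m.group(1))
        if 1 <= day <= 31:
            return str(rng.choice([d for d in range(1, 29) if d != day]))

    raise DateParseError(f"cannot interpret date part: {surface!r}")


_AGE_NUM = re.compile(r"\d{1,3}")


def shift_age(surface: str, config, rng: Random,
              shift: int | None = None) -> str:
    """Shift the integer inside an age surface, clamped to the configured
    adult range; the surrounding text of the span is preserved verbatim.

    When ``shift`` is drawn from the configured range (the normal path) and
    clamping would reproduce the original value, the sign of the draw is
    flipped so the surrogate never equals the original.  An explicitly
    forced ``shift`` is applied as-is (clamping may then be a no-op).
    """
    m = _AGE_NUM.search(surface)
    if m is None:
        raise ValueError(f"no integer found in age surface {surface!r}")
    value = int(m.group())
    lo, hi = config.age_clamp
    if shift is None:
        magnitude = rng.randint(config.age_shift_min, config.age_shift_max)
        sign = rng.choice((-1, 1))
        shifted = min(hi, max(lo, value + sign * magnitude))
        if shifted == value:
            shifted = min(hi, max(lo, value - sign * magnitude))
    else:
        shifted = min(hi, max(lo, value + shift))
    return surface[:m.start()] + str(shifted) + surface[m.end():]
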