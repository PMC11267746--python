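"""Surrogates for structured identifiers: RUN, generic IDs, phones, emails.

The RUN (Rol Único Nacional) is the Chilean national identification number:
a 7–8 digit body plus a check character computed by the standard modulo-11
scheme — weights 2..7 cycling from the least-significant digit; the
remainder 11 renders as "0", 10 as "K", anything else as the digit itself.
Surrogate RUNs are random but always carry a valid check character, and the
punctuation layout (thousands dots, hyphen) of the original is copied.
"""

from __future__ import annotations

import re
import string
from random import Random

_RUN_RE = re.compile(
    r"^\s*(\d{1,2}(?:\.\d{3}){2}|\d{7,8})\s*-\s*([0-9kK])\s*$")

#: plausible range for contemporary adult RUN bodies
RUN_BODY_RANGE = (5_000_000, 26_999_999)


def run_check_digit(body: int | str) -> str:
    digits = [int(c) for c in str(body)]
    total = 0
    weight = 2
    for d in reversed(digits):
        total += d * weight
        weight = 2 if weight == 7 else weight + 1
    remainder = 11 - (total % 11)
    if remainder == 11:
        return "0"
    if remainder == 10:
        return "K"
    return str(remainder)


def validate_run(surface: str) -> bool:
    """True when the surface is a well-formed RUN with a correct check digit."""
    m = _RUN_RE.match(surface)
    if not m:
        return False
    body = m.group(1).replace(".", "")
    return run_check_digit(body) == m.group(2).upper()


def format_run(body: int, *, dots: bool, check: str | None = None) -> str:
    check = run_check_digit(body) if check is None else check
    s = str(body)
    if dots:
        parts = []
        while len(s) > 3:
            parts.append(s[-3:])
            s = s[:-3]
        parts.append(s)
        s = ".".join(reversed(parts))
    return f"{s}-{check}"


def surrogate_run(surface: str, rng: Random) -> str:
    """Random valid RUN rendered with the input's dot/hyphen layout."""
    m = _RUN_RE.match(surface)
    if not m:
        raise ValueError(f"not a RUN pattern: {surface!r}")
    original_body = int(m.group(1).replace(".", ""))
    dots = "." in m.group(1)
    body = rng.randint(*RUN_BODY_RANGE)
    while body == original_body:
        body = rng.randint(*RUN_BODY_RANGE)
    return format_run(body, dots=dots)


def surrogate_id(surface: str, rng: Random) -> str:
    """Random alphanumeric string preserving the character-class structure
    (digit→digit, upper→upper, lower→lower, everything else copied)."""
    if not surface:
        raise ValueError("empty ID surface")
    has_alnum = any(c.isalnum() for c in surface)
    for _ in range(100):
        out = []
        for c in surface:
            if c.isdigit():
                out.append(rng.choice(string.digits))
            elif c.isalpha() and c.isupper():
                out.append(rng.choice(string.ascii_uppercase))
            elif c.isalpha():
                out.append(rng.choice(string.ascii_lowercase))
            else:
                out.append(c)
        result = "".join(out)
        if not has_alnum or result != surface:
            return result
    raise ValueError(f"could not derange ID surface {surface!r}")


def surrogate_phone(surface: str, rng: Random) -> str:
    """Randomize phone digits in place, preserving punctuation layout, a
    leading "+56" national prefix, and the mobile marker "9" after it."""
    digit_positions = [i for i, c in enumerate(surface) if c.isdigit()]
    if len(digit_positions) < 7:
        raise ValueError(f"too few digits for a phone number: {surface!r}")
    protected: set[int] = set()
    digits = "".join(surface[i] for i in digit_positions)
    k = 0
    if surface.lstrip().startswith("+56") or digits.startswith("56"):
        if digits.startswith("56"):
            protected.update(digit_positions[:2])
            k = 2
    if len(digits) > k and digits[k] == "9" and len(digits) - k >= 8:
        protected.add(digit_positions[k])
    free = [i for i in digit_positions if i not in protected]
    for _ in range(100):
        chars = list(surface)
        for i in free:
            chars[i] = rng.choice(string.digits)
        result = "".join(chars)
        if result != surface:
            return result
    raise ValueError(f"could not derange phone surface {surface!r}")


_CONSONANTS = "bcdfgjlmnprstv"
_VOWELS = "aeiou"


def surrogate_email(surface: str, rng: Random) -> str:
    """Random pronounceable local part at a reserved example domain; the
    local part's length matches the original's order of magnitude."""
    if "@" not in surface:
        raise ValueError(f"not an email surface: {surface!r}")
    local = surface.split("@", 1)[0]
    n = min(12, max(4, len(local)))
    token = "".join(
        rng.choice(_CONSONANTS if i % 2 == 0 else _VOWELS) for i in range(n))
    return f"{token}@example.com"
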