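"""Offset-preserving tokenizer shared by statistics and BIO export.

Tokens are maximal runs of word characters (letters including accented ones,
digits, underscore); every other non-space character is a single-character
token.  Offsets are retained so the original text can be reconstructed from
tokens plus gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str


def tokenize(text: str) -> list[Token]:
    return [Token(m.start(), m.end(), m.group())
            for m in _TOKEN_RE.finditer(text)]


Tokenizer = Callable[[str], list[Token]]
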