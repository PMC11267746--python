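"""Monotone offset maps for span-replacement edits.

Replacing PII spans by placeholders or surrogates changes text length, so
every other annotation has to be remapped.  An :class:`OffsetMap` records the
edit as an ordered list of segments that jointly cover the source text; each
segment is either *copied* (positions shift by a constant) or *replaced*
(positions collapse to the replacement interval).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass


@dataclass(frozen=True)
class Segment:
    src_start: int
    src_end: int
    tgt_start: int
    tgt_end: int
    replaced: bool

    @property
    def shift(self) -> int:
        return self.tgt_start - self.src_start


@dataclass(frozen=True)
class OffsetMap:
    segments: tuple[Segment, ...]
    src_len: int
    tgt_len: int

    def __post_init__(self) -> None:
        pos, tpos = 0, 0
        for seg in self.segments:
            if seg.src_start != pos or seg.tgt_start != tpos:
                raise ValueError("segments must tile source and target contiguously")
            if not seg.replaced and (seg.src_end - seg.src_start) != (
                    seg.tgt_end - seg.tgt_start):
                raise ValueError("copied segment must preserve length")
            pos, tpos = seg.src_end, seg.tgt_end
        if pos != self.src_len or tpos != self.tgt_len:
            raise ValueError("segments do not cover [0, len)")

    @classmethod
    def identity(cls, n: int) -> "OffsetMap":
        segs = (Segment(0, n, 0, n, False),) if n else ()
        return cls(segments=segs, src_len=n, tgt_len=n)

    @classmethod
    def from_replacements(cls, src_len: int,
                          edits: list[tuple[int, int, int]]) -> "OffsetMap":
        """Build from ``(start, end, new_length)`` edits, sorted and disjoint."""
        segs: list[Segment] = []
        pos, tpos = 0, 0
        for start, end, new_len in sorted(edits):
            if start < pos:
                raise ValueError("edits overlap")
            if start > pos:
                segs.append(Segment(pos, start, tpos, tpos + (start - pos), False))
                tpos += start - pos
            segs.append(Segment(start, end, tpos, tpos + new_len, True))
            pos, tpos = end, tpos + new_len
        if pos < src_len:
            segs.append(Segment(pos, src_len, tpos, tpos + (src_len - pos), False))
            tpos += src_len - pos
        return cls(segments=tuple(segs), src_len=src_len, tgt_len=tpos)

    def map(self, position: int, inside: str = "start") -> int:
        """Map a source position to the target text.

        Positions inside a replaced interval map to the placeholder start
        (``inside="start"``) or its end (``inside="end"``).  ``position ==
        src_len`` maps to ``tgt_len``.
        """
        if not (0 <= position <= self.src_len):
            raise ValueError(f"position {position} out of [0, {self.src_len}]")
        if position == self.src_len:
            return self.tgt_len
        idx = bisect.bisect_right([s.src_start for s in self.segments], position) - 1
        seg = self.segments[idx]
        if not seg.replaced:
            return position + seg.shift
        return seg.tgt_start if inside == "start" else seg.tgt_end

    def map_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open interval; an end strictly inside a replaced region
        maps to the replacement's end so the image interval is well-formed."""
        t0 = self.map(start, inside="start")
        t1 = self.map(end, inside="end") if self._inside_replaced(end) \
            else self.map(end)
        return t0, t1

    def _inside_replaced(self, position: int) -> bool:
        if position >= self.src_len:
            return False
        idx = bisect.bisect_right([s.src_start for s in self.segments], position) - 1
        return self.segments[idx].replaced

    def unit_copied(self, position: int) -> bool:
        """True when the unit interval [position, position+1) is copied verbatim."""
        return not self._inside_replaced(position)

    def compose(self, other: "OffsetMap") -> "OffsetMap":
        """Map of applying ``self`` then ``other`` (self.tgt == other.src).

        A source unit interval survives as copied text only if it is copied
        by both maps; every maximal run of non-surviving units becomes one
        replaced segment.  Equivalent to replaying the two edit scripts as one.
        """
        if self.tgt_len != other.src_len:
            raise ValueError("maps are not composable")
        copied = [self.unit_copied(p) and other.unit_copied(self.map(p))
                  for p in range(self.src_len)]
        f = [other.map(self.map(p)) for p in range(self.src_len + 1)]
        edits: list[tuple[int, int, int]] = []
        p = 0
        while p < self.src_len:
            if copied[p]:
                p += 1
                continue
            q = p
            while q < self.src_len and not copied[q]:
                q += 1
            edits.append((p, q, f[q] - f[p]))
            p = q
        return OffsetMap.from_replacements(self.src_len, edits)


def map_offset(offset_map: OffsetMap, position: int, inside: str = "start") -> int:
    """Functional alias for :meth:`OffsetMap.map`."""
    return offset_map.map(position, inside=inside)
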