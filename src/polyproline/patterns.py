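"""Secondary-structure pattern language and search.

A small pattern grammar over assignment strings:

* conformation letters ``H G I E B T S P -`` match themselves
  (case-insensitively);
* ``*`` and ``X`` each match any single code;
* ``{m,n}`` after a token repeats it between m and n times
  (an "any run up to n" is written ``X{0,n}``).

Patterns compile to anchored regular expressions evaluated inside a
lookahead, so all overlapping occurrences are reported (one match per
start position, longest-first at each start).  Matches never span
chain boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

from .dssp import SS_ALPHABET, SecondaryStructureString

__all__ = [
    "PatternSyntaxError",
    "CompiledPattern",
    "PatternMatch",
    "compile_pattern",
    "search",
]

_CODE_CLASS = "[" + re.escape(SS_ALPHABET) + "]"
_QUANT_RE = re.compile(r"\{(\d+),(\d+)\}")


class PatternSyntaxError(ValueError):
    """Malformed pattern; ``position`` is the offending 0-based index."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class PatternMatch:
    structure_id: str
    chain_id: str
    start_index: int   # 0-based
    end_index: int     # exclusive
    matched_text: str


@dataclass(frozen=True)
class CompiledPattern:
    raw: str
    _regex: re.Pattern

    def finditer(self, codes: str) -> Iterable[tuple[int, int]]:
        """(start, end) spans of all overlapping matches, in order."""
        for m in self._regex.finditer(codes.upper()):
            yield m.start(1), m.end(1)


def compile_pattern(pattern: str) -> CompiledPattern:
    """Compile pattern text to an overlapping-occurrence matcher."""
    if not pattern:
        raise PatternSyntaxError("empty pattern", 0)
    parts: list[str] = []
    i = 0
    n = len(pattern)
    last_token: str | None = None
    while i < n:
        ch = pattern[i]
        up = ch.upper()
        if up in SS_ALPHABET:
            last_token = re.escape(up)
            parts.append(last_token)
            i += 1
        elif up in ("*", "X"):
            last_token = _CODE_CLASS
            parts.append(last_token)
            i += 1
        elif ch == "{":
            if last_token is None:
                raise PatternSyntaxError("quantifier with no preceding token", i)
            m = _QUANT_RE.match(pattern, i)
            if not m:
                raise PatternSyntaxError("malformed quantifier, expected {m,n}", i)
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise PatternSyntaxError(f"quantifier bounds inverted: {lo} > {hi}", i)
            parts[-1] = f"{last_token}{{{lo},{hi}}}"
            last_token = None  # a quantifier cannot stack on a quantifier
            i = m.end()
        else:
            raise PatternSyntaxError(f"unknown pattern character {ch!r}", i)
    regex = re.compile("(?=(" + "".join(parts) + "))")
    return CompiledPattern(raw=pattern, _regex=regex)


def search(
    assignments: Iterable[tuple[str, str, SecondaryStructureString]],
    pattern: Union[str, CompiledPattern],
) -> list[PatternMatch]:
    """All overlapping matches over a collection of chain assignments.

    ``assignments`` yields (structure_id, chain_id, assignment) triples;
    results are ordered by (structure_id, chain_id, start).
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    matches: list[PatternMatch] = []
    entries = sorted(assignments, key=lambda t: (t[0], t[1]))
    for structure_id, chain_id, ss in entries:
        codes = ss.codes if isinstance(ss, SecondaryStructureString) else str(ss)
        for start, end in pattern.finditer(codes):
            matches.append(
                PatternMatch(
                    structure_id=structure_id,
                    chain_id=chain_id,
                    start_index=start,
                    end_index=end,
                    matched_text=codes[start:end],
                )
            )
    return matches
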