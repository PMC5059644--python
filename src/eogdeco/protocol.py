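"""The Kana input protocol: characters encoded as fixed eye-motion codes.

The character inventory is the Japanese Kana alphabet: 48 basic
characters plus two modification marks (dakuten and handakuten, similar
in function to an umlaut).  Each basic character and each mark is
expressed by a fixed combination of four eye motions; a derived (voiced
or semi-voiced) character concatenates its mark code and the base
character's code, giving eight motions.  Because a repeated motion has
no detectable boundary in the EOG signal, every code -- and every legal
concatenation of codes -- avoids two identical adjacent motions.

Only five table entries of the deployed protocol are public:

    /a/  -> up, down, up, center
    /ko/ -> up, center, up, center
    /e/  -> up, left, up, center
    /ka/ -> up, left, right, center
    /ga/ -> right, left, down, center + the /ka/ code

:func:`build_default_protocol` honours these entries verbatim and fills
the remaining characters deterministically with valid codes that follow
the same pattern (first motion not "center", last motion "center").
There are exactly 52 such codes over five motions, enough for the 48
basic characters and 2 marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic_eog import MOTIONS, MotionSequence

__all__ = [
    "Protocol",
    "char_to_motions",
    "word_to_motions",
    "motions_to_word",
    "build_default_protocol",
    "write_protocol",
    "read_protocol",
    "FIXED_CODES",
    "BASIC_KANA",
    "MARKS",
    "DERIVED_KANA",
]

#: Published protocol entries, honoured verbatim by the default protocol.
FIXED_CODES: dict[str, tuple[str, ...]] = {
    "a": ("up", "down", "up", "center"),
    "ko": ("up", "center", "up", "center"),
    "e": ("up", "left", "up", "center"),
    "ka": ("up", "left", "right", "center"),
    "dakuten": ("right", "left", "down", "center"),
}

#: 48 basic Kana (the 46 modern gojuon plus the historical wi/we).
BASIC_KANA = (
    "a i u e o "
    "ka ki ku ke ko sa si su se so ta ti tu te to na ni nu ne no "
    "ha hi hu he ho ma mi mu me mo ya yu yo ra ri ru re ro "
    "wa wi we wo n"
).split()

#: The two modification marks.
MARKS = ("dakuten", "handakuten")

#: Derived characters: mark + base character.
DERIVED_KANA: dict[str, tuple[str, str]] = {}
for _base_row, _voiced_row, _mark in [
    ("ka ki ku ke ko", "ga gi gu ge go", "dakuten"),
    ("sa si su se so", "za zi zu ze zo", "dakuten"),
    ("ta ti tu te to", "da di du de do", "dakuten"),
    ("ha hi hu he ho", "ba bi bu be bo", "dakuten"),
    ("ha hi hu he ho", "pa pi pu pe po", "handakuten"),
]:
    for _b, _v in zip(_base_row.split(), _voiced_row.split()):
        DERIVED_KANA[_v] = (_mark, _b)


def _valid_adjacent(code: Sequence[str]) -> bool:
    return all(a != b for a, b in zip(code, code[1:]))


@dataclass
class Protocol:
    """A character -> motion-code table.

    ``table`` maps every character (basic, mark and derived) to its full
    motion code.  Basic and mark codes have length 4; derived characters
    concatenate a mark code and a basic code (length 8).  ``strict``
    disables the length/structure checks for non-standard tables (e.g.
    a single-motion table used for motion-level recognition).
    """

    table: dict[str, tuple[str, ...]]
    basic: tuple[str, ...] = ()
    marks: tuple[str, ...] = ()
    derived: dict[str, tuple[str, str]] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self):
        self.table = {c: tuple(code) for c, code in self.table.items()}
        for c, code in self.table.items():
            for m in code:
                if m not in MOTIONS:
                    raise ValueError(f"{c!r}: unknown motion {m!r}")
            if not _valid_adjacent(code):
                raise ValueError(f"{c!r}: code repeats an adjacent motion")
        if not self.strict:
            return
        for c in (*self.basic, *self.marks):
            if len(self.table[c]) != 4:
                raise ValueError(f"{c!r}: basic/mark codes must have length 4")
        seen = {}
        for c in (*self.basic, *self.marks):
            code = self.table[c]
            if code in seen:
                raise ValueError(f"duplicate code for {seen[code]!r} and {c!r}")
            seen[code] = c
        for c, (mark, base) in self.derived.items():
            expect = self.table[mark] + self.table[base]
            if self.table.get(c) != expect:
                raise ValueError(f"{c!r}: derived code is not mark+base")
            if not _valid_adjacent(expect):
                raise ValueError(f"{c!r}: mark/base concatenation repeats a motion")

    @property
    def n_basic(self) -> int:
        return len(self.basic)

    def __contains__(self, c: str) -> bool:
        return c in self.table

    def characters(self) -> list[str]:
        return sorted(self.table)

    def restrict(self, chars: Iterable[str]) -> "Protocol":
        """Sub-protocol over a character subset (closure over marks/bases)."""
        chars = set(chars)
        for c in list(chars):
            if c in self.derived:
                mark, base = self.derived[c]
                chars.update((mark, base))
        table = {c: self.table[c] for c in chars}
        return Protocol(
            table=table,
            basic=tuple(c for c in self.basic if c in chars),
            marks=tuple(c for c in self.marks if c in chars),
            derived={c: mb for c, mb in self.derived.items() if c in chars},
            strict=self.strict,
        )


def char_to_motions(c: str, protocol: Protocol) -> MotionSequence:
    """The stored motion code of one character."""
    if c not in protocol.table:
        raise KeyError(f"character {c!r} not in protocol")
    return MotionSequence(protocol.table[c])


def word_to_motions(chars: Sequence[str], protocol: Protocol) -> MotionSequence:
    """Concatenated motion code of a word.

    Raises ``ValueError`` naming the boundary if the concatenation would
    place two identical motions next to each other.
    """
    motions: list[str] = []
    for i, c in enumerate(chars):
        code = protocol.table.get(c)
        if code is None:
            raise KeyError(f"character {c!r} not in protocol")
        if motions and motions[-1] == code[0]:
            raise ValueError(
                f"adjacency violation at character boundary {i-1}|{i} "
                f"({chars[i-1]!r} ends and {c!r} starts with {code[0]!r})"
            )
        motions.extend(code)
    return MotionSequence(motions)


def motions_to_word(motions: Sequence[str], protocol: Protocol) -> list[str]:
    """Parse a motion sequence back into characters.

    Greedy 4-motion framing: each frame is looked up among basic and
    mark codes; a mark consumes the following frame as its base
    character and emits the derived character.
    """
    code_to_char = {protocol.table[c]: c for c in (*protocol.basic, *protocol.marks)}
    derived_lookup = {mb: c for c, mb in protocol.derived.items()}
    out: list[str] = []
    motions = tuple(motions)
    if len(motions) % 4:
        raise ValueError("motion sequence length is not a multiple of 4")
    i = 0
    while i < len(motions):
        frame = motions[i : i + 4]
        c = code_to_char.get(frame)
        if c is None:
            raise ValueError(f"unknown 4-motion code {frame} at position {i}")
        i += 4
        if c in protocol.marks:
            if i >= len(motions):
                raise ValueError(f"dangling mark {c!r} at end of sequence")
            base_frame = motions[i : i + 4]
            base = code_to_char.get(base_frame)
            if base is None or base in protocol.marks:
                raise ValueError(f"mark {c!r} not followed by a basic code at {i}")
            i += 4
            derived = derived_lookup.get((c, base))
            if derived is None:
                raise ValueError(f"no derived character for mark {c!r} + base {base!r}")
            out.append(derived)
        else:
            out.append(c)
    return out


def _all_candidate_codes() -> list[tuple[str, ...]]:
    """All 4-motion codes starting off-center, ending in center, no repeats."""
    non_center = [m for m in MOTIONS if m != "center"]
    codes = []
    for m1 in non_center:
        for m2 in MOTIONS:
            if m2 == m1:
                continue
            for m3 in non_center:
                if m3 == m2:
                    continue
                codes.append((m1, m2, m3, "center"))
    return codes


def build_default_protocol(seed: int = 0) -> Protocol:
    """The full 48-basic + 2-mark protocol.

    The five published codes are honoured verbatim; the remaining
    characters receive deterministic (seeded) assignments from the pool
    of valid codes following the same first-not-center / last-center
    pattern, which makes every concatenation of codes automatically obey
    the adjacency rule.
    """
    pool = _all_candidate_codes()
    assert len(pool) == 52
    rng = np.random.default_rng(seed)
    used = set(FIXED_CODES.values())
    remaining = [c for c in pool if c not in used]
    order = rng.permutation(len(remaining))
    remaining = [remaining[i] for i in order]

    table: dict[str, tuple[str, ...]] = {}
    it = iter(remaining)
    for c in (*BASIC_KANA, *MARKS):
        table[c] = FIXED_CODES.get(c) or next(it)
    for c, (mark, base) in DERIVED_KANA.items():
        table[c] = table[mark] + table[base]
    return Protocol(
        table=table, basic=tuple(BASIC_KANA), marks=MARKS, derived=dict(DERIVED_KANA)
    )


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    """TSV: ``character<TAB>motion,motion,...`` plus a role column."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("character\tmotions\trole\n")
        for c in sorted(protocol.table):
            if c in protocol.marks:
                role = "mark"
            elif c in protocol.derived:
                mark, base = protocol.derived[c]
                role = f"derived:{mark}+{base}"
            elif c in protocol.basic:
                role = "basic"
            else:
                role = "other"
            fh.write(f"{c}\t{','.join(protocol.table[c])}\t{role}\n")


def read_protocol(path: str | Path) -> Protocol:
    """Load and re-validate a protocol TSV."""
    path = Path(path)
    table: dict[str, tuple[str, ...]] = {}
    basic: list[str] = []
    marks: list[str] = []
    derived: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        head = fh.readline().strip().split("\t")
        if head != ["character", "motions", "role"]:
            raise ValueError(f"{path}: bad protocol header {head}")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 fields")
            c, motions, role = parts
            table[c] = tuple(motions.split(","))
            if role == "basic":
                basic.append(c)
            elif role == "mark":
                marks.append(c)
            elif role.startswith("derived:"):
                mark, base = role.split(":", 1)[1].split("+")
                derived[c] = (mark, base)
    return Protocol(
        table=table, basic=tuple(basic), marks=tuple(marks), derived=derived
    )
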