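"""Canonical data model for RNA sequences and secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` with ``1 <= i < j <= n``
in which every position is paired at most once.  A structure is *nested* when
for any two pairs ``(i, j)`` and ``(k, l)`` the condition ``i < k < j`` holds
exactly when ``i < l < j``; two pairs violating this cross on the arc diagram
and form a pseudoknot.

All public coordinates are 1-based and inclusive, matching the convention of
connectivity tables and most structure-annotation formats.  Helpers are
provided for converting to 0-based half-open coordinates for internal use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "RnaSequence",
    "BasePair",
    "SecondaryStructure",
    "ValidationReport",
    "StructureParseError",
    "StructureCapabilityError",
    "parse_dbn",
    "write_dbn",
    "validate",
    "to_arcs",
    "pairs_cross",
]

#: Unambiguous RNA alphabet.
CANONICAL_BASES = frozenset("ACGU")

#: IUPAC one-letter codes accepted in sequences (ambiguity letters included).
IUPAC_LETTERS = frozenset("ACGURYSWKMBDHVN")

#: Watson-Crick and wobble combinations, as unordered base sets.
CANONICAL_PAIRS = frozenset(
    {frozenset("AU"), frozenset("GC"), frozenset("GU")}
)


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed."""


class StructureCapabilityError(ValueError):
    """Raised when a structure exceeds what a representation can encode."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with an identifier.

    Residues are uppercased on construction and ``T`` is normalised to ``U``
    so that DNA-alphabet FASTA files are tolerated.
    """

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        normalised = self.residues.upper().replace("T", "U")
        bad = set(normalised) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-IUPAC "
                f"letters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", normalised)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, idx) -> str:
        return self.residues[idx]

    @property
    def is_unambiguous(self) -> bool:
        """True when every residue is one of A, C, G, U."""
        return set(self.residues) <= CANONICAL_BASES


@dataclass(frozen=True, order=True)
class BasePair:
    """A base pair between 1-based positions ``i < j``."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise ValueError(f"require 1 <= i < j, got ({self.i}, {self.j})")

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)

    def to_zero_based(self) -> tuple[int, int]:
        """0-based (i, j) indices, for internal array work."""
        return (self.i - 1, self.j - 1)

    @classmethod
    def from_zero_based(cls, i0: int, j0: int) -> "BasePair":
        return cls(i0 + 1, j0 + 1)

    def shifted(self, di: int = 0, dj: int = 0) -> "BasePair":
        return BasePair(self.i + di, self.j + dj)


def pairs_cross(a: BasePair, b: BasePair) -> bool:
    """True when two pairs violate the nested criterion (arcs interleave:
    i < k < j < l).  Pairs sharing a position are a paired-once violation,
    not a crossing."""
    i, j = a.i, a.j
    k, l = b.i, b.j
    return i < k < j < l or k < i < l < j


def _as_pairs(pairs: Iterable) -> frozenset[BasePair]:
    out = set()
    for p in pairs:
        if not isinstance(p, BasePair):
            p = BasePair(*p)
        out.add(p)
    return frozenset(out)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs over positions ``1..n``.

    The ``pseudoknotted`` flag is computed on construction and is true
    exactly when some two pairs cross.
    """

    n: int
    pairs: frozenset[BasePair] = field(default_factory=frozenset)
    pseudoknotted: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"length must be non-negative, got {self.n}")
        pairs = _as_pairs(self.pairs)
        object.__setattr__(self, "pairs", pairs)
        report = validate(pairs, self.n)
        if report.duplicated_positions:
            raise ValueError(
                "positions paired more than once: "
                f"{sorted(report.duplicated_positions)}"
            )
        for p in pairs:
            if p.j > self.n:
                raise ValueError(f"pair {p.as_tuple()} exceeds length {self.n}")
        object.__setattr__(
            self, "pseudoknotted", bool(report.crossing_pairs)
        )

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[BasePair]:
        return iter(sorted(self.pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_array(self) -> list[int]:
        """1-based partner per position, 0 meaning unpaired (index 0 unused)."""
        partner = [0] * (self.n + 1)
        for p in self.pairs:
            partner[p.i] = p.j
            partner[p.j] = p.i
        return partner

    def shifted(self, offset: int) -> "SecondaryStructure":
        """Translate all pairs by ``offset`` within a structure of the same length."""
        pairs = {p.shifted(offset, offset) for p in self.pairs}
        return SecondaryStructure(self.n, frozenset(pairs))

    def to_dbn(self) -> str:
        return write_dbn(self)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of structural validity checks; ``ok`` iff no violations."""

    duplicated_positions: tuple[int, ...]
    crossing_pairs: tuple[tuple[BasePair, BasePair], ...]

    @property
    def ok(self) -> bool:
        return not self.duplicated_positions and not self.crossing_pairs


def validate(pairs: Iterable, n: int) -> ValidationReport:
    """Check the paired-once and nested criteria for a pair set.

    Returns a report listing positions used by more than one pair and
    crossing pair couples, separately.  Never raises.
    """
    pair_list = sorted(_as_pairs(pairs))
    seen: dict[int, int] = {}
    duplicated = set()
    for p in pair_list:
        for pos in (p.i, p.j):
            if pos in seen:
                duplicated.add(pos)
            seen[pos] = seen.get(pos, 0) + 1
    crossing = []
    for a_idx, a in enumerate(pair_list):
        for b in pair_list[a_idx + 1:]:
            if b.i >= a.j:
                break
            if pairs_cross(a, b):
                crossing.append((a, b))
    return ValidationReport(
        duplicated_positions=tuple(sorted(duplicated)),
        crossing_pairs=tuple(crossing),
    )


#: Bracket classes recognised by the dot-bracket parser, in writing priority.
_BRACKETS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_OPENERS = {o: idx for idx, (o, _) in enumerate(_BRACKETS)}
_CLOSERS = {c: idx for idx, (_, c) in enumerate(_BRACKETS)}
_UNPAIRED = frozenset(".")


def parse_dbn(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a :class:`SecondaryStructure`.

    Round brackets encode the nested backbone; square, curly and angle
    brackets encode additional (typically pseudoknotted) pair classes.
    Each bracket class is matched independently with a stack.

    Raises :class:`StructureParseError` on unbalanced brackets (naming the
    offending position) or on an illegal character.
    """
    text = text.strip()
    if not text:
        raise StructureParseError("empty structure string")
    stacks: list[list[int]] = [[] for _ in _BRACKETS]
    pairs = set()
    for pos, ch in enumerate(text, start=1):
        if ch in _UNPAIRED:
            continue
        if ch in _OPENERS:
            stacks[_OPENERS[ch]].append(pos)
        elif ch in _CLOSERS:
            stack = stacks[_CLOSERS[ch]]
            if not stack:
                raise StructureParseError(
                    f"unmatched closing bracket {ch!r} at position {pos}"
                )
            pairs.add(BasePair(stack.pop(), pos))
        else:
            raise StructureParseError(
                f"illegal character {ch!r} at position {pos}"
            )
    for idx, stack in enumerate(stacks):
        if stack:
            raise StructureParseError(
                f"unmatched opening bracket {_BRACKETS[idx][0]!r} "
                f"at position {stack[-1]}"
            )
    return SecondaryStructure(len(text), frozenset(pairs))


def write_dbn(s: SecondaryStructure) -> str:
    """Render a structure as a dot-bracket string.

    Crossing pairs are greedily 2-coloured, round brackets first; a crossing
    pattern that needs more than two bracket classes raises
    :class:`StructureCapabilityError` (a documented limit of this notation
    writer).
    """
    chars = ["."] * s.n
    assigned: list[list[BasePair]] = [[], []]
    for p in sorted(s.pairs):
        for cls in range(2):
            if not any(pairs_cross(p, q) for q in assigned[cls]):
                assigned[cls].append(p)
                break
        else:
            raise StructureCapabilityError(
                f"pair {p.as_tuple()} crosses both bracket classes; "
                "structures needing more than two classes are not writable"
            )
    for cls, members in enumerate(assigned):
        opener, closer = _BRACKETS[cls]
        for p in members:
            chars[p.i - 1] = opener
            chars[p.j - 1] = closer
    return "".join(chars)


def to_arcs(s: SecondaryStructure) -> list[tuple[int, int]]:
    """Arc-diagram view: ``(i, j)`` tuples sorted by ``i`` then ``j``."""
    return [p.as_tuple() for p in sorted(s.pairs)]
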