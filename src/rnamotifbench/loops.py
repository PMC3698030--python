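"""Loop decomposition and structural-complexity profiling.

A nested secondary structure partitions into faces of its planar (arc)
diagram: every base pair closes exactly one face, and unpaired bases outside
all pairs form external elements.  Faces are typed as

* hairpin     — no enclosed pair,
* stack       — exactly one enclosed pair with no unpaired bases between,
* bulge       — one enclosed pair, unpaired bases on exactly one side,
* internal    — one enclosed pair, unpaired bases on both sides,
* multiloop   — two or more enclosed pairs (three or more pairs total),

plus *external* elements: maximal runs of consecutive unpaired bases not
enclosed by any pair.

The complexity profile used to stratify benchmarks collapses each maximal
run of stacked pairs into a single helix and counts only hairpins, bulges,
internal loops, multiloops and external elements — so an uninterrupted
stem-loop counts as one loop regardless of its helix length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .core import BasePair, SecondaryStructure

__all__ = [
    "Loop",
    "ComplexityProfile",
    "TierTable",
    "DEFAULT_TIERS",
    "PseudoknotError",
    "decompose",
    "complexity_profile",
    "classify_tier",
]

LOOP_KINDS = ("hairpin", "stack", "bulge", "internal", "multiloop", "external")

#: Kinds counted by the stratification counter (stack faces collapse into helices).
COUNTED_KINDS = ("hairpin", "bulge", "internal", "multiloop", "external")

#: Kinds contributing to the loop-type count (external excluded).
TYPED_KINDS = ("hairpin", "bulge", "internal", "multiloop")


class PseudoknotError(ValueError):
    """Raised when an operation requires a nested (pseudoknot-free) structure."""


@dataclass(frozen=True)
class Loop:
    """One face of the planar diagram, or one external element."""

    kind: str
    closing_pair: BasePair | None
    branch_pairs: tuple[BasePair, ...] = ()
    unpaired: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in LOOP_KINDS:
            raise ValueError(f"unknown loop kind {self.kind!r}")

    @property
    def n_pairs(self) -> int:
        """Total pairs bounding the face (closing pair plus branches)."""
        return (self.closing_pair is not None) + len(self.branch_pairs)


@dataclass(frozen=True)
class ComplexityProfile:
    """Loop/helix census of a structure, for benchmark stratification.

    ``loop_count`` counts hairpins, bulges, internal loops, multiloops and
    external elements; stack faces are collapsed into helices and reported
    via ``helix_count`` / ``stack_face_count`` instead.
    """

    per_kind: dict[str, int] = field(default_factory=dict)
    stack_face_count: int = 0
    helix_count: int = 0

    @property
    def loop_count(self) -> int:
        return sum(self.per_kind.get(k, 0) for k in COUNTED_KINDS)

    @property
    def loop_type_count(self) -> int:
        return sum(1 for k in TYPED_KINDS if self.per_kind.get(k, 0) > 0)

    @property
    def kinds_present(self) -> frozenset[str]:
        return frozenset(k for k in TYPED_KINDS if self.per_kind.get(k, 0) > 0)

    def as_dict(self) -> dict:
        """JSON-serialisable form for run reports."""
        return {
            "loop_count": self.loop_count,
            "loop_type_count": self.loop_type_count,
            "per_kind": {k: self.per_kind.get(k, 0) for k in COUNTED_KINDS},
            "stack_face_count": self.stack_face_count,
            "helix_count": self.helix_count,
        }


def _require_nested(s: SecondaryStructure) -> None:
    if s.pseudoknotted:
        raise PseudoknotError(
            "structure contains crossing pairs; loop decomposition "
            "is defined for nested structures only"
        )


def decompose(s: SecondaryStructure) -> list[Loop]:
    """Decompose a nested structure into loops (faces) and external elements.

    Every base pair closes exactly one face, so the number of non-external
    loops equals the number of pairs.  Faces are listed in order of their
    closing pair; external elements follow, in position order.
    """
    _require_nested(s)
    partner = s.partner_array()
    loops: list[Loop] = []
    for p in sorted(s.pairs):
        branches: list[BasePair] = []
        unpaired: list[int] = []
        k = p.i + 1
        while k < p.j:
            q = partner[k]
            if q == 0:
                unpaired.append(k)
                k += 1
            else:
                branches.append(BasePair(k, q))
                k = q + 1
        loops.append(_type_face(p, branches, unpaired))
    loops.extend(_external_elements(partner, s.n))
    return loops


def _type_face(
    closing: BasePair, branches: list[BasePair], unpaired: list[int]
) -> Loop:
    if not branches:
        kind = "hairpin"
    elif len(branches) == 1:
        child = branches[0]
        left = child.i - closing.i - 1
        right = closing.j - child.j - 1
        if left == 0 and right == 0:
            kind = "stack"
        elif left > 0 and right > 0:
            kind = "internal"
        else:
            kind = "bulge"
    else:
        kind = "multiloop"
    return Loop(kind, closing, tuple(branches), tuple(unpaired))


def _external_elements(partner: list[int], n: int) -> list[Loop]:
    # external = unpaired and not enclosed by any pair
    depth = 0
    elements: list[Loop] = []
    run: list[int] = []
    for pos in range(1, n + 1):
        q = partner[pos]
        if q > pos:
            if run:
                elements.append(Loop("external", None, (), tuple(run)))
                run = []
            depth += 1
        elif 0 < q < pos:
            depth -= 1
        elif depth == 0:
            run.append(pos)
    if run:
        elements.append(Loop("external", None, (), tuple(run)))
    return elements


def helices(s: SecondaryStructure) -> list[list[BasePair]]:
    """Maximal runs of stacked pairs; an isolated pair is a helix of size 1."""
    _require_nested(s)
    pairset = {p.as_tuple() for p in s.pairs}
    out = []
    for p in sorted(s.pairs):
        if (p.i - 1, p.j + 1) in pairset:
            continue  # not a helix start
        run = [p]
        while (run[-1].i + 1, run[-1].j - 1) in pairset:
            run.append(BasePair(run[-1].i + 1, run[-1].j - 1))
        out.append(run)
    return out


def complexity_profile(s: SecondaryStructure) -> ComplexityProfile:
    """Census of loops and helices for tier stratification."""
    loops = decompose(s)
    counts = Counter(lp.kind for lp in loops)
    per_kind = {k: counts.get(k, 0) for k in COUNTED_KINDS}
    return ComplexityProfile(
        per_kind=per_kind,
        stack_face_count=counts.get("stack", 0),
        helix_count=len(helices(s)),
    )


@dataclass(frozen=True)
class TierTable:
    """Inclusive (loop-count, type-count) ranges per named tier.

    ``tiers`` maps a label to ``((loops_lo, loops_hi), (types_lo, types_hi))``.
    Labels are tried in insertion order; the first match wins.  Overlapping
    definitions are rejected on construction.
    """

    tiers: dict[str, tuple[tuple[int, int], tuple[int, int]]]

    def __post_init__(self) -> None:
        items = list(self.tiers.items())
        for a_idx, (a_name, a_rng) in enumerate(items):
            for b_name, b_rng in items[a_idx + 1:]:
                if _ranges_overlap(a_rng, b_rng):
                    raise ValueError(
                        f"tier definitions {a_name!r} and {b_name!r} overlap"
                    )


def _ranges_overlap(a, b) -> bool:
    (al, ah), (atl, ath) = a
    (bl, bh), (btl, bth) = b
    loops = al <= bh and bl <= ah
    types = atl <= bth and btl <= ath
    return loops and types


#: Default stratification: simple stem-loops, intermediate, and complex folds.
DEFAULT_TIERS = TierTable(
    {
        "Ref.1-like": ((1, 2), (1, 2)),
        "Ref.2-like": ((5, 7), (2, 3)),
        "Ref.3-like": ((8, 17), (4, 5)),
    }
)


def classify_tier(
    profile: "ComplexityProfile | tuple[int, int]",
    table: TierTable = DEFAULT_TIERS,
) -> str:
    """First tier whose loop-count and type-count ranges both contain the
    profile; ``"unclassified"`` when none match.

    ``profile`` may also be a plain ``(loop_count, type_count)`` tuple, for
    classifying counts taken from external annotation rather than from
    :func:`complexity_profile`.
    """
    if isinstance(profile, tuple):
        loops, types = profile
    else:
        loops = profile.loop_count
        types = profile.loop_type_count
    for label, ((ll, lh), (tl, th)) in table.tiers.items():
        if ll <= loops <= lh and tl <= types <= th:
            return label
    return "unclassified"
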