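"""Free-energy scoring of secondary structures under three model families.

Three classic model tiers, in increasing fidelity:

* **base-pair model** — the energy of a structure is the sum of per-pair
  terms ``e(i, j)`` depending only on the bonded base types,
  ``Ep(S) = sum over (i,j) in S of e(i, j)``;
* **stacked-pair model** — a pair ``(i, j)`` contributes a constant ``Es``
  if and only if ``(i+1, j-1)`` is also paired, so isolated pairs score
  nothing and a helix of stacking size ``L`` scores ``(L-1) * Es``;
* **loop (nearest-neighbour) model** — the structure is decomposed into
  loops and each loop contributes a term depending on its type and size;
  multiloops use the affine form ``a + b * branches + c * unpaired``.

Numeric parameters are supplied as tables (JSON or YAML files, or built in
code).  The shipped default table is a deliberately small toy set for
demonstrations and tests; it is not a fitted thermodynamic parameter set.
Energies are in arbitrary units; more negative means more stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import RnaSequence, SecondaryStructure
from .loops import decompose, PseudoknotError

__all__ = [
    "PairEnergyTable",
    "LoopParamTable",
    "base_pair_energy",
    "stacked_pair_energy",
    "loop_energy",
    "load_pair_table",
    "load_loop_table",
]


def _norm_combo(a: str, b: str) -> tuple[str, str]:
    """Unordered base combination as a sorted tuple."""
    return tuple(sorted((a.upper(), b.upper())))  # type: ignore[return-value]


@dataclass(frozen=True)
class PairEnergyTable:
    """Per-pair energies ``e(i, j)`` keyed by the unordered base combination.

    A bond may be flagged internal (same strand) or external; separate
    tables can be supplied but by default the same values serve both.
    Unlisted combinations fall back to ``default``.
    """

    internal: dict[tuple[str, str], float] = field(default_factory=dict)
    external: dict[tuple[str, str], float] | None = None
    default: float = 0.0

    @classmethod
    def uniform(cls, value: float) -> "PairEnergyTable":
        return cls(default=value)

    @classmethod
    def from_mapping(
        cls,
        values: dict[str, float],
        default: float = 0.0,
        external: dict[str, float] | None = None,
    ) -> "PairEnergyTable":
        """Build from string keys like ``"GC"`` or ``"AU"`` (order-free)."""
        internal = {_norm_combo(k[0], k[1]): float(v) for k, v in values.items()}
        ext = (
            {_norm_combo(k[0], k[1]): float(v) for k, v in external.items()}
            if external is not None
            else None
        )
        return cls(internal=internal, external=ext, default=default)

    def energy(self, a: str, b: str, external_bond: bool = False) -> float:
        combo = _norm_combo(a, b)
        if external_bond and self.external is not None:
            return self.external.get(combo, self.default)
        return self.internal.get(combo, self.default)

    def scaled(self, k: float) -> "PairEnergyTable":
        return PairEnergyTable(
            internal={c: k * v for c, v in self.internal.items()},
            external=(
                {c: k * v for c, v in self.external.items()}
                if self.external is not None
                else None
            ),
            default=k * self.default,
        )


def base_pair_energy(
    seq: RnaSequence | str,
    s: SecondaryStructure,
    table: PairEnergyTable,
) -> float:
    """Total energy under the base-pair model: sum of e(i, j) over all pairs."""
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    if len(residues) != s.n:
        raise ValueError(
            f"sequence length {len(residues)} != structure length {s.n}"
        )
    return sum(
        table.energy(residues[p.i - 1], residues[p.j - 1]) for p in s.pairs
    )


def stacked_pair_energy(s: SecondaryStructure, es: float) -> float:
    """Total energy under the stacked-pair model.

    Each pair ``(i, j)`` with ``(i+1, j-1)`` also paired contributes ``es``;
    isolated pairs contribute nothing (stacking size is at least 2).
    """
    pairset = {p.as_tuple() for p in s.pairs}
    return es * sum(1 for (i, j) in pairset if (i + 1, j - 1) in pairset)


@dataclass(frozen=True)
class LoopParamTable:
    """Parameters for the loop (nearest-neighbour) model.

    Size-indexed lookups are total functions: sizes beyond the listed range
    extrapolate linearly from the largest listed size at ``*_extra_per_base``
    per additional unpaired base.
    """

    hairpin_by_size: dict[int, float] = field(default_factory=dict)
    hairpin_extra_per_base: float = 0.0
    terminal_mismatch: dict[tuple[str, str], float] = field(default_factory=dict)
    stack_by_pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    stack_default: float = 0.0
    bulge_by_size: dict[int, float] = field(default_factory=dict)
    bulge_extra_per_base: float = 0.0
    bulge_closing_addend: float = 0.0
    internal_by_size: dict[int, float] = field(default_factory=dict)
    internal_extra_per_base: float = 0.0
    internal_adjacent_addend: float = 0.0
    multiloop_offset: float = 0.0        # a
    multiloop_per_branch: float = 0.0    # b
    multiloop_per_unpaired: float = 0.0  # c

    def _sized(
        self, table: dict[int, float], size: int, extra: float
    ) -> float:
        if not table:
            return 0.0
        if size in table:
            return table[size]
        top = max(table)
        if size > top:
            return table[top] + extra * (size - top)
        bottom = min(table)
        return table[bottom]

    def hairpin(self, size: int) -> float:
        return self._sized(self.hairpin_by_size, size, self.hairpin_extra_per_base)

    def stack(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        key = (
            "".join(b.upper() for b in outer),
            "".join(b.upper() for b in inner),
        )
        return self.stack_by_pairs.get(key, self.stack_default)

    def bulge(self, size: int) -> float:
        return (
            self._sized(self.bulge_by_size, size, self.bulge_extra_per_base)
            + self.bulge_closing_addend
        )

    def internal(self, left: int, right: int) -> float:
        return (
            self._sized(
                self.internal_by_size, left + right, self.internal_extra_per_base
            )
            + self.internal_adjacent_addend
        )

    def multiloop(self, branches: int, unpaired: int) -> float:
        return (
            self.multiloop_offset
            + self.multiloop_per_branch * branches
            + self.multiloop_per_unpaired * unpaired
        )


#: Small demonstration parameter set (arbitrary units), not a fitted set.
TOY_LOOP_TABLE = LoopParamTable(
    hairpin_by_size={3: 5.4},
    hairpin_extra_per_base=0.5,
    stack_default=-2.0,
    bulge_by_size={1: 3.0},
    bulge_extra_per_base=0.0,
    internal_by_size={2: 2.0},
    internal_extra_per_base=0.0,
    multiloop_offset=3.4,
    multiloop_per_branch=0.4,
    multiloop_per_unpaired=0.0,
)


def loop_energy(
    seq: RnaSequence | str,
    s: SecondaryStructure,
    table: LoopParamTable = TOY_LOOP_TABLE,
) -> float:
    """Total energy under the loop model: sum over decomposed loops.

    External elements contribute nothing.  Pseudoknotted structures are
    rejected (the decomposition is defined for nested structures).
    """
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    if len(residues) != s.n:
        raise ValueError(
            f"sequence length {len(residues)} != structure length {s.n}"
        )
    total = 0.0
    for lp in decompose(s):
        if lp.kind == "hairpin":
            total += table.hairpin(len(lp.unpaired))
        elif lp.kind == "stack":
            outer = lp.closing_pair
            inner = lp.branch_pairs[0]
            total += table.stack(
                (residues[outer.i - 1], residues[outer.j - 1]),
                (residues[inner.i - 1], residues[inner.j - 1]),
            )
        elif lp.kind == "bulge":
            total += table.bulge(len(lp.unpaired))
        elif lp.kind == "internal":
            child = lp.branch_pairs[0]
            left = child.i - lp.closing_pair.i - 1
            right = lp.closing_pair.j - child.j - 1
            total += table.internal(left, right)
        elif lp.kind == "multiloop":
            total += table.multiloop(lp.n_pairs, len(lp.unpaired))
        # external elements: no contribution
    return total


# ---------------------------------------------------------------------------
# parameter-table files

def _tupleise_pairs(d: dict) -> dict:
    return {tuple(k.split("/")) if "/" in k else (k[:2], k[2:]): float(v)
            for k, v in d.items()}


def load_pair_table(path: str | Path) -> PairEnergyTable:
    """Read a pair-energy table from JSON or YAML.

    Schema: ``{"pairs": {"GC": -3.0, ...}, "default": 0.0,
    "external_pairs": {...}}`` (``external_pairs`` optional).
    """
    doc = _load_doc(path)
    return PairEnergyTable.from_mapping(
        doc.get("pairs", {}),
        default=float(doc.get("default", 0.0)),
        external=doc.get("external_pairs"),
    )


def load_loop_table(path: str | Path) -> LoopParamTable:
    """Read a loop-model parameter table from JSON or YAML.

    Schema keys mirror :class:`LoopParamTable` field names; size-indexed
    tables use string integer keys, stack tables use ``"GC/AU"`` keys.
    """
    doc = _load_doc(path)

    def sized(key):
        return {int(k): float(v) for k, v in doc.get(key, {}).items()}

    return LoopParamTable(
        hairpin_by_size=sized("hairpin_by_size"),
        hairpin_extra_per_base=float(doc.get("hairpin_extra_per_base", 0.0)),
        stack_by_pairs=_tupleise_pairs(doc.get("stack_by_pairs", {})),
        stack_default=float(doc.get("stack_default", 0.0)),
        bulge_by_size=sized("bulge_by_size"),
        bulge_extra_per_base=float(doc.get("bulge_extra_per_base", 0.0)),
        bulge_closing_addend=float(doc.get("bulge_closing_addend", 0.0)),
        internal_by_size=sized("internal_by_size"),
        internal_extra_per_base=float(doc.get("internal_extra_per_base", 0.0)),
        internal_adjacent_addend=float(doc.get("internal_adjacent_addend", 0.0)),
        multiloop_offset=float(doc.get("multiloop_offset", 0.0)),
        multiloop_per_branch=float(doc.get("multiloop_per_branch", 0.0)),
        multiloop_per_unpaired=float(doc.get("multiloop_per_unpaired", 0.0)),
    )


def _load_doc(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
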