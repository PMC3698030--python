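"""Seeded synthetic generators with known ground truth.

Everything the framework consumes — nested structures, structure-compatible
sequences, gapped seed-style alignments, and perturbed predictions — can be
generated here from a seed, so every other module is testable without any
external data.  All generators are bit-reproducible from their parameters
and seed.

The perturbation generator is the sharp end: it builds a prediction from a
reference structure with exact, constructed confusion counts.  Spurious
pairs are sampled outside the one-nucleotide shift neighbourhood of every
reference pair and shifted pairs are required to match only their own
source, so the expected (TP, FP, FN) follow from the construction rather
than probabilistically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BasePair, RnaSequence, SecondaryStructure
from .formats import SeedAlignment
from .loops import DEFAULT_TIERS, TierTable

__all__ = [
    "PerturbationSpec",
    "FixtureTruth",
    "InfeasibleError",
    "random_structure",
    "compatible_sequence",
    "synthetic_alignment",
    "perturb",
]

MIN_HAIRPIN = 3  # minimum unpaired bases closing a hairpin (steric constraint)

#: Watson-Crick and wobble combinations used by the sequence generator.
COMPATIBLE_COMBOS = ("AU", "UA", "GC", "CG", "GU", "UG")


class InfeasibleError(ValueError):
    """Raised when a generator request cannot be satisfied."""


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# random nested structures

def random_structure(
    n: int,
    rng,
    tier: str | None = None,
    tier_table: TierTable = DEFAULT_TIERS,
    p_pair: float = 0.6,
) -> SecondaryStructure:
    """A random valid nested structure of length ``n``.

    Without a tier, the structure is drawn by a recursive process that pairs
    the current position with probability ``p_pair`` whenever a hairpin of at
    least :data:`MIN_HAIRPIN` unpaired bases still fits.  With a tier label
    from ``tier_table``, a structure is assembled whose complexity profile
    falls inside that tier's loop-count and type-count bands; raises
    :class:`InfeasibleError` when ``n`` is too small for the requested tier.
    """
    rng = _rng(rng)
    if tier is None:
        from .core import parse_dbn

        return parse_dbn(_random_region(n, rng, p_pair))
    return _tier_structure(n, rng, tier)


def _random_region(n: int, rng: np.random.Generator, p_pair: float) -> str:
    out: list[str] = []
    remaining = n
    while remaining > 0:
        if remaining >= MIN_HAIRPIN + 2 and rng.random() < p_pair:
            span = int(rng.integers(MIN_HAIRPIN + 2, remaining + 1))
            out.append("(" + _random_region(span - 2, rng, p_pair) + ")")
            remaining -= span
        else:
            out.append(".")
            remaining -= 1
    return "".join(out)


# -- tier-targeted construction ---------------------------------------------

#: Structural recipes per default tier: ranges for hairpins, bulges,
#: internal loops and multiloops chosen so that loop count = h + b + i + m
#: and type count land inside the tier bands.
_TIER_RECIPES = {
    "Ref.1-like": dict(h=(1, 1), b=(0, 1), i=(0, 0), m=(0, 0)),
    "Ref.2-like": dict(h=(4, 5), b=(0, 1), i=(0, 0), m=(1, 1)),
    "Ref.3-like": dict(h=(4, 5), b=(2, 3), i=(2, 3), m=(1, 2)),
}


def _tier_structure(n: int, rng: np.random.Generator, tier: str):
    from .core import parse_dbn

    if tier not in _TIER_RECIPES:
        raise InfeasibleError(
            f"no structural recipe for tier {tier!r}; "
            f"known: {sorted(_TIER_RECIPES)}"
        )
    recipe = _TIER_RECIPES[tier]
    for _ in range(64):
        h = int(rng.integers(recipe["h"][0], recipe["h"][1] + 1))
        b = int(rng.integers(recipe["b"][0], recipe["b"][1] + 1))
        i = int(rng.integers(recipe["i"][0], recipe["i"][1] + 1))
        m = int(rng.integers(recipe["m"][0], recipe["m"][1] + 1))
        if m and h < m + 1:
            continue
        try:
            dbn = _assemble(n, rng, h, b, i, m)
        except InfeasibleError:
            continue
        candidate = parse_dbn(dbn)
        # closed loop: accept only if the profile lands inside the tier
        from .loops import classify_tier, complexity_profile

        if classify_tier(complexity_profile(candidate)) == tier:
            return candidate
    raise InfeasibleError(
        f"could not build a tier {tier!r} structure within length {n}"
    )


def _assemble(
    n: int, rng: np.random.Generator, h: int, b: int, i: int, m: int
) -> str:
    """Assemble a dot-bracket string with exactly h hairpins, b bulges,
    i internal loops and m multiloops (no external bases)."""
    # distribute bulges/internals over the h stems
    stems = []
    gaps_per_stem = [[] for _ in range(h)]
    for _ in range(b):
        gaps_per_stem[int(rng.integers(h))].append("bulge")
    for _ in range(i):
        gaps_per_stem[int(rng.integers(h))].append("internal")
    for gaps in gaps_per_stem:
        stems.append(_Stem(gaps, loop=MIN_HAIRPIN, helix=2))

    units: list = list(stems)
    # chain multiloops: each takes one unit off the front plus the rest
    for k in range(m):
        inner_count = len(units) if k == m - 1 else 2
        if len(units) < 2:
            raise InfeasibleError("multiloop needs at least two branches")
        group, units = units[:inner_count], units[inner_count:]
        units.insert(0, _Multi(group, helix=2, sep=1))
    if m == 0 and len(units) > 1:
        raise InfeasibleError("multiple stems require a multiloop here")
    root = units[0]

    base_len = root.length()
    if base_len > n:
        raise InfeasibleError(
            f"minimal structure needs {base_len} nt, budget is {n}"
        )
    # spend the leftover length on profile-neutral knobs
    budget = n - base_len
    knobs = root.knobs()
    while budget > 0:
        affordable = [k for k in knobs if k.cost <= budget]
        if not affordable:
            raise InfeasibleError("cannot exactly consume the length budget")
        knob = affordable[int(rng.integers(len(affordable)))]
        knob.grow()
        budget -= knob.cost
    return root.render()


class _Knob:
    """One profile-neutral way to spend sequence length."""

    def __init__(self, cost: int, grow):
        self.cost = cost
        self.grow = grow


class _Stem:
    def __init__(self, gaps: list[str], loop: int, helix: int):
        self.gaps = gaps                      # between consecutive helices
        self.loop = loop
        self.helices = [helix] * (len(gaps) + 1)
        self.gap_sizes = [[1, 0] if g == "bulge" else [1, 1] for g in gaps]

    def length(self) -> int:
        return (
            2 * sum(self.helices)
            + self.loop
            + sum(a + bb for a, bb in self.gap_sizes)
        )

    def knobs(self) -> list[_Knob]:
        out = [_Knob(1, self._grow_loop)]
        for idx in range(len(self.helices)):
            out.append(_Knob(2, self._grow_helix(idx)))
        for idx in range(len(self.gaps)):
            out.append(_Knob(1, self._grow_gap(idx)))
        return out

    def _grow_loop(self):
        self.loop += 1

    def _grow_helix(self, idx):
        def grow():
            self.helices[idx] += 1
        return grow

    def _grow_gap(self, idx):
        def grow():
            self.gap_sizes[idx][0] += 1  # bulges stay one-sided
        return grow

    def render(self) -> str:
        core = "." * self.loop
        for idx in range(len(self.helices) - 1, -1, -1):
            length = self.helices[idx]
            core = "(" * length + core + ")" * length
            if idx > 0:
                left, right = self.gap_sizes[idx - 1]
                core = "." * left + core + "." * right
        return core


class _Multi:
    def __init__(self, branches: list, helix: int, sep: int):
        self.branches = branches
        self.helix = helix
        self.seps = [sep] * (len(branches) + 1)

    def length(self) -> int:
        return (
            2 * self.helix
            + sum(br.length() for br in self.branches)
            + sum(self.seps)
        )

    def knobs(self) -> list[_Knob]:
        out = [_Knob(2, self._grow_helix)]
        for idx in range(len(self.seps)):
            out.append(_Knob(1, self._grow_sep(idx)))
        for br in self.branches:
            out.extend(br.knobs())
        return out

    def _grow_helix(self):
        self.helix += 1

    def _grow_sep(self, idx):
        def grow():
            self.seps[idx] += 1
        return grow

    def render(self) -> str:
        parts = ["." * self.seps[0]]
        for idx, br in enumerate(self.branches):
            parts.append(br.render())
            parts.append("." * self.seps[idx + 1])
        inner = "".join(parts)
        return "(" * self.helix + inner + ")" * self.helix


# ---------------------------------------------------------------------------
# structure-compatible sequences

def compatible_sequence(
    s: SecondaryStructure,
    rng,
    identifier: str = "synthetic",
    pair_weights=None,
) -> RnaSequence:
    """A random sequence realising the structure.

    Paired positions draw a Watson-Crick or wobble combination (uniform by
    default, or per ``pair_weights`` over :data:`COMPATIBLE_COMBOS`);
    unpaired positions draw uniformly from A, C, G, U.
    """
    rng = _rng(rng)
    chars = [""] * s.n
    partner = s.partner_array()
    bases = "ACGU"
    for pos in range(1, s.n + 1):
        if chars[pos - 1]:
            continue
        q = partner[pos]
        if q == 0:
            chars[pos - 1] = bases[int(rng.integers(4))]
        else:
            combo = COMPATIBLE_COMBOS[
                int(rng.choice(len(COMPATIBLE_COMBOS), p=pair_weights))
            ]
            chars[pos - 1], chars[q - 1] = combo[0], combo[1]
    return RnaSequence(identifier, "".join(chars))


# ---------------------------------------------------------------------------
# seed-style alignments

def synthetic_alignment(
    n_rows: int,
    structure: SecondaryStructure,
    rng,
    mutation_rate: float = 0.1,
    gap_rate: float = 0.05,
    id_prefix: str = "seq",
) -> SeedAlignment:
    """A gapped alignment of sequences sharing a nested consensus structure.

    All rows derive from one structure-compatible master sequence.  Point
    substitutions are pair-preserving at paired columns (the whole pair is
    redrawn from the compatible combinations) and free at unpaired columns;
    each column independently becomes a gap in a row at ``gap_rate``.  With
    both rates zero all rows are identical to the master.
    """
    rng = _rng(rng)
    if not 0 <= mutation_rate <= 1 or not 0 <= gap_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    master = compatible_sequence(structure, rng, identifier="master")
    partner = structure.partner_array()
    bases = "ACGU"
    rows = []
    for r in range(n_rows):
        chars = list(master.residues)
        for pos in range(1, structure.n + 1):
            q = partner[pos]
            if q and q < pos:
                continue  # handled with its opening partner
            if rng.random() >= mutation_rate:
                continue
            if q == 0:
                chars[pos - 1] = bases[int(rng.integers(4))]
            else:
                combo = COMPATIBLE_COMBOS[int(rng.integers(len(COMPATIBLE_COMBOS)))]
                chars[pos - 1], chars[q - 1] = combo[0], combo[1]
        for pos in range(structure.n):
            if rng.random() < gap_rate:
                chars[pos] = "-"
        rows.append((f"{id_prefix}{r + 1}", "".join(chars)))
    return SeedAlignment(
        tuple(rows), structure.to_dbn(), structure.n
    )


# ---------------------------------------------------------------------------
# perturbed predictions with exact confusion counts

@dataclass(frozen=True)
class PerturbationSpec:
    """How to distort a reference pair set into a prediction.

    ``keep + shift + delete`` must equal the reference pair count.
    """

    keep: int
    shift: int
    delete: int
    add: int
    seed: int

    def __post_init__(self) -> None:
        if min(self.keep, self.shift, self.delete, self.add) < 0:
            raise ValueError("all spec counts must be non-negative")


@dataclass(frozen=True)
class FixtureTruth:
    """Confusion counts implied by a perturbation, by construction."""

    tp: int
    fp: int
    fn: int


def _shift_neighbourhood(p: BasePair) -> set[tuple[int, int]]:
    return {
        (p.i, p.j),
        (p.i + 1, p.j),
        (p.i - 1, p.j),
        (p.i, p.j + 1),
        (p.i, p.j - 1),
    }


def perturb(
    reference: SecondaryStructure, spec: PerturbationSpec
) -> tuple[frozenset[BasePair], FixtureTruth]:
    """Build a prediction realising the spec exactly.

    Kept pairs are copied; shifted pairs move by one nucleotide on one side
    such that they match only their own source under the shift-tolerant
    rule; deleted pairs vanish; spurious pairs are added outside the shift
    neighbourhood of every reference pair.  The returned
    :class:`FixtureTruth` is ``(keep + shift, add, delete)``.

    Raises :class:`InfeasibleError` when the spec cannot be realised on this
    reference (counts that do not sum to the pair count, no collision-free
    shift available, or no room for spurious pairs).
    """
    if spec.keep + spec.shift + spec.delete != reference.n_pairs:
        raise InfeasibleError(
            "keep + shift + delete must equal the reference pair count "
            f"({reference.n_pairs})"
        )
    rng = np.random.default_rng(spec.seed)
    n = reference.n
    ref_pairs = sorted(reference.pairs)
    forbidden = set()
    for p in ref_pairs:
        forbidden |= _shift_neighbourhood(p)

    for _ in range(32):  # retry the random partition on rare dead ends
        order = [ref_pairs[k] for k in rng.permutation(len(ref_pairs))]
        kept = order[: spec.keep]
        to_shift = order[spec.keep: spec.keep + spec.shift]
        predicted: set[BasePair] = set(kept)
        ok = True
        for p in to_shift:
            moves = [(1, 0), (-1, 0), (0, 1), (0, -1)]
            rng.shuffle(moves)
            for di, dj in moves:
                qi, qj = p.i + di, p.j + dj
                if not (1 <= qi < qj <= n):
                    continue
                q = BasePair(qi, qj)
                if q in predicted:
                    continue
                others = [r for r in ref_pairs if r != p]
                if any((qi, qj) in _shift_neighbourhood(r) for r in others):
                    continue
                predicted.add(q)
                break
            else:
                ok = False
                break
        if ok:
            break
    else:
        raise InfeasibleError("no collision-free one-side shift available")

    candidates = [
        (a, bb)
        for a in range(1, n)
        for bb in range(a + 1, n + 1)
        if (a, bb) not in forbidden
        and BasePair(a, bb) not in predicted
    ]
    if len(candidates) < spec.add:
        raise InfeasibleError(
            f"only {len(candidates)} positions available for "
            f"{spec.add} spurious pairs"
        )
    chosen = rng.choice(len(candidates), size=spec.add, replace=False)
    for k in chosen:
        predicted.add(BasePair(*candidates[int(k)]))

    truth = FixtureTruth(
        tp=spec.keep + spec.shift, fp=spec.add, fn=spec.delete
    )
    return frozenset(predicted), truth
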