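"""Readers and writers for the formats the framework touches.

FASTA and Stockholm parsing go through Biopython; the connectivity-table
(CT) dialect and consensus-structure projection are implemented here.

Consensus structure annotations follow the WUSS conventions used in seed
alignments: ``<>``, ``()``, ``[]``, ``{}`` open/close nested pair classes,
matched upper/lowercase letter columns (``Aa``, ``Bb``, ...) encode
pseudoknotted pair classes, and any of ``. , _ : ~ -`` marks an unpaired
or gap column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BasePair,
    RnaSequence,
    SecondaryStructure,
    StructureParseError,
    write_dbn,
)

__all__ = [
    "SeedAlignment",
    "ColumnMap",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_stockholm",
    "write_stockholm",
    "parse_wuss",
    "project_consensus",
    "read_ct",
    "write_ct",
    "read_dbn_file",
    "write_dbn_file",
]

GAP_CHARS = frozenset("-.")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into :class:`RnaSequence` records, order preserved.

    Raises :class:`FormatError` on an empty file or duplicate identifiers.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(RnaSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Sequence[RnaSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Stockholm seed alignments

@dataclass(frozen=True)
class SeedAlignment:
    """A multiple alignment with a consensus secondary structure line."""

    rows: tuple[tuple[str, str], ...]
    consensus_structure: str
    n_cols: int

    def __post_init__(self) -> None:
        for name, row in self.rows:
            if len(row) != self.n_cols:
                raise FormatError(
                    f"row {name!r} has {len(row)} columns, expected {self.n_cols}"
                )
        if len(self.consensus_structure) != self.n_cols:
            raise FormatError(
                "consensus annotation length "
                f"{len(self.consensus_structure)} != column count {self.n_cols}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row_index(self, name: str) -> int:
        for idx, (row_name, _) in enumerate(self.rows):
            if row_name == name:
                return idx
        raise KeyError(name)

    def consensus_pairs(self) -> frozenset[BasePair]:
        return parse_wuss(self.consensus_structure)


def read_stockholm(path: str | Path) -> SeedAlignment:
    """Read a Stockholm 1.0 alignment with its ``#=GC SS_cons`` line.

    Raises :class:`FormatError` when the consensus structure annotation is
    missing or rows are ragged.
    """
    try:
        alignment = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"cannot parse Stockholm file {path}: {exc}") from exc
    ss = alignment.column_annotations.get("secondary_structure")
    if ss is None:
        raise FormatError(
            f"{path} has no consensus secondary-structure (#=GC SS_cons) line"
        )
    rows = tuple((rec.id, str(rec.seq)) for rec in alignment)
    return SeedAlignment(rows, ss, alignment.get_alignment_length())


def write_stockholm(a: SeedAlignment, path: str | Path) -> None:
    """Write a minimal Stockholm 1.0 file with the consensus line."""
    width = max((len(name) for name, _ in a.rows), default=0)
    width = max(width, len("#=GC SS_cons"))
    lines = ["# STOCKHOLM 1.0", ""]
    for name, row in a.rows:
        lines.append(f"{name:<{width}}  {row}")
    lines.append(f"{'#=GC SS_cons':<{width}}  {a.consensus_structure}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# WUSS consensus annotation

_WUSS_OPEN = {"<": ">", "(": ")", "[": "]", "{": "}"}
_WUSS_CLOSE = {v: k for k, v in _WUSS_OPEN.items()}
_WUSS_UNPAIRED = frozenset(".,_:~-")


def parse_wuss(annotation: str) -> frozenset[BasePair]:
    """Base pairs of a WUSS-style consensus line, in 1-based column indices.

    Bracket classes are matched independently; uppercase letters open and
    the matching lowercase letters close pseudoknot classes.
    """
    stacks: dict[str, list[int]] = {}
    pairs = set()
    for col, ch in enumerate(annotation, start=1):
        if ch in _WUSS_UNPAIRED:
            continue
        if ch in _WUSS_OPEN:
            stacks.setdefault(ch, []).append(col)
        elif ch in _WUSS_CLOSE:
            stack = stacks.get(_WUSS_CLOSE[ch], [])
            if not stack:
                raise StructureParseError(
                    f"unmatched {ch!r} at column {col} in consensus annotation"
                )
            pairs.add(BasePair(stack.pop(), col))
        elif ch.isalpha():
            if ch.isupper():
                stacks.setdefault(ch, []).append(col)
            else:
                stack = stacks.get(ch.upper(), [])
                if not stack:
                    raise StructureParseError(
                        f"unmatched pseudoknot letter {ch!r} at column {col}"
                    )
                pairs.add(BasePair(stack.pop(), col))
        else:
            raise StructureParseError(
                f"illegal consensus character {ch!r} at column {col}"
            )
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(
                f"unmatched {opener!r} at column {stack[-1]} in consensus"
            )
    return frozenset(pairs)


# ---------------------------------------------------------------------------
# consensus projection

@dataclass(frozen=True)
class ColumnMap:
    """Mapping from 1-based alignment columns to 1-based ungapped positions.

    ``positions[col - 1]`` is the sequence position for a residue column and
    ``None`` for a gap column; strictly increasing over residue columns.
    """

    positions: tuple[int | None, ...]

    @classmethod
    def from_row(cls, gapped: str) -> "ColumnMap":
        out: list[int | None] = []
        pos = 0
        for ch in gapped:
            if ch in GAP_CHARS:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return cls(tuple(out))

    def __getitem__(self, col: int) -> int | None:
        return self.positions[col - 1]

    @property
    def ungapped_length(self) -> int:
        return sum(1 for p in self.positions if p is not None)


def project_consensus(
    a: SeedAlignment, row: int, canonical_only: bool = False
) -> tuple[RnaSequence, SecondaryStructure]:
    """Project the consensus structure onto one alignment row.

    Consensus pairs are mapped through the row's column map; a pair whose
    columns include a gap in this row is dropped.  With ``canonical_only``
    the projected pairs are additionally restricted to Watson-Crick and
    wobble combinations; by default non-canonical pairs are kept, since the
    truth is taken from the curated alignment.
    """
    name, gapped = a.rows[row]
    cmap = ColumnMap.from_row(gapped)
    residues = "".join(ch for ch in gapped if ch not in GAP_CHARS)
    seq = RnaSequence(name, residues)
    pairs = set()
    for p in a.consensus_pairs():
        pi, pj = cmap[p.i], cmap[p.j]
        if pi is None or pj is None:
            continue
        if canonical_only:
            combo = frozenset((seq[pi - 1], seq[pj - 1]))
            if combo not in ({frozenset("AU"), frozenset("GC"), frozenset("GU")}):
                continue
        pairs.add(BasePair(pi, pj))
    return seq, SecondaryStructure(len(residues), frozenset(pairs))


# ---------------------------------------------------------------------------
# connectivity tables (CT)

#: Column orders for the two supported CT dialects: the common mfold-style
#: order (previous index before next index) and the alternative that lists
#: the next index first.
_CT_DIALECTS = {"mfold": ("prev", "next"), "nextprev": ("next", "prev")}


def write_ct(
    seq: RnaSequence | str,
    s: SecondaryStructure,
    name: str,
    path: str | Path,
    dialect: str = "mfold",
) -> None:
    """Write a 6-column connectivity table.

    Columns: index, base, then the previous/next backbone indices in the
    chosen dialect order, the pairing partner (0 for unpaired), and the
    natural numbering.
    """
    if dialect not in _CT_DIALECTS:
        raise ValueError(f"unknown CT dialect {dialect!r}")
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    if len(residues) != s.n:
        raise ValueError("sequence and structure lengths differ")
    partner = s.partner_array()
    lines = [f"{s.n} {name}"]
    for i in range(1, s.n + 1):
        prev_i, next_i = i - 1, (i + 1) if i < s.n else 0
        a, b = (
            (prev_i, next_i)
            if _CT_DIALECTS[dialect] == ("prev", "next")
            else (next_i, prev_i)
        )
        lines.append(f"{i} {residues[i-1]} {a} {b} {partner[i]} {i}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(
    path: str | Path, dialect: str = "mfold"
) -> tuple[RnaSequence, SecondaryStructure]:
    """Read a 6-column connectivity table.

    Raises :class:`FormatError` on non-contiguous indices or an asymmetric
    pairing column (row i claims j but row j does not claim i).
    """
    if dialect not in _CT_DIALECTS:
        raise ValueError(f"unknown CT dialect {dialect!r}")
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise FormatError(f"empty CT file {path}")
    header = text[0].split(None, 1)
    try:
        n = int(header[0])
    except ValueError as exc:
        raise FormatError(f"bad CT header in {path}: {text[0]!r}") from exc
    name = header[1].strip() if len(header) > 1 else ""
    if len(text) - 1 != n:
        raise FormatError(
            f"{path}: header claims {n} bases, found {len(text) - 1} rows"
        )
    bases = []
    partner = [0] * (n + 1)
    for row_no, line in enumerate(text[1:], start=1):
        cols = line.split()
        if len(cols) < 6:
            raise FormatError(f"{path}: row {row_no} has {len(cols)} columns")
        idx = int(cols[0])
        if idx != row_no:
            raise FormatError(
                f"{path}: expected index {row_no}, found {idx} (indices must "
                "be contiguous 1..n)"
            )
        bases.append(cols[1])
        partner[idx] = int(cols[4])
    pairs = set()
    for i in range(1, n + 1):
        j = partner[i]
        if j == 0:
            continue
        if not (1 <= j <= n) or partner[j] != i:
            raise FormatError(
                f"{path}: asymmetric pairing (row {i} claims {j}, "
                f"row {j if 1 <= j <= n else '?'} does not reciprocate)"
            )
        if i < j:
            pairs.add(BasePair(i, j))
    seq = RnaSequence(name or Path(path).stem, "".join(bases))
    return seq, SecondaryStructure(n, frozenset(pairs))


# ---------------------------------------------------------------------------
# plain dot-bracket text

def read_dbn_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Read dot-bracket text: optional ``>header`` then sequence and/or
    structure lines.  Returns (identifier, sequence, structure) triples;
    sequence may be empty when the file holds structures only."""
    out = []
    ident, seq, struct = "", "", ""
    counter = 0

    def flush():
        nonlocal ident, seq, struct, counter
        if struct:
            counter += 1
            out.append((ident or f"structure_{counter}", seq, struct))
        ident, seq, struct = "", "", ""

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            ident = line[1:].strip()
        elif set(line) <= set("().[]{}<>"):
            struct = line
            flush()
        else:
            seq = line
    flush()
    return out


def write_dbn_file(
    entries: Sequence[tuple[str, str, SecondaryStructure]], path: str | Path
) -> None:
    """Write (identifier, sequence, structure) triples as dot-bracket text."""
    lines = []
    for ident, seq, s in entries:
        lines.append(f">{ident}")
        if seq:
            lines.append(seq)
        lines.append(write_dbn(s))
    Path(path).write_text("\n".join(lines) + "\n")
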