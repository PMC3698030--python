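"""FASTA / Stockholm / CT readers and consensus projection."""

import pytest

from rnamotifbench.core import BasePair, RnaSequence, SecondaryStructure, parse_dbn
from rnamotifbench.fixtures import random_structure, synthetic_alignment
from rnamotifbench.formats import (
    ColumnMap,
    FormatError,
    SeedAlignment,
    parse_wuss,
    project_consensus,
    read_ct,
    read_fasta,
    read_stockholm,
    write_ct,
    write_fasta,
    write_stockholm,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGU\n")
        (seq,) = read_fasta(p)
        assert seq.identifier == "x" and len(seq) == 4

    def test_round_trip_preserves_records(self, tmp_path, rng):
        seqs = [
            RnaSequence(f"s{k}", "".join(rng.choice(list("ACGU"), size=30)))
            for k in range(10)
        ]
        p = tmp_path / "r.fasta"
        write_fasta(seqs, p)
        assert read_fasta(p) == seqs

    def test_duplicate_identifiers_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nAC\n>x\nGU\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)


STO = """\
# STOCKHOLM 1.0

row1          AGGCUU
row2          AG-CU-
#=GC SS_cons  <<..>>
//
"""

STO_NO_SS = STO.replace("#=GC SS_cons  <<..>>\n", "")

STO_PK = """\
# STOCKHOLM 1.0

row1          AAGGCCUU
row2          AAGGCCUU
#=GC SS_cons  <<AA>>aa
//
"""


class TestStockholm:
    def test_toy_alignment(self, tmp_path):
        p = tmp_path / "toy.sto"
        p.write_text(STO)
        a = read_stockholm(p)
        assert a.n_cols == 6 and a.n_rows == 2
        assert a.consensus_structure == "<<..>>"
        assert a.consensus_pairs() == frozenset(
            {BasePair(1, 6), BasePair(2, 5)}
        )

    def test_missing_consensus_line_rejected(self, tmp_path):
        p = tmp_path / "noss.sto"
        p.write_text(STO_NO_SS)
        with pytest.raises(FormatError, match="secondary-structure"):
            read_stockholm(p)

    def test_letter_coded_pseudoknot_columns(self, tmp_path):
        p = tmp_path / "pk.sto"
        p.write_text(STO_PK)
        pairs = read_stockholm(p).consensus_pairs()
        # oracle: match each annotation class independently by hand
        assert pairs == frozenset(
            {BasePair(1, 6), BasePair(2, 5), BasePair(3, 8), BasePair(4, 7)}
        )

    def test_write_read_round_trip(self, tmp_path, rng):
        structure = random_structure(40, rng)
        a = synthetic_alignment(5, structure, rng, gap_rate=0.1)
        p = tmp_path / "rt.sto"
        write_stockholm(a, p)
        b = read_stockholm(p)
        assert b.rows == a.rows
        assert b.consensus_structure == a.consensus_structure


class TestWuss:
    def test_bracket_classes_and_letters(self):
        pairs = parse_wuss("<(A[{.a}])>")
        assert BasePair(3, 7) in pairs  # A..a letter class
        assert len(pairs) == 5

    def test_unmatched_rejected(self):
        with pytest.raises(Exception, match="unmatched"):
            parse_wuss("<<.>")


class TestProjection:
    def test_gapped_row_drops_gap_pairs(self):
        a = SeedAlignment((("r1", "AGGCUU"), ("r2", "AG-CU-")), "<<..>>", 6)
        seq, s = project_consensus(a, 1)
        assert seq.residues == "AGCU"
        # (1,6) dropped at gapped column 6; (2,5) maps to (2,4)
        assert s.pairs == frozenset({BasePair(2, 4)})

    def test_ungapped_row_is_identity(self):
        a = SeedAlignment((("r1", "AGGCUU"),), "<<..>>", 6)
        _, s = project_consensus(a, 0)
        assert s.pairs == parse_dbn("((..))").pairs

    def test_all_gap_row_degenerates(self):
        a = SeedAlignment((("r1", "AGGCUU"), ("gap", "------")), "<<..>>", 6)
        seq, s = project_consensus(a, 1)
        assert len(seq) == 0 and s.n_pairs == 0

    def test_canonical_only_filter(self):
        # projected A-G pair kept by default, dropped under the filter
        a = SeedAlignment((("r1", "AGCUG"),), "(...)", 5)
        _, kept = project_consensus(a, 0)
        assert kept.n_pairs == 1
        _, dropped = project_consensus(a, 0, canonical_only=True)
        assert dropped.n_pairs == 0

    def test_projection_preserves_nestedness(self, rng):
        # gap-dropping a nested consensus can never introduce a crossing
        for _ in range(50):
            structure = random_structure(30, rng)
            a = synthetic_alignment(4, structure, rng, gap_rate=0.2)
            for row in range(a.n_rows):
                _, s = project_consensus(a, row)
                assert not s.pseudoknotted

    def test_column_map_strictly_increasing(self):
        cmap = ColumnMap.from_row("A--GC.U")
        got = [cmap[c] for c in range(1, 8)]
        assert got == [1, None, None, 2, 3, None, 4]
        assert cmap.ungapped_length == 4


class TestCt:
    def test_round_trip(self, tmp_path):
        seq = RnaSequence("hp", "GGGAAACCC")
        s = SecondaryStructure(
            9, {BasePair(1, 9), BasePair(2, 8), BasePair(3, 7)}
        )
        p = tmp_path / "hp.ct"
        write_ct(seq, s, "hp", p)
        seq2, s2 = read_ct(p)
        assert seq2.residues == seq.residues
        assert s2 == s

    def test_all_unpaired_writes_zero_column(self, tmp_path):
        p = tmp_path / "u.ct"
        write_ct("ACGU", SecondaryStructure(4), "u", p)
        rows = p.read_text().strip().splitlines()[1:]
        assert all(r.split()[4] == "0" for r in rows)

    def test_asymmetric_pairing_rejected(self, tmp_path):
        p = tmp_path / "bad.ct"
        lines = ["9 bad"]
        partner = {5: 9}  # row 5 claims 9, row 9 claims nothing
        for i in range(1, 10):
            lines.append(f"{i} A {i-1} {0 if i == 9 else i+1} {partner.get(i, 0)} {i}")
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="asymmetric"):
            read_ct(p)

    def test_dialect_switch_swaps_backbone_columns(self, tmp_path):
        seq = RnaSequence("x", "GAAAC")
        s = SecondaryStructure(5, {BasePair(1, 5)})
        p1, p2 = tmp_path / "a.ct", tmp_path / "b.ct"
        write_ct(seq, s, "x", p1, dialect="mfold")
        write_ct(seq, s, "x", p2, dialect="nextprev")
        row1 = p1.read_text().splitlines()[1].split()
        row2 = p2.read_text().splitlines()[1].split()
        assert (row1[2], row1[3]) == (row2[3], row2[2])
        # both dialects read back to the same structure
        assert read_ct(p1, "mfold")[1] == read_ct(p2, "nextprev")[1]

    def test_ct_and_dbn_agree_on_pair_sets(self, tmp_path, rng):
        for k in range(20):
            s = random_structure(25, rng)
            seq = "A" * 25
            p = tmp_path / f"s{k}.ct"
            write_ct(seq, s, f"s{k}", p)
            _, from_ct = read_ct(p)
            assert from_ct.pairs == parse_dbn(s.to_dbn()).pairs
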