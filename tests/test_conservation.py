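import math

import pytest
from hypothesis import given, settings, strategies as st

from ribomotif.config import DetectionConfig
from ribomotif.conservation import (
    Alignment,
    column_profiles,
    insert_sequence,
    motif_conservation,
    read_stockholm,
    write_stockholm,
)
from ribomotif.synthetic_data import make_alignment, write_stockholm as write_rows


def _aln(rows):
    return Alignment(rows=list(rows))


def _rid(i):
    return ("A", i, "")


class TestStockholmIO:
    def test_toy_round_trip(self, tmp_path):
        p = tmp_path / "toy.sto"
        p.write_text(
            "# STOCKHOLM 1.0\n\n"
            "seq1  GGAACC\n"
            "seq2  GGUACC\n"
            "seq3  GG-ACC\n"
            "#=GC SS_cons  ((..))\n"
            "//\n"
        )
        a = read_stockholm(p)
        assert len(a.rows) == 3 and a.ncols == 6
        assert a.ss_cons == "((..))"
        out = tmp_path / "out.sto"
        write_stockholm(a, out)
        b = read_stockholm(out)
        assert b.rows == a.rows and b.ss_cons == a.ss_cons

    def test_case_and_t_normalized(self, tmp_path):
        p = tmp_path / "t.sto"
        p.write_text("# STOCKHOLM 1.0\n\nseq1  ggTtAa\nseq2  GGUUAA\n//\n")
        a = read_stockholm(p)
        assert a.rows[0][1] == "GGUUAA"

    def test_length_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.sto"
        p.write_text("# STOCKHOLM 1.0\n\nseq1  GGAA\nseq2  GGA\n//\n")
        with pytest.raises(ValueError):
            read_stockholm(p)


class TestColumnProfiles:
    def test_unanimous_column_is_conserved(self):
        a = _aln([(f"s{i}", "A") for i in range(20)])
        p = column_profiles(a)[0]
        assert p.modal_fraction == 1.0 and p.conserved

    def test_exact_95_percent_is_not_conserved(self):
        """19 of 20: exactly 0.95 fails the strictly-greater rule."""
        a = _aln([(f"s{i}", "A") for i in range(19)] + [("s19", "G")])
        p = column_profiles(a)[0]
        assert p.modal_fraction == pytest.approx(0.95)
        assert not p.conserved

    def test_gap_denominator_mode(self):
        rows = [(f"s{i}", "A") for i in range(10)] + [("g", "-")]
        strict = column_profiles(_aln(rows), DetectionConfig())
        assert strict[0].modal_fraction == pytest.approx(10 / 11)
        lenient = column_profiles(
            _aln(rows), DetectionConfig(gaps_in_denominator=False)
        )
        assert lenient[0].modal_fraction == pytest.approx(1.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            column_profiles(_aln([("s", "ACGU")]))

    def test_profiles_invariant_under_row_permutation(self):
        rows = make_alignment(12, 6, [1.0, 0.9, 0.5, 0.75, 1.0, 0.4], seed=5)
        p1 = column_profiles(_aln(rows))
        p2 = column_profiles(_aln(list(reversed(rows))))
        assert [(x.modal_base, x.modal_fraction) for x in p1] == [
            (x.modal_base, x.modal_fraction) for x in p2
        ]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        nrows=st.integers(8, 40),
        fracs=st.lists(st.sampled_from([0.4, 0.6, 0.8, 0.9, 0.95, 0.97, 1.0]),
                       min_size=1, max_size=8),
        seed=st.integers(0, 10_000),
    )
    def test_planted_conservation_recovered(self, nrows, fracs, seed):
        """The generator's deterministic rounding is the oracle: realized
        modal fraction equals round(f * nrows) / nrows for every column."""
        rows = make_alignment(nrows, len(fracs), fracs, seed=seed)
        profiles = column_profiles(_aln(rows))
        for frac, p in zip(fracs, profiles):
            realized = math.floor(frac * nrows + 0.5) / nrows
            assert p.modal_fraction == pytest.approx(realized)
            assert p.conserved == (realized > 0.95)


class TestInsertSequence:
    def _toy(self):
        return _aln([
            ("s1", "GG-AACC"),
            ("s2", "GGUAAC-"),
            ("s3", "GG-AAUC"),
        ])

    def test_identical_sequence_copies_gap_pattern(self):
        a = self._toy()
        seq = a.ungapped(0)
        new, row, rmap = insert_sequence(a, seq)
        assert new.ncols == a.ncols and new.insert_columns == []
        assert new.rows[row][1] == a.rows[0][1]
        assert len(rmap) == len(seq)

    def test_extra_residue_creates_one_insert_column(self):
        a = self._toy()
        seq = a.ungapped(0)
        longer = seq[:3] + "G" + seq[3:]
        new, _row, rmap = insert_sequence(a, longer)
        assert len(new.insert_columns) == 1
        assert new.ncols == a.ncols + 1
        assert len(rmap) == len(longer)

    def test_insertion_is_idempotent_for_present_sequence(self):
        a = self._toy()
        seq = a.ungapped(1)
        new1, _r1, map1 = insert_sequence(a, seq)
        new2, _r2, map2 = insert_sequence(new1, seq, seq_id="again")
        assert new2.ncols == new1.ncols
        assert map1 == map2

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            insert_sequence(Alignment(rows=[]), "ACGU")


class TestMotifConservation:
    def _profiles(self, fracs, modal="A"):
        from ribomotif.conservation import ColumnProfile

        return [
            ColumnProfile(column=i, counts={}, modal_base=modal,
                          modal_fraction=f, conserved=f > 0.95)
            for i, f in enumerate(fracs)
        ]

    def test_fully_conserved(self):
        profs = self._profiles([1.0, 1.0, 1.0])
        rmap = {_rid(i): i for i in range(3)}
        mc = motif_conservation(
            [_rid(0), _rid(1), _rid(2)], rmap, profs,
            structure_base={_rid(i): "A" for i in range(3)},
        )
        assert mc.klass == "fully_conserved"

    def test_mismatching_structure_base_downgrades(self):
        profs = self._profiles([1.0, 1.0])
        rmap = {_rid(0): 0, _rid(1): 1}
        mc = motif_conservation(
            [_rid(0), _rid(1)], rmap, profs,
            structure_base={_rid(0): "G", _rid(1): "A"},
        )
        assert mc.klass == "highly_conserved"

    def test_highly_conserved_at_096(self):
        profs = self._profiles([1.0, 0.96])
        rmap = {_rid(0): 0, _rid(1): 1}
        mc = motif_conservation([_rid(0), _rid(1)], rmap, profs)
        assert mc.klass == "highly_conserved"

    def test_variable_at_060(self):
        profs = self._profiles([1.0, 0.60])
        rmap = {_rid(0): 0, _rid(1): 1}
        mc = motif_conservation([_rid(0), _rid(1)], rmap, profs)
        assert mc.klass == "variable"

    def test_unmapped_residue_is_unassessed(self):
        profs = self._profiles([1.0])
        mc = motif_conservation([_rid(0), _rid(7)], {_rid(0): 0}, profs)
        assert mc.klass == "unassessed"


def test_structure_to_alignment_round_trip(tmp_path):
    """A sequence inserted into a generated alignment maps every residue
    onto a non-insert column whose profile exists."""
    fracs = [1.0, 0.9, 1.0, 0.8, 1.0, 1.0]
    rows = make_alignment(15, 6, fracs, seed=11)
    p = tmp_path / "gen.sto"
    write_rows(rows, p)
    a = read_stockholm(p)
    seq = a.ungapped(3)
    new, _row, rmap = insert_sequence(a, seq)
    profiles = column_profiles(new)
    cols = {pr.column for pr in profiles}
    assert all(c in cols for c in rmap.values())
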