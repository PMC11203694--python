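"""Peptidoform notation parsing and matrix/design/GMT ingestion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msoxome.ingest import (
    AMINO_ACIDS,
    BRACKET,
    MSOX,
    PEAKS_DELTA,
    PeptidoformParseError,
    PeptidoformValidationError,
    SchemaError,
    apply_id_filters,
    detect_dialect,
    parse_peptidoform,
    read_design,
    read_gmt,
    read_peptide_matrix,
    render_peptidoform,
    sample_columns,
)

from conftest import make_table


class TestParsePeptidoform:
    @pytest.mark.parametrize(
        "text,dialect,bare,sites",
        [
            ("LGAD[M]EDLR", None, "LGADMEDLR", {5}),
            ("AEM[M]ELNDR", None, "AEMMELNDR", {4}),  # position-3 M unmodified
            ("LGADMEDLR", None, "LGADMEDLR", set()),
            ("LGADM(+15.99)EDLR", PEAKS_DELTA, "LGADMEDLR", {5}),
            ("LGADM(+15.99)EDLR", None, "LGADMEDLR", {5}),  # auto-detected
            ("GWFEPIVED[M]HR", BRACKET, "GWFEPIVEDMHR", {10}),
            ("[M]K[M]R", BRACKET, "MKMR", {1, 3}),
        ],
    )
    def test_examples(self, text, dialect, bare, sites):
        got_bare, mods = parse_peptidoform(text, dialect)
        assert got_bare == bare
        assert {pos for pos, m in mods if m == MSOX} == sites

    def test_carbamidomethyl_delta(self):
        bare, mods = parse_peptidoform("AC(+57.02)M(+15.99)K", PEAKS_DELTA)
        assert bare == "ACMK"
        assert (2, "CARBAMIDOMETHYL") in mods and (3, MSOX) in mods

    @pytest.mark.parametrize(
        "text,dialect,err",
        [
            ("", None, PeptidoformParseError),
            ("LGAD[MEDLR", None, PeptidoformParseError),  # unclosed bracket
            ("LGAD]M[EDLR", None, PeptidoformParseError),
            ("LGAD[X]EDLR", None, PeptidoformParseError),  # invalid residue
            ("LGAD[A]EDLR", None, PeptidoformValidationError),  # MSox on non-M
            ("LGADA(+15.99)EDLR", PEAKS_DELTA, PeptidoformValidationError),
            ("(+15.99)MK", PEAKS_DELTA, PeptidoformParseError),  # mod before residue
            ("M(+15.99K", PEAKS_DELTA, PeptidoformParseError),  # unclosed paren
        ],
    )
    def test_malformed(self, text, dialect, err):
        with pytest.raises(err):
            parse_peptidoform(text, dialect)

    def test_ambiguous_mixed_notation_requires_explicit_dialect(self):
        with pytest.raises(PeptidoformParseError, match="ambiguous"):
            detect_dialect("LGAD[M]EDC(+57.02)LR")


@st.composite
def peptidoforms(draw):
    n = draw(st.integers(min_value=1, max_value=25))
    seq = "".join(draw(st.sampled_from(AMINO_ACIDS)) for _ in range(n))
    met_positions = [i + 1 for i, ch in enumerate(seq) if ch == "M"]
    oxidized = draw(st.sets(st.sampled_from(met_positions))) if met_positions else set()
    return seq, frozenset((p, MSOX) for p in oxidized)


@given(peptidoforms())
@settings(max_examples=200, derandomize=True)
def test_parse_render_round_trip(pf):
    """Rendering then re-parsing preserves (sequence, MSox sites)."""
    bare, mods = pf
    assert parse_peptidoform(render_peptidoform(bare, mods), BRACKET) == (bare, mods)


class TestReadPeptideMatrix:
    def _write(self, tmp_path, text, name="matrix.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def _design(self, tmp_path):
        lines = ["sample_id\tgenotype\tsex\ttimepoint\tbatch"]
        for i, s in enumerate(["s1", "s2", "s3", "s4"]):
            geno = "WT" if i < 2 else "FAD5X"
            lines.append(f"{s}\t{geno}\tF\t3m\tB1")
        p = tmp_path / "design.tsv"
        p.write_text("\n".join(lines) + "\n")
        return read_design(p)

    def test_toy_file(self, tmp_path):
        design = self._design(tmp_path)
        path = self._write(
            tmp_path,
            "peptide\tprotein\ts1\ts2\ts3\ts4\n"
            "LGAD[M]EDLR\tAPOE\t10\t\t30\t40\n"  # empty cell -> missing
            "LGADMEDLR\tAPOE\t100\t200\t0\t400\n"  # zero -> missing
            "AEMK\tGFAP\t1\t2\t3\t4\n",
        )
        table = read_peptide_matrix(path, design)
        assert len(table) == 3
        assert sample_columns(table) == ["s1", "s2", "s3", "s4"]
        assert np.isnan(table.loc[0, "s2"])
        assert np.isnan(table.loc[1, "s3"])
        # ingest never invents values: finite AUC multiset preserved
        finite = sorted(
            v for v in table[["s1", "s2", "s3", "s4"]].to_numpy().ravel()
            if np.isfinite(v)
        )
        assert finite == [1, 2, 3, 4, 10, 30, 40, 100, 200, 400]

    def test_missing_sample_column_is_schema_error(self, tmp_path):
        design = self._design(tmp_path)
        path = self._write(
            tmp_path, "peptide\tprotein\ts1\ts2\ts3\nAK\tP1\t1\t2\t3\n"
        )
        with pytest.raises(SchemaError, match="s4"):
            read_peptide_matrix(path, design)

    def test_unknown_sample_column_is_schema_error(self, tmp_path):
        design = self._design(tmp_path)
        path = self._write(
            tmp_path,
            "peptide\tprotein\ts1\ts2\ts3\ts4\ts9\nAK\tP1\t1\t2\t3\t4\t5\n",
        )
        with pytest.raises(SchemaError, match="s9"):
            read_peptide_matrix(path, design)

    def test_duplicate_rows_summed(self, tmp_path):
        """Charge-state duplicates collapse to one record with summed AUC."""
        design = self._design(tmp_path)
        path = self._write(
            tmp_path,
            "peptide\tprotein\tscore\ts1\ts2\ts3\ts4\n"
            "LGAD[M]EDLR\tAPOE\t20\t10\t\t30\t40\n"
            "LGAD[M]EDLR\tAPOE\t35\t1\t\t\t4\n",
        )
        table = read_peptide_matrix(path, design)
        assert len(table) == 1
        assert table.loc[0, "s1"] == 11
        assert np.isnan(table.loc[0, "s2"])  # missing in every duplicate
        assert table.loc[0, "s3"] == 30
        assert table.loc[0, "score"] == 35

    def test_multi_accession_keeps_first(self, tmp_path):
        design = self._design(tmp_path)
        path = self._write(
            tmp_path, "peptide\tprotein\ts1\ts2\ts3\ts4\nAK\tP1;P2\t1\t2\t3\t4\n"
        )
        table = read_peptide_matrix(path, design)
        assert table.loc[0, "protein"] == "P1"

    def test_negative_auc_rejected(self, tmp_path):
        design = self._design(tmp_path)
        path = self._write(
            tmp_path, "peptide\tprotein\ts1\ts2\ts3\ts4\nAK\tP1\t-5\t2\t3\t4\n"
        )
        with pytest.raises(SchemaError, match="negative"):
            read_peptide_matrix(path, design)


class TestIdFilters:
    def test_score_threshold(self):
        table = make_table(
            [("AK", "P1", [1]), ("CK", "P2", [1]), ("DK", "P3", [1])],
            ["s1"],
            scores=[14.9, 15.0, 40.0],
        )
        out = apply_id_filters(table, min_score=15)
        assert list(out["bare_sequence"]) == ["CK", "DK"]

    def test_disabled_filter_is_identity(self):
        table = make_table([("AK", "P1", [1])], ["s1"], scores=[np.nan])
        out = apply_id_filters(table, min_score=None)
        pd.testing.assert_frame_equal(out, table)

    def test_empty_table(self):
        table = make_table([], ["s1"])
        assert len(apply_id_filters(table)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_id_filters(make_table([], ["s1"]), min_score=-1)

    @given(st.lists(st.floats(min_value=0, max_value=100), max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_idempotent(self, scores):
        table = make_table(
            [("AK", f"P{i}", [1]) for i in range(len(scores))],
            ["s1"],
            scores=scores,
        )
        once = apply_id_filters(table)
        twice = apply_id_filters(once)
        pd.testing.assert_frame_equal(once, twice)


class TestGmt:
    def test_two_line_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc one\tP1\tP2\nT2\tdesc two\tP2\tP3\tP4\n")
        sets = read_gmt(p)
        assert len(sets) == 2
        assert sets.members("T2") == frozenset({"P2", "P3", "P4"})

    def test_short_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\tdesc\tP1\nT2\tonlydesc\n")
        with pytest.raises(SchemaError, match=":2"):
            read_gmt(p)

    def test_duplicate_term_errors(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\ta\tP1\nT1\tb\tP2\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_gmt(p)

    def test_repeated_member_stored_once(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("T1\ta\tP1\tP1\tP2\n")
        assert read_gmt(p).members("T1") == frozenset({"P1", "P2"})
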