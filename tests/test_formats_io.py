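"""Parsers, serializers and variant-to-model mapping."""

import logging

import pytest

from strudel.formats_io import (
    ChainError, CleanModel, FormatError, MismatchError, Residue, ScoreTable,
    UNMAPPED, ValidationError, VariantSpec, map_variant_to_model, parse_pssm,
    parse_probe_output, parse_rosetta_scorefile, read_predictions,
    read_variant_table, standardize_structure, write_predictions,
    write_probe_output, write_pssm, write_scorefile, write_variant_table,
)
from strudel.synthetic import generate_profile, make_stub_pdb


# ---------------------------------------------------------------------------
# VariantSpec and variant tables
# ---------------------------------------------------------------------------


class TestVariantSpec:
    def test_valid_substitution(self):
        v = VariantSpec("IL6", 204, "S", "P")
        assert (v.protein_id, v.position, v.native_aa, v.variant_aa) == \
            ("IL6", 204, "S", "P")
        assert v.label == "unknown"
        assert v.name == "S204P"

    @pytest.mark.parametrize("kwargs", [
        dict(protein_id="GCK", position=168, native_aa="T", variant_aa="T"),
        dict(protein_id="X", position=0, native_aa="A", variant_aa="G"),
        dict(protein_id="X", position=1, native_aa="B", variant_aa="G"),
        dict(protein_id="X", position=1, native_aa="A", variant_aa="Z"),
        dict(protein_id="X", position=1, native_aa="A", variant_aa="G",
             label="damaging"),
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            VariantSpec(**kwargs)


class TestVariantTable:
    def test_read_rows(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("protein\tposition\tnative\tvariant\n"
                        "IL6\t204\tS\tP\n"
                        "GCK\t168\tT\tP\n")
        variants = read_variant_table(path)
        assert variants[0] == VariantSpec("IL6", 204, "S", "P")
        assert variants[1].name == "T168P"

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("protein\tposition\tnative\nIL6\t204\tS\n")
        with pytest.raises(FormatError):
            read_variant_table(path)

    def test_invalid_rows_rejected_with_row_numbers(self, tmp_path, caplog):
        path = tmp_path / "v.tsv"
        path.write_text("protein\tposition\tnative\tvariant\n"
                        "IL6\t204\tS\tP\n"
                        "GCK\t168\tT\tT\n"       # identity substitution
                        "A\t5\tL\tI\n"
                        "B\t9\tK\tR\n")
        with caplog.at_level(logging.WARNING, logger="strudel.formats_io"):
            variants = read_variant_table(path)
        assert len(variants) == 3
        rejected = [r for r in caplog.records if "rejected" in r.getMessage()]
        assert len(rejected) == 1
        assert "row 2" in rejected[0].getMessage()

    def test_round_trip(self, tmp_path):
        variants = [VariantSpec("P1", 3, "A", "V", "deleterious"),
                    VariantSpec("P2", 9, "K", "E", "neutral")]
        path = tmp_path / "v.tsv"
        write_variant_table(variants, path)
        assert read_variant_table(path) == variants


# ---------------------------------------------------------------------------
# ASCII PSSM
# ---------------------------------------------------------------------------

HAND_PSSM = """
Last position-specific scoring matrix computed
            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M  -1 -2 -3 -4 -5 -6 -7 -8 -9 -1 -2 -3  8 -5 -6 -7 -8 -9 -1 -2   0  0  0  0  0  0  0  0  0  0  0  0 99  0  0  0  0  0  0  0  2.10 0.30
    2 K   0  1  0 -1  0  2 -1  0  0 -1 -1  5 -1 -2 -1  0  0 -3 -2 -1   5  8  5  2  1  9  3  4  2  1  2 40  1  1  2  6  5  1  1  1  0.40 0.10
    3 V  -1 -3 -3 -3 -1 -2 -3 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4   1  0  0  0  1  0  0  0  0 20 10  1  5  2  1  1  5  0  2 51  1.50 0.80
"""


class TestPssm:
    def test_hand_written_values_read_verbatim(self):
        profile = parse_pssm(HAND_PSSM, protein_id="toy")
        assert profile.sequence == "MKV"
        assert profile.info_content[0] == 2.10
        assert profile.log_odds_of(1, "M") == 8
        assert profile.log_odds_of(2, "K") == 5
        assert profile.log_odds_of(3, "V") == 4
        assert profile.weights == (0.30, 0.10, 0.80)

    def test_empty_body_is_format_error(self):
        header_only = "\nLast position-specific scoring matrix computed\n  A R N\n"
        with pytest.raises(FormatError):
            parse_pssm(header_only)

    def test_wrong_field_count_is_dialect_error(self):
        bad = HAND_PSSM.replace("  2.10 0.30", "  2.10")
        with pytest.raises(FormatError, match="42"):
            parse_pssm(bad)

    def test_round_trip_preserves_profile(self):
        profile = generate_profile("MKTAYIAK", conserved_positions=(3, 6), seed=5,
                                   protein_id="toy")
        text = write_pssm(profile)
        assert parse_pssm(text, protein_id="toy") == profile


# ---------------------------------------------------------------------------
# Score files
# ---------------------------------------------------------------------------


class TestScorefile:
    def test_bare_table(self):
        text = ("total_score fa_rep hbond_sc\n"
                "-100.5 20.0 -5.0\n"
                "-98.0 22.5 -4.5\n")
        table = parse_rosetta_scorefile(text, "fast_relax")
        assert table.n_decoys == 2
        assert table.terms == ("total_score", "fa_rep", "hbond_sc")
        assert table.column("fa_rep") == (20.0, 22.5)

    def test_score_token_dialect_with_description(self):
        text = ("SEQUENCE: ABC\n"
                "SCORE: total_score fa_rep description\n"
                "SCORE: -1.0 2.0 d_0001\n")
        table = parse_rosetta_scorefile(text, "ddg_monomer")
        assert table.terms == ("total_score", "fa_rep")
        assert table.descriptions == ("d_0001",)

    def test_single_all_zero_decoy(self):
        table = parse_rosetta_scorefile("a b c\n0 0 0\n", "fast_relax")
        assert table.decoys == ((0.0, 0.0, 0.0),)

    @pytest.mark.parametrize("text,match", [
        ("total_score\n", "zero decoys"),
        ("total_score fa_rep\n-1.0\n", "fields"),
        ("total_score\nNaN-ish\n", "non-numeric"),
    ])
    def test_malformed_tables(self, text, match):
        with pytest.raises(FormatError, match=match):
            parse_rosetta_scorefile(text, "fast_relax")

    @pytest.mark.parametrize("dialect", ["score", "bare"])
    def test_round_trip(self, dialect):
        table = ScoreTable(protocol="fast_relax", terms=("a", "b"),
                           decoys=((1.25, -3.5), (0.1, 2.0)),
                           descriptions=("x", "y"))
        text = write_scorefile(table, dialect=dialect)
        assert parse_rosetta_scorefile(text, "fast_relax") == table


# ---------------------------------------------------------------------------
# Structure standardization and mapping
# ---------------------------------------------------------------------------


def _model(sequence="ACDEFGHIK", start=1, offset_map=None):
    residues = tuple(
        Residue(number=start + i, amino_acid=aa, atoms=())
        for i, aa in enumerate(sequence)
    )
    return CleanModel(model_id="m", chain="A", residues=residues,
                      offset_map=offset_map or {})


class TestStandardize:
    def test_heteroatoms_and_duplicate_chains_removed(self):
        seq = "MKTAYIAK"
        pdb = make_stub_pdb(seq, chain="A", het_records=1) \
            .replace("END\n", "") + make_stub_pdb(seq, chain="B")
        clean = standardize_structure(pdb)
        assert clean.chain == "A"
        assert clean.sequence == seq
        assert all(len(r.atoms) == 1 for r in clean.residues)

    def test_already_clean_model_unchanged(self):
        seq = "MKTAYIAK"
        clean = standardize_structure(make_stub_pdb(seq))
        assert clean.sequence == seq
        assert [r.number for r in clean.residues] == list(range(1, len(seq) + 1))

    def test_idempotent(self):
        pdb = make_stub_pdb("MKTAYIAK", het_records=2)
        once = standardize_structure(pdb)
        # re-render the cleaned model and standardize again
        rerendered = make_stub_pdb(once.sequence, chain=once.chain)
        twice = standardize_structure(rerendered)
        assert twice.sequence == once.sequence
        assert [r.number for r in twice.residues] == \
            [r.number for r in once.residues]

    def test_offset_map_from_sliding_window(self):
        ref = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3    # 99 residues
        pdb = make_stub_pdb(ref, start_resnum=5)
        clean = standardize_structure(pdb, reference_sequence=ref)
        assert clean.offset_map[1] == 5
        assert clean.offset_map[len(ref)] == len(ref) + 4

    def test_absent_chain_is_chain_error(self):
        with pytest.raises(ChainError):
            standardize_structure(make_stub_pdb("MKTA"), chain="Q")

    def test_requested_chain_kept(self):
        pdb = make_stub_pdb("MKTA", chain="A").replace("END\n", "") + \
            make_stub_pdb("GGGG", chain="B")
        clean = standardize_structure(pdb, chain="B")
        assert clean.sequence == "GGGG"


class TestMapVariant:
    def test_offset_arithmetic(self):
        model = _model("ACDEFGHIKL", start=5,
                       offset_map={i: i + 4 for i in range(1, 11)})
        variant = VariantSpec("P", 10, "L", "M")
        assert map_variant_to_model(variant, model) == 14

    def test_outside_coverage_is_unmapped(self):
        model = _model("ACDEF", offset_map={i: i for i in range(1, 6)})
        assert map_variant_to_model(VariantSpec("P", 300, "A", "G"), model) == UNMAPPED

    def test_native_mismatch_raises(self):
        model = _model("AAAAA", offset_map={i: i for i in range(1, 6)})
        with pytest.raises(MismatchError):
            map_variant_to_model(VariantSpec("P", 2, "S", "G"), model)

    def test_never_returns_mismatching_residue(self):
        # property: a successful mapping always lands on the native residue
        seq = "ACDEFGHIKLMNPQRSTVWY"
        model = _model(seq, offset_map={i: i for i in range(1, 21)})
        for pos, aa in enumerate(seq, start=1):
            other = "A" if aa != "A" else "C"
            got = map_variant_to_model(VariantSpec("P", pos, aa, other), model)
            assert model.residue_by_number(got).amino_acid == aa


# ---------------------------------------------------------------------------
# Surface tables and predictions
# ---------------------------------------------------------------------------


class TestProbeTable:
    def test_round_trip(self):
        areas = {42: 55.2, 7: 0.0, 100: 149.9}
        assert parse_probe_output(write_probe_output(areas)) == areas

    def test_comments_ignored(self):
        assert parse_probe_output("# header\n42 ALA 55.2\n") == {42: 55.2}


class TestPredictionsFile:
    @staticmethod
    def _rows():
        return [
            {"protein": "IL6", "position": 204, "native": "S", "variant": "P",
             "score": 0.835, "label": "deleterious",
             "top_structural_terms": "ddg_dslf_fa13",
             "interpretation": "predicted deleterious (0.835); evidence: disulfide"},
        ]

    def test_score_printed_with_three_decimals(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_predictions(self._rows(), path)
        assert "0.835" in path.read_text()

    def test_empty_predictions_header_only(self, tmp_path):
        path = tmp_path / "p.tsv"
        write_predictions([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("protein\t")

    def test_round_trip(self, tmp_path):
        rows = self._rows() * 1
        for i in range(9):
            row = dict(rows[0])
            row["position"] = 10 + i
            row["score"] = round(0.05 + 0.1 * i, 3)
            rows.append(row)
        path = tmp_path / "p.tsv"
        write_predictions(rows, path, provenance={"seed": 1})
        back = read_predictions(path)
        assert len(back) == 10
        for orig, rec in zip(rows, back):
            assert rec["position"] == orig["position"]
            assert rec["score"] == pytest.approx(orig["score"], abs=5e-4)
            assert rec["interpretation"] == orig["interpretation"]
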