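import math

import pytest

from cpifusion.data_io import (
    CPIDataset,
    CompoundRecord,
    InteractionRecord,
    ProteinRecord,
    RowParseError,
    SchemaError,
    load_activity_csv,
    load_cpi_table,
    pec50_from_concentration,
    read_fasta,
    read_predictions,
    read_smi,
    write_predictions,
)

HEADER = "compound_id,smiles,protein_id,sequence,affinity\n"


def write(tmp_path, text, name="table.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadCpiTable:
    def test_header_only_gives_empty_dataset(self, tmp_path):
        ds = load_cpi_table(write(tmp_path, HEADER))
        assert ds.n_interactions == 0
        assert ds.scale_tag is None

    def test_duplicate_pairs_collapsed_keeping_first(self, tmp_path):
        rows = (
            "c1,CCO,p1,ACDE,1.5\n"
            "c2,CCC,p1,ACDE,2.5\n"
            "c1,CCO,p2,MKVL,3.5\n"
            "c1,CCO,p1,ACDE,9.9\n"  # duplicate pair, different affinity
            "c2,CCC,p2,MKVL,4.5\n"
        )
        ds = load_cpi_table(write(tmp_path, HEADER + rows))
        assert ds.n_interactions == 4
        first = {(i.compound_id, i.protein_id): i.affinity for i in ds.interactions}
        assert first[("c1", "p1")] == 1.5  # first occurrence wins

    def test_missing_column_is_schema_error(self, tmp_path):
        p = write(tmp_path, "compound_id,smiles,protein_id,affinity\nc1,CCO,p1,1.0\n")
        with pytest.raises(SchemaError, match="sequence"):
            load_cpi_table(p)

    def test_unparseable_affinity_reports_line_number(self, tmp_path):
        p = write(tmp_path, HEADER + "c1,CCO,p1,ACDE,1.0\nc2,CCC,p2,MKVL,oops\n")
        with pytest.raises(RowParseError, match="line 3"):
            load_cpi_table(p)

    def test_schema_mapping_and_tab_delimiter(self, tmp_path):
        text = "cid\tSMILES\tpid\tseq\tkiba\nc1\tCCO\tp1\tACDE\t2.0\n"
        ds = load_cpi_table(
            write(tmp_path, text),
            schema={"compound_id": "cid", "smiles": "SMILES", "protein_id": "pid",
                    "sequence": "seq", "affinity": "kiba"},
            delimiter="\t",
        )
        assert ds.n_interactions == 1
        assert ds.compound("c1").smiles == "CCO"

    def test_ids_synthesized_when_absent(self, tmp_path):
        text = "smiles,sequence,affinity\nCCO,ACDE,1.0\nCCC,ACDE,2.0\n"
        ds = load_cpi_table(write(tmp_path, text))
        assert len(ds.compounds) == 2 and len(ds.proteins) == 1
        assert ds.n_interactions == 2

    def test_conflicting_smiles_for_one_id_rejected(self, tmp_path):
        p = write(tmp_path, HEADER + "c1,CCO,p1,ACDE,1.0\nc1,CCC,p2,MKVL,2.0\n")
        with pytest.raises(RowParseError, match="conflicting"):
            load_cpi_table(p)

    def test_load_write_load_idempotent(self, tmp_path):
        rows = "c1,CCO,p1,ACDE,1.25\nc2,CCC,p2,MKVL,-0.75\n"
        ds1 = load_cpi_table(write(tmp_path, HEADER + rows))
        out = tmp_path / "roundtrip.csv"
        ds1.to_frame().to_csv(out, index=False)
        ds2 = load_cpi_table(out)
        assert ds1.to_frame().equals(ds2.to_frame())


class TestActivityCsv:
    @pytest.mark.parametrize(
        "value,units,expected",
        [
            (1000.0, "nM", 6.0),
            (1.0, "M", 0.0),
            (37.0, "uM", 4.4318),
        ],
    )
    def test_pec50_transform(self, value, units, expected):
        assert pec50_from_concentration(value, units) == pytest.approx(expected, abs=1e-4)

    def test_pec50_strictly_decreasing_in_ec50(self):
        values = [0.5, 1.0, 10.0, 1e3, 1e6]
        p = [pec50_from_concentration(v, "nM") for v in values]
        assert all(a > b for a, b in zip(p, p[1:]))

    def test_loader_converts_and_tags_scale(self, tmp_path):
        text = "smiles,sequence,ec50_nM\nCCO,ACDE,1000\nCCC,ACDE,10\n"
        ds = load_activity_csv(write(tmp_path, text), value_column="ec50_nM", value_units="nM")
        assert ds.scale_tag == "pEC50"
        assert sorted(ds.affinities()) == pytest.approx([6.0, 8.0])

    def test_nonpositive_concentration_is_row_error(self, tmp_path):
        text = "smiles,sequence,ec50\nCCO,ACDE,-5\n"
        with pytest.raises(RowParseError, match="line 2"):
            load_activity_csv(write(tmp_path, text), value_column="ec50", value_units="nM")

    def test_unknown_units_is_config_error(self, tmp_path):
        text = "smiles,sequence,ec50\nCCO,ACDE,5\n"
        with pytest.raises(SchemaError, match="units"):
            load_activity_csv(write(tmp_path, text), value_column="ec50", value_units="mg")


class TestPredictionsIO:
    def test_round_trip_exact(self, tmp_path):
        rows = [("c1", "p1", 1.2345678901234567), ("c2", "p1", -0.1), ("c3", "p2", 7.0)]
        path = tmp_path / "pred.csv"
        write_predictions(rows, path)
        assert path.read_text().count("\n") == 4  # header + 3 rows
        df = read_predictions(path)
        for (cid, pid, val), row in zip(rows, df.itertuples(index=False)):
            assert (cid, pid) == (row.compound_id, row.protein_id)
            assert abs(val - row.predicted_affinity) < 1e-12

    def test_empty_rows_is_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_predictions([], tmp_path / "pred.csv")


class TestEntityFormats:
    def test_smi_round_trip(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\tc1\nc1ccccc1 benzene\nCCC\n")
        recs = read_smi(p)
        assert [r.compound_id for r in recs] == ["c1", "benzene", "C00003"]
        assert recs[1].smiles == "c1ccccc1"

    def test_fasta_reader_normalizes_alphabet(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">p1\nACDEbz\n>p2\nMKVL\n")
        recs = read_fasta(p)
        assert recs[0].sequence == "ACDEXX"  # lowercase + non-standard -> X
        assert recs[1].sequence == "MKVL"


class TestDatasetInvariants:
    def test_referential_integrity_enforced(self):
        with pytest.raises(ValueError, match="unknown compound"):
            CPIDataset(
                compounds=[CompoundRecord("c1", "CCO")],
                proteins=[ProteinRecord("p1", "ACDE")],
                interactions=[InteractionRecord("c9", "p1", 1.0, "kiba")],
            )

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            CPIDataset(
                compounds=[CompoundRecord("c1", "CCO"), CompoundRecord("c2", "CCC")],
                proteins=[ProteinRecord("p1", "ACDE")],
                interactions=[
                    InteractionRecord("c1", "p1", 1.0, "kiba"),
                    InteractionRecord("c2", "p1", 2.0, "pEC50"),
                ],
            )

    def test_nonfinite_affinity_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            InteractionRecord("c1", "p1", math.inf, "kiba")

    def test_alphabet_restriction(self):
        with pytest.raises(ValueError, match="alphabet"):
            ProteinRecord("p1", "ACDE*")
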