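import numpy as np
import pandas as pd
import pytest

from zratio import (
    ExpressionMatrix,
    SampleMetadata,
    load_hmgn_annotation,
    map_probes_to_genes,
    parse_series_matrix,
    read_annotation_tsv,
    read_metadata_tsv,
    write_series_matrix,
)
from zratio.geo_io import SeriesMatrixParseError


def _make_matrix(values, probes=None, samples=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), scale_tag=scale)


def _meta_for(matrix):
    return [SampleMetadata(s, "DS" if i % 2 == 0 else "control") for i, s in enumerate(matrix.sample_ids)]


class TestParseSeriesMatrix:
    def test_fixture_round_trip_shape_and_metadata(self, fixture_dir):
        matrix, metadata = parse_series_matrix(fixture_dir["series_matrix"])
        assert matrix.shape == (6, 4)
        assert len(metadata) == 4
        by_id = {m.sample_id: m for m in metadata}
        assert by_id["DS_HIP_01"].group == "DS"
        assert by_id["DS_HIP_01"].region == "HIP"
        assert by_id["DS_HIP_01"].age_value == 18.0
        assert by_id["DS_HIP_01"].age_unit == "WG"
        assert by_id["CT_HIP_02"].group == "control"
        assert by_id["CT_HIP_02"].sex == "M"

    def test_missing_table_markers(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("!Series_title\t\"x\"\nno markers here\n")
        with pytest.raises(SeriesMatrixParseError, match="markers"):
            parse_series_matrix(f)

    def test_zero_data_rows(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text(
            "!Sample_geo_accession\t\"s0\"\n"
            "!Sample_characteristics_ch1\t\"group: DS\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"s0"\n'
            "!series_matrix_table_end\n"
        )
        with pytest.raises(SeriesMatrixParseError, match="zero data rows"):
            parse_series_matrix(f)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        f = tmp_path / "nonnum.txt"
        f.write_text(
            "!Sample_geo_accession\t\"s0\"\n"
            "!Sample_characteristics_ch1\t\"group: DS\"\n"
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"s0"\n'
            '"probeX"\tnot_a_number\n'
            "!series_matrix_table_end\n"
        )
        with pytest.raises(SeriesMatrixParseError, match="probeX.*s0"):
            parse_series_matrix(f)

    def test_duplicate_sample_id(self, tmp_path):
        f = tmp_path / "dup.txt"
        f.write_text(
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"s0"\t"s0"\n'
            '"p1"\t1.0\t2.0\n'
            "!series_matrix_table_end\n"
        )
        with pytest.raises(SeriesMatrixParseError, match="duplicate"):
            parse_series_matrix(f)


class TestRoundTrip:
    def test_random_matrix_round_trip_values_and_metadata(self, tmp_path):
        rng = np.random.default_rng(1)
        matrix = _make_matrix(rng.normal(8, 1.5, (20, 10)))
        metadata = [
            SampleMetadata(s, "DS" if i < 5 else "control", "CBC", 3.25 + i, "Y", "F")
            for i, s in enumerate(matrix.sample_ids)
        ]
        path = tmp_path / "rt.txt"
        write_series_matrix(matrix, metadata, path)
        back, meta_back = parse_series_matrix(path)
        assert back.sample_ids == matrix.sample_ids
        assert back.probe_ids == matrix.probe_ids
        assert np.max(np.abs(back.values.to_numpy() - matrix.values.to_numpy())) < 1e-5
        assert meta_back == metadata

    def test_fixture_reparse_identical_to_6_decimals(self, fixture_dir, tmp_path):
        matrix, metadata = parse_series_matrix(fixture_dir["series_matrix"])
        path = tmp_path / "again.txt"
        write_series_matrix(matrix, metadata, path)
        back, _ = parse_series_matrix(path)
        np.testing.assert_allclose(
            back.values.to_numpy(), matrix.values.to_numpy(), atol=5e-7
        )

    def test_write_refuses_empty_matrix(self, tmp_path):
        empty = ExpressionMatrix(pd.DataFrame(dtype=float))
        with pytest.raises(ValueError, match="empty"):
            write_series_matrix(empty, [], tmp_path / "x.txt")

    def test_metadata_tsv_round_trip(self, fixture_dir):
        metadata = read_metadata_tsv(fixture_dir["metadata"])
        assert len(metadata) == 4
        assert {m.group for m in metadata} == {"DS", "control"}


class TestCheckJoin:
    def test_missing_sample_column_raises(self, random_matrix):
        matrix, metadata = random_matrix
        metadata = metadata + [SampleMetadata("ghost", "DS")]
        with pytest.raises(KeyError, match="ghost"):
            matrix.check_join(metadata)

    def test_duplicate_probe_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate probe"):
            _make_matrix([[1.0], [2.0]], probes=["p", "p"])


class TestProbeCollapse:
    @pytest.mark.parametrize(
        "collapse,values,expected",
        [
            ("mean", [[4.0], [6.0]], 5.0),
            ("median", [[2.0], [4.0], [10.0]], 4.0),
            ("max", [[2.0], [4.0], [10.0]], 10.0),
        ],
    )
    def test_collapse_rules(self, collapse, values, expected):
        matrix = _make_matrix(values)
        ann = pd.DataFrame({"probe_id": matrix.probe_ids, "gene_symbol": "GX"})
        out = map_probes_to_genes(matrix, ann, collapse)
        assert out.values.loc["GX", "s0"] == pytest.approx(expected)

    @pytest.mark.parametrize("collapse", ["mean", "median", "max"])
    def test_single_probe_gene_is_identity(self, collapse):
        matrix = _make_matrix([[3.7, 8.1]])
        ann = pd.DataFrame({"probe_id": ["p0"], "gene_symbol": ["GY"]})
        out = map_probes_to_genes(matrix, ann, collapse)
        np.testing.assert_array_equal(out.values.loc["GY"].to_numpy(), [3.7, 8.1])

    def test_unmapped_probes_dropped(self):
        matrix = _make_matrix([[1.0], [2.0], [3.0]])
        ann = pd.DataFrame({"probe_id": ["p0"], "gene_symbol": ["GZ"]})
        out = map_probes_to_genes(matrix, ann)
        assert out.probe_ids == ["GZ"]

    def test_empty_annotation_errors(self, random_matrix):
        matrix, _ = random_matrix
        with pytest.raises(ValueError, match="empty"):
            map_probes_to_genes(matrix, pd.DataFrame(columns=["probe_id", "gene_symbol"]))


class TestBundledAnnotation:
    def test_five_hmgn_genes_with_unique_entrez_ids(self):
        ann = load_hmgn_annotation()
        assert len(ann) == 5
        by_symbol = {a.gene_symbol: a for a in ann}
        assert by_symbol["HMGN1"].entrez_id == 3150
        assert by_symbol["HMGN1"].locus == "21q22.2"
        assert by_symbol["HMGN5"].entrez_id == 79366
        assert by_symbol["HMGN5"].locus == "Xq21.1"
        assert len({a.entrez_id for a in ann}) == 5

    def test_fixture_probe_annotation_maps_hmgn1(self, fixture_dir):
        ann = read_annotation_tsv(fixture_dir["probe_annotation"])
        hmgn1 = ann[ann.gene_symbol == "HMGN1"]
        assert set(hmgn1.entrez_id) == {3150}
        assert len(hmgn1) == 2
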