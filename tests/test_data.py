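import numpy as np
import pytest

from cpgselect.data import (
    DataError,
    MethylationDataset,
    SelectionReport,
    merge_datasets,
    read_geo_series_matrix,
    read_methylation_matrix,
    read_selection_report,
    write_methylation_matrix,
    write_selection_report,
)


def _make(ids, sites, beta, age):
    return MethylationDataset(sample_ids=ids, site_ids=sites,
                              beta=np.asarray(beta, dtype=float),
                              age=np.asarray(age, dtype=float))


class TestMethylationDataset:
    def test_invariants_enforced(self):
        with pytest.raises(DataError, match="duplicate site"):
            _make(["a", "b"], ["s1", "s1"], [[0.1, 0.2], [0.3, 0.4]], [1, 2])
        with pytest.raises(DataError, match="duplicate sample"):
            _make(["a", "a"], ["s1", "s2"], [[0.1, 0.2], [0.3, 0.4]], [1, 2])
        with pytest.raises(DataError, match=r"\[0, 1\]"):
            _make(["a"], ["s1"], [[1.5]], [1])
        with pytest.raises(DataError, match="non-negative"):
            _make(["a"], ["s1"], [[0.5]], [-1])
        with pytest.raises(DataError):
            _make(["a", "b"], ["s1"], [[0.5]], [1])

    def test_nan_is_legal_missing(self):
        ds = _make(["a"], ["s1", "s2"], [[np.nan, 0.3]], [4])
        assert np.isnan(ds.beta[0, 0])

    def test_select_sites_by_id_reorders(self, tiny_dataset):
        sub = tiny_dataset.select_sites(["cg2", "cg1"])
        assert sub.site_ids == ["cg2", "cg1"]
        np.testing.assert_array_equal(sub.beta[:, 0], tiny_dataset.beta[:, 1])


class TestReadMatrix:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,age,cg1,cg2\na,1,0.1,0.9\nb,5,0.2,0.8\nc,9,0.3,0.7\n")
        ds = read_methylation_matrix(p)
        assert ds.beta.shape == (3, 2)
        np.testing.assert_array_equal(ds.age, [1, 5, 9])
        assert ds.site_ids == ["cg1", "cg2"]

    def test_empty_cell_is_missing_not_zero(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,age,cg1,cg2\na,1,,0.9\nb,5,0.2,0.8\n")
        ds = read_methylation_matrix(p)
        assert np.isnan(ds.beta[0, 0])
        assert np.isfinite(ds.beta).sum() == 3

    def test_duplicate_site_header_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,age,cg1,cg1\na,1,0.1,0.9\n")
        with pytest.raises(DataError, match="cg1"):
            read_methylation_matrix(p)

    def test_non_numeric_age_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("sample_id,age,cg1\na,young,0.1\n")
        with pytest.raises(DataError, match="age"):
            read_methylation_matrix(p)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(DataError, match="no such file"):
            read_methylation_matrix(tmp_path / "nope.csv")

    def test_round_trip(self, tmp_path, tiny_dataset):
        p = tmp_path / "m.csv"
        write_methylation_matrix(tiny_dataset, p)
        back = read_methylation_matrix(p)
        np.testing.assert_allclose(back.beta, tiny_dataset.beta)
        np.testing.assert_allclose(back.age, tiny_dataset.age)
        assert back.sample_ids == tiny_dataset.sample_ids


GEO_FIXTURE = '''!Series_title\t"synthetic"
!Sample_geo_accession\t"GSM1"\t"GSM2"
!Sample_characteristics_ch1\t"age: 34"\t"age: 56"
!Sample_characteristics_ch1\t"sex: F"\t"sex: M"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"
"cg01"\t0.50\t0.60
"cg02"\t0.10\t0.20
"cg03"\t0.90\t0.80
!series_matrix_table_end
'''


class TestGeoReader:
    def test_fixture_round_trip(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(GEO_FIXTURE)
        ds = read_geo_series_matrix(p)
        assert ds.beta.shape == (2, 3)  # transposed to samples x sites
        assert ds.sample_ids == ["GSM1", "GSM2"]
        assert ds.site_ids == ["cg01", "cg02", "cg03"]
        np.testing.assert_allclose(ds.beta[0], [0.5, 0.1, 0.9])

    def test_age_parsed_from_characteristics(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(GEO_FIXTURE)
        ds = read_geo_series_matrix(p, age_field="age")
        np.testing.assert_array_equal(ds.age, [34, 56])

    def test_missing_end_marker_errors(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(GEO_FIXTURE.replace("!series_matrix_table_end\n", ""))
        with pytest.raises(DataError, match="delimiter"):
            read_geo_series_matrix(p)

    def test_unparseable_age_leaves_age_unset(self, tmp_path):
        p = tmp_path / "series.txt"
        p.write_text(GEO_FIXTURE.replace('"age: 56"', '"age: unknown"'))
        with pytest.warns(UserWarning, match="age"):
            ds = read_geo_series_matrix(p)
        assert ds.age is None


class TestMerge:
    def _ab(self):
        a = _make(["a1", "a2"], ["s1", "s2", "s3"],
                  [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]], [10, 20])
        b = _make(["b1"], ["s2", "s3", "s4"], [[0.7, 0.8, 0.9]], [30])
        return a, b

    def test_intersection_and_concat(self):
        a, b = self._ab()
        m = merge_datasets([a, b])
        assert m.site_ids == ["s2", "s3"]  # order of the first dataset
        assert m.n_samples == 3
        np.testing.assert_allclose(m.beta[2], [0.7, 0.8])
        np.testing.assert_array_equal(m.age, [10, 20, 30])

    def test_single_dataset_identity(self):
        a, _ = self._ab()
        m = merge_datasets([a])
        assert m.site_ids == a.site_ids
        np.testing.assert_allclose(m.beta, a.beta)

    def test_disjoint_sites_error(self):
        a = _make(["a"], ["s1"], [[0.1]], [1])
        b = _make(["b"], ["s2"], [[0.2]], [2])
        with pytest.raises(DataError, match="no CpG sites"):
            merge_datasets([a, b])

    def test_duplicate_sample_ids_suffixed(self):
        a = _make(["x"], ["s1"], [[0.1]], [1])
        b = _make(["x"], ["s1"], [[0.2]], [2])
        with pytest.warns(UserWarning, match="duplicate sample"):
            m = merge_datasets([a, b])
        assert len(set(m.sample_ids)) == 2

    def test_associative_up_to_sample_order(self):
        a, b = self._ab()
        c = _make(["c1"], ["s2", "s3"], [[0.05, 0.15]], [40])
        left = merge_datasets([merge_datasets([a, b]), c])
        right = merge_datasets([a, merge_datasets([b, c])])
        assert left.site_ids == right.site_ids
        assert sorted(left.sample_ids) == sorted(right.sample_ids)
        order_l = np.argsort(left.sample_ids)
        order_r = np.argsort(right.sample_ids)
        np.testing.assert_allclose(left.beta[order_l], right.beta[order_r])


class TestSelectionReport:
    def test_round_trip(self, tmp_path):
        rep = SelectionReport(group_label="2", ranked_sites=["cg2", "cg1", "cg9"],
                              per_site_cv_mad=[5.0, 3.5, 3.25],
                              final_metrics={"mad": 3.25, "r2": 0.91})
        path = tmp_path / "report.tsv"
        write_selection_report(rep, path)
        back = read_selection_report(path)
        assert back.ranked_sites == rep.ranked_sites
        assert back.per_site_cv_mad == rep.per_site_cv_mad
        assert back.group_label == "2"
        assert back.final_metrics["mad"] == 3.25

    def test_three_sites_three_rows(self, tmp_path):
        rep = SelectionReport("1", ["a", "b", "c"], [3.0, 2.0, 1.0])
        path = tmp_path / "r.tsv"
        write_selection_report(rep, path)
        rows = [l for l in path.read_text().splitlines()
                if l and not l.startswith(("#", "rank\t"))]
        assert len(rows) == 3
        assert rows[0].startswith("1\ta\t")

    def test_empty_report_valid(self, tmp_path):
        rep = SelectionReport("1", [], [])
        path = tmp_path / "r.tsv"
        write_selection_report(rep, path)
        back = read_selection_report(path)
        assert back.ranked_sites == []

    def test_mismatched_lengths_error(self):
        with pytest.raises(DataError):
            SelectionReport("1", ["a"], [])

    def test_unwritable_path_errors(self, tmp_path):
        rep = SelectionReport("1", [], [])
        with pytest.raises(DataError):
            write_selection_report(rep, tmp_path / "no" / "dir" / "r.tsv")
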