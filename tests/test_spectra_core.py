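import numpy as np
import pytest

from chemocal import (IntervalSelection, SpectrumSet, WavenumberGrid,
                      read_csv_spectra, read_jcamp, select_intervals,
                      write_csv_spectra)
from chemocal.errors import DataError, FormatError, SelectionError


class TestWavenumberGrid:
    def test_rejects_non_monotonic(self):
        with pytest.raises(DataError, match="increasing"):
            WavenumberGrid(np.array([400.0, 400.0, 500.0]))

    def test_rejects_out_of_band_values(self):
        with pytest.raises(DataError, match="range"):
            WavenumberGrid(np.array([50.0, 400.0]))

    def test_uniformity_detection(self):
        assert WavenumberGrid(np.array([400.0, 402.0, 404.0])).is_uniform()
        assert not WavenumberGrid(np.array([400.0, 402.0, 405.0])).is_uniform()


class TestCsvIO:
    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip(self, tiny_set, tmp_path, layout):
        path = tmp_path / "spectra.csv"
        write_csv_spectra(tiny_set, path, layout=layout)
        back = read_csv_spectra(path, layout=layout)
        assert back.sample_ids == tiny_set.sample_ids
        np.testing.assert_allclose(back.matrix, tiny_set.matrix, rtol=1e-9)
        np.testing.assert_allclose(back.wavenumbers, tiny_set.wavenumbers)

    def test_wide_three_by_five(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "wavenumber_cm-1,a,b,c\n"
            "400,1,2,3\n500,4,5,6\n600,7,8,9\n700,1,1,1\n800,2,2,2\n")
        sset = read_csv_spectra(path)
        assert sset.matrix.shape == (3, 5)
        assert sset.sample_ids == ["a", "b", "c"]

    def test_descending_grid_normalized(self, tmp_path):
        path = tmp_path / "desc.csv"
        path.write_text("wavenumber_cm-1,a\n800,3\n600,2\n400,1\n")
        sset = read_csv_spectra(path)
        np.testing.assert_array_equal(sset.wavenumbers, [400.0, 600.0, 800.0])
        np.testing.assert_array_equal(sset.matrix[0], [1.0, 2.0, 3.0])

    def test_missing_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavenumber_cm-1,a,b\n400,1,2\n500,,3\n")
        with pytest.raises(FormatError):
            read_csv_spectra(path)

    def test_duplicate_wavenumber_is_data_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("wavenumber_cm-1,a\n400,1\n400,2\n")
        with pytest.raises(DataError):
            read_csv_spectra(path)


class TestJcamp:
    def test_xypoints_minimal(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=mini\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
            "##XYPOINTS=(XY..XY)\n400,0.1; 500,0.2; 600,0.3; 700,0.4\n##END=\n")
        spectrum = read_jcamp(path)
        assert len(spectrum.grid) == 4
        np.testing.assert_allclose(spectrum.absorbance, [0.1, 0.2, 0.3, 0.4])

    def test_transmittance_converted(self, tmp_path):
        path = tmp_path / "t.jdx"
        path.write_text(
            "##TITLE=t\n##YUNITS=TRANSMITTANCE\n##XYPOINTS=(XY..XY)\n"
            "400,0.1; 500,0.1; 600,0.1\n##END=\n")
        spectrum = read_jcamp(path)
        np.testing.assert_allclose(spectrum.absorbance, 1.0)

    def test_xydata_grid_reconstruction(self, tmp_path):
        path = tmp_path / "d.jdx"
        path.write_text(
            "##TITLE=d\n##XFACTOR=1\n##YFACTOR=0.5\n##FIRSTX=400\n##LASTX=410\n"
            "##XYDATA=(X++(Y..Y))\n400 2 4 6\n406 8 10 12\n##END=\n")
        spectrum = read_jcamp(path)
        np.testing.assert_allclose(spectrum.grid.values,
                                   [400, 402, 404, 406, 408, 410])
        np.testing.assert_allclose(spectrum.absorbance, [1, 2, 3, 4, 5, 6])

    def test_missing_data_block_is_format_error(self, tmp_path):
        path = tmp_path / "no.jdx"
        path.write_text("##TITLE=no data\n##END=\n")
        with pytest.raises(FormatError, match="XYDATA"):
            read_jcamp(path)

    def test_compressed_dialect_rejected(self, tmp_path):
        path = tmp_path / "sqz.jdx"
        path.write_text(
            "##TITLE=sqz\n##XYDATA=(X++(Y..Y))\n400 J1J2J3\n##END=\n")
        with pytest.raises(FormatError, match="compressed"):
            read_jcamp(path)


class TestSelectIntervals:
    @pytest.fixture
    def four_point_set(self):
        grid = WavenumberGrid(np.array([400.0, 1000.0, 2000.0, 3000.0]))
        return SpectrumSet(grid=grid, matrix=np.arange(8.0).reshape(2, 4),
                           sample_ids=["a", "b"],
                           reference=np.array([1.0, 2.0]))

    def test_single_interval_containment(self, four_point_set):
        out = select_intervals(four_point_set,
                               IntervalSelection(((500.0, 1700.0),)))
        np.testing.assert_array_equal(out.wavenumbers, [1000.0])

    def test_union_of_intervals(self, four_point_set):
        sel = IntervalSelection(((500.0, 1700.0), (2500.0, 4000.0)))
        out = select_intervals(four_point_set, sel)
        np.testing.assert_array_equal(out.wavenumbers, [1000.0, 3000.0])
        np.testing.assert_array_equal(out.matrix, [[1.0, 3.0], [5.0, 7.0]])
        np.testing.assert_array_equal(out.reference, four_point_set.reference)

    def test_bounds_are_inclusive(self, four_point_set):
        out = select_intervals(four_point_set,
                               IntervalSelection(((1000.0, 2000.0),)))
        np.testing.assert_array_equal(out.wavenumbers, [1000.0, 2000.0])

    def test_empty_selection_raises(self, four_point_set):
        with pytest.raises(SelectionError):
            select_intervals(four_point_set,
                             IntervalSelection(((4100.0, 4200.0),)))

    def test_idempotent(self, four_point_set):
        sel = IntervalSelection(((500.0, 2500.0),))
        once = select_intervals(four_point_set, sel)
        twice = select_intervals(once, sel)
        np.testing.assert_array_equal(once.matrix, twice.matrix)
        np.testing.assert_array_equal(once.wavenumbers, twice.wavenumbers)

    def test_full_cover_is_identity(self, four_point_set):
        out = select_intervals(four_point_set,
                               IntervalSelection(((100.0, 8000.0),)))
        np.testing.assert_array_equal(out.matrix, four_point_set.matrix)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            IntervalSelection(((400.0, 1000.0), (900.0, 2000.0)))


class TestSpectrumSet:
    def test_duplicate_ids_rejected(self):
        grid = WavenumberGrid(np.array([400.0, 500.0]))
        with pytest.raises(DataError, match="unique"):
            SpectrumSet(grid=grid, matrix=np.ones((2, 2)),
                        sample_ids=["a", "a"])

    def test_subset_preserves_order_and_reference(self, tiny_set):
        sub = tiny_set.subset(["s3", "s1"])
        assert sub.sample_ids == ["s3", "s1"]
        np.testing.assert_array_equal(sub.reference, [12.0, 4.0])
        np.testing.assert_array_equal(sub.matrix[0], tiny_set.matrix[2])
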