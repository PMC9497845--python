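import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsdl_spectra.errors import FormatError, ParseError, ValidationError
from lsdl_spectra.spectra_io import (
    SpectraDataset,
    Spectrum,
    average_replicates,
    concatenate_datasets,
    read_jcampdx,
    read_spectra_csv,
    write_jcampdx,
    write_spectra_csv,
)


def _csv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestSpectrum:
    def test_ascending_axis_is_stored_descending(self):
        wn = np.arange(650.0, 730.0, 8.0)
        inten = np.arange(len(wn), dtype=float)
        s = Spectrum("a", wn, inten)
        assert s.wavenumbers[0] > s.wavenumbers[-1]
        # intensities reordered in lockstep
        assert s.intensities[0] == len(wn) - 1
        assert s.intensities[-1] == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            Spectrum("a", np.arange(10.0), np.arange(9.0))

    def test_non_monotonic_rejected(self):
        wn = np.array([10.0, 9.0, 9.5, 8.0, 7.0, 6.0, 5.0, 4.0])
        with pytest.raises(ValidationError, match="monotonic"):
            Spectrum("a", wn, np.zeros(8))

    def test_nonfinite_intensity_rejected(self):
        wn = np.arange(8.0, 0.0, -1.0)
        y = np.zeros(8)
        y[3] = np.nan
        with pytest.raises(ValidationError):
            Spectrum("a", wn, y)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError, match="at least"):
            Spectrum("a", np.arange(5.0, 0.0, -1.0), np.zeros(5))


class TestCsvRoundTrip:
    def test_three_samples_with_labels(self, tmp_path):
        header = "sample_id," + ",".join(str(v) for v in range(10, 0, -1)) + ",label"
        lines = [header]
        for i, lbl in enumerate(["cancer", "noncancer", "cancer"]):
            lines.append(f"s{i}," + ",".join(str(i + j) for j in range(10)) + f",{lbl}")
        path = _csv(tmp_path / "m.csv", "\n".join(lines))
        ds = read_spectra_csv(path)
        assert len(ds) == 3
        assert ds.class_counts == {"cancer": 2, "noncancer": 1}

    def test_ascending_axis_reordered(self, tmp_path):
        header = "sample_id," + ",".join(str(v) for v in range(1, 11)) + ",label"
        row = "s0," + ",".join(str(v) for v in range(10)) + ",cancer"
        ds = read_spectra_csv(_csv(tmp_path / "m.csv", header + "\n" + row))
        s = ds.spectra[0]
        assert s.wavenumbers[0] == 10.0
        assert s.intensities[0] == 9.0

    def test_nan_cell_named(self, tmp_path):
        header = "sample_id," + ",".join(str(v) for v in range(10, 0, -1)) + ",label"
        row = "s0,0,1,2,nan,4,5,6,7,8,9,cancer"
        with pytest.raises(ParseError, match="row 1, column 4"):
            read_spectra_csv(_csv(tmp_path / "m.csv", header + "\n" + row))

    def test_ragged_row_rejected(self, tmp_path):
        header = "sample_id," + ",".join(str(v) for v in range(10, 0, -1)) + ",label"
        row = "s0,0,1,2,cancer"
        with pytest.raises(FormatError, match="ragged"):
            read_spectra_csv(_csv(tmp_path / "m.csv", header + "\n" + row))

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        header = "sample_id,5,4,4,3,2.5,2,1.5,1,0.7,0.5,label"
        row = "s0," + ",".join("1" for _ in range(10)) + ",cancer"
        with pytest.raises(ValidationError, match="duplicate"):
            read_spectra_csv(_csv(tmp_path / "m.csv", header + "\n" + row))

    def test_write_read_round_trip_exact(self, tmp_path, labeled_dataset):
        path = tmp_path / "ds.csv"
        write_spectra_csv(labeled_dataset, path)
        back = read_spectra_csv(path)
        assert len(back) == len(labeled_dataset)
        for a, b in zip(labeled_dataset, back):
            np.testing.assert_allclose(a.wavenumbers, b.wavenumbers, atol=1e-9, rtol=0)
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9, rtol=0)
            assert a.label == b.label

    def test_samples_as_columns(self, tmp_path):
        text = (
            "wavenumber,s0,s1\n"
            + "\n".join(f"{10 - i},{i},{2 * i}" for i in range(10))
            + "\nlabel,cancer,noncancer"
        )
        ds = read_spectra_csv(_csv(tmp_path / "m.csv", text),
                              orientation="samples_as_columns")
        assert len(ds) == 2
        assert ds.class_counts == {"cancer": 1, "noncancer": 1}


class TestJcampDx:
    def test_yfactor_applied(self, tmp_path):
        text = "\n".join(
            [
                "##TITLE=mini",
                "##JCAMP-DX=4.24",
                "##FIRSTX=1000",
                "##LASTX=992",
                "##DELTAX=-1",
                "##NPOINTS=9",
                "##YFACTOR=0.001",
                "##XYDATA=(X++(Y..Y))",
                "1000 100 200 300 400 500",
                "995 600 700 800 900",
                "##END=",
            ]
        )
        path = tmp_path / "a.jdx"
        path.write_text(text)
        s = read_jcampdx(path)
        np.testing.assert_allclose(
            s.intensities, np.arange(1, 10) * 0.1, atol=1e-12
        )

    def test_inconsistent_lastx_rejected(self, tmp_path):
        text = "\n".join(
            [
                "##TITLE=bad",
                "##FIRSTX=1000",
                "##LASTX=0",
                "##DELTAX=-1",
                "##NPOINTS=9",
                "##XYDATA=(X++(Y..Y))",
                "1000 1 2 3 4 5 6 7 8 9",
                "##END=",
            ]
        )
        path = tmp_path / "a.jdx"
        path.write_text(text)
        with pytest.raises(FormatError, match="LASTX"):
            read_jcampdx(path)

    def test_inconsistent_npoints_rejected(self, tmp_path):
        text = "\n".join(
            [
                "##TITLE=bad",
                "##FIRSTX=1000",
                "##DELTAX=-1",
                "##NPOINTS=12",
                "##XYDATA=(X++(Y..Y))",
                "1000 1 2 3 4 5 6 7 8 9",
                "##END=",
            ]
        )
        path = tmp_path / "a.jdx"
        path.write_text(text)
        with pytest.raises(FormatError, match="NPOINTS"):
            read_jcampdx(path)

    def test_unsupported_compression_named(self, tmp_path):
        text = "\n".join(
            [
                "##TITLE=sqz",
                "##FIRSTX=1000",
                "##DELTAX=-1",
                "##NPOINTS=9",
                "##XYDATA=(X++(Y..Y))",
                "1000 A1B2C3",  # SQZ-style digits are not AFFN
                "##END=",
            ]
        )
        path = tmp_path / "a.jdx"
        path.write_text(text)
        with pytest.raises(FormatError, match="unsupported dialect"):
            read_jcampdx(path)

    def test_round_trip(self, tmp_path, make_spectrum, rng):
        s = make_spectrum(rng.uniform(0, 2, size=113), sample_id="rt")
        path = tmp_path / "rt.jdx"
        write_jcampdx(s, path, yfactor=1e-6)
        back = read_jcampdx(path)
        np.testing.assert_allclose(back.wavenumbers, s.wavenumbers, atol=1e-9, rtol=0)
        np.testing.assert_allclose(back.intensities, s.intensities, atol=1e-9, rtol=0)

    def test_xypoints(self, tmp_path):
        text = "\n".join(
            [
                "##TITLE=pts",
                "##XYPOINTS=(XY..XY)",
                "; ".join(f"{1000 - i}, {i * 0.5}" for i in range(10)),
                "##END=",
            ]
        )
        path = tmp_path / "p.jdx"
        path.write_text(text)
        s = read_jcampdx(path)
        assert len(s) == 10
        assert s.intensities[0] == 0.0


class TestAverageReplicates:
    def test_identical_replicates(self, make_spectrum):
        reps = [make_spectrum() for _ in range(3)]
        avg = average_replicates(reps)
        np.testing.assert_allclose(avg.intensities, reps[0].intensities, rtol=1e-15)
        assert avg.acquisition_mode == "averaged"

    def test_pointwise_mean(self, small_grid):
        reps = [
            Spectrum("s", small_grid, np.full(len(small_grid), v)) for v in (0.0, 3.0, 6.0)
        ]
        avg = average_replicates(reps)
        np.testing.assert_array_equal(avg.intensities, np.full(len(small_grid), 3.0))

    def test_grid_mismatch_rejected(self, small_grid):
        a = Spectrum("s", small_grid, np.zeros(len(small_grid)))
        b = Spectrum("s", small_grid + 1.0, np.zeros(len(small_grid)))
        with pytest.raises(ValidationError):
            average_replicates([a, b, a])

    def test_too_few_replicates_rejected(self, make_spectrum):
        with pytest.raises(ValidationError, match="at least 3"):
            average_replicates([make_spectrum(), make_spectrum()])

    def test_permutation_invariant(self, small_grid, rng):
        reps = [
            Spectrum("s", small_grid, rng.uniform(0, 1, len(small_grid)))
            for _ in range(3)
        ]
        a = average_replicates(reps)
        b = average_replicates(reps[::-1])
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-15)


class TestConcatenate:
    def test_count_additivity(self, labeled_dataset):
        out = concatenate_datasets(labeled_dataset, labeled_dataset, "both")
        assert len(out) == 2 * len(labeled_dataset)

    def test_empty_is_identity(self, labeled_dataset, small_grid):
        empty = SpectraDataset([], name="empty", _grid=small_grid)
        out = concatenate_datasets(labeled_dataset, empty, "same")
        assert len(out) == len(labeled_dataset)

    def test_grid_mismatch_rejected(self, labeled_dataset, small_grid):
        other = SpectraDataset(
            [Spectrum("x", small_grid + 1.0, np.zeros(len(small_grid)))], name="o"
        )
        with pytest.raises(ValidationError):
            concatenate_datasets(labeled_dataset, other, "bad")

    def test_provenance_retained(self, labeled_dataset):
        out = concatenate_datasets(labeled_dataset, labeled_dataset, "both")
        assert all(s.source == "tiny" for s in out)

    @settings(max_examples=20, deadline=None)
    @given(na=st.integers(0, 5), nb=st.integers(0, 5))
    def test_additivity_property(self, na, nb):
        grid = np.arange(100.0, 20.0, -10.0)
        mk = lambda n, tag: SpectraDataset(
            [Spectrum(f"{tag}{i}", grid, np.ones(len(grid))) for i in range(n)],
            name=tag, _grid=grid,
        )
        assert len(concatenate_datasets(mk(na, "a"), mk(nb, "b"), "c")) == na + nb
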