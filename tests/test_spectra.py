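"""Spectrum I/O (TSV and mzML), nearest-peak query, manifest and database."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiscreen.plate import (
    DatabaseError,
    ManifestError,
    default_database,
    default_reference_ions,
    read_database,
    read_manifest,
    read_reference_ions,
    write_reference_ions,
)
from maldiscreen.spectra import (
    CentroidSpectrum,
    SpectrumError,
    nearest_peak,
    read_spectrum,
    read_tsv_spectrum,
    write_spectrum,
)

from .conftest import make_spectrum


class TestTsvDialect:
    def test_reads_two_column_peaks(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("100.0\t5.0\n200.0\t7.0\n")
        s = read_tsv_spectrum(p)
        assert len(s) == 2
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [5.0, 7.0]

    def test_comma_dialect_and_comments(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("# a comment\n100.0,5.0\n200.0,7.0\n")
        assert len(read_tsv_spectrum(p)) == 2

    def test_duplicate_mz_rows_kept_faithfully(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("100.0\t5.0\n100.0\t7.0\n")
        s = read_tsv_spectrum(p)
        assert len(s) == 2
        assert sorted(s.intensity.tolist()) == [5.0, 7.0]

    def test_unsorted_input_sorted_with_warning(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("200.0\t7.0\n100.0\t5.0\n")
        with pytest.warns(UserWarning, match="unsorted"):
            s = read_tsv_spectrum(p)
        assert s.mz.tolist() == [100.0, 200.0]

    def test_bad_rows_error_with_location(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("100.0\t5.0\nnot-a-number\n")
        with pytest.raises(SpectrumError, match=":2"):
            read_tsv_spectrum(p)

    def test_tsv_round_trip(self, tmp_path):
        s = make_spectrum([(249.0317, 1000.0), (500.123456, 42.5)], "negative", "W07")
        path = tmp_path / "w.tsv"
        write_spectrum(path, s)
        back = read_spectrum(path, polarity="negative")
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-6)
        np.testing.assert_allclose(back.intensity, s.intensity, atol=1e-6)


class TestMzml:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        mz = np.sort(rng.uniform(100, 1100, size=50))
        inten = rng.exponential(100, size=50)
        s = CentroidSpectrum(mz, inten, "negative", "W03")
        path = tmp_path / "w.mzML"
        write_spectrum(path, s)
        back = read_spectrum(path)
        assert back.polarity == "negative"
        assert back.well_id == "W03"
        np.testing.assert_allclose(back.mz, s.mz, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, s.intensity, rtol=1e-6)

    def test_zlib_compressed_arrays_read(self, tmp_path):
        import zlib, base64, re

        s = make_spectrum([(100.0, 5.0), (200.5, 7.25)], well_id="W09")
        path = tmp_path / "w.mzML"
        write_spectrum(path, s)
        text = path.read_text()

        def compress(m):
            raw = zlib.compress(base64.b64decode(m.group(1)))
            return "<binary>" + base64.b64encode(raw).decode() + "</binary>"

        text = re.sub(r"<binary>([^<]*)</binary>", compress, text)
        text = text.replace(
            'accession="MS:1000576" name="no compression"',
            'accession="MS:1000574" name="zlib compression"',
        )
        path.write_text(text)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.mz, s.mz)
        np.testing.assert_allclose(back.intensity, s.intensity)

    def test_profile_mode_rejected(self, tmp_path):
        s = make_spectrum([(100.0, 1.0)], well_id="W01")
        path = tmp_path / "w.mzML"
        write_spectrum(path, s)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path.write_text(text)
        with pytest.raises(SpectrumError, match="centroid"):
            read_spectrum(path)


class TestNearestPeak:
    def test_hit_within_tolerance(self):
        s = make_spectrum([(249.0320, 10.0)])
        assert nearest_peak(s, 249.0317, 0.005) == (249.0320, 10.0)

    def test_miss_outside_tolerance(self):
        s = make_spectrum([(249.0380, 10.0)])
        assert nearest_peak(s, 249.0317, 0.005) is None

    def test_total_on_empty_spectrum(self):
        s = CentroidSpectrum(np.array([]), np.array([]))
        assert nearest_peak(s, 100.0, 0.01) is None

    def test_tie_breaks_prefer_intensity_then_low_mz(self):
        s = make_spectrum([(99.999, 5.0), (100.001, 9.0)])
        assert nearest_peak(s, 100.0, 0.01) == (100.001, 9.0)
        s2 = make_spectrum([(99.999, 5.0), (100.001, 5.0)])
        assert nearest_peak(s2, 100.0, 0.01) == (99.999, 5.0)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=100, max_value=1100, allow_nan=False),
                st.floats(min_value=0.1, max_value=1e5, allow_nan=False),
            ),
            min_size=1,
            max_size=40,
        ),
        st.floats(min_value=100, max_value=1100, allow_nan=False),
        st.floats(min_value=1e-4, max_value=1.0, allow_nan=False),
    )
    def test_matches_linear_scan_oracle(self, peaks, target, tol):
        s = make_spectrum(peaks)
        got = nearest_peak(s, target, tol)
        candidates = [
            (abs(mz - target), -i, mz)
            for mz, i in zip(s.mz, s.intensity)
            if abs(mz - target) <= tol
        ]
        if not candidates:
            assert got is None
        else:
            d, neg_i, mz = min(candidates)
            assert got == (mz, -neg_i)


class TestManifestAndDatabase:
    def test_valid_48_well_manifest(self, tmp_path):
        rows = ["well_id,role,sample_id,replicate"]
        rows.append("W01,calibrant,,0")
        for i in range(2, 5):
            rows.append(f"W{i:02d},blank,,0")
        for i in range(5, 48):
            rows.append(f"W{i:02d},sample,S{(i - 5) // 3 + 1:02d},{(i - 5) % 3 + 1}")
        rows.append("W48,calibrant,,0")
        p = tmp_path / "m.csv"
        p.write_text("\n".join(rows) + "\n")
        m = read_manifest(p)
        assert len(m.wells) == 48
        assert [w.well_id for w in m.by_role("calibrant")] == ["W01", "W48"]
        assert len(m.by_role("blank")) == 3
        assert all(len(v) == 3 for v in list(m.samples().values())[:-1])

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("well_id,role\nW01,blank\n")
        with pytest.raises(ManifestError, match="sample_id"):
            read_manifest(p)

    def test_database_row_species_counts(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(
            "name,cas,formula,class,pos_species,neg_species\n"
            "TPhP,115-86-6,C18H15O4P,OPFR,M+H;M+K;M+Na,M-C6H5\n"
        )
        db = read_database(p)
        assert len(db) == 1
        assert len(db[0].pos_species) == 3
        assert len(db[0].neg_species) == 1
        assert db[0].neg_species[0].label == "M-C6H5"

    def test_empty_species_cell_uses_mode_defaults(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(
            "name,cas,formula,class,pos_species,neg_species\nX,0-0-0,C10H10O4,phthalate,,\n"
        )
        rec = read_database(p)[0]
        assert [s.label for s in rec.species_for("positive")] == ["M+H", "M+K", "M+Na"]
        assert [s.label for s in rec.species_for("negative")] == ["M-H"]

    def test_bad_formula_reports_row_number(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(
            "name,cas,formula,class,pos_species,neg_species\n"
            "Good,0-0-0,C10H10O4,x,,\nBad,0-0-0,C10Qq,x,,\n"
        )
        with pytest.raises(DatabaseError, match="row 3"):
            read_database(p)

    def test_bundled_database_loads_eagerly(self, database):
        names = {c.name for c in database}
        assert {"TPhP", "TBBPA", "TTBP-TAZ", "DEHP", "DNOP", "BPA"} <= names


class TestReferenceIons:
    def test_default_list_spans_calibration_ranges(self):
        refs = default_reference_ions()
        neg = [r.mz for r in refs if r.polarity == "negative"]
        pos = [r.mz for r in refs if r.polarity == "positive"]
        assert len(neg) >= 2 and len(pos) >= 2
        assert min(neg) == pytest.approx(298.943, abs=0.01)  # C4 [M-H]-
        assert 299 <= min(neg) + 0.1 and max(neg) <= 1037
        assert 377 <= min(pos) and max(pos) <= 1115

    def test_config_round_trip(self, tmp_path):
        refs = default_reference_ions()
        p = tmp_path / "refs.tsv"
        write_reference_ions(p, refs)
        back = read_reference_ions(p)
        assert [(r.label, r.polarity) for r in back] == [(r.label, r.polarity) for r in refs]
        assert all(abs(a.mz - b.mz) < 1e-5 for a, b in zip(back, refs))
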