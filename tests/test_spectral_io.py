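"""MGF / MassBank / peak-list reading and writing."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from mslibsearch import (
    CollisionEnergy,
    MGFParseError,
    MassBankRecordError,
    Peak,
    Spectrum,
    extract_spectra,
    parse_collision_energy,
    read_massbank_record,
    read_mgf,
    read_peaklist,
    write_massbank_record,
    write_mgf,
    write_peaklist,
)

ONE_BLOCK = """BEGIN IONS
TITLE=query 1
PEPMASS=300.10
CHARGE=1+
100.0 50
150.0 100
END IONS
"""


class TestReadMGF:
    def test_single_block(self):
        spectra = read_mgf(io.StringIO(ONE_BLOCK))
        assert len(spectra) == 1
        s = spectra[0]
        assert s.precursor_mz == pytest.approx(300.10)
        assert s.peaks == [Peak(100.0, 50.0), Peak(150.0, 100.0)]
        assert s.source_id == "query 1"

    def test_two_blocks_in_order(self):
        text = ONE_BLOCK + "BEGIN IONS\nTITLE=query 2\nPEPMASS=400.2\n200.0 1\nEND IONS\n"
        spectra = read_mgf(io.StringIO(text))
        assert [s.source_id for s in spectra] == ["query 1", "query 2"]

    def test_unterminated_block_names_line(self):
        bad = "BEGIN IONS\nPEPMASS=300.1\n100.0 50\n"
        with pytest.raises(MGFParseError, match="line 1"):
            read_mgf(io.StringIO(bad))

    def test_non_numeric_peak_line(self):
        bad = "BEGIN IONS\nPEPMASS=300.1\nabc def\nEND IONS\n"
        with pytest.raises(MGFParseError, match="non-numeric"):
            read_mgf(io.StringIO(bad))

    def test_missing_intensity_defaults_to_one(self):
        text = "BEGIN IONS\nPEPMASS=300.1\n100.0\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.peaks == [Peak(100.0, 1.0)]

    def test_pepmass_with_intensity_and_unknown_headers(self):
        text = "BEGIN IONS\nPEPMASS=300.1 12345.0\nSCANS=57\n100.0 1\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.precursor_mz == pytest.approx(300.1)

    def test_zero_peak_block_kept(self):
        text = "BEGIN IONS\nTITLE=empty\nPEPMASS=300.1\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.peaks == []

    def test_duplicate_mz_merged(self):
        text = "BEGIN IONS\nPEPMASS=300.1\n100.0 40\n100.0 60\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.peaks == [Peak(100.0, 100.0)]

    def test_negative_charge_dialect(self):
        text = "BEGIN IONS\nPEPMASS=300.1\nCHARGE=1-\n100.0 1\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.charge == -1

    def test_collision_energy_header(self):
        text = "BEGIN IONS\nPEPMASS=300.1\nCOLLISION_ENERGY=35 eV\n100.0 1\nEND IONS\n"
        (s,) = read_mgf(io.StringIO(text))
        assert s.collision_energy == CollisionEnergy("eV", 35.0)


class TestWriteMGF:
    def test_round_trip_single(self, simple_spectrum):
        sink = io.StringIO()
        n = write_mgf([simple_spectrum], sink)
        assert n == len(sink.getvalue().encode())
        (back,) = read_mgf(io.StringIO(sink.getvalue()))
        assert back.peaks == simple_spectrum.peaks
        assert back.precursor_mz == pytest.approx(simple_spectrum.precursor_mz, abs=1e-6)
        assert back.collision_energy == simple_spectrum.collision_energy

    def test_empty_list(self):
        sink = io.StringIO()
        write_mgf([], sink)
        assert read_mgf(io.StringIO(sink.getvalue())) == []

    def test_negative_charge_written_as_suffix_dialect(self):
        s = Spectrum(peaks=[Peak(100.0, 1.0)], precursor_mz=300.1, charge=-1)
        sink = io.StringIO()
        write_mgf([s], sink)
        assert "CHARGE=1-" in sink.getvalue()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.data())
    def test_round_trip_preserves_peaks(self, data):
        mzs = data.draw(
            st.lists(
                st.floats(50.0, 999.0, allow_nan=False),
                min_size=1, max_size=20, unique_by=lambda x: round(x, 3),
            )
        )
        peaks = [
            Peak(mz, data.draw(st.floats(0.01, 1e6, allow_nan=False))) for mz in mzs
        ]
        s = Spectrum(peaks=peaks, precursor_mz=data.draw(st.floats(100.0, 1000.0)))
        sink = io.StringIO()
        write_mgf([s], sink)
        (back,) = read_mgf(io.StringIO(sink.getvalue()))
        assert len(back.peaks) == len(s.peaks)
        for p, q in zip(s.peaks, back.peaks):
            assert q.mz == pytest.approx(p.mz, abs=1e-6)
            assert q.intensity == pytest.approx(p.intensity, rel=1e-6, abs=1e-6)

    def test_cross_check_against_pyteomics(self, simple_spectrum):
        """The writer's dialect is readable by an independent MGF parser."""
        mgf = pytest.importorskip("pyteomics.mgf")
        sink = io.StringIO()
        write_mgf([simple_spectrum], sink)
        (parsed,) = list(mgf.read(io.StringIO(sink.getvalue()), use_index=False))
        assert list(parsed["m/z array"]) == pytest.approx([100.0, 150.0])
        assert list(parsed["intensity array"]) == pytest.approx([50.0, 100.0])
        assert parsed["params"]["pepmass"][0] == pytest.approx(300.10)


MASSBANK_RECORD = """ACCESSION: ETS00001
RECORD_TITLE: Atrazine; LC-ESI-ITFT; MS2; CE: 45%
CH$NAME: Atrazine
CH$FORMULA: C8H14ClN5
CH$EXACT_MASS: 215.0938
CH$SMILES: CCNc1nc(Cl)nc(NC(C)C)n1
CH$LINK: INCHIKEY MXWJVTOOROXGIU-UHFFFAOYSA-N
AC$MASS_SPECTROMETRY: FRAGMENTATION_MODE HCD
AC$MASS_SPECTROMETRY: COLLISION_ENERGY 45 % (nominal)
AC$MASS_SPECTROMETRY: RESOLUTION 7500
AC$MASS_SPECTROMETRY: ION_MODE POSITIVE
MS$FOCUSED_ION: PRECURSOR_M/Z 216.1010
PK$NUM_PEAK: 3
PK$PEAK: m/z int. rel.int.
  68.0243 1200.0 96
  96.0557 12500.0 999
  174.0541 8100.0 647
//
"""


class TestMassBank:
    def test_parse_full_record(self):
        rec = read_massbank_record(io.StringIO(MASSBANK_RECORD))
        assert rec.accession == "ETS00001"
        assert rec.name == "Atrazine"
        assert rec.inchikey == "MXWJVTOOROXGIU-UHFFFAOYSA-N"
        assert rec.formula == "C8H14ClN5"
        s = rec.spectrum
        assert s.precursor_mz == pytest.approx(216.1010)
        assert len(s.peaks) == 3
        assert s.activation == "HCD"
        assert s.collision_energy == CollisionEnergy("NCE", 45.0)
        assert s.resolution == 7500

    def test_cid_fragmentation_mode(self):
        text = MASSBANK_RECORD.replace("HCD", "CID").replace(
            "45 % (nominal)", "35 eV"
        )
        rec = read_massbank_record(io.StringIO(text))
        assert rec.spectrum.activation == "CID"
        assert rec.spectrum.collision_energy == CollisionEnergy("eV", 35.0)

    def test_unparseable_ce_kept_as_absent(self):
        text = MASSBANK_RECORD.replace("45 % (nominal)", "Ramp 21.1-31.6 arb")
        rec = read_massbank_record(io.StringIO(text))
        assert rec.spectrum.collision_energy is None

    def test_missing_peak_table_rejected(self):
        text = MASSBANK_RECORD[: MASSBANK_RECORD.index("PK$PEAK")] + "//\n"
        with pytest.raises(MassBankRecordError, match="no peaks"):
            read_massbank_record(io.StringIO(text))

    def test_missing_precursor_rejected(self):
        text = MASSBANK_RECORD.replace(
            "MS$FOCUSED_ION: PRECURSOR_M/Z 216.1010\n", ""
        )
        with pytest.raises(MassBankRecordError, match="PRECURSOR_M/Z"):
            read_massbank_record(io.StringIO(text))

    def test_write_round_trip(self):
        rec = read_massbank_record(io.StringIO(MASSBANK_RECORD))
        sink = io.StringIO()
        write_massbank_record(rec, sink)
        back = read_massbank_record(io.StringIO(sink.getvalue()))
        assert back.accession == rec.accession
        assert back.spectrum.precursor_mz == pytest.approx(rec.spectrum.precursor_mz)
        assert len(back.spectrum.peaks) == len(rec.spectrum.peaks)


class TestCollisionEnergyParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("45 % (nominal)", CollisionEnergy("NCE", 45.0)),
            ("45% (nominal)", CollisionEnergy("NCE", 45.0)),
            ("35 eV", CollisionEnergy("eV", 35.0)),
            ("HCD 60", CollisionEnergy("NCE", 60.0)),
            ("35 eV (spread 10)", CollisionEnergy("eV", 35.0, 10.0)),
            ("55 NCE", CollisionEnergy("NCE", 55.0)),
        ],
    )
    def test_pattern_table(self, text, expected):
        assert parse_collision_energy(text) == expected

    def test_unparseable_returns_none(self):
        assert parse_collision_energy("banana") is None


class TestPeaklistExtraction:
    def test_peaklist_round_trip(self, tmp_path, simple_spectrum):
        path = tmp_path / "one.txt"
        write_peaklist(simple_spectrum, path)
        back = read_peaklist(path)
        assert back.peaks == [
            Peak(pytest.approx(p.mz), pytest.approx(p.intensity))
            for p in simple_spectrum.peaks
        ]
        assert back.precursor_mz == pytest.approx(simple_spectrum.precursor_mz)
        assert back.collision_energy == simple_spectrum.collision_energy

    def test_extract_counts_nonempty_only(self, tmp_path, simple_spectrum):
        empty = Spectrum(peaks=[], precursor_mz=500.0, source_id="empty")
        run = [simple_spectrum, empty, simple_spectrum]
        n = extract_spectra(run, tmp_path / "out")
        assert n == 2
        assert len(list((tmp_path / "out").glob("*.txt"))) == 2
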