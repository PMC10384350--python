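"""MGF/mzML I/O, cosine scoring, library search and ppm arithmetic."""

import base64
import itertools
import struct
import zlib

import numpy as np
import pytest

from saponinms.reference import PRECURSOR_TABLE
from saponinms.speclib import (
    LibraryRecord,
    Spectrum,
    cosine_score,
    library_search,
    ppm_error,
    read_mgf,
    read_mzml,
    write_mgf,
)
from saponinms.synthetic import SimulationConfig, simulate_library


def spectrum(mzs, intens, precursor=500.0, charge=1, rt=None, sid="s"):
    return Spectrum(
        mz=np.asarray(mzs, float), intensity=np.asarray(intens, float),
        precursor_mz=precursor, charge=charge, rt=rt, id=sid,
    )


def brute_force_cosine(a, b, frag_tol=0.05, shift=0.0):
    """Oracle: optimal one-to-one peak assignment by exhaustive enumeration."""
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    admissible = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.mz[i] - b.mz[j]) <= frag_tol
        or (shift and abs(a.mz[i] - b.mz[j] - shift) <= frag_tol)
    ]
    best = 0.0
    for r in range(len(admissible) + 1):
        for combo in itertools.combinations(admissible, r):
            if len({i for i, _ in combo}) < r or len({j for _, j in combo}) < r:
                continue
            best = max(best, sum(wa[i] * wb[j] for i, j in combo))
    denom = np.sqrt(np.sum(wa**2)) * np.sqrt(np.sum(wb**2))
    return best / denom if denom else 0.0


class TestMGF:
    def test_round_trip_peaks_and_metadata(self, tmp_path, rng):
        records = simulate_library(10, seed=7)
        spectra = [r.spectrum for r in records]
        path = tmp_path / "lib.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 10
        for orig, rt in zip(spectra, back):
            assert np.allclose(np.round(orig.mz, 4), rt.mz)
            assert np.allclose(np.round(orig.intensity, 4), rt.intensity)
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
            assert rt.charge == orig.charge and rt.negative
            if orig.rt is not None:
                assert rt.rt == pytest.approx(orig.rt, abs=1e-3)

    def test_write_is_idempotent_bytewise(self, tmp_path):
        spectra = [r.spectrum for r in simulate_library(5, seed=8)]
        p1, p2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
        write_mgf(spectra, p1)
        write_mgf(read_mgf(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_charge_notation(self, tmp_path):
        path = tmp_path / "neg.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=t\nPEPMASS=621.0\nCHARGE=2-\n"
            "100.0 10\n200.0 20\nEND IONS\n"
        )
        s = read_mgf(path)[0]
        assert s.charge == 2 and s.negative

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_missing_pepmass_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "nopm.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=a\n100.0 1\nEND IONS\n\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=500.0\n100.0 1\nEND IONS\n"
        )
        with caplog.at_level("WARNING"):
            out = read_mgf(path)
        assert [s.id for s in out] == ["b"]
        assert any("PEPMASS" in r.message for r in caplog.records)


class TestMzML:
    def make_mzml(self, path, mzs, intens, precursor, rt_min):
        def encode(values):
            raw = struct.pack(f"<{len(values)}d", *values)
            return base64.b64encode(zlib.compress(raw)).decode()

        path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r">
  <spectrumList count="1">
   <spectrum index="0" id="scan=1" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitName="minute"/>
     </scan>
    </scanList>
    <precursorList count="1">
     <precursor>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{precursor}"/>
        <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="1"/>
       </selectedIon>
      </selectedIonList>
     </precursor>
    </precursorList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{encode(mzs)}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{encode(intens)}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
  </spectrumList>
 </run>
</mzML>
""")

    def test_read_centroided(self, tmp_path):
        path = tmp_path / "tiny.mzML"
        self.make_mzml(path, [241.0, 695.1, 987.2], [5.0, 10.0, 20.0],
                       precursor=1163.5, rt_min=8.4)
        spectra = read_mzml(path)
        assert len(spectra) == 1
        s = spectra[0]
        assert np.allclose(s.mz, [241.0, 695.1, 987.2])
        assert s.precursor_mz == pytest.approx(1163.5)
        assert s.negative
        assert s.rt == pytest.approx(8.4)


class TestCosine:
    def test_self_match(self):
        a = spectrum([100, 200, 300], [1, 5, 2])
        score, n = cosine_score(a, a)
        assert score == pytest.approx(1.0)
        assert n == 3

    def test_disjoint_zero(self):
        a = spectrum([100, 200], [1, 1])
        b = spectrum([150, 250], [1, 1])
        assert cosine_score(a, b) == (0.0, 0)

    def test_empty_spectrum(self):
        a = spectrum([100], [1])
        b = spectrum([], [])
        assert cosine_score(a, b) == (0.0, 0)

    def test_symmetry_random_pairs(self, rng):
        for _ in range(20):
            a = spectrum(np.sort(rng.uniform(100, 1000, 6)), rng.uniform(1, 100, 6))
            b = spectrum(np.sort(rng.uniform(100, 1000, 6)), rng.uniform(1, 100, 6))
            sab, nab = cosine_score(a, b, frag_tol=5.0)
            sba, nba = cosine_score(b, a, frag_tol=5.0)
            assert sab == pytest.approx(sba, abs=1e-12)
            assert nab == nba
            assert 0.0 <= sab <= 1.0

    def test_greedy_matches_brute_force_on_toys(self, rng):
        """3-peak toys against the exhaustive optimal-assignment oracle."""
        for _ in range(30):
            a = spectrum(np.sort(rng.uniform(100, 500, 3)), rng.uniform(1, 100, 3))
            b = spectrum(a.mz + rng.normal(0, 0.02, 3), rng.uniform(1, 100, 3))
            got, _ = cosine_score(a, b, frag_tol=0.05)
            expected = brute_force_cosine(a, b, frag_tol=0.05)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_matchms(self):
        """Independent cross-check against the matchms CosineGreedy
        implementation (square-root intensity weighting)."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(3)
        for _ in range(10):
            mza = np.sort(rng.uniform(100, 900, 8))
            ia = rng.uniform(1, 100, 8)
            mzb = np.sort(np.concatenate([mza[:4] + rng.normal(0, 0.01, 4),
                                          rng.uniform(100, 900, 4)]))
            ib = rng.uniform(1, 100, 8)
            a = spectrum(mza, ia)
            b = spectrum(mzb, ib)
            ref = CosineGreedy(tolerance=0.05, intensity_power=0.5).pair(
                matchms.Spectrum(mz=a.mz, intensities=a.intensity,
                                 metadata={"precursor_mz": 500.0}),
                matchms.Spectrum(mz=b.mz, intensities=b.intensity,
                                 metadata={"precursor_mz": 500.0}),
            )
            got, n = cosine_score(a, b, frag_tol=0.05)
            assert got == pytest.approx(float(ref["score"]), abs=1e-6)
            assert n == int(ref["matches"])


class TestLibrarySearch:
    def make_library(self):
        specs = [r.spectrum for r in simulate_library(15, seed=11)]
        return [LibraryRecord(spectrum=s) for s in specs]

    def test_self_search_top1(self):
        lib = self.make_library()
        for rec in lib:
            hits = library_search(rec.spectrum, lib, precursor_tol=0.02)
            assert hits[0].record_id == rec.id
            assert hits[0].cosine == pytest.approx(1.0)

    def test_rt_shift_within_gate(self):
        lib = self.make_library()
        rec = next(r for r in lib if r.spectrum.rt is not None)
        q = Spectrum(
            mz=rec.spectrum.mz, intensity=rec.spectrum.intensity,
            precursor_mz=rec.spectrum.precursor_mz, charge=rec.spectrum.charge,
            rt=rec.spectrum.rt + 0.1, id="query",
        )
        hits = library_search(q, lib, rt_tol=0.3)
        assert hits[0].record_id == rec.id
        assert hits[0].passed_rt_gate is True
        assert hits[0].rt_delta_min == pytest.approx(0.1)

    def test_rt_gate_disambiguates_isomers(self):
        """Three isomeric records (same precursor, near-identical spectra,
        distinct RTs): only the RT-consistent record is gated in."""
        mz = np.array([300.0, 500.0, 723.0, 1100.0])
        inten = np.array([10.0, 40.0, 100.0, 30.0])
        iso = [
            Spectrum(mz=mz, intensity=inten, precursor_mz=1307.5, rt=rt,
                     id=f"isomer-{k}")
            for k, rt in enumerate([8.0, 10.0, 12.4])
        ]
        lib = [LibraryRecord(spectrum=s) for s in iso]
        q = Spectrum(mz=mz, intensity=inten, precursor_mz=1307.5, rt=12.5, id="q")
        hits = library_search(q, lib, rt_tol=0.3)
        assert hits[0].record_id == "isomer-2" and hits[0].passed_rt_gate
        assert all(h.passed_rt_gate is False for h in hits[1:])

    def test_empty_after_precursor_filter(self):
        lib = self.make_library()
        q = Spectrum(mz=np.array([100.0]), intensity=np.array([1.0]),
                     precursor_mz=9999.0, id="far")
        assert library_search(q, lib) == []


class TestPpmError:
    @pytest.mark.parametrize(
        "calc, meas, expected",
        [(1281.5216, 1281.5135, 6.3), (630.2093, 630.2104, -1.7), (700.0, 700.0, 0.0)],
    )
    def test_examples(self, calc, meas, expected):
        assert ppm_error(calc, meas) == pytest.approx(expected, abs=0.05)

    def test_published_table_reproduced(self):
        """The published mass-error column is recomputed from the printed
        calculated/measured pairs to within 0.2 ppm (the bound set by the
        4-decimal print precision of the m/z pairs)."""
        for name, calc, meas, printed in PRECURSOR_TABLE:
            assert abs(ppm_error(calc, meas) - printed) <= 0.2, name

    def test_nonpositive_calc_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(0.0, 100.0)
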