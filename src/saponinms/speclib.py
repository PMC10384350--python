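"""Spectral-library storage, MGF/mzML I/O, cosine matching and dereplication.

The dereplication workflow mirrors common library-search practice for
negative-mode saponin data: candidate library records are pre-filtered by
precursor m/z, compared by a square-root-intensity cosine with greedy peak
pairing, and confirmed by retention time when both query and record carry one.
Mass accuracy is reported as a signed ppm error of the measured precursor
against the calculated (library) value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import base64
import struct
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _pyteomics_mgf

from .chem_model import Glycoside

__all__ = [
    "Spectrum",
    "LibraryRecord",
    "MatchResult",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "cosine_score",
    "library_search",
    "ppm_error",
]

logger = logging.getLogger(__name__)

#: collision-energy levels used when acquiring multi-energy spectra (%).
CE_LEVELS = (75, 100, 125)


@dataclass
class Spectrum:
    """A centroided peak list with precursor information.

    Peaks are stored m/z-ascending; exact duplicate m/z values are merged by
    summing intensities.  ``charge`` is the absolute charge; ``negative``
    flags polarity (negative mode throughout this package).  ``rt`` is in
    minutes and optional.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    charge: int = 1
    negative: bool = True
    rt: float | None = None
    id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if mz.size and (not np.all(np.isfinite(mz)) or not np.all(np.isfinite(inten))):
            raise ValueError("peaks must be finite")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            # merge exact duplicates so m/z is strictly increasing
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                summed = np.zeros(uniq.size)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        self.mz, self.intensity = mz, inten
        if self.charge < 1:
            raise ValueError("charge must be a positive count (polarity is a flag)")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.n_peaks else 0.0


@dataclass
class LibraryRecord:
    """A reference spectrum joined to its (optional) structure."""

    spectrum: Spectrum
    glycoside: Glycoside | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.glycoside is not None and self.spectrum.precursor_mz is not None:
            calc, _ = self.glycoside.precursor_mz(
                n_charges=self.spectrum.charge, mode="mono"
            )
            if abs(ppm_error(calc, self.spectrum.precursor_mz)) > 20:
                logger.warning(
                    "library record %s: precursor %.4f disagrees with structure "
                    "(calculated %.4f) by more than 20 ppm",
                    self.spectrum.id,
                    self.spectrum.precursor_mz,
                    calc,
                )

    @property
    def id(self) -> str:
        return self.spectrum.id


@dataclass(frozen=True)
class MatchResult:
    """A scored query-vs-library comparison."""

    query_id: str
    record_id: str
    cosine: float
    n_matched: int
    ppm_error: float | None
    rt_delta_min: float | None
    passed_rt_gate: bool | None


# --- MGF I/O -----------------------------------------------------------------

_HANDLED_KEYS = {"title", "pepmass", "charge", "rtinseconds"}


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file.  Negative charges use the '2-' notation; records
    without PEPMASS are skipped with a warning."""
    spectra: list[Spectrum] = []
    try:
        with _pyteomics_mgf.read(str(path), use_index=False) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                if "pepmass" not in params or params["pepmass"][0] is None:
                    logger.warning("%s: record %d has no PEPMASS, skipped", path, i)
                    continue
                charge, negative = 1, True
                if params.get("charge"):
                    c = int(params["charge"][0])
                    charge, negative = abs(c), c < 0
                rt = None
                if "rtinseconds" in params:
                    rt = float(params["rtinseconds"]) / 60.0
                metadata = {
                    k: str(v) for k, v in params.items() if k not in _HANDLED_KEYS
                }
                spectra.append(
                    Spectrum(
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        precursor_mz=float(params["pepmass"][0]),
                        charge=charge,
                        negative=negative,
                        rt=rt,
                        id=str(params.get("title", f"spectrum_{i}")),
                        metadata=metadata,
                    )
                )
    except Exception as exc:
        if isinstance(exc, (OSError, ValueError)) and not spectra:
            raise type(exc)(f"{path}: {exc}") from exc
        raise
    return spectra


def write_mgf(spectra, path) -> None:
    """Write spectra as MGF (normalized: 4-decimal peaks, sorted metadata).

    The output is byte-stable: writing, reading and writing again produces an
    identical file.
    """
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.4f}\n")
            sign = "-" if s.negative else "+"
            fh.write(f"CHARGE={s.charge}{sign}\n")
            if s.rt is not None:
                fh.write(f"RTINSECONDS={s.rt * 60.0:.2f}\n")
            for key in sorted(s.metadata):
                fh.write(f"{key.upper()}={s.metadata[key]}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.4f} {inten:.4f}\n")
            fh.write("END IONS\n\n")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(array_elem) -> np.ndarray:
    names = {
        p.get("name") for p in array_elem.iter(f"{_MZML_NS}cvParam")
    }
    binary = array_elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "zlib compression" in names:
        raw = zlib.decompress(raw)
    if "64-bit float" in names:
        fmt, width = "d", 8
    else:
        fmt, width = "f", 4
    return np.array(struct.unpack(f"<{len(raw) // width}{fmt}", raw))


def read_mzml(path) -> list[Spectrum]:
    """Read centroided spectra from an mzML file.

    Read-only support for the subset needed here: 32/64-bit (optionally
    zlib-compressed) peak arrays, precursor m/z and charge, polarity and
    retention time.  Vendor-format conversion is out of scope.
    """
    spectra = []
    tree = etree.parse(str(path))
    for i, elem in enumerate(tree.iter(f"{_MZML_NS}spectrum")):
        params = {
            p.get("name"): p for p in elem.findall(f"{_MZML_NS}cvParam")
        }
        negative = "positive scan" not in params
        precursor_mz, charge = None, 1
        ion = elem.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        if ion is not None:
            ion_params = {p.get("name"): p.get("value")
                          for p in ion.findall(f"{_MZML_NS}cvParam")}
            if "selected ion m/z" in ion_params:
                precursor_mz = float(ion_params["selected ion m/z"])
            if ion_params.get("charge state"):
                charge = abs(int(ion_params["charge state"]))
        rt = None
        scan = elem.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan is not None:
            for p in scan.findall(f"{_MZML_NS}cvParam"):
                if p.get("name") == "scan start time":
                    rt = float(p.get("value"))
                    if p.get("unitName") == "second":
                        rt /= 60.0
        mz_arr = inten_arr = None
        for arr in elem.iter(f"{_MZML_NS}binaryDataArray"):
            names = {p.get("name") for p in arr.findall(f"{_MZML_NS}cvParam")}
            if "m/z array" in names:
                mz_arr = _decode_binary_array(arr)
            elif "intensity array" in names:
                inten_arr = _decode_binary_array(arr)
        if mz_arr is None or inten_arr is None:
            logger.warning("%s: spectrum %d lacks peak arrays, skipped", path, i)
            continue
        spectra.append(
            Spectrum(
                mz=mz_arr,
                intensity=inten_arr,
                precursor_mz=precursor_mz,
                charge=charge,
                negative=negative,
                rt=rt,
                id=str(elem.get("id", f"scan_{i}")),
            )
        )
    return spectra


# --- similarity --------------------------------------------------------------


def _greedy_pairs(
    mz_a, wa, mz_b, wb, pair_ok
) -> list[tuple[int, int]]:
    """Greedy one-to-one peak pairing: admissible pairs sorted by decreasing
    weight product (ties by index for determinism), accepted if both peaks are
    still unused."""
    cand = [
        (wa[i] * wb[j], i, j)
        for i in range(len(mz_a))
        for j in range(len(mz_b))
        if pair_ok(i, j)
    ]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def cosine_score(a: Spectrum, b: Spectrum, frag_tol: float = 0.05) -> tuple[float, int]:
    """Square-root-intensity cosine similarity with greedy peak pairing.

    Peaks match within ``frag_tol`` Da; each peak is used at most once,
    highest intensity-product pairs first.  Returns ``(cosine, n_matched)``;
    an empty spectrum scores (0.0, 0).
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    wa, wb = np.sqrt(a.intensity), np.sqrt(b.intensity)
    pairs = _greedy_pairs(
        a.mz, wa, b.mz, wb, lambda i, j: abs(a.mz[i] - b.mz[j]) <= frag_tol
    )
    if not pairs:
        return 0.0, 0
    num = sum(wa[i] * wb[j] for i, j in pairs)
    denom = math.sqrt(float(np.sum(wa**2))) * math.sqrt(float(np.sum(wb**2)))
    score = float(num / denom) if denom > 0 else 0.0
    return min(score, 1.0), len(pairs)


def ppm_error(calc: float, meas: float) -> float:
    """Signed mass error (calc - meas)/calc in ppm, reported to 1 decimal."""
    if calc <= 0:
        raise ValueError("calculated m/z must be positive")
    return round((calc - meas) / calc * 1e6, 1)


def library_search(
    query: Spectrum,
    library,
    precursor_tol: float = 0.02,
    frag_tol: float = 0.05,
    rt_tol: float = 0.3,
) -> list[MatchResult]:
    """Rank library records against a query spectrum.

    Candidates are filtered by precursor m/z (``precursor_tol`` Da), scored by
    :func:`cosine_score`, and gated by retention time when both query and
    record have one (|dRT| <= ``rt_tol`` min).  RT-gate failures are retained
    but ranked below every passer; within a group ranking is by cosine.
    """
    if query.precursor_mz is None:
        raise ValueError("query spectrum has no precursor m/z")
    results = []
    for rec in library:
        spec = rec.spectrum if isinstance(rec, LibraryRecord) else rec
        rec_id = rec.id if isinstance(rec, LibraryRecord) else spec.id
        if spec.precursor_mz is None:
            continue
        if abs(spec.precursor_mz - query.precursor_mz) > precursor_tol:
            continue
        cosine, n_matched = cosine_score(query, spec, frag_tol=frag_tol)
        rt_delta = None
        passed = None
        if query.rt is not None and spec.rt is not None:
            rt_delta = abs(query.rt - spec.rt)
            passed = rt_delta <= rt_tol
        results.append(
            MatchResult(
                query_id=query.id,
                record_id=rec_id,
                cosine=cosine,
                n_matched=n_matched,
                ppm_error=ppm_error(spec.precursor_mz, query.precursor_mz),
                rt_delta_min=rt_delta,
                passed_rt_gate=passed,
            )
        )
    results.sort(
        key=lambda r: (
            0 if r.passed_rt_gate in (True, None) else 1,
            -r.cosine,
            r.record_id,
        )
    )
    return results
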