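"""Centroided MS/MS spectrum container and MGF / mzML input-output.

The internal unit is :class:`Spectrum`: one MS2 scan with its precursor
m/z, charge, retention time in minutes and an m/z-ascending peak list.
MGF is parsed and written directly (TITLE, PEPMASS, CHARGE, RTINSECONDS);
mzML 1.1 is handled by a deliberately minimal stdlib reader/writer that
understands the handful of CV terms needed for centroided MS2 peak lists
(64/32-bit float arrays, optional zlib compression). No vendor formats.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .chem import PROTON_MASS, ChimaError

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "read_spectra",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "write_mzml",
]


class SpectrumFormatError(ChimaError):
    """Malformed MGF/mzML content, reported with scan context."""


@dataclass
class Spectrum:
    """One centroided MS/MS scan.

    peaks is an (n, 2) float array of (m/z, intensity), strictly ascending
    in m/z; zero-intensity centroids are dropped on construction. A
    precursor charge of 0 means "unknown" and is resolved downstream by
    trying charges 2-4.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: Optional[float]  # minutes
    peaks: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        peaks = peaks[peaks[:, 1] > 0]
        order = np.argsort(peaks[:, 0], kind="stable")
        peaks = peaks[order]
        if np.any(peaks[:, 1] < 0):
            raise SpectrumFormatError(f"scan {self.scan_id}: negative intensity")
        self.peaks = peaks
        if self.precursor_mz <= 0:
            raise SpectrumFormatError(f"scan {self.scan_id}: non-positive precursor m/z")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.peaks[:, 1].max()) if len(self.peaks) else 0.0

    def precursor_neutral_mass(self, charge: Optional[int] = None) -> float:
        z = charge if charge is not None else self.precursor_charge
        if z < 1:
            raise ValueError(f"scan {self.scan_id}: unknown precursor charge")
        return self.precursor_mz * z - z * PROTON_MASS


def read_spectra(path, fmt: Optional[str] = None) -> Iterator[Spectrum]:
    """Stream MS2 spectra from an MGF or mzML file; format inferred from suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "mzml" if "mzml" in path.suffix.lower() else "mgf"
    fmt = fmt.lower()
    if fmt == "mgf":
        yield from read_mgf(path)
    elif fmt == "mzml":
        yield from read_mzml(path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path) -> Iterator[Spectrum]:
    path = Path(path)
    in_block = False
    title = None
    pepmass = None
    charge = 0
    rt_min: Optional[float] = None
    peaks: list = []
    index = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                title, pepmass, charge, rt_min, peaks = None, None, 0, None, []
                continue
            if line == "END IONS":
                if pepmass is None:
                    raise SpectrumFormatError(
                        f"{path.name} line {lineno}: spectrum without PEPMASS"
                    )
                index += 1
                yield Spectrum(
                    scan_id=title or f"index={index}",
                    precursor_mz=pepmass,
                    precursor_charge=charge,
                    retention_time=rt_min,
                    peaks=np.array(peaks, dtype=float).reshape(-1, 2),
                    source=f"{path.name}#{index}",
                )
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    v = value.strip().rstrip("+")
                    charge = -int(v.rstrip("-")) if v.endswith("-") else int(v or 0)
                elif key == "RTINSECONDS":
                    rt_min = float(value) / 60.0
                continue
            try:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                raise SpectrumFormatError(
                    f"{path.name} line {lineno}: bad peak line {line!r}"
                ) from None
    if in_block:
        raise SpectrumFormatError(f"{path.name}: unterminated BEGIN IONS block")


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Deterministic MGF writer (fixed float formatting, RT in seconds)."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.scan_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            if sp.precursor_charge:
                fh.write(f"CHARGE={sp.precursor_charge}+\n")
            if sp.retention_time is not None:
                fh.write(f"RTINSECONDS={sp.retention_time * 60.0:.3f}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# mzML (minimal)

_NS = "http://psi.hupo.org/ms/mzml"

# CV accessions this reader understands
_MS_LEVEL = "MS:1000511"
_PROFILE = "MS:1000128"
_SELECTED_MZ = "MS:1000744"
_CHARGE_STATE = "MS:1000041"
_SCAN_START = "MS:1000016"
_MZ_ARRAY = "MS:1000514"
_INTENSITY_ARRAY = "MS:1000515"
_F64 = "MS:1000523"
_F32 = "MS:1000521"
_ZLIB = "MS:1000574"
_NO_COMPRESSION = "MS:1000576"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict:
    out = {}
    for cv in elem.iter():
        if _local(cv.tag) == "cvParam":
            out[cv.get("accession")] = cv
    return out


def _decode_binary_array(bda) -> tuple:
    """Return (kind, numpy array) for one <binaryDataArray>."""
    accessions = {}
    text = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            accessions[child.get("accession")] = child
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if _ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = np.float64 if _F64 in accessions else np.float32
    arr = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if _MZ_ARRAY in accessions:
        return "mz", arr
    if _INTENSITY_ARRAY in accessions:
        return "intensity", arr
    return "other", arr


def read_mzml(path) -> Iterator[Spectrum]:
    """Stream MS2-level spectra from an mzML 1.1 file.

    MS1 scans are skipped; profile-mode spectra raise a warning and are
    treated as centroided.
    """
    path = Path(path)
    index = 0
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            index += 1
            scan_id = elem.get("id") or f"index={index}"
            params = {}
            for cv in elem.iter():
                if _local(cv.tag) == "cvParam":
                    params.setdefault(cv.get("accession"), cv)
            ms_level = int(params[_MS_LEVEL].get("value")) if _MS_LEVEL in params else None
            if ms_level != 2:
                elem.clear()
                continue
            if _PROFILE in params:
                warnings.warn(
                    f"scan {scan_id}: profile-mode data treated as centroided"
                )
            precursor_mz = 0.0
            charge = 0
            if _SELECTED_MZ in params:
                precursor_mz = float(params[_SELECTED_MZ].get("value"))
            if _CHARGE_STATE in params:
                charge = int(params[_CHARGE_STATE].get("value"))
            rt_min = None
            if _SCAN_START in params:
                cv = params[_SCAN_START]
                value = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                rt_min = value if unit.startswith("min") else value / 60.0
            mz = np.array([])
            intensity = np.array([])
            for child in elem.iter():
                if _local(child.tag) == "binaryDataArray":
                    kind, arr = _decode_binary_array(child)
                    if kind == "mz":
                        mz = arr
                    elif kind == "intensity":
                        intensity = arr
            if len(mz) != len(intensity):
                raise SpectrumFormatError(
                    f"{path.name} scan {scan_id}: m/z and intensity array "
                    f"lengths differ ({len(mz)} vs {len(intensity)})"
                )
            yield Spectrum(
                scan_id=scan_id,
                precursor_mz=precursor_mz,
                precursor_charge=charge,
                retention_time=rt_min,
                peaks=np.column_stack([mz, intensity]) if len(mz) else np.empty((0, 2)),
                source=f"{path.name}#{index}",
            )
            elem.clear()
    except ET.ParseError as exc:
        raise SpectrumFormatError(
            f"{path.name}: malformed mzML near scan {index}: {exc}"
        ) from None


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()


def write_mzml(spectra: Iterable[Spectrum], path) -> None:
    """Write a minimal mzML 1.1 document (64-bit, uncompressed, MS2 only)."""
    spectra = list(spectra)
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_NS}" version="1.1.0">',
        f'  <run id="run">',
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for i, sp in enumerate(spectra):
        rt = sp.retention_time if sp.retention_time is not None else 0.0
        lines += [
            f'      <spectrum index="{i}" id="{sp.scan_id}" defaultArrayLength="{len(sp.peaks)}">',
            f'        <cvParam cvRef="MS" accession="{_MS_LEVEL}" name="ms level" value="2"/>',
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
            '        <scanList count="1"><scan>',
            f'          <cvParam cvRef="MS" accession="{_SCAN_START}" name="scan start time" value="{rt:.6f}" unitName="minute"/>',
            '        </scan></scanList>',
            '        <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>',
            f'          <cvParam cvRef="MS" accession="{_SELECTED_MZ}" name="selected ion m/z" value="{sp.precursor_mz:.6f}"/>',
        ]
        if sp.precursor_charge:
            lines.append(
                f'          <cvParam cvRef="MS" accession="{_CHARGE_STATE}" name="charge state" value="{sp.precursor_charge}"/>'
            )
        lines += [
            '        </selectedIon></selectedIonList></precursor></precursorList>',
            '        <binaryDataArrayList count="2">',
            '          <binaryDataArray>',
            f'            <cvParam cvRef="MS" accession="{_F64}" name="64-bit float" value=""/>',
            f'            <cvParam cvRef="MS" accession="{_NO_COMPRESSION}" name="no compression" value=""/>',
            f'            <cvParam cvRef="MS" accession="{_MZ_ARRAY}" name="m/z array" value=""/>',
            f'            <binary>{_b64(sp.mz)}</binary>',
            '          </binaryDataArray>',
            '          <binaryDataArray>',
            f'            <cvParam cvRef="MS" accession="{_F64}" name="64-bit float" value=""/>',
            f'            <cvParam cvRef="MS" accession="{_NO_COMPRESSION}" name="no compression" value=""/>',
            f'            <cvParam cvRef="MS" accession="{_INTENSITY_ARRAY}" name="intensity array" value=""/>',
            f'            <binary>{_b64(sp.intensity)}</binary>',
            '          </binaryDataArray>',
            '        </binaryDataArrayList>',
            '      </spectrum>',
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    Path(path).write_text("\n".join(lines))
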