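"""Reading and writing centroided MS2 spectra (MGF and mzML).

``Ms2Spectrum`` is the boundary type every downstream module consumes.  MGF
round-trips through :mod:`pyteomics.mgf` with acquisition provenance embedded
in the TITLE line; mzML is read with :mod:`pyteomics.mzml` and written by a
minimal built-in mzML 1.1 serializer (base64-encoded 64-bit arrays, no
compression) sufficient for self-contained round-trip testing.

Retention times are seconds internally; minutes are converted on read.
m/z values are kept at full double precision in memory and formatted to five
decimals only at MGF serialization.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "Ms2Spectrum",
    "Ms1Feature",
    "SpectrumFormatError",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_ms1_features",
    "write_mzml",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed or unsupported spectrum files."""


@dataclass(frozen=True)
class Ms2Spectrum:
    """One centroided MS2 scan.

    ``provenance`` is ``"survey"`` for ordinary data-dependent scans and
    ``"triggered_step"`` for the extra stepped-collision-energy scans that a
    diagnostic-ion trigger schedules; triggered scans carry the scan id of the
    survey scan that fired the trigger.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    retention_time: float                     # seconds
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    nce: float = 28.0
    provenance: str = "survey"
    trigger_parent_scan: str | None = None

    def __post_init__(self):
        mz = np.asarray(self.peaks_mz, dtype=float)
        inten = np.asarray(self.peaks_intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        if self.provenance not in ("survey", "triggered_step"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "peaks_mz", mz)
        object.__setattr__(self, "peaks_intensity", inten)

    @property
    def n_peaks(self) -> int:
        return int(self.peaks_mz.size)

    def with_peaks(self, mz, intensity) -> "Ms2Spectrum":
        return replace(self, peaks_mz=np.asarray(mz, float),
                       peaks_intensity=np.asarray(intensity, float))


@dataclass(frozen=True)
class Ms1Feature:
    mz: float
    charge: int
    rt_start: float
    rt_end: float
    apex_intensity: float

    def __post_init__(self):
        if self.apex_intensity < 0:
            raise ValueError("negative apex intensity")


def _title(spectrum: Ms2Spectrum) -> str:
    parts = [spectrum.scan_id,
             f"provenance={spectrum.provenance}",
             f"nce={spectrum.nce:g}"]
    if spectrum.trigger_parent_scan is not None:
        parts.append(f"trigger_parent={spectrum.trigger_parent_scan}")
    return " ".join(parts)


def _parse_title(title: str) -> dict:
    tokens = title.split()
    out = {"scan_id": tokens[0] if tokens else "", "provenance": "survey",
           "nce": 28.0, "trigger_parent_scan": None}
    for token in tokens[1:]:
        if token.startswith("provenance="):
            out["provenance"] = token.split("=", 1)[1]
        elif token.startswith("nce="):
            out["nce"] = float(token.split("=", 1)[1])
        elif token.startswith("trigger_parent="):
            out["trigger_parent_scan"] = token.split("=", 1)[1]
    return out


def write_mgf(spectra: Iterable[Ms2Spectrum], path) -> None:
    """Write spectra as Mascot generic format, five-decimal m/z."""
    entries = []
    for s in spectra:
        entries.append({
            "m/z array": s.peaks_mz,
            "intensity array": s.peaks_intensity,
            "params": {
                "TITLE": _title(s),
                "PEPMASS": round(s.precursor_mz, 5),
                "CHARGE": f"{s.precursor_charge}+",
                "RTINSECONDS": round(s.retention_time, 3),
            },
        })
    _mgf.write(entries, str(path), fragment_format="{:.5f} {:.6g}",
               write_charges=False, use_numpy=False, file_mode="w")


def read_mgf(path) -> list[Ms2Spectrum]:
    """Read an MGF file; malformed blocks raise :class:`SpectrumFormatError`
    naming the offending block."""
    out: list[Ms2Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                title = params.get("title", "")
                if "pepmass" not in params:
                    raise SpectrumFormatError(
                        f"block {i + 1} (title {title!r}): missing PEPMASS")
                meta = _parse_title(title)
                charge = params.get("charge")
                charge = int(charge[0]) if charge else 1
                out.append(Ms2Spectrum(
                    scan_id=meta["scan_id"] or f"scan{i + 1}",
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    retention_time=float(params.get("rtinseconds", 0.0)),
                    peaks_mz=entry["m/z array"],
                    peaks_intensity=entry["intensity array"],
                    nce=meta["nce"],
                    provenance=meta["provenance"],
                    trigger_parent_scan=meta["trigger_parent_scan"],
                ))
    except SpectrumFormatError:
        raise
    except Exception as exc:  # pyteomics parse failures
        raise SpectrumFormatError(f"malformed MGF {path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# mzML

_NS = "http://psi.ms/mzml"


def _encode(array: np.ndarray) -> str:
    raw = np.asarray(array, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: Sequence[Ms2Spectrum], path) -> None:
    """Write a minimal centroided mzML 1.1 document (64-bit, uncompressed)."""
    spectra = list(spectra)
    root = etree.Element("mzML", nsmap={None: _NS}, version="1.1.0")
    etree.SubElement(root, "cvList", count="0")
    run = etree.SubElement(root, "run", id="run")
    speclist = etree.SubElement(run, "spectrumList",
                                count=str(len(spectra)))

    def cv(parent, accession, name, value="", **extra):
        etree.SubElement(parent, "cvParam", cvRef="MS", accession=accession,
                         name=name, value=value, **extra)

    for i, s in enumerate(spectra):
        spec = etree.SubElement(
            speclist, "spectrum", index=str(i),
            id=f"scan={s.scan_id}", defaultArrayLength=str(s.n_peaks))
        cv(spec, "MS:1000511", "ms level", "2")
        cv(spec, "MS:1000127", "centroid spectrum")
        cv(spec, "MS:1000512", "filter string",
           f"provenance={s.provenance} nce={s.nce:g}"
           + (f" trigger_parent={s.trigger_parent_scan}"
              if s.trigger_parent_scan else ""))
        scans = etree.SubElement(spec, "scanList", count="1")
        scan = etree.SubElement(scans, "scan")
        cv(scan, "MS:1000016", "scan start time", f"{s.retention_time:.4f}",
           unitName="second")
        precs = etree.SubElement(spec, "precursorList", count="1")
        prec = etree.SubElement(precs, "precursor")
        ions = etree.SubElement(prec, "selectedIonList", count="1")
        ion = etree.SubElement(ions, "selectedIon")
        cv(ion, "MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}")
        cv(ion, "MS:1000041", "charge state", str(s.precursor_charge))
        arrays = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, data in (
            ("MS:1000514", "m/z array", s.peaks_mz),
            ("MS:1000515", "intensity array", s.peaks_intensity),
        ):
            encoded = _encode(data)
            arr = etree.SubElement(arrays, "binaryDataArray",
                                   encodedLength=str(len(encoded)))
            cv(arr, "MS:1000523", "64-bit float")
            cv(arr, "MS:1000576", "no compression")
            cv(arr, accession, name)
            etree.SubElement(arr, "binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8",
               pretty_print=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, dict]:
    """accession-keyed and name-keyed cvParams directly under element."""
    out = {}
    for child in element:
        if _local(child.tag) != "cvParam":
            continue
        record = dict(child.attrib)
        out[record.get("accession", "")] = record
        out[record.get("name", "")] = record
    return out


def _decode_array(array_element) -> tuple[str, np.ndarray]:
    params = _cv_params(array_element)
    if "MS:1000514" in params or "m/z array" in params:
        kind = "mz"
    elif "MS:1000515" in params or "intensity array" in params:
        kind = "intensity"
    else:
        kind = "other"
    dtype = "<f8"
    if "MS:1000521" in params or "32-bit float" in params:
        dtype = "<f4"
    binary = ""
    for child in array_element:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if "MS:1000574" in params or "zlib compression" in params:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_spectrum_elements(path):
    try:
        for _event, element in etree.iterparse(str(path), events=("end",)):
            if _local(element.tag) == "spectrum":
                yield element
                element.clear()
    except etree.XMLSyntaxError as exc:
        raise SpectrumFormatError(f"malformed mzML {path}: {exc}") from exc


def _parse_spectrum_element(element) -> dict:
    params = _cv_params(element)
    record = {
        "id": element.get("id", ""),
        "ms_level": int(params["MS:1000511"]["value"])
        if "MS:1000511" in params else None,
        "profile": "MS:1000128" in params or "profile spectrum" in params,
        "filter": params.get("MS:1000512", {}).get("value", ""),
        "rt": 0.0, "precursor_mz": None, "charge": 1,
        "mz": np.array([]), "intensity": np.array([]),
    }
    for child in element.iter():
        tag = _local(child.tag)
        if tag == "scan":
            scan_params = _cv_params(child)
            if "MS:1000016" in scan_params:
                entry = scan_params["MS:1000016"]
                rt = float(entry["value"])
                if entry.get("unitName", "second").startswith("min"):
                    rt *= 60.0
                record["rt"] = rt
        elif tag == "selectedIon":
            ion_params = _cv_params(child)
            if "MS:1000744" in ion_params:
                record["precursor_mz"] = float(
                    ion_params["MS:1000744"]["value"])
            if "MS:1000041" in ion_params:
                record["charge"] = int(ion_params["MS:1000041"]["value"])
        elif tag == "binaryDataArray":
            kind, values = _decode_array(child)
            if kind == "mz":
                record["mz"] = values
            elif kind == "intensity":
                record["intensity"] = values
    return record


def read_mzml(path) -> list[Ms2Spectrum]:
    """Read centroided MS2 scans from an mzML 1.1 file.

    The built-in reader handles 32/64-bit float peak arrays with zlib or no
    compression.  Profile-mode spectra raise :class:`SpectrumFormatError`;
    MS1 scans are skipped here (see :func:`read_ms1_features`).
    """
    out: list[Ms2Spectrum] = []
    for element in _iter_spectrum_elements(path):
        record = _parse_spectrum_element(element)
        if record["ms_level"] != 2:
            continue
        if record["profile"]:
            raise SpectrumFormatError(
                "profile-mode spectra are not supported; centroid first")
        if record["precursor_mz"] is None:
            raise SpectrumFormatError(
                f"MS2 spectrum {record['id']!r} lacks a selected ion m/z")
        meta = {"provenance": "survey", "nce": 28.0,
                "trigger_parent_scan": None}
        if record["filter"]:
            meta.update({k: v for k, v in
                         _parse_title("x " + record["filter"]).items()
                         if k != "scan_id"})
        out.append(Ms2Spectrum(
            scan_id=record["id"].split("scan=")[-1],
            precursor_mz=record["precursor_mz"],
            precursor_charge=record["charge"],
            retention_time=record["rt"],
            peaks_mz=record["mz"],
            peaks_intensity=record["intensity"],
            nce=meta["nce"],
            provenance=meta["provenance"],
            trigger_parent_scan=meta["trigger_parent_scan"],
        ))
    return out


def read_ms1_features(path) -> list[Ms1Feature]:
    """Expose MS1 scans of an mzML file as a flat apex-feature stream.

    Each MS1 peak becomes one feature whose retention-time window is the scan
    time itself; feature finding across scans is out of scope.
    """
    out: list[Ms1Feature] = []
    for element in _iter_spectrum_elements(path):
        record = _parse_spectrum_element(element)
        if record["ms_level"] != 1:
            continue
        for mz, inten in zip(record["mz"], record["intensity"]):
            out.append(Ms1Feature(mz=float(mz), charge=0,
                                  rt_start=record["rt"],
                                  rt_end=record["rt"],
                                  apex_intensity=float(inten)))
    return out
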