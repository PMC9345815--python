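"""Reading and writing centroided mass-spectrometry runs.

Flow-infusion electrospray (FIE) acquisitions produce a short train of
scans per file, typically interleaving several *scan filters* — a
(polarity, acquisition m/z range) pair such as ``positive 55-280``.
This module loads each spectrum as a :class:`ScanEvent`, discovers the
filter structure of a run, and assigns each scan a *cycle ordinal*: its
rank among the scans of its own filter.  Cycle ordinals align the
per-filter ion chromatograms so that infusion profiles can be averaged
across filters and replicate injections.

mzML (PSI standard) is the reference format; mzXML is accepted read-only
as a convenience dialect.  Only centroided MS1 spectra are supported —
profile-mode data must be centroided upstream (e.g. with msconvert).
"""

from __future__ import annotations

import base64
import os
import struct
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "CentroidPeak",
    "ScanEvent",
    "ScanFilter",
    "read_centroided_run",
    "detect_scan_filters",
    "assign_cycle_ordinals",
    "write_mzml",
]

Polarity = Literal["positive", "negative"]

_MZML_NS = "http://psi.hupo.org/ms/mzml"
_MZXML_NS_PREFIX = "http://sashimi.sourceforge.net/schema_revision/mzXML"


class CentroidPeak(NamedTuple):
    """A single centroided mass-spectral signal: (m/z in Da, abundance)."""

    mz: float
    intensity: float


@dataclass
class ScanEvent:
    """One centroided scan of one sample.

    Parameters
    ----------
    sample_id : str
        Opaque sample label (defaults to the file stem on reading).
    scan_index : int
        1-based ordinal position of the scan in its file, in acquisition
        order.  Vendor scan numbers are deliberately ignored; the method
        only needs position along the infusion.
    polarity : {"positive", "negative"}
    scan_range : (float, float) or None
        Acquisition window (low, high) in Da.  ``None`` when the file
        carries no window metadata; downstream filter detection rejects
        such scans.
    mz, intensity : ndarray
        Parallel peak arrays, sorted ascending by m/z.
    cycle : int
        Cycle ordinal: rank of this scan among scans sharing its filter
        (1-based).  Assigned by :func:`assign_cycle_ordinals`; 0 means
        unassigned.
    """

    sample_id: str
    scan_index: int
    polarity: Polarity
    scan_range: tuple[float, float] | None
    mz: np.ndarray
    intensity: np.ndarray
    cycle: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.scan_range is not None:
            low, high = self.scan_range
            if not low < high:
                raise ValueError(f"invalid scan range {self.scan_range!r}")

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, a) for m, a in zip(self.mz, self.intensity)]

    @property
    def tic(self) -> float:
        """Total ion count: the sum of all peak intensities."""
        return float(self.intensity.sum())

    @property
    def filter(self) -> "ScanFilter":
        if self.scan_range is None:
            raise ValueError(
                f"scan {self.scan_index} of {self.sample_id!r} has no "
                "acquisition range; cannot form a scan filter"
            )
        return ScanFilter(self.polarity, self.scan_range)


class ScanFilter(NamedTuple):
    """A (polarity, acquisition range) pair identifying one scan event type."""

    polarity: Polarity
    scan_range: tuple[float, float]


def detect_scan_filters(scans: Sequence[ScanEvent]) -> list[ScanFilter]:
    """Enumerate the distinct scan filters present in a run.

    Returns the set of distinct (polarity, range) pairs in deterministic
    order: polarity first (negative before positive, alphabetical), then
    low range bound.  Raises ``ValueError`` on an empty scan list or if
    any scan lacks an acquisition range.
    """
    if not scans:
        raise ValueError("cannot detect scan filters of an empty run")
    filters = {scan.filter for scan in scans}
    return sorted(filters, key=lambda f: (f.polarity, f.scan_range))


def assign_cycle_ordinals(scans: Sequence[ScanEvent]) -> list[ScanEvent]:
    """Assign each scan its cycle ordinal: rank among scans of its filter.

    Scans of different filters acquired in the same instrument cycle get
    the same ordinal, so per-filter chromatograms align when profiles are
    averaged across filters.  Returns new ScanEvents; input order kept.
    """
    counters: dict[ScanFilter, int] = {}
    out = []
    for scan in scans:
        f = scan.filter
        counters[f] = counters.get(f, 0) + 1
        out.append(replace(scan, cycle=counters[f]))
    return out


# ---------------------------------------------------------------------------
# Reading

_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_WINDOW_LOW = "MS:1000501"
_ACC_WINDOW_HIGH = "MS:1000502"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def read_centroided_run(path: str | os.PathLike) -> list[ScanEvent]:
    """Read a centroided mzML (or mzXML) file into ScanEvents.

    Every spectrum becomes one :class:`ScanEvent` with a 1-based
    ``scan_index`` in file order and its ``cycle`` ordinal assigned.
    Polarity and acquisition range are taken from scan metadata.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file cannot be parsed, a spectrum is profile-mode, or a
        spectrum carries no polarity metadata.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sample_id = os.path.splitext(os.path.basename(path))[0]
    if path.lower().endswith((".mzxml",)):
        scans = _read_mzxml(path, sample_id)
    else:
        scans = _read_mzml(path, sample_id)
    return assign_cycle_ordinals(scans) if scans else scans


def _decode_binary(text: str | None, accessions: set[str], n: int) -> np.ndarray:
    raw = base64.b64decode(text or "")
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if n and arr.size != n:
        raise ValueError(f"binary array length {arr.size} != declared {n}")
    return arr


def _read_mzml(path: str, sample_id: str) -> list[ScanEvent]:
    scans: list[ScanEvent] = []
    tag = f"{{{_MZML_NS}}}spectrum"
    try:
        context = etree.iterparse(path, events=("end",), tag=tag)
        for _, elem in context:
            scans.append(_parse_mzml_spectrum(elem, sample_id, len(scans) + 1))
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot parse {path!r} as mzML: {exc}") from exc
    return scans


def _cv_accessions(elem) -> dict[str, str]:
    """accession -> value for all cvParams directly under ``elem`` subtree."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in elem.iter(f"{{{_MZML_NS}}}cvParam")
    }


def _parse_mzml_spectrum(elem, sample_id: str, index: int) -> ScanEvent:
    spec_params = {
        cv.get("accession")
        for cv in elem.findall(f"{{{_MZML_NS}}}cvParam")
    }
    scan_id = elem.get("id", f"index={index - 1}")
    if _ACC_PROFILE in spec_params:
        raise ValueError(
            f"spectrum {scan_id!r} in {sample_id!r} is profile-mode; "
            "centroid the data before processing"
        )
    if _ACC_POSITIVE in spec_params:
        polarity: Polarity = "positive"
    elif _ACC_NEGATIVE in spec_params:
        polarity = "negative"
    else:
        raise ValueError(
            f"spectrum {scan_id!r} in {sample_id!r} has no polarity metadata"
        )

    scan_range = None
    window = elem.find(
        f"{{{_MZML_NS}}}scanList/{{{_MZML_NS}}}scan/"
        f"{{{_MZML_NS}}}scanWindowList/{{{_MZML_NS}}}scanWindow"
    )
    if window is not None:
        params = _cv_accessions(window)
        if _ACC_WINDOW_LOW in params and _ACC_WINDOW_HIGH in params:
            scan_range = (float(params[_ACC_WINDOW_LOW]), float(params[_ACC_WINDOW_HIGH]))

    n = int(elem.get("defaultArrayLength", 0))
    mz = np.empty(0)
    intensity = np.empty(0)
    for arr_elem in elem.findall(
        f"{{{_MZML_NS}}}binaryDataArrayList/{{{_MZML_NS}}}binaryDataArray"
    ):
        accs = {cv.get("accession") for cv in arr_elem.findall(f"{{{_MZML_NS}}}cvParam")}
        binary = arr_elem.find(f"{{{_MZML_NS}}}binary")
        data = _decode_binary(binary.text if binary is not None else None, accs, n)
        if _ACC_MZ_ARRAY in accs:
            mz = data
        elif _ACC_INT_ARRAY in accs:
            intensity = data
    return ScanEvent(sample_id, index, polarity, scan_range, mz, intensity)


def _read_mzxml(path: str, sample_id: str) -> list[ScanEvent]:
    scans: list[ScanEvent] = []
    try:
        for _, elem in etree.iterparse(path, events=("end",)):
            if etree.QName(elem).localname != "scan":
                continue
            scans.append(_parse_mzxml_scan(elem, sample_id, len(scans) + 1))
            elem.clear(keep_tail=True)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot parse {path!r} as mzXML: {exc}") from exc
    return scans


def _parse_mzxml_scan(elem, sample_id: str, index: int) -> ScanEvent:
    if elem.get("centroided", "1") in ("0", "false"):
        raise ValueError(
            f"scan {elem.get('num', index)} in {sample_id!r} is profile-mode"
        )
    pol_attr = elem.get("polarity")
    if pol_attr == "+":
        polarity: Polarity = "positive"
    elif pol_attr == "-":
        polarity = "negative"
    else:
        raise ValueError(
            f"scan {elem.get('num', index)} in {sample_id!r} has no polarity metadata"
        )
    scan_range = None
    if elem.get("lowMz") and elem.get("highMz"):
        scan_range = (float(elem.get("lowMz")), float(elem.get("highMz")))

    peaks_elem = next(
        (c for c in elem if etree.QName(c).localname == "peaks"), None
    )
    mz = np.empty(0)
    intensity = np.empty(0)
    if peaks_elem is not None and peaks_elem.text:
        raw = base64.b64decode(peaks_elem.text)
        if peaks_elem.get("compressionType", "none") == "zlib":
            raw = zlib.decompress(raw)
        # mzXML packs interleaved m/z,intensity pairs in network byte order
        prec = peaks_elem.get("precision", "32")
        pairs = np.frombuffer(raw, dtype=">f8" if prec == "64" else ">f4")
        mz = pairs[0::2].astype(float)
        intensity = pairs[1::2].astype(float)
    return ScanEvent(sample_id, index, polarity, scan_range, mz, intensity)


# ---------------------------------------------------------------------------
# Writing (mzML only)


def _b64(values: Iterable[float]) -> str:
    return base64.b64encode(np.asarray(list(values), dtype="<f8").tobytes()).decode()


def write_mzml(path: str | os.PathLike, scans: Sequence[ScanEvent]) -> None:
    """Write scans as a minimal standard-conforming centroid mzML file.

    Peak arrays are encoded as uncompressed little-endian 64-bit floats.
    """
    nsmap = {None: _MZML_NS}
    root = etree.Element(f"{{{_MZML_NS}}}mzML", nsmap=nsmap, version="1.1.0")

    def sub(parent, tag, **attrib):
        return etree.SubElement(parent, f"{{{_MZML_NS}}}{tag}", **attrib)

    def cv(parent, accession, name, value=""):
        etree.SubElement(
            parent,
            f"{{{_MZML_NS}}}cvParam",
            cvRef="MS",
            accession=accession,
            name=name,
            value=value,
        )

    cvlist = sub(root, "cvList", count="1")
    sub(
        cvlist,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdesc = sub(root, "fileDescription")
    fcontent = sub(fdesc, "fileContent")
    cv(fcontent, "MS:1000579", "MS1 spectrum")
    cv(fcontent, _ACC_CENTROID, "centroid spectrum")
    slist = sub(root, "softwareList", count="1")
    sw = sub(slist, "software", id="fiebin", version="0.1.0")
    cv(sw, "MS:1000799", "custom unreleased software tool", "fiebin")
    iclist = sub(root, "instrumentConfigurationList", count="1")
    ic = sub(iclist, "instrumentConfiguration", id="IC1")
    cv(ic, "MS:1000031", "instrument model")
    dplist = sub(root, "dataProcessingList", count="1")
    dp = sub(dplist, "dataProcessing", id="DP1")
    pm = sub(dp, "processingMethod", order="1", softwareRef="fiebin")
    cv(pm, "MS:1000544", "Conversion to mzML")

    run = sub(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    speclist = sub(run, "spectrumList", count=str(len(scans)), defaultDataProcessingRef="DP1")
    for i, scan in enumerate(scans):
        spec = sub(
            speclist,
            "spectrum",
            index=str(i),
            id=f"scan={scan.scan_index}",
            defaultArrayLength=str(scan.mz.size),
        )
        cv(spec, "MS:1000579", "MS1 spectrum")
        cv(spec, "MS:1000511", "ms level", "1")
        cv(spec, _ACC_CENTROID, "centroid spectrum")
        if scan.polarity == "positive":
            cv(spec, _ACC_POSITIVE, "positive scan")
        else:
            cv(spec, _ACC_NEGATIVE, "negative scan")
        sl = sub(spec, "scanList", count="1")
        cv(sl, "MS:1000795", "no combination")
        sc = sub(sl, "scan")
        cv(sc, "MS:1000016", "scan start time", str(float(scan.scan_index)))
        if scan.scan_range is not None:
            swl = sub(sc, "scanWindowList", count="1")
            sw_elem = sub(swl, "scanWindow")
            cv(sw_elem, _ACC_WINDOW_LOW, "scan window lower limit", repr(scan.scan_range[0]))
            cv(sw_elem, _ACC_WINDOW_HIGH, "scan window upper limit", repr(scan.scan_range[1]))
        bdal = sub(spec, "binaryDataArrayList", count="2")
        for accession, name, values in (
            (_ACC_MZ_ARRAY, "m/z array", scan.mz),
            (_ACC_INT_ARRAY, "intensity array", scan.intensity),
        ):
            encoded = _b64(values)
            bda = sub(bdal, "binaryDataArray", encodedLength=str(len(encoded)))
            cv(bda, _ACC_F64, "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, accession, name)
            binary = sub(bda, "binary")
            binary.text = encoded

    tree = etree.ElementTree(root)
    tree.write(os.fspath(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
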