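"""Parse mzML/mzXML scan fragments and file headers.

Fragments may come from a whole-file parse (namespaced) or from raw byte
spans cut out by the indexer (usually namespace-free); all tag matching is
on local names so both work identically.

mzML metadata is annotated against a bundled snapshot of the PSI-MS
controlled vocabulary; mzXML metadata is taken directly from attributes.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Iterator, Optional

import numpy as np

from . import codec
from .errors import FormatParseError, MalformedChromatogramError, MalformedSpectrumError
from .model import (
    ArrayKind,
    ArrayLayout,
    BinaryArrayDescriptor,
    ByteOrder,
    Chromatogram,
    Compression,
    MetadataEntry,
    PeakList,
    Polarity,
    Precision,
    PrecursorRef,
    RunMetadata,
    ScanHeader,
    SourceFormat,
    Spectrum,
    canonicalize,
)

__all__ = [
    "CvTerm",
    "parse_mzml_spectrum",
    "parse_mzxml_scan",
    "parse_mzml_chromatogram",
    "annotate_metadata",
    "load_vocabulary",
    "parse_iso_duration",
    "rt_to_seconds",
]

_ACCESSION_RE = re.compile(r"^(?:MS|UO):\d{7}$")

# accessions this reader acts on
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_BASE_PEAK_MZ = "MS:1000504"
_ACC_BASE_PEAK_INT = "MS:1000505"
_ACC_TIC = "MS:1000285"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_F32 = "MS:1000521"
_ACC_F64 = "MS:1000523"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_UNIT_SECOND = "UO:0000010"
_ACC_UNIT_MINUTE = "UO:0000031"
_ACC_UNIT_MS = "UO:0000028"


@dataclass(frozen=True)
class CvTerm:
    """One controlled-vocabulary parameter as it appears in the file."""

    accession: str
    name: str
    value: Optional[str] = None
    unit_accession: Optional[str] = None

    @property
    def is_syntactically_valid(self) -> bool:
        return bool(_ACCESSION_RE.match(self.accession))


@lru_cache(maxsize=1)
def load_vocabulary() -> dict[str, str]:
    """Bundled accession -> preferred-name table (PSI-MS + unit ontology)."""
    table: dict[str, str] = {}
    text = (
        resources.files("mzview").joinpath("data/psi_ms_terms.tsv").read_text("utf-8")
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        accession, _, name = line.partition("\t")
        table[accession] = name
    return table


def annotate_metadata(raw_terms: Iterable[CvTerm]) -> list[MetadataEntry]:
    """Replace term names with the vocabulary's preferred names.

    Unknown accessions keep the file's own name and are marked unverified.
    Best-effort by design: never raises.
    """
    vocab = load_vocabulary()
    out: list[MetadataEntry] = []
    for term in raw_terms:
        preferred = vocab.get(term.accession)
        out.append(
            MetadataEntry(
                name=preferred if preferred is not None else term.name,
                accession=term.accession or None,
                value=term.value,
                verified=preferred is not None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# low-level XML helpers


def local_name(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_fragment(fragment: bytes | str) -> ET.Element:
    try:
        return ET.fromstring(fragment)
    except ET.ParseError as exc:
        raise FormatParseError(f"unparseable XML fragment: {exc}") from exc


def _find_child(elem: ET.Element, name: str) -> Optional[ET.Element]:
    for child in elem:
        if local_name(child.tag) == name:
            return child
    return None


def _iter_children(elem: ET.Element, name: str) -> Iterator[ET.Element]:
    for child in elem:
        if local_name(child.tag) == name:
            yield child


def iter_cv_params(elem: ET.Element) -> Iterator[CvTerm]:
    """Direct cvParam children of *elem* (non-recursive)."""
    for child in _iter_children(elem, "cvParam"):
        yield CvTerm(
            accession=child.get("accession", ""),
            name=child.get("name", ""),
            value=child.get("value"),
            unit_accession=child.get("unitAccession"),
        )


_ISO_DURATION_RE = re.compile(
    r"^(?P<sign>-)?P(?:(?P<days>[\d.]+)D)?"
    r"(?:T(?:(?P<hours>[\d.]+)H)?(?:(?P<minutes>[\d.]+)M)?(?:(?P<seconds>[\d.]+)S)?)?$"
)


def parse_iso_duration(text: str) -> float:
    """ISO-8601 duration (mzXML retentionTime, e.g. "PT600.5S") -> seconds."""
    m = _ISO_DURATION_RE.match(text.strip())
    if not m or text.strip() in ("P", "PT"):
        raise MalformedSpectrumError(f"invalid ISO-8601 duration: {text!r}")
    total = (
        float(m.group("days") or 0) * 86400.0
        + float(m.group("hours") or 0) * 3600.0
        + float(m.group("minutes") or 0) * 60.0
        + float(m.group("seconds") or 0)
    )
    return -total if m.group("sign") else total


def rt_to_seconds(value: float, unit_accession: Optional[str]) -> float:
    """Normalize a scan-start-time value to seconds via its CV unit."""
    if unit_accession == _ACC_UNIT_MINUTE:
        return value * 60.0
    if unit_accession == _ACC_UNIT_MS:
        return value / 1000.0
    # seconds, or unit omitted (mzML default practice: treat as seconds)
    return value


# ---------------------------------------------------------------------------
# mzML


def _parse_binary_array(
    bda: ET.Element, default_length: Optional[int]
) -> tuple[ArrayKind, codec.EncodedArray, Optional[str]]:
    precision = Precision.F64
    compression = Compression.NONE
    kind = ArrayKind.OTHER
    unit = None
    for term in iter_cv_params(bda):
        if term.accession == _ACC_F32:
            precision = Precision.F32
        elif term.accession == _ACC_F64:
            precision = Precision.F64
        elif term.accession == _ACC_ZLIB:
            compression = Compression.ZLIB
        elif term.accession == _ACC_NO_COMPRESSION:
            compression = Compression.NONE
        elif term.accession == _ACC_MZ_ARRAY:
            kind = ArrayKind.MZ
        elif term.accession == _ACC_INT_ARRAY:
            kind = ArrayKind.INTENSITY
        elif term.accession == _ACC_TIME_ARRAY:
            kind = ArrayKind.TIME
            unit = term.unit_accession
    binary = _find_child(bda, "binary")
    text = (binary.text or "") if binary is not None else ""
    length = bda.get("arrayLength")
    declared = int(length) if length is not None else default_length
    desc = BinaryArrayDescriptor(
        precision=precision,
        compression=compression,
        byte_order=ByteOrder.LITTLE,
        layout=ArrayLayout.SEPARATE,
        array_kind=kind,
    )
    return kind, codec.EncodedArray(text.strip(), desc, declared), unit


def _parse_mzml_precursor(spectrum_elem: ET.Element) -> Optional[PrecursorRef]:
    plist = _find_child(spectrum_elem, "precursorList")
    if plist is None:
        return None
    precursor = _find_child(plist, "precursor")
    if precursor is None:
        return None
    parent_ref = precursor.get("spectrumRef")
    selected_mz = None
    charge = None
    window = None
    iso = _find_child(precursor, "isolationWindow")
    if iso is not None:
        target = lower = upper = None
        for term in iter_cv_params(iso):
            if term.accession == _ACC_ISO_TARGET and term.value:
                target = float(term.value)
            elif term.accession == _ACC_ISO_LOWER and term.value:
                lower = float(term.value)
            elif term.accession == _ACC_ISO_UPPER and term.value:
                upper = float(term.value)
        if target is not None and lower is not None and upper is not None:
            window = (target - lower, target + upper)
    silist = _find_child(precursor, "selectedIonList")
    if silist is not None:
        si = _find_child(silist, "selectedIon")
        if si is not None:
            for term in iter_cv_params(si):
                if term.accession == _ACC_SELECTED_MZ and term.value:
                    selected_mz = float(term.value)
                elif term.accession == _ACC_CHARGE and term.value:
                    charge = int(term.value)
    if selected_mz is None:
        return None
    return PrecursorRef(
        selected_ion_mz=selected_mz,
        parent_scan_id=parent_ref,
        charge=charge,
        isolation_window=window,
    )


def parse_mzml_header(
    elem: ET.Element | bytes | str, index_position: int = 0
) -> ScanHeader:
    """ScanHeader from a ``<spectrum>`` element, without decoding arrays."""
    if not isinstance(elem, ET.Element):
        elem = parse_fragment(elem)
    scan_id = elem.get("id", "")
    ms_level = 1
    base_peak_mz = base_peak_int = tic = None
    polarity = Polarity.UNKNOWN
    centroided: Optional[bool] = None
    for term in iter_cv_params(elem):
        if term.accession == _ACC_MS_LEVEL and term.value:
            ms_level = int(term.value)
        elif term.accession == _ACC_BASE_PEAK_MZ and term.value:
            base_peak_mz = float(term.value)
        elif term.accession == _ACC_BASE_PEAK_INT and term.value:
            base_peak_int = float(term.value)
        elif term.accession == _ACC_TIC and term.value:
            tic = float(term.value)
        elif term.accession == _ACC_POSITIVE:
            polarity = Polarity.POSITIVE
        elif term.accession == _ACC_NEGATIVE:
            polarity = Polarity.NEGATIVE
        elif term.accession == _ACC_CENTROID:
            centroided = True
        elif term.accession == _ACC_PROFILE:
            centroided = False
    rt = 0.0
    scan_list = _find_child(elem, "scanList")
    if scan_list is not None:
        scan = _find_child(scan_list, "scan")
        if scan is not None:
            for term in iter_cv_params(scan):
                if term.accession == _ACC_SCAN_START and term.value:
                    rt = rt_to_seconds(float(term.value), term.unit_accession)
    return ScanHeader(
        scan_id=scan_id,
        index_position=index_position,
        ms_level=ms_level,
        retention_time_s=rt,
        base_peak_mz=base_peak_mz,
        base_peak_intensity=base_peak_int,
        total_ion_current=tic,
        precursor=_parse_mzml_precursor(elem),
        polarity=polarity,
        centroided=centroided,
    )


def parse_mzml_spectrum(
    fragment: ET.Element | bytes | str, index_position: int = 0
) -> Spectrum:
    """Full Spectrum (header + decoded, canonicalized peaks) from a
    ``<spectrum>`` element or its serialized bytes."""
    elem = fragment if isinstance(fragment, ET.Element) else parse_fragment(fragment)
    if local_name(elem.tag) != "spectrum":
        raise MalformedSpectrumError(
            f"expected <spectrum>, got <{local_name(elem.tag)}>"
        )
    header = parse_mzml_header(elem, index_position)
    default_len = elem.get("defaultArrayLength")
    default_len = int(default_len) if default_len is not None else None
    mz_arr = int_arr = None
    bda_list = _find_child(elem, "binaryDataArrayList")
    if bda_list is not None:
        for bda in _iter_children(bda_list, "binaryDataArray"):
            kind, enc, _ = _parse_binary_array(bda, default_len)
            if kind is ArrayKind.MZ:
                mz_arr = codec.decode_array(enc)
            elif kind is ArrayKind.INTENSITY:
                int_arr = codec.decode_array(enc)
    if mz_arr is None or int_arr is None:
        if default_len == 0 and mz_arr is None and int_arr is None and bda_list is None:
            mz_arr, int_arr = np.array([]), np.array([])
        else:
            raise MalformedSpectrumError(
                f"spectrum {header.scan_id!r} lacks "
                f"{'m/z' if mz_arr is None else 'intensity'} array"
            )
    peaks = canonicalize(PeakList(mz=mz_arr, intensity=int_arr))
    return Spectrum(header=header, peaks=peaks)


def parse_mzml_chromatogram(fragment: ET.Element | bytes | str) -> Chromatogram:
    """Decode one mzML ``<chromatogram>`` element into a (time, intensity)
    trace with time normalized to seconds."""
    elem = fragment if isinstance(fragment, ET.Element) else parse_fragment(fragment)
    chrom_id = elem.get("id", "")
    default_len = elem.get("defaultArrayLength")
    default_len = int(default_len) if default_len is not None else None
    time_arr = int_arr = None
    time_unit = None
    bda_list = _find_child(elem, "binaryDataArrayList")
    if bda_list is not None:
        for bda in _iter_children(bda_list, "binaryDataArray"):
            kind, enc, unit = _parse_binary_array(bda, default_len)
            if kind is ArrayKind.TIME:
                time_arr = codec.decode_array(enc)
                time_unit = unit
            elif kind is ArrayKind.INTENSITY:
                int_arr = codec.decode_array(enc)
    if time_arr is None or int_arr is None:
        raise MalformedChromatogramError(
            f"chromatogram {chrom_id!r} lacks time or intensity array"
        )
    if time_arr.size != int_arr.size:
        raise MalformedChromatogramError(
            f"chromatogram {chrom_id!r}: time/intensity length mismatch "
            f"({time_arr.size} vs {int_arr.size})"
        )
    if time_unit == _ACC_UNIT_MINUTE:
        time_arr = time_arr * 60.0
    elif time_unit == _ACC_UNIT_MS:
        time_arr = time_arr / 1000.0
    return Chromatogram(
        kind="file_declared", chrom_id=chrom_id, time_s=time_arr, intensity=int_arr
    )


# ---------------------------------------------------------------------------
# mzXML


def parse_mzxml_header(
    elem: ET.Element | bytes | str, index_position: int = 0
) -> ScanHeader:
    """ScanHeader from a ``<scan>`` element's attributes (child scans,
    which are separate index entries, are ignored)."""
    if not isinstance(elem, ET.Element):
        elem = parse_fragment(elem)
    num = elem.get("num", "")
    ms_level = int(elem.get("msLevel", "1"))
    rt_attr = elem.get("retentionTime")
    rt = parse_iso_duration(rt_attr) if rt_attr else 0.0
    pol_attr = elem.get("polarity")
    polarity = {
        "+": Polarity.POSITIVE,
        "-": Polarity.NEGATIVE,
    }.get(pol_attr or "", Polarity.UNKNOWN)
    centroided_attr = elem.get("centroided")
    centroided = None if centroided_attr is None else centroided_attr == "1"

    def _float_attr(name: str) -> Optional[float]:
        v = elem.get(name)
        return float(v) if v is not None else None

    precursor = None
    pmz = _find_child(elem, "precursorMz")
    if pmz is not None and pmz.text and pmz.text.strip():
        charge = pmz.get("precursorCharge")
        parent = pmz.get("precursorScanNum")
        precursor = PrecursorRef(
            selected_ion_mz=float(pmz.text.strip()),
            parent_scan_id=parent,
            charge=int(charge) if charge is not None else None,
        )
    return ScanHeader(
        scan_id=str(int(num)) if num else "",
        index_position=index_position,
        ms_level=ms_level,
        retention_time_s=rt,
        base_peak_mz=_float_attr("basePeakMz"),
        base_peak_intensity=_float_attr("basePeakIntensity"),
        total_ion_current=_float_attr("totIonCurrent"),
        precursor=precursor,
        polarity=polarity,
        centroided=centroided,
    )


def parse_mzxml_scan(
    fragment: ET.Element | bytes | str, index_position: int = 0
) -> Spectrum:
    """Full Spectrum from a ``<scan>`` element: attributes mapped to the
    header, the ``<peaks>`` child decoded (big-endian, interleaved pairs)."""
    elem = fragment if isinstance(fragment, ET.Element) else parse_fragment(fragment)
    if local_name(elem.tag) != "scan":
        raise MalformedSpectrumError(f"expected <scan>, got <{local_name(elem.tag)}>")
    header = parse_mzxml_header(elem, index_position)
    peaks_elem = _find_child(elem, "peaks")
    if peaks_elem is None:
        raise MalformedSpectrumError(f"scan {header.scan_id!r} lacks <peaks>")
    precision = peaks_elem.get("precision", "64")
    compression = peaks_elem.get("compressionType", "none")
    byte_order = peaks_elem.get("byteOrder", "network")
    desc = BinaryArrayDescriptor(
        precision=Precision.F32 if precision == "32" else Precision.F64,
        compression=Compression.ZLIB if compression == "zlib" else Compression.NONE,
        byte_order=ByteOrder.LITTLE if byte_order == "little" else ByteOrder.BIG,
        layout=ArrayLayout.INTERLEAVED,
        array_kind=ArrayKind.OTHER,
    )
    count = elem.get("peaksCount")
    declared = 2 * int(count) if count is not None else None
    enc = codec.EncodedArray((peaks_elem.text or "").strip(), desc, declared)
    values = codec.decode_array(enc)
    peaks = canonicalize(codec.deinterleave(values))
    return Spectrum(header=header, peaks=peaks)


# ---------------------------------------------------------------------------
# run metadata


def parse_mzml_run_metadata(
    header_xml: dict[str, ET.Element | None],
    source_format: SourceFormat,
    spectrum_count: int,
    chromatogram_count: int,
) -> RunMetadata:
    """RunMetadata from pre-extracted mzML header elements
    (keys: fileDescription, softwareList, instrumentConfigurationList, run)."""
    instrument: list[CvTerm] = []
    software: list[MetadataEntry] = []
    run_attrs: list[MetadataEntry] = []

    icl = header_xml.get("instrumentConfigurationList")
    if icl is not None:
        for config in icl.iter():
            if local_name(config.tag) in ("instrumentConfiguration", "analyzer",
                                          "source", "detector"):
                instrument.extend(iter_cv_params(config))
    swl = header_xml.get("softwareList")
    if swl is not None:
        for sw in _iter_children(swl, "software"):
            terms = annotate_metadata(iter_cv_params(sw))
            if terms:
                for t in terms:
                    software.append(
                        MetadataEntry(
                            name=t.name,
                            accession=t.accession,
                            value=sw.get("version"),
                            verified=t.verified,
                        )
                    )
            else:
                software.append(
                    MetadataEntry(name=sw.get("id", "software"),
                                  value=sw.get("version"))
                )
    fd = header_xml.get("fileDescription")
    if fd is not None:
        content = _find_child(fd, "fileContent")
        if content is not None:
            run_attrs.extend(annotate_metadata(iter_cv_params(content)))
    run = header_xml.get("run")
    if run is not None:
        for key, value in run.attrib.items():
            run_attrs.append(MetadataEntry(name=key, value=value))
    return RunMetadata(
        source_format=source_format,
        instrument_descriptions=annotate_metadata(instrument),
        software_descriptions=software,
        run_attributes=run_attrs,
        spectrum_count=spectrum_count,
        chromatogram_count=chromatogram_count,
    )


def parse_mzxml_run_metadata(
    header_xml: dict[str, ET.Element | None],
    spectrum_count: int,
) -> RunMetadata:
    """RunMetadata read directly from mzXML attributes
    (keys: msInstrument, dataProcessing, msRun)."""
    instrument: list[MetadataEntry] = []
    software: list[MetadataEntry] = []
    run_attrs: list[MetadataEntry] = []

    msi = header_xml.get("msInstrument")
    if msi is not None:
        for child in msi:
            name = local_name(child.tag)
            if name == "software":
                software.append(
                    MetadataEntry(name=child.get("name", "software"),
                                  value=child.get("version"))
                )
            elif child.get("value") is not None:
                instrument.append(
                    MetadataEntry(name=child.get("category", name),
                                  value=child.get("value"))
                )
    dp = header_xml.get("dataProcessing")
    if dp is not None:
        for sw in _iter_children(dp, "software"):
            software.append(
                MetadataEntry(name=sw.get("name", "software"),
                              value=sw.get("version"))
            )
    msrun = header_xml.get("msRun")
    if msrun is not None:
        for key, value in msrun.attrib.items():
            run_attrs.append(MetadataEntry(name=key, value=value))
    return RunMetadata(
        source_format=SourceFormat.MZXML,
        instrument_descriptions=instrument,
        software_descriptions=software,
        run_attributes=run_attrs,
        spectrum_count=spectrum_count,
        chromatogram_count=0,
    )
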