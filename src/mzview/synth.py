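"""Deterministic generator for standards-shaped mzML / indexedmzML / mzXML
fixture files, with a ground-truth manifest.

The same seeded spectral content is written to both formats (the "twin
files"), so cross-format agreement is testable without any external data.
Spectra are structurally valid, not chemically plausible: m/z uniform over a
range, intensities log-uniform over three decades (so base peaks are
unambiguous almost surely).
"""

from __future__ import annotations

import hashlib
import json
import random
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import codec
from .model import (
    ArrayKind,
    ArrayLayout,
    BinaryArrayDescriptor,
    ByteOrder,
    Compression,
    PeakList,
    Precision,
    derive_base_peak,
)

__all__ = ["SynthConfig", "SynthScan", "Manifest", "GeneratedRun",
           "generate_run", "corrupt", "CORRUPT_MODES"]

CORRUPT_MODES = ("truncate", "bad_offsets", "bad_base64", "cycle_precursors")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for one synthetic run. Deterministic given ``seed``."""

    n_ms1: int = 10
    msn_per_ms1: tuple[tuple[int, int], ...] = ((2, 2),)
    peaks_per_scan: tuple[int, int] = (5, 20)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_spacing_s: float = 10.0
    precision: Precision = Precision.F64
    compression: Compression = Compression.NONE
    write_chromatogram: bool = True
    write_parent_refs: bool = True
    corrupt_offset_table: bool = False
    wrap_indexed: bool = True
    rt_unit: str = "second"  # mzML scan start time unit: "second" or "minute"
    seed: int = 0

    def __post_init__(self):
        if self.n_ms1 < 0:
            raise ValueError("n_ms1 must be >= 0")
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range low must be < high")
        lo, hi = self.peaks_per_scan
        if lo < 0 or lo > hi:
            raise ValueError("invalid peaks_per_scan range")
        if self.rt_spacing_s <= 0:
            raise ValueError("rt_spacing_s must be > 0")
        if self.rt_unit not in ("second", "minute"):
            raise ValueError("rt_unit must be 'second' or 'minute'")
        for level, count in self.msn_per_ms1:
            if level < 2 or count < 0:
                raise ValueError(f"invalid msn_per_ms1 entry ({level}, {count})")


@dataclass
class SynthScan:
    """Ground truth for one scan (shared by the mzML and mzXML twins)."""

    num: int  # mzXML scan number; mzML id is f"scan={num}"
    ms_level: int
    rt_s: float
    mz: list[float]
    intensity: list[float]
    base_peak_mz: Optional[float]
    base_peak_intensity: Optional[float]
    tic: float
    parent_num: Optional[int]
    lineage: list[int]  # ancestor nums, immediate parent first, up to MS1
    selected_ion_mz: Optional[float] = None
    charge: Optional[int] = None
    children: list["SynthScan"] = field(default_factory=list, repr=False)

    @property
    def mzml_id(self) -> str:
        return f"scan={self.num}"


@dataclass
class Manifest:
    """Everything the tests need to know about a generated run."""

    seed: int
    spectrum_count: int
    scans: list[SynthScan]
    chromatogram_time_s: Optional[list[float]] = None
    chromatogram_intensity: Optional[list[float]] = None

    def by_num(self, num: int) -> SynthScan:
        return next(s for s in self.scans if s.num == num)

    def by_mzml_id(self, scan_id: str) -> SynthScan:
        return next(s for s in self.scans if s.mzml_id == scan_id)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "spectrum_count": self.spectrum_count,
            "scans": [
                {
                    "num": s.num,
                    "mzml_id": s.mzml_id,
                    "ms_level": s.ms_level,
                    "rt_s": s.rt_s,
                    "mz": s.mz,
                    "intensity": s.intensity,
                    "base_peak_mz": s.base_peak_mz,
                    "base_peak_intensity": s.base_peak_intensity,
                    "tic": s.tic,
                    "parent_num": s.parent_num,
                    "lineage": s.lineage,
                    "selected_ion_mz": s.selected_ion_mz,
                    "charge": s.charge,
                }
                for s in self.scans
            ],
            "chromatogram_time_s": self.chromatogram_time_s,
            "chromatogram_intensity": self.chromatogram_intensity,
        }

    def save(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: Path) -> "Manifest":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        scans = [
            SynthScan(
                num=s["num"],
                ms_level=s["ms_level"],
                rt_s=s["rt_s"],
                mz=s["mz"],
                intensity=s["intensity"],
                base_peak_mz=s["base_peak_mz"],
                base_peak_intensity=s["base_peak_intensity"],
                tic=s["tic"],
                parent_num=s["parent_num"],
                lineage=s["lineage"],
                selected_ion_mz=s.get("selected_ion_mz"),
                charge=s.get("charge"),
            )
            for s in doc["scans"]
        ]
        return cls(
            seed=doc["seed"],
            spectrum_count=doc["spectrum_count"],
            scans=scans,
            chromatogram_time_s=doc.get("chromatogram_time_s"),
            chromatogram_intensity=doc.get("chromatogram_intensity"),
        )


@dataclass(frozen=True)
class GeneratedRun:
    mzml_path: Path
    mzxml_path: Path
    manifest_path: Path
    manifest: Manifest


# ---------------------------------------------------------------------------
# content generation


def _round_trip_precision(values: list[float], precision: Precision) -> list[float]:
    if precision is Precision.F32:
        return np.asarray(values, dtype=np.float32).astype(np.float64).tolist()
    return values


def _generate_scans(config: SynthConfig) -> list[SynthScan]:
    rng = random.Random(config.seed)
    scans: list[SynthScan] = []
    num = 0
    for i in range(config.n_ms1):
        ms1_rt = (i + 1) * config.rt_spacing_s
        num += 1
        ms1 = _make_scan(rng, config, num, 1, ms1_rt, parent=None)
        scans.append(ms1)
        group: list[SynthScan] = []
        last_at_level: dict[int, SynthScan] = {1: ms1}
        for level, count in config.msn_per_ms1:
            for _ in range(count):
                parent = last_at_level.get(level - 1)
                if parent is None:
                    raise ValueError(
                        f"msn_per_ms1 requests level {level} before any "
                        f"level-{level - 1} scan exists"
                    )
                num += 1
                group.append(num)  # placeholder for rt computation below
                rt = ms1_rt + len(group) * (
                    config.rt_spacing_s / (sum(c for _, c in config.msn_per_ms1) + 1)
                )
                child = _make_scan(rng, config, num, level, rt, parent=parent)
                parent.children.append(child)
                last_at_level[level] = child
                scans.append(child)
                group[-1] = child
    return scans


def _make_scan(
    rng: random.Random,
    config: SynthConfig,
    num: int,
    level: int,
    rt: float,
    parent: Optional[SynthScan],
) -> SynthScan:
    lo, hi = config.peaks_per_scan
    n_peaks = rng.randint(lo, hi)
    mzlo, mzhi = config.mz_range
    mz = sorted(rng.uniform(mzlo, mzhi) for _ in range(n_peaks))
    intensity = [10.0 ** rng.uniform(0.0, 3.0) for _ in range(n_peaks)]
    mz = _round_trip_precision(mz, config.precision)
    intensity = _round_trip_precision(intensity, config.precision)
    order = np.argsort(np.asarray(mz), kind="stable")
    mz = np.asarray(mz)[order].tolist()
    intensity = np.asarray(intensity)[order].tolist()
    bp = derive_base_peak(PeakList(np.asarray(mz), np.asarray(intensity)))
    tic = float(np.sum(np.asarray(intensity))) if intensity else 0.0
    selected = charge = None
    parent_num = None
    lineage: list[int] = []
    if parent is not None:
        parent_num = parent.num
        lineage = [parent.num, *parent.lineage]
        selected = (
            parent.base_peak_mz
            if parent.base_peak_mz is not None
            else (config.mz_range[0] + config.mz_range[1]) / 2.0
        )
        charge = rng.choice([1, 2, 3])
    return SynthScan(
        num=num,
        ms_level=level,
        rt_s=rt,
        mz=mz,
        intensity=intensity,
        base_peak_mz=bp[0] if bp else None,
        base_peak_intensity=bp[1] if bp else None,
        tic=tic,
        parent_num=parent_num,
        lineage=lineage,
        selected_ion_mz=selected,
        charge=charge,
    )


# ---------------------------------------------------------------------------
# mzML writing


def _mzml_descriptor(config: SynthConfig, kind: ArrayKind) -> BinaryArrayDescriptor:
    return BinaryArrayDescriptor(
        precision=config.precision,
        compression=config.compression,
        byte_order=ByteOrder.LITTLE,
        layout=ArrayLayout.SEPARATE,
        array_kind=kind,
    )


def _cv(accession: str, name: str, value: str = "",
        unit: Optional[tuple[str, str, str]] = None) -> str:
    ref = accession.split(":", 1)[0]
    unit_attrs = ""
    if unit is not None:
        uacc, uname, uref = unit
        unit_attrs = (
            f' unitCvRef="{uref}" unitAccession="{uacc}" unitName="{uname}"'
        )
    return (
        f'<cvParam cvRef="{ref}" accession="{accession}" name="{name}" '
        f'value="{value}"{unit_attrs}/>'
    )


def _binary_array_xml(values: list[float], config: SynthConfig,
                      kind: ArrayKind) -> str:
    enc = codec.encode_array(values, _mzml_descriptor(config, kind))
    prec_cv = (
        _cv("MS:1000523", "64-bit float")
        if config.precision is Precision.F64
        else _cv("MS:1000521", "32-bit float")
    )
    comp_cv = (
        _cv("MS:1000574", "zlib compression")
        if config.compression is Compression.ZLIB
        else _cv("MS:1000576", "no compression")
    )
    kind_cv = {
        ArrayKind.MZ: _cv("MS:1000514", "m/z array"),
        ArrayKind.INTENSITY: _cv("MS:1000515", "intensity array"),
        ArrayKind.TIME: _cv("MS:1000595", "time array",
                            unit=("UO:0000010", "second", "UO")),
    }[kind]
    return (
        f'<binaryDataArray encodedLength="{len(enc.text)}">'
        f"{prec_cv}{comp_cv}{kind_cv}"
        f"<binary>{enc.text}</binary></binaryDataArray>"
    )


def _mzml_spectrum_xml(scan: SynthScan, position: int, config: SynthConfig) -> str:
    n = len(scan.mz)
    parts = [
        f'<spectrum index="{position}" id="{scan.mzml_id}" defaultArrayLength="{n}">'
    ]
    if scan.ms_level == 1:
        parts.append(_cv("MS:1000579", "MS1 spectrum"))
    else:
        parts.append(_cv("MS:1000580", "MSn spectrum"))
    parts.append(_cv("MS:1000511", "ms level", str(scan.ms_level)))
    parts.append(_cv("MS:1000130", "positive scan"))
    parts.append(_cv("MS:1000127", "centroid spectrum"))
    if scan.base_peak_mz is not None:
        parts.append(_cv("MS:1000504", "base peak m/z", repr(scan.base_peak_mz),
                         unit=("MS:1000040", "m/z", "MS")))
        parts.append(_cv("MS:1000505", "base peak intensity",
                         repr(scan.base_peak_intensity)))
    parts.append(_cv("MS:1000285", "total ion current", repr(scan.tic)))
    if config.rt_unit == "minute":
        rt_value, rt_unit = repr(scan.rt_s / 60.0), ("UO:0000031", "minute", "UO")
    else:
        rt_value, rt_unit = repr(scan.rt_s), ("UO:0000010", "second", "UO")
    parts.append(
        '<scanList count="1">'
        + _cv("MS:1000795", "no combination")
        + "<scan>"
        + _cv("MS:1000016", "scan start time", rt_value, unit=rt_unit)
        + "</scan></scanList>"
    )
    if scan.ms_level >= 2 and scan.selected_ion_mz is not None:
        ref = (
            f' spectrumRef="scan={scan.parent_num}"'
            if config.write_parent_refs and scan.parent_num is not None
            else ""
        )
        charge = (
            _cv("MS:1000041", "charge state", str(scan.charge))
            if scan.charge is not None
            else ""
        )
        parts.append(
            f'<precursorList count="1"><precursor{ref}>'
            "<isolationWindow>"
            + _cv("MS:1000827", "isolation window target m/z",
                  repr(scan.selected_ion_mz), unit=("MS:1000040", "m/z", "MS"))
            + _cv("MS:1000828", "isolation window lower offset", "0.5",
                  unit=("MS:1000040", "m/z", "MS"))
            + _cv("MS:1000829", "isolation window upper offset", "0.5",
                  unit=("MS:1000040", "m/z", "MS"))
            + "</isolationWindow>"
            '<selectedIonList count="1"><selectedIon>'
            + _cv("MS:1000744", "selected ion m/z", repr(scan.selected_ion_mz),
                  unit=("MS:1000040", "m/z", "MS"))
            + charge
            + "</selectedIon></selectedIonList>"
            "<activation>"
            + _cv("MS:1000133", "collision-induced dissociation")
            + _cv("MS:1000045", "collision energy", "35.0")
            + "</activation></precursor></precursorList>"
        )
    parts.append('<binaryDataArrayList count="2">')
    parts.append(_binary_array_xml(scan.mz, config, ArrayKind.MZ))
    parts.append(_binary_array_xml(scan.intensity, config, ArrayKind.INTENSITY))
    parts.append("</binaryDataArrayList></spectrum>")
    return "".join(parts)


def _mzml_chromatogram_xml(manifest: Manifest, config: SynthConfig) -> str:
    times = manifest.chromatogram_time_s or []
    intens = manifest.chromatogram_intensity or []
    return (
        f'<chromatogram index="0" id="TIC" defaultArrayLength="{len(times)}">'
        + _cv("MS:1000235", "total ion current chromatogram")
        + '<binaryDataArrayList count="2">'
        + _binary_array_xml(times, config, ArrayKind.TIME)
        + _binary_array_xml(intens, config, ArrayKind.INTENSITY)
        + "</binaryDataArrayList></chromatogram>"
    )


_MZML_HEADER = """\
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="mzview_synth_run">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" version="4.0.3" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" version="releases/2014-09-04" URI="https://unit-ontology.googlecode.com/svn/trunk/unit.obo"/>
</cvList>
<fileDescription>
<fileContent>
<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
</fileContent>
</fileDescription>
<softwareList count="1">
<software id="mzview_synth" version="0.1.0">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</software>
</softwareList>
<instrumentConfigurationList count="1">
<instrumentConfiguration id="IC1">
<cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value="mzview synthetic instrument"/>
<cvParam cvRef="MS" accession="MS:1000529" name="instrument serial number" value="SN-0000"/>
</instrumentConfiguration>
</instrumentConfigurationList>
<dataProcessingList count="1">
<dataProcessing id="DP1">
<processingMethod order="1" softwareRef="mzview_synth">
<cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
</processingMethod>
</dataProcessing>
</dataProcessingList>
"""


def _build_mzml(manifest: Manifest, config: SynthConfig) -> bytes:
    parts = [_MZML_HEADER]
    parts.append('<run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
    parts.append(
        f'<spectrumList count="{manifest.spectrum_count}" '
        'defaultDataProcessingRef="DP1">\n'
    )
    for i, scan in enumerate(manifest.scans):
        parts.append(_mzml_spectrum_xml(scan, i, config))
        parts.append("\n")
    parts.append("</spectrumList>\n")
    if config.write_chromatogram and manifest.chromatogram_time_s is not None:
        parts.append('<chromatogramList count="1" defaultDataProcessingRef="DP1">\n')
        parts.append(_mzml_chromatogram_xml(manifest, config))
        parts.append("\n</chromatogramList>\n")
    parts.append("</run>\n</mzML>\n")
    return "".join(parts).encode("utf-8")


def _wrap_indexed(inner: bytes) -> bytes:
    """Wrap a plain <mzML> document in <indexedmzML> with a correct
    trailing offset table and checksum."""
    prefix = (
        b'<?xml version="1.0" encoding="utf-8"?>\n'
        b'<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
    )
    body = prefix + inner
    spectrum_offsets = [
        (m.start(), _attr(body, m.start(), b"id"))
        for m in re.finditer(rb"<spectrum[\s>]", body)
    ]
    chrom_offsets = [
        (m.start(), _attr(body, m.start(), b"id"))
        for m in re.finditer(rb"<chromatogram[\s>]", body)
    ]
    tail = ["<indexList count=\"%d\">" % (1 + (1 if chrom_offsets else 0))]
    tail.append('<index name="spectrum">')
    for off, sid in spectrum_offsets:
        tail.append(f'<offset idRef="{sid}">{off}</offset>')
    tail.append("</index>")
    if chrom_offsets:
        tail.append('<index name="chromatogram">')
        for off, cid in chrom_offsets:
            tail.append(f'<offset idRef="{cid}">{off}</offset>')
        tail.append("</index>")
    tail.append("</indexList>")
    index_list = "".join(tail).encode("utf-8")
    index_list_offset = len(body)
    body += index_list
    body += b"\n<indexListOffset>%d</indexListOffset>\n" % index_list_offset
    body += b"<fileChecksum>"
    checksum = hashlib.sha1(body).hexdigest()
    body += checksum.encode("ascii") + b"</fileChecksum>\n</indexedmzML>\n"
    return body


def _attr(data: bytes, elem_start: int, name: bytes) -> str:
    gt = data.find(b">", elem_start)
    m = re.search(rb'\b' + name + rb'="([^"]*)"', data[elem_start : gt + 1])
    return m.group(1).decode("utf-8") if m else ""


# ---------------------------------------------------------------------------
# mzXML writing


def _iso(seconds: float) -> str:
    return f"PT{repr(seconds)}S"


def _mzxml_peaks_xml(scan: SynthScan, config: SynthConfig) -> str:
    desc = BinaryArrayDescriptor(
        precision=config.precision,
        compression=config.compression,
        byte_order=ByteOrder.BIG,
        layout=ArrayLayout.INTERLEAVED,
    )
    interleaved: list[float] = []
    for mz, inten in zip(scan.mz, scan.intensity):
        interleaved.extend((mz, inten))
    enc = codec.encode_array(interleaved, desc)
    comp_attrs = 'compressionType="none"'
    if config.compression is Compression.ZLIB:
        raw = np.asarray(interleaved, dtype=np.float64).astype(desc.dtype).tobytes()
        comp_attrs = (
            f'compressionType="zlib" compressedLen="{len(zlib.compress(raw))}"'
        )
    precision = "32" if config.precision is Precision.F32 else "64"
    return (
        f'<peaks {comp_attrs} precision="{precision}" byteOrder="network" '
        f'contentType="m/z-int">{enc.text}</peaks>'
    )


def _mzxml_scan_xml(scan: SynthScan, config: SynthConfig, depth: int) -> str:
    pad = " " * depth
    attrs = (
        f'num="{scan.num}" msLevel="{scan.ms_level}" '
        f'peaksCount="{len(scan.mz)}" polarity="+" '
        f'retentionTime="{_iso(scan.rt_s)}"'
    )
    if scan.base_peak_mz is not None:
        attrs += (
            f' basePeakMz="{repr(scan.base_peak_mz)}"'
            f' basePeakIntensity="{repr(scan.base_peak_intensity)}"'
        )
    attrs += f' totIonCurrent="{repr(scan.tic)}"'
    parts = [f"{pad}<scan {attrs}>\n"]
    if scan.ms_level >= 2 and scan.selected_ion_mz is not None:
        ref = (
            f'precursorScanNum="{scan.parent_num}" '
            if config.write_parent_refs and scan.parent_num is not None
            else ""
        )
        charge = f'precursorCharge="{scan.charge}" ' if scan.charge else ""
        parts.append(
            f"{pad}<precursorMz {ref}{charge}"
            f'precursorIntensity="1000.0">{repr(scan.selected_ion_mz)}</precursorMz>\n'
        )
    parts.append(pad + _mzxml_peaks_xml(scan, config) + "\n")
    for child in scan.children:
        parts.append(_mzxml_scan_xml(child, config, depth + 1))
    parts.append(f"{pad}</scan>\n")
    return "".join(parts)


def _build_mzxml(manifest: Manifest, config: SynthConfig) -> bytes:
    scans = manifest.scans
    start = _iso(scans[0].rt_s) if scans else "PT0S"
    end = _iso(scans[-1].rt_s) if scans else "PT0S"
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
        f'<msRun scanCount="{manifest.spectrum_count}" '
        f'startTime="{start}" endTime="{end}">\n'
        '<parentFile fileName="synthetic" fileType="RAWData" '
        'fileSha1="0000000000000000000000000000000000000000"/>\n'
        "<msInstrument>\n"
        '<msManufacturer category="msManufacturer" value="mzview"/>\n'
        '<msModel category="msModel" value="synthetic instrument"/>\n'
        '<software type="acquisition" name="mzview_synth" version="0.1.0"/>\n'
        "</msInstrument>\n"
        "<dataProcessing>\n"
        '<software type="conversion" name="mzview_synth" version="0.1.0"/>\n'
        "</dataProcessing>\n"
    ]
    roots = [s for s in scans if s.parent_num is None]
    for root in roots:
        parts.append(_mzxml_scan_xml(root, config, depth=1))
    parts.append("</msRun>\n")
    body = "".join(parts).encode("utf-8")
    offsets = [
        (_attr(body, m.start(), b"num"), m.start())
        for m in re.finditer(rb"<scan[\s>]", body)
    ]
    index_parts = ['<index name="scan">']
    for num, off in offsets:
        index_parts.append(f'<offset id="{num}">{off}</offset>')
    index_parts.append("</index>\n")
    index_offset = len(body)
    body += "".join(index_parts).encode("utf-8")
    body += b"<indexOffset>%d</indexOffset>\n</mzXML>\n" % index_offset
    return body


# ---------------------------------------------------------------------------
# public API


def generate_run(config: SynthConfig, out_dir: Path | str) -> GeneratedRun:
    """Write twin mzML/mzXML files plus their manifest into *out_dir*.

    Same config (incl. seed) => byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scans = _generate_scans(config)
    manifest = Manifest(seed=config.seed, spectrum_count=len(scans), scans=scans)
    if config.write_chromatogram:
        ms1 = [s for s in scans if s.ms_level == 1]
        manifest.chromatogram_time_s = [s.rt_s for s in ms1]
        manifest.chromatogram_intensity = [s.tic for s in ms1]

    inner = _build_mzml(manifest, config)
    if config.wrap_indexed:
        mzml_bytes = _wrap_indexed(inner)
    else:
        mzml_bytes = b'<?xml version="1.0" encoding="utf-8"?>\n' + inner
    mzml_path = out_dir / "run.mzML"
    mzml_path.write_bytes(mzml_bytes)

    mzxml_path = out_dir / "run.mzXML"
    mzxml_path.write_bytes(_build_mzxml(manifest, config))

    manifest_path = manifest.save(out_dir / "manifest.json")

    if config.corrupt_offset_table:
        for path in (mzml_path, mzxml_path):
            corrupted = corrupt(path, "bad_offsets")
            path.write_bytes(corrupted.read_bytes())
            corrupted.unlink()
    return GeneratedRun(mzml_path, mzxml_path, manifest_path, manifest)


def corrupt(file: Path | str, mode: str) -> Path:
    """Deterministic minimal corruption of a generated file; returns the
    path of the corrupted copy (``<stem>.<mode><suffix>``).

    Modes
    -----
    truncate
        Cut the file mid-way through the last scan element.
    bad_offsets
        Add 7 to every embedded offset-table entry.
    bad_base64
        Overwrite 4 base64 characters of one scan's peak data with ``@@@@``
        (length-preserving, so offsets stay valid).
    cycle_precursors
        Make the first two precursor references point at each other's
        containing scans.
    """
    file = Path(file)
    if mode not in CORRUPT_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; one of {CORRUPT_MODES}")
    data = file.read_bytes()
    if mode == "truncate":
        starts = [m.start() for m in re.finditer(rb"<spectrum[\s>]|<scan[\s>]", data)]
        if not starts:
            raise ValueError(f"{file}: no scan elements to truncate")
        cut = min(starts[-1] + 80, len(data) - 1)
        out = data[:cut]
    elif mode == "bad_offsets":
        def bump(m: re.Match) -> bytes:
            return m.group(1) + str(int(m.group(2)) + 7).encode() + m.group(3)

        out, n = re.subn(rb"(<offset[^>]*>)(\d+)(</offset>)", bump, data)
        if n == 0:
            raise ValueError(f"{file}: no embedded offset table to corrupt")
    elif mode == "bad_base64":
        payloads = [
            m
            for m in re.finditer(rb"(?:<binary>|<peaks[^>]*>)([A-Za-z0-9+/=]{4,})<",
                                 data)
        ]
        if not payloads:
            raise ValueError(f"{file}: no base64 payload large enough to corrupt")
        target = payloads[2] if len(payloads) > 2 else payloads[0]
        pos = target.start(1)
        out = data[:pos] + b"@@@@" + data[pos + 4 :]
    else:  # cycle_precursors
        out = _make_cycle(data)
    dest = file.with_name(file.stem + f".{mode}" + file.suffix)
    dest.write_bytes(out)
    return dest


def _make_cycle(data: bytes) -> bytes:
    if b"spectrumRef" in data:
        scan_starts = [
            (m.start(), _attr(data, m.start(), b"id"))
            for m in re.finditer(rb"<spectrum[\s>]", data)
        ]
        refs = list(re.finditer(rb'spectrumRef="([^"]*)"', data))
        host = lambda pos: next(
            sid for start, sid in reversed(scan_starts) if start < pos
        )
        if len(refs) < 2:
            raise ValueError("need at least two precursor references for a cycle")
        r1, r2 = refs[0], refs[1]
        h1, h2 = host(r1.start()), host(r2.start())
        # rebuild with swapped targets (later match first so positions hold)
        out = data[: r1.start(1)] + h2.encode() + data[r1.end(1) : r2.start(1)]
        out += h1.encode() + data[r2.end(1) :]
        return out
    scan_starts = [
        (m.start(), _attr(data, m.start(), b"num"))
        for m in re.finditer(rb"<scan[\s>]", data)
    ]
    refs = list(re.finditer(rb'precursorScanNum="(\d+)"', data))
    if len(refs) < 2:
        raise ValueError("need at least two precursor references for a cycle")
    host = lambda pos: next(
        num for start, num in reversed(scan_starts) if start < pos
    )
    r1, r2 = refs[0], refs[1]
    h1, h2 = host(r1.start()), host(r2.start())
    out = data[: r1.start(1)] + h2.encode() + data[r1.end(1) : r2.start(1)]
    out += h1.encode() + data[r2.end(1) :]
    return out
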