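"""Format detection and lazy scan indexing.

One streaming, chunked pass over the file records the byte span of every
``<spectrum>``/``<scan>`` element together with its parsed header (peak
arrays are left encoded). Subsequent :func:`fetch_spectrum` calls seek to a
span and read only those bytes, so multi-GB files never have to fit in
memory.

Byte offsets are offsets into the raw (UTF-8) byte stream, never character
positions, so they are directly seekable.
"""

from __future__ import annotations

import difflib
import json
import os
import re
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import BinaryIO, Iterator, Optional

from . import readers
from .errors import (
    CodecError,
    CorruptScanError,
    DialectWarning,
    FormatParseError,
    IndexIncompleteError,
    MalformedSpectrumError,
    ScanNotFoundError,
    UnsupportedFormatError,
)
from .model import (
    ChromatogramEntry,
    IndexEntry,
    Polarity,
    PrecursorRef,
    RunMetadata,
    MetadataEntry,
    ScanHeader,
    ScanIndex,
    SourceFormat,
    Spectrum,
)

__all__ = [
    "detect_format",
    "build_index",
    "fetch_spectrum",
    "fetch_chromatogram",
    "iter_spectra",
    "save_sidecar",
    "load_sidecar",
    "open_run",
]

_CHUNK = 1 << 18
_TAIL_MAX = 1 << 20  # rolling tail kept for offset-table validation
_DETECT_PREFIX = 1 << 16

_ROOT_MAP = {
    "mzML": SourceFormat.MZML,
    "indexedmzML": SourceFormat.INDEXED_MZML,
    "mzXML": SourceFormat.MZXML,
}


def detect_format(file: str | os.PathLike) -> SourceFormat:
    """Decide the format from the document root element.

    Reads at most a small bounded prefix; the filename extension is never
    consulted.
    """
    with open(file, "rb") as fh:
        prefix = fh.read(_DETECT_PREFIX)
    root = _first_element_name(prefix)
    if root is None:
        raise FormatParseError(f"{file}: no XML element found in file prefix")
    bare = root.rsplit(":", 1)[-1]
    fmt = _ROOT_MAP.get(bare)
    if fmt is None:
        raise UnsupportedFormatError(
            f"{file}: unsupported root element <{root}>", root=root
        )
    return fmt


def _first_element_name(data: bytes) -> Optional[str]:
    """Name of the first real element, skipping BOM/decl/comments/doctype."""
    if data.startswith(b"\xef\xbb\xbf"):
        data = data[3:]
    pos = 0
    while True:
        lt = data.find(b"<", pos)
        if lt < 0 or lt + 1 >= len(data):
            return None
        nxt = data[lt + 1 : lt + 2]
        if nxt == b"?":  # <?xml ...?>
            end = data.find(b"?>", lt)
            if end < 0:
                return None
            pos = end + 2
        elif nxt == b"!":  # comment or doctype
            if data.startswith(b"<!--", lt):
                end = data.find(b"-->", lt)
                if end < 0:
                    return None
                pos = end + 3
            else:
                end = data.find(b">", lt)
                if end < 0:
                    return None
                pos = end + 1
        else:
            m = re.match(rb"<([A-Za-z_][\w.:-]*)", data[lt:])
            if m is None:
                return None
            return m.group(1).decode("ascii", "replace")


# ---------------------------------------------------------------------------
# chunked sequential reader


class _Stream:
    """Sequential chunked view of a file with absolute byte addressing and a
    rolling tail buffer (so the trailing offset table can be inspected
    without a second pass)."""

    def __init__(self, fh: BinaryIO):
        self.fh = fh
        self.base = 0  # abs offset of data[0]
        self.data = b""
        self.eof = False
        self.tail = b""
        self.tail_base = 0

    def extend(self) -> bool:
        chunk = self.fh.read(_CHUNK)
        if not chunk:
            self.eof = True
            return False
        self.data += chunk
        combined = self.tail + chunk
        if len(combined) > _TAIL_MAX:
            drop = len(combined) - _TAIL_MAX
            self.tail_base += drop
            combined = combined[drop:]
        else:
            self.tail_base = self.base + len(self.data) - len(combined)
        self.tail = combined
        return True

    @property
    def end(self) -> int:
        return self.base + len(self.data)

    def find(self, pattern: re.Pattern, from_abs: int) -> Optional[re.Match]:
        start = max(from_abs - self.base, 0)
        return pattern.search(self.data, start)

    def find_bytes(self, token: bytes, from_abs: int) -> int:
        start = max(from_abs - self.base, 0)
        i = self.data.find(token, start)
        return -1 if i < 0 else self.base + i

    def abs_slice(self, a: int, b: int) -> bytes:
        return self.data[a - self.base : b - self.base]

    def trim(self, keep_from_abs: int) -> None:
        cut = keep_from_abs - self.base
        if cut > 0:
            self.data = self.data[cut:]
            self.base = keep_from_abs


_MZML_START = re.compile(rb"<(spectrum|chromatogram)[\s>]")
_MZXML_TOKEN = re.compile(rb"<scan[\s>]|</scan\s*>")


def build_index(
    file: str | os.PathLike,
    *,
    validate_offset_table: bool = True,
) -> tuple[ScanIndex, RunMetadata]:
    """Single streaming pass: byte spans + headers for every scan, plus
    file-level metadata.

    When the file carries its own offset table (indexedmzML ``<indexList>``
    or the trailing mzXML ``<index>``), the table is checked against the
    streamed spans; disagreement emits a :class:`DialectWarning` and the
    streamed index wins.

    Raises
    ------
    IndexIncompleteError
        Truncated XML mid-scan; the partial index rides on the exception.
    """
    fmt = detect_format(file)
    path = Path(file)
    file_size = path.stat().st_size
    with open(path, "rb") as fh:
        stream = _Stream(fh)
        if fmt is SourceFormat.MZXML:
            entries, chrom_entries, header_bytes = _scan_mzxml(stream, path, fmt, file_size)
        else:
            entries, chrom_entries, header_bytes = _scan_mzml(stream, path, fmt, file_size)

    index = ScanIndex(
        entries=entries,
        source_path=path,
        source_format=fmt,
        file_size=file_size,
        chromatogram_entries=chrom_entries,
    )
    metadata = _build_metadata(fmt, header_bytes, index)
    if validate_offset_table:
        _validate_offset_table(fmt, stream.tail, stream.tail_base, index)
    return index, metadata


def _scan_mzml(
    stream: _Stream, path: Path, fmt: SourceFormat, file_size: int
) -> tuple[list[IndexEntry], list[ChromatogramEntry], bytes]:
    entries: list[IndexEntry] = []
    chroms: list[ChromatogramEntry] = []
    header_bytes: Optional[bytes] = None
    pos = 0
    last_by_level: dict[int, str] = {}
    while True:
        m = stream.find(_MZML_START, pos)
        if m is None:
            if stream.extend():
                # token may straddle the boundary: back up a little
                pos = min(pos, max(stream.base, pos - 16))
                continue
            break
        kind = m.group(1).decode()
        start_abs = stream.base + m.start()
        if header_bytes is None:
            header_bytes = stream.abs_slice(stream.base, start_abs)
        close = b"</" + m.group(1) + b">"
        end_abs = stream.find_bytes(close, start_abs)
        while end_abs < 0:
            if not stream.extend():
                raise IndexIncompleteError(
                    f"{path}: truncated inside <{kind}> starting at byte {start_abs}",
                    partial_index=ScanIndex(
                        entries=entries,
                        source_path=path,
                        source_format=fmt,
                        file_size=file_size,
                        chromatogram_entries=chroms,
                    ),
                )
            end_abs = stream.find_bytes(close, start_abs)
        end_abs += len(close)
        frag = stream.abs_slice(start_abs, end_abs)
        if kind == "spectrum":
            header = readers.parse_mzml_header(frag, index_position=len(entries))
            header = _infer_parent(header, last_by_level)
            last_by_level[header.ms_level] = header.scan_id
            entries.append(IndexEntry(header.scan_id, start_abs, end_abs, header))
        else:
            chrom_id = _attr_from_fragment(frag, b"id") or f"chromatogram={len(chroms)}"
            chroms.append(ChromatogramEntry(chrom_id, start_abs, end_abs))
        stream.trim(end_abs)
        pos = end_abs
    if header_bytes is None:  # empty run: whole file is header region
        header_bytes = stream.data
    return entries, chroms, header_bytes


def _scan_mzxml(
    stream: _Stream, path: Path, fmt: SourceFormat, file_size: int
) -> tuple[list[IndexEntry], list[ChromatogramEntry], bytes]:
    raw: list[tuple[int, int, bytes]] = []  # (start, end, fragment)
    stack: list[int] = []
    header_bytes: Optional[bytes] = None
    pos = 0
    while True:
        m = stream.find(_MZXML_TOKEN, pos)
        if m is None:
            if stream.extend():
                pos = min(pos, max(stream.base, pos - 16))
                continue
            if stack:
                raise IndexIncompleteError(
                    f"{path}: truncated inside <scan> starting at byte {stack[-1]}",
                    partial_index=_finish_mzxml(raw, path, fmt, file_size)[0],
                )
            break
        tok_abs = stream.base + m.start()
        if m.group(0).startswith(b"</"):
            if not stack:
                pos = stream.base + m.end()
                continue
            start_abs = stack.pop()
            end_abs = stream.base + m.end()
            raw.append((start_abs, end_abs, stream.abs_slice(start_abs, end_abs)))
            if not stack:
                stream.trim(end_abs)
            pos = end_abs
        else:
            if header_bytes is None:
                header_bytes = stream.abs_slice(stream.base, tok_abs)
            # self-closing <scan .../> has no separate end tag
            gt = stream.find_bytes(b">", tok_abs)
            while gt < 0:
                if not stream.extend():
                    raise IndexIncompleteError(
                        f"{path}: truncated inside <scan> tag at byte {tok_abs}",
                        partial_index=_finish_mzxml(raw, path, fmt, file_size)[0],
                    )
                gt = stream.find_bytes(b">", tok_abs)
            if stream.abs_slice(gt - 1, gt) == b"/":
                end_abs = gt + 1
                raw.append((tok_abs, end_abs, stream.abs_slice(tok_abs, end_abs)))
                if not stack:
                    stream.trim(end_abs)
                pos = end_abs
            else:
                stack.append(tok_abs)
                pos = gt + 1
    if header_bytes is None:
        header_bytes = stream.data
    index, _ = _finish_mzxml(raw, path, fmt, file_size)
    return list(index.entries), [], header_bytes


def _finish_mzxml(
    raw: list[tuple[int, int, bytes]], path: Path, fmt: SourceFormat, file_size: int
) -> tuple[ScanIndex, None]:
    raw_sorted = sorted(raw, key=lambda t: t[0])
    entries: list[IndexEntry] = []
    last_by_level: dict[int, str] = {}
    for i, (start, end, frag) in enumerate(raw_sorted):
        header = readers.parse_mzxml_header(frag, index_position=i)
        header = _infer_parent(header, last_by_level)
        last_by_level[header.ms_level] = header.scan_id
        entries.append(IndexEntry(header.scan_id, start, end, header))
    return (
        ScanIndex(
            entries=entries,
            source_path=path,
            source_format=fmt,
            file_size=file_size,
        ),
        None,
    )


def _infer_parent(header: ScanHeader, last_by_level: dict[int, str]) -> ScanHeader:
    """Nearest-preceding-scan fallback when the file omits an explicit
    parent reference (marked ``parent_inferred``)."""
    pre = header.precursor
    if header.ms_level < 2 or pre is None or pre.parent_scan_id is not None:
        return header
    inferred = last_by_level.get(header.ms_level - 1)
    if inferred is None:
        return header
    return header.with_precursor(
        PrecursorRef(
            selected_ion_mz=pre.selected_ion_mz,
            parent_scan_id=inferred,
            charge=pre.charge,
            isolation_window=pre.isolation_window,
            parent_inferred=True,
        )
    )


def _attr_from_fragment(frag: bytes, attr: bytes) -> Optional[str]:
    m = re.search(rb'\b' + attr + rb'="([^"]*)"', frag[: frag.find(b">") + 1])
    return m.group(1).decode("utf-8") if m else None


# ---------------------------------------------------------------------------
# run metadata extraction


def _extract_element(data: bytes, name: str) -> Optional[ET.Element]:
    """First complete <name>...</name> element in a header-region byte blob
    (the blob itself is not well-formed XML — the run element is unclosed)."""
    m = re.search(rb"<" + name.encode() + rb"[\s>]", data)
    if m is None:
        return None
    start = m.start()
    # self-contained empty element?
    gt = data.find(b">", start)
    if gt > 0 and data[gt - 1 : gt] == b"/":
        blob = data[start : gt + 1]
    else:
        close = b"</" + name.encode() + b">"
        end = data.find(close, start)
        if end < 0:
            return None
        blob = data[start : end + len(close)]
    try:
        return ET.fromstring(blob)
    except ET.ParseError:
        return None


def _extract_open_tag(data: bytes, name: str) -> Optional[ET.Element]:
    """Parse just the attributes of an element whose body spans the rest of
    the file (e.g. <run>, <msRun>)."""
    m = re.search(rb"<" + name.encode() + rb"\b[^>]*>", data)
    if m is None:
        return None
    tag = m.group(0)
    if not tag.endswith(b"/>"):
        tag = tag[:-1] + b"/>"
    try:
        return ET.fromstring(tag)
    except ET.ParseError:
        return None


def _build_metadata(
    fmt: SourceFormat, header_bytes: bytes, index: ScanIndex
) -> RunMetadata:
    if fmt is SourceFormat.MZXML:
        parts = {
            "msInstrument": _extract_element(header_bytes, "msInstrument"),
            "dataProcessing": _extract_element(header_bytes, "dataProcessing"),
            "msRun": _extract_open_tag(header_bytes, "msRun"),
        }
        return readers.parse_mzxml_run_metadata(parts, spectrum_count=len(index))
    parts = {
        "fileDescription": _extract_element(header_bytes, "fileDescription"),
        "softwareList": _extract_element(header_bytes, "softwareList"),
        "instrumentConfigurationList": _extract_element(
            header_bytes, "instrumentConfigurationList"
        ),
        "run": _extract_open_tag(header_bytes, "run"),
    }
    return readers.parse_mzml_run_metadata(
        parts,
        source_format=fmt,
        spectrum_count=len(index),
        chromatogram_count=len(index.chromatogram_entries),
    )


# ---------------------------------------------------------------------------
# embedded offset-table validation


def _validate_offset_table(
    fmt: SourceFormat, tail: bytes, tail_base: int, index: ScanIndex
) -> None:
    declared: Optional[list[tuple[str, int]]] = None
    if fmt is SourceFormat.INDEXED_MZML:
        declared = _read_mzml_index_list(tail)
    elif fmt is SourceFormat.MZXML:
        declared = _read_mzxml_index(tail)
    if declared is None:
        return
    actual = [(e.scan_id, e.byte_start) for e in index.entries]
    if declared != actual:
        warnings.warn(
            f"{index.source_path}: embedded offset table disagrees with actual "
            f"element positions; using the streamed index",
            DialectWarning,
            stacklevel=3,
        )


def _read_mzml_index_list(tail: bytes) -> Optional[list[tuple[str, int]]]:
    matches = list(re.finditer(rb"<indexList[\s>]", tail))
    if not matches:
        return None
    start = matches[-1].start()
    end = tail.find(b"</indexList>", start)
    if end < 0:
        return None
    try:
        elem = ET.fromstring(tail[start : end + len(b"</indexList>")])
    except ET.ParseError:
        return None
    out: list[tuple[str, int]] = []
    for idx in elem:
        if idx.get("name") != "spectrum":
            continue
        for off in idx:
            try:
                out.append((off.get("idRef", ""), int(off.text or "")))
            except ValueError:
                return None
    return out


def _read_mzxml_index(tail: bytes) -> Optional[list[tuple[str, int]]]:
    start = tail.rfind(b"<index ")
    if start < 0:
        return None
    end = tail.find(b"</index>", start)
    if end < 0:
        return None
    try:
        elem = ET.fromstring(tail[start : end + len(b"</index>")])
    except ET.ParseError:
        return None
    if elem.get("name") != "scan":
        return None
    out: list[tuple[str, int]] = []
    for off in elem:
        try:
            out.append((off.get("id", ""), int(off.text or "")))
        except ValueError:
            return None
    return out


# ---------------------------------------------------------------------------
# random access


def fetch_spectrum(
    index: ScanIndex, scan_id: str, fileobj: Optional[BinaryIO] = None
) -> Spectrum:
    """Read and decode exactly one scan by seeking to its byte span.

    ``fileobj`` (optional, seekable, binary) lets callers reuse a handle or
    instrument the reads; each call is otherwise independent.
    """
    entry = index.get(scan_id)
    if entry is None:
        near = difflib.get_close_matches(scan_id, index.scan_ids, n=3, cutoff=0.0)
        raise ScanNotFoundError(
            f"scan {scan_id!r} not in index; nearest ids: {near}", suggestions=near
        )
    frag = _read_span(index, entry.byte_start, entry.byte_end, fileobj)
    try:
        if index.source_format is SourceFormat.MZXML:
            spec = readers.parse_mzxml_scan(frag, entry.header.index_position)
        else:
            spec = readers.parse_mzml_spectrum(frag, entry.header.index_position)
    except (FormatParseError, CodecError, MalformedSpectrumError) as exc:
        raise CorruptScanError(
            f"scan {scan_id!r} at bytes [{entry.byte_start}, {entry.byte_end}) "
            f"failed to parse: {exc}",
            byte_start=entry.byte_start,
            byte_end=entry.byte_end,
        ) from exc
    # keep the (possibly inferred) parent linkage from index time
    return Spectrum(header=spec.header.with_precursor(entry.header.precursor),
                    peaks=spec.peaks)


def fetch_chromatogram(
    index: ScanIndex, entry: ChromatogramEntry, fileobj: Optional[BinaryIO] = None
):
    frag = _read_span(index, entry.byte_start, entry.byte_end, fileobj)
    return readers.parse_mzml_chromatogram(frag)


def _read_span(
    index: ScanIndex, start: int, end: int, fileobj: Optional[BinaryIO]
) -> bytes:
    if fileobj is not None:
        fileobj.seek(start)
        return fileobj.read(end - start)
    with open(index.source_path, "rb") as fh:
        fh.seek(start)
        return fh.read(end - start)


def iter_spectra(index: ScanIndex) -> Iterator[Spectrum]:
    """All spectra in file order, one fetch at a time over a shared handle."""
    with open(index.source_path, "rb") as fh:
        for entry in index.entries:
            yield fetch_spectrum(index, entry.scan_id, fileobj=fh)


# ---------------------------------------------------------------------------
# sidecar persistence


_SIDECAR_VERSION = 1


def _header_to_dict(h: ScanHeader) -> dict:
    d = {
        "scan_id": h.scan_id,
        "index_position": h.index_position,
        "ms_level": h.ms_level,
        "retention_time_s": h.retention_time_s,
        "base_peak_mz": h.base_peak_mz,
        "base_peak_intensity": h.base_peak_intensity,
        "total_ion_current": h.total_ion_current,
        "polarity": h.polarity.value,
        "centroided": h.centroided,
        "precursor": None,
    }
    if h.precursor is not None:
        p = h.precursor
        d["precursor"] = {
            "selected_ion_mz": p.selected_ion_mz,
            "parent_scan_id": p.parent_scan_id,
            "charge": p.charge,
            "isolation_window": list(p.isolation_window) if p.isolation_window else None,
            "parent_inferred": p.parent_inferred,
        }
    return d


def _header_from_dict(d: dict) -> ScanHeader:
    pre = None
    if d.get("precursor") is not None:
        p = d["precursor"]
        window = tuple(p["isolation_window"]) if p.get("isolation_window") else None
        pre = PrecursorRef(
            selected_ion_mz=p["selected_ion_mz"],
            parent_scan_id=p.get("parent_scan_id"),
            charge=p.get("charge"),
            isolation_window=window,
            parent_inferred=p.get("parent_inferred", False),
        )
    return ScanHeader(
        scan_id=d["scan_id"],
        index_position=d["index_position"],
        ms_level=d["ms_level"],
        retention_time_s=d["retention_time_s"],
        base_peak_mz=d.get("base_peak_mz"),
        base_peak_intensity=d.get("base_peak_intensity"),
        total_ion_current=d.get("total_ion_current"),
        precursor=pre,
        polarity=Polarity(d.get("polarity", "unknown")),
        centroided=d.get("centroided"),
    )


def sidecar_path(file: str | os.PathLike) -> Path:
    return Path(str(file) + ".mzvidx.json")


def save_sidecar(index: ScanIndex, metadata: RunMetadata,
                 path: Optional[os.PathLike] = None) -> Path:
    """Persist the index (keyed by source size + mtime) so reopening a large
    file skips the streaming pass."""
    out = Path(path) if path is not None else sidecar_path(index.source_path)
    stat = index.source_path.stat()
    doc = {
        "version": _SIDECAR_VERSION,
        "source": {"size": stat.st_size, "mtime": stat.st_mtime},
        "format": index.source_format.value,
        "file_size": index.file_size,
        "entries": [
            {
                "scan_id": e.scan_id,
                "byte_start": e.byte_start,
                "byte_end": e.byte_end,
                "header": _header_to_dict(e.header),
            }
            for e in index.entries
        ],
        "chromatograms": [
            {"chrom_id": c.chrom_id, "byte_start": c.byte_start, "byte_end": c.byte_end}
            for c in index.chromatogram_entries
        ],
        "metadata": {
            "instrument": [e.__dict__ for e in metadata.instrument_descriptions],
            "software": [e.__dict__ for e in metadata.software_descriptions],
            "run": [e.__dict__ for e in metadata.run_attributes],
            "spectrum_count": metadata.spectrum_count,
            "chromatogram_count": metadata.chromatogram_count,
        },
    }
    out.write_text(json.dumps(doc), encoding="utf-8")
    return out


def load_sidecar(
    file: str | os.PathLike, path: Optional[os.PathLike] = None
) -> Optional[tuple[ScanIndex, RunMetadata]]:
    """Load a sidecar if present and still matching the source file;
    returns None (caller rebuilds) when absent or stale."""
    source = Path(file)
    sc = Path(path) if path is not None else sidecar_path(source)
    if not sc.exists():
        return None
    try:
        doc = json.loads(sc.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError):
        return None
    stat = source.stat()
    src = doc.get("source", {})
    if (
        doc.get("version") != _SIDECAR_VERSION
        or src.get("size") != stat.st_size
        or src.get("mtime") != stat.st_mtime
    ):
        return None
    fmt = SourceFormat(doc["format"])
    index = ScanIndex(
        entries=[
            IndexEntry(
                e["scan_id"], e["byte_start"], e["byte_end"],
                _header_from_dict(e["header"]),
            )
            for e in doc["entries"]
        ],
        source_path=source,
        source_format=fmt,
        file_size=doc["file_size"],
        chromatogram_entries=[
            ChromatogramEntry(c["chrom_id"], c["byte_start"], c["byte_end"])
            for c in doc["chromatograms"]
        ],
    )
    md = doc["metadata"]
    metadata = RunMetadata(
        source_format=fmt,
        instrument_descriptions=[MetadataEntry(**e) for e in md["instrument"]],
        software_descriptions=[MetadataEntry(**e) for e in md["software"]],
        run_attributes=[MetadataEntry(**e) for e in md["run"]],
        spectrum_count=md["spectrum_count"],
        chromatogram_count=md["chromatogram_count"],
    )
    return index, metadata


def open_run(
    file: str | os.PathLike, *, use_sidecar: bool = False
) -> tuple[ScanIndex, RunMetadata]:
    """Convenience wrapper: load a fresh sidecar when allowed, else build
    the index (and refresh the sidecar)."""
    if use_sidecar:
        cached = load_sidecar(file)
        if cached is not None:
            return cached
    index, metadata = build_index(file)
    if use_sidecar:
        save_sidecar(index, metadata)
    return index, metadata
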