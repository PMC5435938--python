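"""Independent reference reader used as an oracle by the tests.

Deliberately shares no code with mzview: whole-document ElementTree parse,
struct-based float unpacking, stdlib base64/zlib. Slow and memory-hungry by
design — it exists to cross-check the streaming implementation, not to be
efficient.
"""

from __future__ import annotations

import base64
import re
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem):
    return [
        (c.get("accession"), c.get("name"), c.get("value"), c.get("unitAccession"))
        for c in elem
        if _local(c.tag) == "cvParam"
    ]


def _decode_mzml_binary(bda) -> list[float]:
    fmt_char, size = "d", 8
    compressed = False
    for acc, *_ in _cv_params(bda):
        if acc == "MS:1000521":
            fmt_char, size = "f", 4
        elif acc == "MS:1000574":
            compressed = True
    text = ""
    for child in bda:
        if _local(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    n = len(raw) // size
    return list(struct.unpack("<" + fmt_char * n, raw))


def read_mzml(path: str | Path) -> list[dict]:
    """Every spectrum in the file, fully parsed, in document order."""
    root = ET.parse(str(path)).getroot()
    out = []
    for elem in root.iter():
        if _local(elem.tag) != "spectrum":
            continue
        spec = {
            "id": elem.get("id"),
            "default_array_length": int(elem.get("defaultArrayLength", "0")),
            "ms_level": None,
            "rt_s": None,
            "base_peak_mz": None,
            "tic": None,
            "selected_ion_mz": None,
            "parent_id": None,
            "mz": [],
            "intensity": [],
        }
        for acc, _, value, _ in _cv_params(elem):
            if acc == "MS:1000511":
                spec["ms_level"] = int(value)
            elif acc == "MS:1000504":
                spec["base_peak_mz"] = float(value)
            elif acc == "MS:1000285":
                spec["tic"] = float(value)
        for sub in elem.iter():
            name = _local(sub.tag)
            if name == "scan":
                for acc, _, value, unit in _cv_params(sub):
                    if acc == "MS:1000016":
                        rt = float(value)
                        if unit == "UO:0000031":
                            rt *= 60.0
                        spec["rt_s"] = rt
            elif name == "precursor":
                spec["parent_id"] = sub.get("spectrumRef")
            elif name == "selectedIon":
                for acc, _, value, _ in _cv_params(sub):
                    if acc == "MS:1000744":
                        spec["selected_ion_mz"] = float(value)
            elif name == "binaryDataArray":
                kinds = [a for a, *_ in _cv_params(sub)]
                values = _decode_mzml_binary(sub)
                if "MS:1000514" in kinds:
                    spec["mz"] = values
                elif "MS:1000515" in kinds:
                    spec["intensity"] = values
        out.append(spec)
    return out


def read_mzxml(path: str | Path) -> list[dict]:
    root = ET.parse(str(path)).getroot()
    out = []
    for elem in root.iter():
        if _local(elem.tag) != "scan":
            continue
        rt_attr = elem.get("retentionTime", "PT0S")
        m = re.match(r"PT([\d.]+)S", rt_attr)
        scan = {
            "num": elem.get("num"),
            "ms_level": int(elem.get("msLevel", "1")),
            "rt_s": float(m.group(1)) if m else 0.0,
            "peaks_count": int(elem.get("peaksCount", "0")),
            "base_peak_mz": (
                float(elem.get("basePeakMz")) if elem.get("basePeakMz") else None
            ),
            "tic": (
                float(elem.get("totIonCurrent")) if elem.get("totIonCurrent") else None
            ),
            "selected_ion_mz": None,
            "parent_num": None,
            "mz": [],
            "intensity": [],
        }
        for child in elem:
            name = _local(child.tag)
            if name == "precursorMz":
                scan["selected_ion_mz"] = float((child.text or "0").strip())
                scan["parent_num"] = child.get("precursorScanNum")
            elif name == "peaks":
                size = 4 if child.get("precision") == "32" else 8
                fmt_char = "f" if size == 4 else "d"
                raw = base64.b64decode(child.text or "")
                if child.get("compressionType") == "zlib":
                    raw = zlib.decompress(raw)
                n = len(raw) // size
                flat = struct.unpack(">" + fmt_char * n, raw)
                scan["mz"] = list(flat[0::2])
                scan["intensity"] = list(flat[1::2])
        out.append(scan)
    return out


def count_scan_elements(path: str | Path) -> int:
    """Textual count of spectrum elements (mzML) or scan elements (mzXML).

    mzML's <scanList> also contains <scan> children, so the token counted
    depends on the document root.
    """
    data = Path(path).read_bytes()
    if re.search(rb"<mzXML[\s>]", data[:4096]):
        return len(re.findall(rb"<scan[\s>]", data))
    return len(re.findall(rb"<spectrum[\s>]", data))
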