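"""Domain types shared across mzview. Pure data, no I/O.

Conventions fixed here once and relied on everywhere else:

* retention times are **seconds** internally, whatever the source unit;
* scan identity is the mzML native ``id`` string verbatim, or the mzXML
  ``num`` attribute rendered as its decimal string;
* base-peak ties break toward the **lowest m/z**.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import MalformedSpectrumError

__all__ = [
    "Polarity",
    "SourceFormat",
    "PeakList",
    "PrecursorRef",
    "ScanHeader",
    "BinaryArrayDescriptor",
    "IndexEntry",
    "ScanIndex",
    "ChromatogramEntry",
    "RunMetadata",
    "MetadataEntry",
    "Spectrum",
    "Chromatogram",
    "FilterCriteria",
    "derive_base_peak",
    "canonicalize",
]


class Polarity(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class SourceFormat(str, enum.Enum):
    MZML = "mzml"
    INDEXED_MZML = "indexed_mzml"
    MZXML = "mzxml"


@dataclass(frozen=True)
class PeakList:
    """Paired (m/z, intensity) arrays for one spectrum.

    ``mz`` is in Thomson, ``intensity`` in arbitrary counts. Both are float64
    numpy arrays of equal length; spectra may be empty.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=np.float64)
        intensity = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise MalformedSpectrumError(
                f"m/z and intensity lengths differ: {mz.shape} vs {intensity.shape}"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return zip(self.mz.tolist(), self.intensity.tolist())

    @property
    def is_sorted(self) -> bool:
        return bool(np.all(np.diff(self.mz) >= 0))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return (
            np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass(frozen=True)
class PrecursorRef:
    """Reference from an MSn scan to the ion it fragments."""

    selected_ion_mz: float
    parent_scan_id: Optional[str] = None
    charge: Optional[int] = None
    isolation_window: Optional[tuple[float, float]] = None
    parent_inferred: bool = False

    def __post_init__(self):
        if self.isolation_window is not None:
            lo, hi = self.isolation_window
            if lo > hi:
                raise MalformedSpectrumError(
                    f"isolation window inverted: {lo} > {hi}"
                )


@dataclass(frozen=True)
class ScanHeader:
    """Per-scan metadata, parsed without touching the peak arrays."""

    scan_id: str
    index_position: int
    ms_level: int
    retention_time_s: float
    base_peak_mz: Optional[float] = None
    base_peak_intensity: Optional[float] = None
    total_ion_current: Optional[float] = None
    precursor: Optional[PrecursorRef] = None
    polarity: Polarity = Polarity.UNKNOWN
    centroided: Optional[bool] = None

    def with_precursor(self, precursor: Optional[PrecursorRef]) -> "ScanHeader":
        return replace(self, precursor=precursor)


class Precision(str, enum.Enum):
    F32 = "f32"
    F64 = "f64"


class Compression(str, enum.Enum):
    NONE = "none"
    ZLIB = "zlib"


class ByteOrder(str, enum.Enum):
    LITTLE = "little"
    BIG = "big"


class ArrayLayout(str, enum.Enum):
    SEPARATE = "separate"
    INTERLEAVED = "interleaved_mz_int"


class ArrayKind(str, enum.Enum):
    MZ = "mz"
    INTENSITY = "intensity"
    TIME = "time"
    OTHER = "other"


@dataclass(frozen=True)
class BinaryArrayDescriptor:
    """How one embedded binary array is encoded.

    mzML arrays are little-endian with separate m/z and intensity arrays;
    mzXML stores one big-endian array of interleaved (m/z, intensity) pairs.
    """

    precision: Precision = Precision.F64
    compression: Compression = Compression.NONE
    byte_order: ByteOrder = ByteOrder.LITTLE
    layout: ArrayLayout = ArrayLayout.SEPARATE
    array_kind: ArrayKind = ArrayKind.OTHER

    @property
    def element_size(self) -> int:
        return 4 if self.precision is Precision.F32 else 8

    @property
    def dtype(self) -> np.dtype:
        order = "<" if self.byte_order is ByteOrder.LITTLE else ">"
        width = "f4" if self.precision is Precision.F32 else "f8"
        return np.dtype(order + width)


@dataclass(frozen=True)
class IndexEntry:
    scan_id: str
    byte_start: int
    byte_end: int
    header: ScanHeader


@dataclass(frozen=True)
class ChromatogramEntry:
    chrom_id: str
    byte_start: int
    byte_end: int


@dataclass
class ScanIndex:
    """Ordered scan-id -> byte-span map; the random-access backbone.

    ``entries`` are in file order; sibling spans never overlap (nested mzXML
    MSn scans may nest inside their parent's span).
    """

    entries: list[IndexEntry]
    source_path: Path
    source_format: SourceFormat
    file_size: int
    chromatogram_entries: list[ChromatogramEntry] = field(default_factory=list)

    def __post_init__(self):
        self.source_path = Path(self.source_path)
        self._by_id = {e.scan_id: e for e in self.entries}
        if len(self._by_id) != len(self.entries):
            raise MalformedSpectrumError("duplicate scan ids in index")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, scan_id: str) -> bool:
        return scan_id in self._by_id

    def get(self, scan_id: str) -> Optional[IndexEntry]:
        return self._by_id.get(scan_id)

    @property
    def scan_ids(self) -> list[str]:
        return [e.scan_id for e in self.entries]

    @property
    def headers(self) -> list[ScanHeader]:
        return [e.header for e in self.entries]


@dataclass(frozen=True)
class MetadataEntry:
    """One instrument/software/run description item.

    ``accession`` is a CV accession (MS:nnnnnnn) for mzML-derived entries,
    absent for mzXML attribute metadata. ``verified`` is False when the
    accession was not found in the bundled vocabulary snapshot.
    """

    name: str
    accession: Optional[str] = None
    value: Optional[str] = None
    verified: bool = True


@dataclass
class RunMetadata:
    source_format: SourceFormat
    instrument_descriptions: list[MetadataEntry] = field(default_factory=list)
    software_descriptions: list[MetadataEntry] = field(default_factory=list)
    run_attributes: list[MetadataEntry] = field(default_factory=list)
    spectrum_count: int = 0
    chromatogram_count: int = 0


@dataclass(frozen=True)
class Spectrum:
    header: ScanHeader
    peaks: PeakList

    @property
    def base_peak(self) -> Optional[tuple[float, float]]:
        """File-declared base peak if present, else derived from the peaks."""
        if self.header.base_peak_mz is not None and self.header.base_peak_intensity is not None:
            return (self.header.base_peak_mz, self.header.base_peak_intensity)
        return derive_base_peak(self.peaks)


@dataclass(frozen=True)
class Chromatogram:
    kind: str  # "tic" (synthesized) or "file_declared"
    chrom_id: str
    time_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=np.float64)
        i = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity", i)
        if t.shape != i.shape:
            from .errors import MalformedChromatogramError

            raise MalformedChromatogramError(
                f"time/intensity lengths differ: {t.size} vs {i.size}"
            )

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunction of scan search filters; absent fields match everything."""

    mz_target: Optional[float] = None
    mz_field: str = "base_peak"  # or "selected_ion"
    mz_tolerance: float = 0.5
    rt_min_s: Optional[float] = None
    rt_max_s: Optional[float] = None
    ms_level: Optional[int] = None

    def __post_init__(self):
        if self.mz_field not in ("base_peak", "selected_ion"):
            raise ValueError(f"unknown mz_field: {self.mz_field!r}")
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be > 0")
        if (
            self.rt_min_s is not None
            and self.rt_max_s is not None
            and self.rt_min_s > self.rt_max_s
        ):
            raise ValueError("rt_min_s > rt_max_s")


def derive_base_peak(peaks: PeakList) -> Optional[tuple[float, float]]:
    """Return the (m/z, intensity) of the most intense peak.

    Ties break toward the lowest m/z; empty peak lists return None.
    """
    if len(peaks) == 0:
        return None
    imax = float(np.max(peaks.intensity))
    candidates = peaks.mz[peaks.intensity == imax]
    return (float(np.min(candidates)), imax)


def canonicalize(peaks: PeakList) -> PeakList:
    """Sort peak pairs by ascending m/z (stable: duplicate m/z keep input order)."""
    order = np.argsort(peaks.mz, kind="stable")
    return PeakList(mz=peaks.mz[order], intensity=peaks.intensity[order])


def make_peaklist(mz: Sequence[float], intensity: Sequence[float]) -> PeakList:
    """Convenience constructor from plain sequences (validates lengths)."""
    return PeakList(
        mz=np.asarray(mz, dtype=np.float64),
        intensity=np.asarray(intensity, dtype=np.float64),
    )
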