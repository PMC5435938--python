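"""Search filters, precursor-chain traversal, and chromatogram retrieval
over a built ScanIndex."""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from . import indexer
from .errors import ContradictionWarning, PrecursorCycleError, ScanNotFoundError
from .model import (
    Chromatogram,
    FilterCriteria,
    ScanHeader,
    ScanIndex,
    SourceFormat,
    Spectrum,
)

__all__ = ["filter_scans", "precursor_chain", "get_chromatograms"]


def _criterion_mz(header: ScanHeader, criteria: FilterCriteria) -> Optional[float]:
    if criteria.mz_field == "base_peak":
        return header.base_peak_mz
    if header.precursor is None:
        return None
    return header.precursor.selected_ion_mz


def matches(header: ScanHeader, criteria: FilterCriteria) -> bool:
    """True when *header* satisfies every present criterion (conjunction).

    Scans lacking a filtered field never match (they are excluded, not an
    error).
    """
    if criteria.ms_level is not None and header.ms_level != criteria.ms_level:
        return False
    if criteria.rt_min_s is not None and header.retention_time_s < criteria.rt_min_s:
        return False
    if criteria.rt_max_s is not None and header.retention_time_s > criteria.rt_max_s:
        return False
    if criteria.mz_target is not None:
        field_mz = _criterion_mz(header, criteria)
        if field_mz is None:
            return False
        if abs(field_mz - criteria.mz_target) > criteria.mz_tolerance:
            return False
    return True


def filter_scans(index: ScanIndex, criteria: FilterCriteria) -> list[ScanHeader]:
    """Headers (file order preserved) satisfying all present criteria.

    A selected-ion m/z filter combined with ``ms_level=1`` is contradictory
    (MS1 scans have no precursor): the result is empty and a
    :class:`ContradictionWarning` is emitted.
    """
    if (
        criteria.mz_target is not None
        and criteria.mz_field == "selected_ion"
        and criteria.ms_level == 1
    ):
        warnings.warn(
            "selected-ion m/z filter with ms_level=1 can never match",
            ContradictionWarning,
            stacklevel=2,
        )
        return []
    return [h for h in index.headers if matches(h, criteria)]


def precursor_chain(index: ScanIndex, scan_id: str) -> list[Spectrum]:
    """Ancestor spectra of *scan_id*, immediate precursor first, ending at
    the MS1 root.

    Follows explicit parent references (or the nearest-preceding-scan
    linkage inferred at index time). Unresolvable links terminate the chain
    early; cyclic references raise :class:`PrecursorCycleError`.
    """
    entry = index.get(scan_id)
    if entry is None:
        raise ScanNotFoundError(f"scan {scan_id!r} not in index")
    chain: list[Spectrum] = []
    seen = {scan_id}
    current = entry.header
    while current.precursor is not None and current.precursor.parent_scan_id:
        parent_id = current.precursor.parent_scan_id
        if parent_id in seen:
            raise PrecursorCycleError(
                f"precursor references cycle back to scan {parent_id!r}",
                scan_id=parent_id,
            )
        seen.add(parent_id)
        parent_entry = index.get(parent_id)
        if parent_entry is None:
            break  # dangling reference: truncated chain
        chain.append(indexer.fetch_spectrum(index, parent_id))
        current = parent_entry.header
    return chain


def get_chromatograms(index: ScanIndex) -> list[Chromatogram]:
    """File-declared chromatograms (mzML), or a synthesized TIC.

    mzML files with a chromatogramList return every declared trace with time
    normalized to seconds. Files declaring none — and all mzXML files —
    return a single TIC built from per-scan total ion current over retention
    time, MS1 scans only.
    """
    if index.source_format is not SourceFormat.MZXML and index.chromatogram_entries:
        with open(index.source_path, "rb") as fh:
            return [
                indexer.fetch_chromatogram(index, entry, fileobj=fh)
                for entry in index.chromatogram_entries
            ]
    ms1 = [h for h in index.headers if h.ms_level == 1]
    times = np.array([h.retention_time_s for h in ms1], dtype=np.float64)
    intensities = np.array(
        [h.total_ion_current if h.total_ion_current is not None else 0.0
         for h in ms1],
        dtype=np.float64,
    )
    return [Chromatogram(kind="tic", chrom_id="TIC (synthesized)",
                         time_s=times, intensity=intensities)]
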