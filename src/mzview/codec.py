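"""Encode/decode the base64 binary peak arrays embedded in mzML/mzXML.

Covers both precisions (32/64-bit IEEE-754 floats), both compressions
(none / RFC-1950 zlib), both byte orders, and both layouts (separate arrays
for mzML, big-endian interleaved (m/z, intensity) pairs for mzXML).
"""

from __future__ import annotations

import base64
import binascii
import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    CodecError,
    LengthMismatchWarning,
    MalformedPeaksError,
    NonFiniteDataWarning,
    TruncationError,
)
from .model import (
    ArrayLayout,
    BinaryArrayDescriptor,
    ByteOrder,
    Compression,
    PeakList,
    Precision,
)

__all__ = [
    "EncodedArray",
    "decode_array",
    "encode_array",
    "deinterleave",
    "interleave",
]


@dataclass(frozen=True)
class EncodedArray:
    """A base64 payload plus the descriptor needed to decode it.

    ``declared_length`` is the element count the file claims
    (mzML ``defaultArrayLength``, mzXML ``peaksCount`` * 2).
    """

    text: str
    descriptor: BinaryArrayDescriptor
    declared_length: Optional[int] = None


def decode_array(
    enc: EncodedArray,
    *,
    strict_length: bool = False,
    warn_nonfinite: bool = False,
) -> np.ndarray:
    """base64-decode, inflate if zlib, reinterpret as IEEE-754 floats.

    Returns a float64 array regardless of the source precision (values from
    f32 sources are exact float32 values widened to float64).

    Raises
    ------
    CodecError
        Invalid base64, or zlib inflate failure.
    TruncationError
        Byte count is not a multiple of the element size.
    """
    desc = enc.descriptor
    try:
        raw = base64.b64decode(enc.text, validate=True)
    except (binascii.Error, ValueError) as exc:
        raise CodecError(f"invalid base64 payload: {exc}") from exc
    if desc.compression is Compression.ZLIB:
        try:
            raw = zlib.decompress(raw)
        except zlib.error as exc:
            raise CodecError(f"zlib inflate failed: {exc}") from exc
    if len(raw) % desc.element_size != 0:
        raise TruncationError(
            f"{len(raw)} bytes is not a multiple of element size {desc.element_size}"
        )
    values = np.frombuffer(raw, dtype=desc.dtype).astype(np.float64)
    if enc.declared_length is not None and values.size != enc.declared_length:
        msg = (
            f"decoded {values.size} elements but file declares "
            f"{enc.declared_length}"
        )
        if strict_length:
            raise CodecError(msg)
        warnings.warn(msg, LengthMismatchWarning, stacklevel=2)
    if warn_nonfinite and values.size and not np.all(np.isfinite(values)):
        warnings.warn(
            "decoded array contains non-finite values (preserved as-is)",
            NonFiniteDataWarning,
            stacklevel=2,
        )
    return values


def encode_array(
    values: Sequence[float] | np.ndarray, descriptor: BinaryArrayDescriptor
) -> EncodedArray:
    """Inverse of :func:`decode_array`.

    Bit-exact round trip for f64; f32 rounds to single precision first.
    Non-finite values pass through as their IEEE representations.
    """
    arr = np.asarray(values, dtype=np.float64).astype(descriptor.dtype)
    raw = arr.tobytes()
    if descriptor.compression is Compression.ZLIB:
        raw = zlib.compress(raw)
    return EncodedArray(
        text=base64.b64encode(raw).decode("ascii"),
        descriptor=descriptor,
        declared_length=int(arr.size),
    )


def deinterleave(values: Sequence[float] | np.ndarray) -> PeakList:
    """Split an interleaved [mz0, i0, mz1, i1, ...] array into a PeakList."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size % 2 != 0:
        raise MalformedPeaksError(
            f"interleaved peak array has odd element count {arr.size}"
        )
    return PeakList(mz=arr[0::2].copy(), intensity=arr[1::2].copy())


def interleave(peaks: PeakList) -> np.ndarray:
    """Inverse of :func:`deinterleave`."""
    out = np.empty(2 * len(peaks), dtype=np.float64)
    out[0::2] = peaks.mz
    out[1::2] = peaks.intensity
    return out


MZML_DESCRIPTOR = BinaryArrayDescriptor(
    byte_order=ByteOrder.LITTLE, layout=ArrayLayout.SEPARATE
)
MZXML_DESCRIPTOR = BinaryArrayDescriptor(
    byte_order=ByteOrder.BIG, layout=ArrayLayout.INTERLEAVED
)
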