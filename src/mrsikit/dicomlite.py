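"""Minimal DICOM Part-10 codec: Explicit VR Little Endian only.

No general-purpose DICOM library is available in the deployment environment,
so this module implements exactly the subset of PS3.10/PS3.5 the toolkit's
writers and readers need: the 128-byte preamble + "DICM" marker, the group
0002 file meta information, flat data sets of Explicit VR Little Endian
elements, and defined-length sequences (SQ) of defined-length items.  It is
deliberately strict — undefined lengths, implicit VR, and non-LE transfer
syntaxes are rejected rather than guessed.

All UIDs produced here are deterministic functions of their inputs
(:func:`deterministic_uid`), so identical pipeline runs write byte-identical
files.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CorruptionError, FormatError

__all__ = [
    "Element",
    "DataSet",
    "deterministic_uid",
    "write_file",
    "read_file",
    "peek_sop_class",
    "EXPLICIT_VR_LE",
]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLEMENTATION_UID_SEED = "mrsikit-0.1"

# VRs whose length field is 4 bytes after a 2-byte reserved gap
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}
_TEXT_VRS = {"AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN", "SH", "ST", "TM", "UI", "UR", "UC", "UT"}

ITEM_TAG = (0xFFFE, 0xE000)


def deterministic_uid(*parts) -> str:
    """A UID in the 2.25 (UUID-derived) root computed from a SHA1 of parts."""
    h = hashlib.sha1("\x00".join(str(p) for p in parts).encode("utf-8")).digest()
    return "2.25." + str(int.from_bytes(h[:12], "big"))


@dataclass
class Element:
    """One data element: (group, elem) tag, VR, and a decoded value.

    Values are stored in natural Python form: str for text VRs, list[float]
    for DS/FD/FL, list[int] for IS/UL/US/SL/SS, bytes for OB/OW/OF, and
    list[DataSet] for SQ.
    """

    tag: tuple[int, int]
    vr: str
    value: object

    def encode(self) -> bytes:
        body = _encode_value(self.vr, self.value)
        g, e = self.tag
        if self.vr in _LONG_VRS:
            head = struct.pack("<HH2sHI", g, e, self.vr.encode(), 0, len(body))
        else:
            if len(body) > 0xFFFF:
                raise ValueError(f"value too long for short VR {self.vr}")
            head = struct.pack("<HH2sH", g, e, self.vr.encode(), len(body))
        return head + body


def _encode_value(vr: str, value) -> bytes:
    if vr == "SQ":
        parts = []
        for item in value:
            blob = item.encode()
            parts.append(struct.pack("<HHI", *ITEM_TAG, len(blob)) + blob)
        return b"".join(parts)
    if vr in ("OB",):
        b = bytes(value)
        return b + (b"\x00" if len(b) % 2 else b"")
    if vr == "OW":
        b = bytes(value)
        return b + (b"\x00" if len(b) % 2 else b"")
    if vr == "OF":
        if isinstance(value, (bytes, bytearray)):
            return bytes(value)
        return np.asarray(value, dtype="<f4").tobytes()
    if vr == "FD":
        return np.asarray(_aslist(value), dtype="<f8").tobytes()
    if vr == "FL":
        return np.asarray(_aslist(value), dtype="<f4").tobytes()
    if vr == "UL":
        return b"".join(struct.pack("<I", int(v)) for v in _aslist(value))
    if vr == "US":
        return b"".join(struct.pack("<H", int(v)) for v in _aslist(value))
    if vr == "SL":
        return b"".join(struct.pack("<i", int(v)) for v in _aslist(value))
    if vr == "SS":
        return b"".join(struct.pack("<h", int(v)) for v in _aslist(value))
    if vr == "DS":
        text = "\\".join(_format_ds(v) for v in _aslist(value))
        return _pad_text(text, b" ")
    if vr == "IS":
        text = "\\".join(str(int(v)) for v in _aslist(value))
        return _pad_text(text, b" ")
    if vr in _TEXT_VRS:
        if isinstance(value, (list, tuple)):
            value = "\\".join(str(v) for v in value)
        pad = b"\x00" if vr == "UI" else b" "
        return _pad_text(str(value), pad)
    raise ValueError(f"unsupported VR {vr!r}")


def _aslist(value):
    if isinstance(value, (list, tuple, np.ndarray)):
        return list(value)
    return [value]


def _format_ds(v) -> str:
    # DS is limited to 16 bytes per value
    s = f"{float(v):.10g}"
    if len(s) > 16:
        s = f"{float(v):.8g}"
    return s


def _pad_text(text: str, pad: bytes) -> bytes:
    b = text.encode("ascii")
    return b + (pad if len(b) % 2 else b"")


@dataclass
class DataSet:
    """An ordered collection of elements (also used for sequence items)."""

    elements: list[Element] = field(default_factory=list)

    def add(self, tag: tuple[int, int], vr: str, value) -> "DataSet":
        self.elements.append(Element(tag, vr, value))
        return self

    def get(self, tag: tuple[int, int], default=None):
        for el in self.elements:
            if el.tag == tag:
                return el.value
        return default

    def __contains__(self, tag: tuple[int, int]) -> bool:
        return any(el.tag == tag for el in self.elements)

    def require(self, tag: tuple[int, int], what: str = ""):
        for el in self.elements:
            if el.tag == tag:
                return el.value
        raise CorruptionError(
            f"missing required element ({tag[0]:04X},{tag[1]:04X}) {what}".strip()
        )

    def encode(self) -> bytes:
        els = sorted(self.elements, key=lambda el: el.tag)
        return b"".join(el.encode() for el in els)


def write_file(path, sop_class_uid: str, body: DataSet, sop_instance_uid: str) -> Path:
    """Write a Part-10 file: preamble, DICM, file meta group, then the body."""
    path = Path(path)
    meta = DataSet()
    meta.add((0x0002, 0x0001), "OB", b"\x00\x01")
    meta.add((0x0002, 0x0002), "UI", sop_class_uid)
    meta.add((0x0002, 0x0003), "UI", sop_instance_uid)
    meta.add((0x0002, 0x0010), "UI", EXPLICIT_VR_LE)
    meta.add((0x0002, 0x0012), "UI", deterministic_uid(IMPLEMENTATION_UID_SEED))
    meta_blob = meta.encode()
    group_len = Element((0x0002, 0x0000), "UL", len(meta_blob)).encode()
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta_blob)
        fh.write(body.encode())
    return path


def read_file(path) -> tuple[DataSet, DataSet]:
    """Parse a Part-10 file written in Explicit VR LE; returns (meta, body)."""
    blob = Path(path).read_bytes()
    if len(blob) < 132 or blob[128:132] != b"DICM":
        raise FormatError(f"{path}: not a DICOM Part-10 file")
    meta, offset = _parse_group2(blob, 132)
    ts = meta.get((0x0002, 0x0010))
    if ts != EXPLICIT_VR_LE:
        raise FormatError(
            f"{path}: unsupported transfer syntax {ts!r} (only Explicit VR LE)"
        )
    body, _ = _parse_elements(blob, offset, len(blob))
    return meta, body


def peek_sop_class(path) -> str:
    """Media Storage SOP Class UID from the file meta group alone."""
    with open(path, "rb") as fh:
        blob = fh.read(4096)
    if len(blob) < 132 or blob[128:132] != b"DICM":
        raise FormatError(f"{path}: not a DICOM Part-10 file")
    meta, _ = _parse_group2(blob, 132)
    uid = meta.get((0x0002, 0x0002))
    if uid is None:
        raise CorruptionError(f"{path}: file meta lacks Media Storage SOP Class UID")
    return str(uid)


def _parse_group2(blob: bytes, offset: int) -> tuple[DataSet, int]:
    """Parse the file meta group using its declared group length."""
    el, offset = _parse_one(blob, offset)
    if el.tag != (0x0002, 0x0000):
        raise FormatError("file meta must begin with its group length element")
    end = offset + int(_aslist(el.value)[0])
    ds, offset = _parse_elements(blob, offset, end)
    return ds, offset


def _parse_elements(blob: bytes, offset: int, end: int) -> tuple[DataSet, int]:
    ds = DataSet()
    while offset < end:
        el, offset = _parse_one(blob, offset)
        ds.elements.append(el)
    return ds, offset


def _parse_one(blob: bytes, offset: int) -> tuple[Element, int]:
    if offset + 8 > len(blob):
        raise CorruptionError("truncated element header")
    group, elem = struct.unpack_from("<HH", blob, offset)
    vr = blob[offset + 4 : offset + 6].decode("ascii", errors="replace")
    if vr in _LONG_VRS:
        (length,) = struct.unpack_from("<I", blob, offset + 8)
        offset += 12
    else:
        (length,) = struct.unpack_from("<H", blob, offset + 6)
        offset += 8
    if length == 0xFFFFFFFF:
        raise FormatError("undefined element lengths are not supported")
    if offset + length > len(blob):
        raise CorruptionError(
            f"element ({group:04X},{elem:04X}) declares {length} bytes, "
            f"file holds {len(blob) - offset}"
        )
    raw = blob[offset : offset + length]
    offset += length
    return Element((group, elem), vr, _decode_value(vr, raw)), offset


def _decode_value(vr: str, raw: bytes):
    if vr == "SQ":
        items = []
        off = 0
        while off < len(raw):
            g, e, ln = struct.unpack_from("<HHI", raw, off)
            if (g, e) != ITEM_TAG:
                raise CorruptionError(f"expected sequence item tag, got ({g:04X},{e:04X})")
            if ln == 0xFFFFFFFF:
                raise FormatError("undefined item lengths are not supported")
            off += 8
            item, _ = _parse_elements(raw, off, off + ln)
            items.append(item)
            off += ln
        return items
    if vr in ("OB", "OW", "OF", "UN"):
        return raw
    if vr == "FD":
        vals = list(np.frombuffer(raw, dtype="<f8"))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FL":
        vals = list(np.frombuffer(raw, dtype="<f4"))
        return float(vals[0]) if len(vals) == 1 else [float(v) for v in vals]
    if vr == "UL":
        vals = [v[0] for v in struct.iter_unpack("<I", raw)]
        return vals[0] if len(vals) == 1 else vals
    if vr == "US":
        vals = [v[0] for v in struct.iter_unpack("<H", raw)]
        return vals[0] if len(vals) == 1 else vals
    if vr == "SL":
        vals = [v[0] for v in struct.iter_unpack("<i", raw)]
        return vals[0] if len(vals) == 1 else vals
    if vr == "SS":
        vals = [v[0] for v in struct.iter_unpack("<h", raw)]
        return vals[0] if len(vals) == 1 else vals
    text = raw.decode("ascii", errors="replace")
    if vr == "UI":
        return text.rstrip("\x00 ")
    if vr == "DS":
        parts = [p for p in text.strip().split("\\") if p.strip()]
        vals = [float(p) for p in parts]
        return vals[0] if len(vals) == 1 else vals
    if vr == "IS":
        parts = [p for p in text.strip().split("\\") if p.strip()]
        vals = [int(p) for p in parts]
        return vals[0] if len(vals) == 1 else vals
    return text.strip()
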