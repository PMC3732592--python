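"""Independent minimal DICOM element walker used as a cross-check in tests.

Implemented directly from the DICOM encoding rules (PS3.10 file structure,
PS3.5 Explicit VR Little Endian) and deliberately sharing no code with the
package's own codec: it walks every element of a file, validating structure
as it goes, and returns a flat {tag: raw bytes} mapping (sequence items are
recursed into with their nesting recorded).  Any structural inconsistency —
bad preamble, truncated value, misaligned item tag — raises ValueError.
"""

from __future__ import annotations

import struct

EXPLICIT_LONG = (b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN")


def walk_file(path):
    """Parse a whole DICOM file; returns (meta_elements, body_elements).

    Each is a list of (tag_tuple, vr_string, raw_value_bytes_or_items).
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 132:
        raise ValueError("file shorter than preamble + magic")
    if blob[128:132] != b"DICM":
        raise ValueError("missing DICM magic at offset 128")
    pos = 132
    meta = []
    # file meta group: first element must be (0002,0000) UL group length
    tag, vr, val, pos = _element(blob, pos)
    if tag != (2, 0) or vr != "UL":
        raise ValueError("file meta does not start with (0002,0000) UL")
    meta.append((tag, vr, val))
    meta_end = pos + struct.unpack("<I", val)[0]
    while pos < meta_end:
        tag, vr, val, pos = _element(blob, pos)
        if tag[0] != 2:
            raise ValueError("non-group-0002 element inside file meta")
        meta.append((tag, vr, val))
    body = []
    while pos < len(blob):
        tag, vr, val, pos = _element(blob, pos)
        body.append((tag, vr, val))
    return meta, body


def _element(blob, pos):
    if pos + 8 > len(blob):
        raise ValueError(f"truncated element header at byte {pos}")
    group, element = struct.unpack_from("<HH", blob, pos)
    vr = blob[pos + 4 : pos + 6]
    if not all(65 <= c <= 90 for c in vr):
        raise ValueError(f"invalid VR bytes {vr!r} at byte {pos}")
    if vr in EXPLICIT_LONG:
        reserved, length = struct.unpack_from("<HI", blob, pos + 6)
        if reserved != 0:
            raise ValueError("non-zero reserved bytes in long-form element")
        pos += 12
    else:
        (length,) = struct.unpack_from("<H", blob, pos + 6)
        pos += 8
    if length == 0xFFFFFFFF:
        raise ValueError("undefined lengths not supported by this walker")
    if pos + length > len(blob):
        raise ValueError(f"element ({group:04x},{element:04x}) value overruns file")
    raw = blob[pos : pos + length]
    if vr == b"SQ":
        return (group, element), "SQ", _items(raw), pos + length
    return (group, element), vr.decode(), raw, pos + length


def _items(raw):
    items, off = [], 0
    while off < len(raw):
        g, e, ln = struct.unpack_from("<HHI", raw, off)
        if (g, e) != (0xFFFE, 0xE000):
            raise ValueError("sequence content does not begin with an item tag")
        off += 8
        if off + ln > len(raw):
            raise ValueError("sequence item overruns sequence value")
        item_blob = raw[off : off + ln]
        elements, pos = [], 0
        while pos < len(item_blob):
            tag, vr, val, pos = _element(item_blob, pos)
            elements.append((tag, vr, val))
        items.append(elements)
        off += ln
    return items


def find(elements, tag):
    """First value for a tag in a flat element list, else None."""
    for t, _, v in elements:
        if t == tag:
            return v
    return None


def text(elements, tag):
    raw = find(elements, tag)
    return None if raw is None else raw.decode("ascii").rstrip("\x00 ")
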