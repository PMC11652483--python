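"""Minimal DICOM codec for RT-Plan files.

Supports the Explicit VR Little Endian transfer syntax only, which is all
this package ever writes. The scope is deliberately narrow: enough of Part 10
framing plus nested sequences to serialize and parse VMAT arc beams
(control points, MLC banks, meterset weights). It is not a general DICOM
implementation and performs no charset, pixel-data or compressed-syntax
handling.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Any

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

# VRs whose explicit encoding carries a 2-byte reserved field + 32-bit length
_LONG_VRS = {"OB", "OW", "OF", "OD", "OL", "SQ", "UC", "UR", "UT", "UN"}
_STRING_VRS = {"AE", "AS", "CS", "DA", "DT", "LO", "LT", "PN", "SH", "ST", "TM", "UC", "UR", "UT"}

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE0DD)


class DicomError(ValueError):
    pass


@dataclass
class Element:
    tag: tuple[int, int]
    vr: str
    value: Any


@dataclass
class Dataset:
    """Ordered tag -> Element mapping; SQ values are lists of Dataset."""

    elements: dict[tuple[int, int], Element] = field(default_factory=dict)

    def put(self, group: int, elem: int, vr: str, value: Any) -> None:
        self.elements[(group, elem)] = Element((group, elem), vr, value)

    def get(self, group: int, elem: int, default: Any = None) -> Any:
        el = self.elements.get((group, elem))
        return default if el is None else el.value

    def require(self, group: int, elem: int, what: str) -> Any:
        el = self.elements.get((group, elem))
        if el is None:
            raise DicomError(f"missing required element ({group:04X},{elem:04X}) [{what}]")
        return el.value


# ---------------------------------------------------------------- decoding


def _decode_value(vr: str, raw: bytes) -> Any:
    if vr == "UI":
        return raw.rstrip(b"\x00 ").decode("ascii")
    if vr in _STRING_VRS:
        text = raw.rstrip(b"\x00 ").decode("ascii")
        return text
    if vr == "DS":
        text = raw.rstrip(b"\x00 ").decode("ascii")
        if not text:
            return None
        parts = [float(p) for p in text.split("\\")]
        return parts[0] if len(parts) == 1 else parts
    if vr == "IS":
        text = raw.rstrip(b"\x00 ").decode("ascii")
        if not text:
            return None
        parts = [int(p) for p in text.split("\\")]
        return parts[0] if len(parts) == 1 else parts
    if vr == "US":
        vals = list(struct.unpack(f"<{len(raw) // 2}H", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "UL":
        vals = list(struct.unpack(f"<{len(raw) // 4}I", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FL":
        vals = list(struct.unpack(f"<{len(raw) // 4}f", raw))
        return vals[0] if len(vals) == 1 else vals
    if vr == "FD":
        vals = list(struct.unpack(f"<{len(raw) // 8}d", raw))
        return vals[0] if len(vals) == 1 else vals
    return raw  # opaque


class _Reader:
    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def eof(self) -> bool:
        return self.pos >= len(self.buf)

    def _take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise DicomError(f"truncated file at byte {self.pos}")
        out = self.buf[self.pos : self.pos + n]
        self.pos += n
        return out

    def read_tag(self) -> tuple[int, int]:
        g, e = struct.unpack("<HH", self._take(4))
        return g, e

    def read_element(self) -> Element:
        tag = self.read_tag()
        if tag in (_ITEM, _ITEM_DELIM, _SEQ_DELIM):
            length = struct.unpack("<I", self._take(4))[0]
            return Element(tag, "", length)
        vr = self._take(2).decode("ascii")
        if vr in _LONG_VRS:
            self._take(2)
            length = struct.unpack("<I", self._take(4))[0]
        else:
            length = struct.unpack("<H", self._take(2))[0]
        if vr == "SQ":
            return Element(tag, vr, self._read_sequence(length))
        if length == 0xFFFFFFFF:
            raise DicomError(f"undefined length outside SQ at tag {tag}")
        return Element(tag, vr, _decode_value(vr, self._take(length)))

    def _read_sequence(self, length: int) -> list[Dataset]:
        items: list[Dataset] = []
        end = None if length == 0xFFFFFFFF else self.pos + length
        while True:
            if end is not None and self.pos >= end:
                break
            el = self.read_element()
            if el.tag == _SEQ_DELIM:
                break
            if el.tag != _ITEM:
                raise DicomError(f"expected item tag in sequence, got {el.tag}")
            item_len = el.value
            items.append(self._read_item(item_len))
        return items

    def _read_item(self, length: int) -> Dataset:
        ds = Dataset()
        end = None if length == 0xFFFFFFFF else self.pos + length
        while True:
            if end is not None and self.pos >= end:
                break
            if self.eof():
                break
            el = self.read_element()
            if el.tag == _ITEM_DELIM:
                break
            ds.elements[el.tag] = el
        return ds

    def read_dataset(self) -> Dataset:
        ds = Dataset()
        while not self.eof():
            el = self.read_element()
            ds.elements[el.tag] = el
        return ds


def read_file(path) -> Dataset:
    """Parse a Part-10 DICOM file; returns the main dataset.

    Raises DicomError on missing preamble, unsupported transfer syntax or
    malformed structure.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM part-10 file (no DICM magic)")
    rd = _Reader(buf, 132)
    # file meta group (0002) is always explicit little endian
    meta = Dataset()
    while not rd.eof():
        mark = rd.pos
        tag = rd.read_tag()
        rd.pos = mark
        if tag[0] != 0x0002:
            break
        el = rd.read_element()
        meta.elements[el.tag] = el
    ts = meta.get(0x0002, 0x0010)
    if ts is not None and ts != EXPLICIT_VR_LE:
        raise DicomError(f"unsupported transfer syntax {ts!r} (only explicit VR LE)")
    return rd.read_dataset()


# ---------------------------------------------------------------- encoding


def _format_ds(v: float) -> str:
    # DS is limited to 16 bytes; %.10g round-trips well below the 1e-6
    # tolerance the plan contract requires.
    s = f"{float(v):.10g}"
    return s[:16]


def _encode_value(vr: str, value: Any) -> bytes:
    if vr == "DS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        raw = "\\".join(_format_ds(v) for v in vals).encode("ascii")
    elif vr == "IS":
        vals = value if isinstance(value, (list, tuple)) else [value]
        raw = "\\".join(str(int(v)) for v in vals).encode("ascii")
    elif vr == "UI":
        raw = str(value).encode("ascii")
        if len(raw) % 2:
            raw += b"\x00"
        return raw
    elif vr in _STRING_VRS:
        raw = str(value).encode("ascii")
    elif vr == "US":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}H", *[int(v) for v in vals])
    elif vr == "UL":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}I", *[int(v) for v in vals])
    elif vr == "FD":
        vals = value if isinstance(value, (list, tuple)) else [value]
        return struct.pack(f"<{len(vals)}d", *[float(v) for v in vals])
    else:
        raise DicomError(f"cannot encode VR {vr!r}")
    if len(raw) % 2:
        raw += b" "
    return raw


def _encode_element(el: Element) -> bytes:
    g, e = el.tag
    if el.vr == "SQ":
        body = b""
        for item in el.value:
            item_body = _encode_dataset(item)
            body += struct.pack("<HHI", 0xFFFE, 0xE000, len(item_body)) + item_body
        return struct.pack("<HH", g, e) + b"SQ" + b"\x00\x00" + struct.pack("<I", len(body)) + body
    raw = _encode_value(el.vr, el.value)
    if el.vr in _LONG_VRS:
        return struct.pack("<HH", g, e) + el.vr.encode() + b"\x00\x00" + struct.pack("<I", len(raw)) + raw
    return struct.pack("<HH", g, e) + el.vr.encode() + struct.pack("<H", len(raw)) + raw


def _encode_dataset(ds: Dataset) -> bytes:
    out = b""
    for tag in sorted(ds.elements):
        out += _encode_element(ds.elements[tag])
    return out


def write_file(path, ds: Dataset, sop_class_uid: str, sop_instance_uid: str) -> None:
    """Write dataset as Part-10 explicit-VR-LE with a standard meta header."""
    meta = Dataset()
    meta.put(0x0002, 0x0002, "UI", sop_class_uid)
    meta.put(0x0002, 0x0003, "UI", sop_instance_uid)
    meta.put(0x0002, 0x0010, "UI", EXPLICIT_VR_LE)
    meta_body = _encode_dataset(meta)
    group_len = struct.pack("<HH", 0x0002, 0x0000) + b"UL" + struct.pack("<H", 4) + struct.pack("<I", len(meta_body))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(group_len)
        fh.write(meta_body)
        fh.write(_encode_dataset(ds))
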