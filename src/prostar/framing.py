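"""Low-level byte framing shared by the codecs and the archive container.

Variable-length integers (LEB128, unsigned), length-prefixed chunks, an
8-byte BLAKE2b checksum, and a thin Zstandard wrapper.
"""

from __future__ import annotations

import hashlib

import zstandard

from .errors import TruncatedStream

_ZC = {}
_ZD = zstandard.ZstdDecompressor()


def zstd_compress(data: bytes, level: int = 19) -> bytes:
    c = _ZC.get(level)
    if c is None:
        c = _ZC[level] = zstandard.ZstdCompressor(level=level)
    return c.compress(data)


def zstd_decompress(data: bytes) -> bytes:
    return _ZD.decompress(data)


def checksum64(data: bytes) -> int:
    """64-bit BLAKE2b digest as an integer."""
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "little")


class ByteWriter:
    def __init__(self) -> None:
        self._buf = bytearray()

    def u8(self, v: int) -> None:
        self._buf.append(v & 0xFF)

    def u64(self, v: int) -> None:
        self._buf += v.to_bytes(8, "little")

    def uvarint(self, v: int) -> None:
        if v < 0:
            raise ValueError("uvarint needs v >= 0")
        while True:
            b = v & 0x7F
            v >>= 7
            if v:
                self._buf.append(b | 0x80)
            else:
                self._buf.append(b)
                return

    def svarint(self, v: int) -> None:
        # zig-zag
        self.uvarint((v << 1) ^ (v >> 63) if v < 0 else (v << 1))

    def chunk(self, data: bytes) -> None:
        self.uvarint(len(data))
        self._buf += data

    def text(self, s: str) -> None:
        self.chunk(s.encode("utf-8"))

    def getvalue(self) -> bytes:
        return bytes(self._buf)


class ByteReader:
    def __init__(self, data: bytes, pos: int = 0) -> None:
        self._data = data
        self._pos = pos

    def _take(self, n: int) -> bytes:
        if self._pos + n > len(self._data):
            raise TruncatedStream("unexpected end of stream")
        b = self._data[self._pos:self._pos + n]
        self._pos += n
        return b

    def u8(self) -> int:
        return self._take(1)[0]

    def u64(self) -> int:
        return int.from_bytes(self._take(8), "little")

    def uvarint(self) -> int:
        shift = 0
        v = 0
        while True:
            b = self.u8()
            v |= (b & 0x7F) << shift
            if not b & 0x80:
                return v
            shift += 7
            if shift > 63:
                raise TruncatedStream("varint too long")

    def svarint(self) -> int:
        u = self.uvarint()
        return (u >> 1) ^ -(u & 1)

    def chunk(self) -> bytes:
        return self._take(self.uvarint())

    def text(self) -> str:
        return self.chunk().decode("utf-8")

    def eof(self) -> bool:
        return self._pos >= len(self._data)

    @property
    def pos(self) -> int:
        return self._pos
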