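"""Random-access archive container.

Layout: an 8-byte magic, then the compressed entry payloads back to back,
then a Zstandard-compressed JSON directory, and finally a fixed 32-byte
footer (directory offset, length, checksum, magic).  Listing reads only
footer + directory; extracting one entry reads only its payload range.
Appending truncates the tail directory, writes the new payloads and
rewrites directory + footer — existing payload bytes are never touched.

Every entry is compressed independently, so any file can be extracted
without decoding the others.  Structure entries record the fingerprint of
the prediction model they were encoded with; extraction with a different
model is refused rather than producing wrong coordinates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

from .coord_codec import LossyParams, LOSSLESS
from .errors import ArchiveError, ModelMismatch, ParseError
from .formats_io import parse_confidence, parse_pae, write_confidence, write_pae
from .framing import checksum64, zstd_compress, zstd_decompress
from .pae_codec import decode_pae, encode_pae
from .structure_codec import decode_structure, encode_structure
from .table_codec import decode_confidence, encode_confidence
from .training import PredictionModel

MAGIC = b"PSARv001"
FOOTER_MAGIC = b"PSARDIR!"
FOOTER_SIZE = 32

FILE_TYPES = ("cif", "pdb", "pae", "confidence", "opaque")


@dataclass(frozen=True)
class CompressionParams:
    lossy: LossyParams = LOSSLESS
    pae_level: int = 0
    fast: bool = False


@dataclass
class ArchiveEntry:
    name: str
    file_type: str
    offset: int
    length: int
    checksum: int            # of the compressed payload
    model_fingerprint: int | None = None
    lossy_backbone: int = 0
    lossy_sidechain: int = 0
    pae_level: int = 0
    minimal: bool = False
    fast: bool = False
    bf_average: bool = False
    opaque_fallback: bool = False   # stored whole because coding was refused

    def to_json(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @classmethod
    def from_json(cls, obj: dict) -> "ArchiveEntry":
        return cls(**obj)


def detect_file_type(name: str, data: bytes) -> str:
    """Classify an input by extension, falling back to JSON content."""
    lower = name.lower()
    if lower.endswith(".pdb"):
        return "pdb"
    if lower.endswith((".cif", ".mmcif")):
        return "cif"
    if lower.endswith(".json"):
        try:
            obj = json.loads(data.decode())
        except (UnicodeDecodeError, json.JSONDecodeError):
            return "opaque"
        if isinstance(obj, list) and len(obj) == 1 and isinstance(obj[0], dict):
            obj = obj[0]
        if isinstance(obj, dict):
            if "predicted_aligned_error" in obj:
                return "pae"
            if "confidenceScore" in obj:
                return "confidence"
        elif isinstance(obj, list):
            return "pae"
    return "opaque"


class Archive:
    """``Archive.create(path)`` / ``Archive.open(path)`` /
    ``Archive.append(path)``; use as a context manager in write modes."""

    def __init__(self, path: str | Path, mode: str,
                 model: PredictionModel | None = None) -> None:
        if mode not in ("r", "w", "a"):
            raise ValueError("mode must be 'r', 'w' or 'a'")
        self.path = Path(path)
        self.mode = mode
        self._model = model
        self.entries: list[ArchiveEntry] = []
        self._by_name: dict[str, ArchiveEntry] = {}
        if mode == "w":
            self._fh = open(self.path, "w+b")
            self._fh.write(MAGIC)
            self._data_end = len(MAGIC)
        else:
            self._fh = open(self.path, "r+b" if mode == "a" else "rb")
            self._read_directory()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def create(cls, path: str | Path,
               model: PredictionModel | None = None) -> "Archive":
        return cls(path, "w", model)

    @classmethod
    def open(cls, path: str | Path,
             model: PredictionModel | None = None) -> "Archive":
        return cls(path, "r", model)

    @classmethod
    def append(cls, path: str | Path,
               model: PredictionModel | None = None) -> "Archive":
        if not Path(path).exists():
            return cls(path, "w", model)
        return cls(path, "a", model)

    @property
    def model(self) -> PredictionModel:
        if self._model is None:
            from .models import default_model
            self._model = default_model()
        return self._model

    # -- directory ------------------------------------------------------------

    def _read_directory(self) -> None:
        self._fh.seek(0)
        if self._fh.read(len(MAGIC)) != MAGIC:
            raise ArchiveError(f"{self.path}: not a prostar archive")
        self._fh.seek(0, os.SEEK_END)
        size = self._fh.tell()
        if size < len(MAGIC) + FOOTER_SIZE:
            raise ArchiveError(f"{self.path}: truncated archive")
        self._fh.seek(size - FOOTER_SIZE)
        footer = self._fh.read(FOOTER_SIZE)
        if footer[24:] != FOOTER_MAGIC:
            raise ArchiveError(f"{self.path}: bad footer magic")
        dir_off = int.from_bytes(footer[0:8], "little")
        dir_len = int.from_bytes(footer[8:16], "little")
        dir_sum = int.from_bytes(footer[16:24], "little")
        if dir_off + dir_len + FOOTER_SIZE > size:
            raise ArchiveError(f"{self.path}: directory out of bounds")
        self._fh.seek(dir_off)
        blob = self._fh.read(dir_len)
        if checksum64(blob) != dir_sum:
            raise ArchiveError(f"{self.path}: directory checksum mismatch")
        obj = json.loads(zstd_decompress(blob).decode())
        if obj.get("version") != 1:
            raise ArchiveError(f"{self.path}: unsupported archive version")
        self.entries = [ArchiveEntry.from_json(e) for e in obj["entries"]]
        self._by_name = {e.name: e for e in self.entries}
        self._data_end = dir_off

    def _write_directory(self) -> None:
        obj = {"version": 1, "entries": [e.to_json() for e in self.entries]}
        blob = zstd_compress(json.dumps(obj).encode(), 19)
        self._fh.seek(self._data_end)
        self._fh.write(blob)
        footer = (self._data_end.to_bytes(8, "little")
                  + len(blob).to_bytes(8, "little")
                  + checksum64(blob).to_bytes(8, "little") + FOOTER_MAGIC)
        self._fh.write(footer)
        self._fh.truncate()
        self._fh.flush()

    def close(self) -> None:
        if self.mode in ("w", "a"):
            self._write_directory()
        self._fh.close()

    def __enter__(self) -> "Archive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- adding ---------------------------------------------------------------

    def add_file(self, path: str | Path,
                 params: CompressionParams = CompressionParams(),
                 name: str | None = None) -> ArchiveEntry:
        p = Path(path)
        try:
            data = p.read_bytes()
        except OSError as exc:
            raise ArchiveError(f"cannot read {p}: {exc}") from exc
        return self.add_bytes(name or p.name, data, params)

    def add_bytes(self, name: str, data: bytes,
                  params: CompressionParams = CompressionParams(),
                  ) -> ArchiveEntry:
        if self.mode == "r":
            raise ArchiveError("archive opened read-only")
        if name in self._by_name:
            raise ArchiveError(f"duplicate entry name {name!r}")
        ftype = detect_file_type(name, data)
        payload, entry = self._encode_entry(name, ftype, data, params)
        entry.offset = self._data_end
        entry.length = len(payload)
        entry.checksum = checksum64(payload)
        self._fh.seek(self._data_end)
        self._fh.write(payload)
        self._data_end += len(payload)
        self.entries.append(entry)
        self._by_name[name] = entry
        return entry

    def _encode_entry(self, name: str, ftype: str, data: bytes,
                      params: CompressionParams,
                      ) -> tuple[bytes, ArchiveEntry]:
        entry = ArchiveEntry(name=name, file_type=ftype, offset=0, length=0,
                             checksum=0)
        lossy = params.lossy
        try:
            if ftype in ("pdb", "cif"):
                payload = encode_structure(data.decode(),
                                           "pdb" if ftype == "pdb" else "mmcif",
                                           self.model, lossy, params.fast)
                entry.model_fingerprint = self.model.fingerprint
                entry.lossy_backbone = lossy.m_backbone
                entry.lossy_sidechain = lossy.m_sidechain
                entry.minimal = lossy.minimal
                entry.fast = params.fast
                entry.bf_average = lossy.bf_average
                return payload, entry
            if ftype == "pae":
                m = parse_pae(data.decode())
                entry.pae_level = params.pae_level
                return encode_pae(m, params.pae_level), entry
            if ftype == "confidence":
                c = parse_confidence(data.decode())
                return encode_confidence(c), entry
        except (ParseError, UnicodeDecodeError):
            entry.opaque_fallback = True
        entry.file_type = "opaque"
        return zstd_compress(data, 19), entry

    # -- listing / extraction --------------------------------------------------

    def list(self) -> list[ArchiveEntry]:
        return list(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def extract(self, name: str) -> bytes:
        entry = self._by_name.get(name)
        if entry is None:
            raise ArchiveError(f"no entry named {name!r}")
        self._fh.seek(entry.offset)
        payload = self._fh.read(entry.length)
        if len(payload) != entry.length or checksum64(payload) != entry.checksum:
            raise ArchiveError(f"entry {name!r}: payload checksum mismatch")
        if entry.file_type == "opaque":
            return zstd_decompress(payload)
        if entry.file_type in ("pdb", "cif"):
            if (entry.model_fingerprint is not None
                    and entry.model_fingerprint != self.model.fingerprint):
                raise ModelMismatch(
                    f"entry {name!r} was compressed with model fingerprint "
                    f"{entry.model_fingerprint}, loaded model has "
                    f"{self.model.fingerprint}")
            return decode_structure(payload, self.model).encode()
        if entry.file_type == "pae":
            return write_pae(decode_pae(payload)).encode()
        if entry.file_type == "confidence":
            return write_confidence(decode_confidence(payload)).encode()
        raise ArchiveError(f"unknown entry type {entry.file_type!r}")

    def extract_to(self, name: str, path: str | Path) -> None:
        Path(path).write_bytes(self.extract(name))
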