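"""Whole-file coding of PDB/mmCIF structures.

A parsed file is a sequence of sections.  All *block* sections are
gathered and Zstandard-compressed together; each table is coded on its
own: atom tables through the coordinate predictor, hetatm and generic
tables column-wise.  The section-kind sequence is stored so the file is
reassembled in order.  *Minimal* mode keeps only the leading block (the
header) and the atom tables.

If an atom table is not covered by the prediction model it is demoted to
generic handling on the spot — the archive never loses data over model
coverage.
"""

from __future__ import annotations

from .coord_codec import (LossyParams, LOSSLESS, decode_atom_table,
                          encode_atom_table)
from .errors import ProstarError
from .formats_io import Section, parse_structure, serialize_atom_table
from .framing import ByteReader, ByteWriter
from .table_codec import decode_blocks, decode_generic_table, encode_blocks, \
    encode_generic_table
from .training import PredictionModel

_SEC_BLOCK = 0
_SEC_GENERIC = 1
_SEC_ATOM = 2


def encode_structure(text: str, dialect: str, model: PredictionModel,
                     lossy: LossyParams = LOSSLESS,
                     fast: bool = False) -> bytes:
    """Compress one structure file.  Raises ParseError for files the parser
    rejects outright (callers store those opaquely)."""
    sections = parse_structure(text, dialect)
    if lossy.minimal:
        sections = _minimal_sections(sections)
    w = ByteWriter()
    w.u8(1 if dialect == "pdb" else 0)
    kinds: list[int] = []
    blocks: list[str] = []
    tables: list[bytes] = []
    for sec in sections:
        if sec.kind == "block":
            kinds.append(_SEC_BLOCK)
            blocks.append(sec.raw_text)
            continue
        if sec.table_kind == "atom":
            try:
                payload = encode_atom_table(sec.atom_data, model, lossy, fast)
                kinds.append(_SEC_ATOM)
                tables.append(payload)
                continue
            except ProstarError:
                pass  # outside model coverage: demote to generic
        kinds.append(_SEC_GENERIC)
        m_sc = lossy.m_sidechain if lossy.is_lossy else 0
        tables.append(encode_generic_table(sec, m_sc))
    w.uvarint(len(kinds))
    for k in kinds:
        w.u8(k)
    w.chunk(encode_blocks(blocks))
    for t in tables:
        w.chunk(t)
    return w.getvalue()


def _minimal_sections(sections: list[Section]) -> list[Section]:
    out: list[Section] = []
    for i, sec in enumerate(sections):
        if sec.kind == "block" and i == 0:
            out.append(sec)
        elif sec.kind == "table" and sec.table_kind == "atom":
            out.append(sec)
    return out


def decode_structure(payload: bytes, model: PredictionModel) -> str:
    r = ByteReader(payload)
    dialect = "pdb" if r.u8() == 1 else "mmcif"
    kinds = [r.u8() for _ in range(r.uvarint())]
    blocks = decode_blocks(r.chunk())
    out: list[str] = []
    bi = 0
    for k in kinds:
        if k == _SEC_BLOCK:
            out.append(blocks[bi])
            bi += 1
        elif k == _SEC_GENERIC:
            out.append(decode_generic_table(r.chunk(), dialect))
        else:
            table = decode_atom_table(r.chunk(), model)
            out.append(serialize_atom_table(table))
    return "".join(out)


def roundtrip_check(text: str, dialect: str, model: PredictionModel) -> bool:
    """Lossless self-test used by callers that must never mis-store a file."""
    return decode_structure(encode_structure(text, dialect, model), model) == text
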