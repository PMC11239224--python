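"""Column-wise coding of generic tables, block sections and confidence
files.

Generic (and hetatm) tables are processed per column.  Numeric columns —
cells sharing one fixed-point scale — are stored as the minimal
reconstruction info when they are constant or an arithmetic progression,
and as entropy-coded row deltas otherwise.  Coordinate columns may be
grid-rounded first in lossy mode.  Text columns are concatenated and
Zstandard-compressed, as are block sections (headers, footers) and
confidence files.
"""

from __future__ import annotations

from dataclasses import dataclass

from .entropy import (FrequencyModel, RangeDecoder, RangeEncoder,
                      RESIDUAL_ALPHABET, get_residual, put_residual)
from .errors import ProstarError
from .formats_io import (ConfidenceFile, Section, format_fixed,
                         format_pdb_atom_line, parse_confidence, parse_fixed,
                         write_confidence, AtomRecord)
from .framing import ByteReader, ByteWriter, zstd_compress, zstd_decompress
from .geometry import round_coord, rounding_step

#: Zstandard levels: archival for text/blocks, light for small confidence files
ZSTD_TEXT_LEVEL = 19
ZSTD_CONF_LEVEL = 3

#: column names that carry coordinates (lossy-eligible in generic tables)
COORDINATE_COLUMNS = {"Cartn_x", "Cartn_y", "Cartn_z",
                      "_atom_site.Cartn_x", "_atom_site.Cartn_y",
                      "_atom_site.Cartn_z"}


@dataclass(frozen=True)
class ColumnClass:
    kind: str                 # constant | arithmetic | delta_numeric | text
    scale: int = 0            # fixed-point decimals for numeric kinds
    value: str | None = None  # constant: the cell text
    first: int = 0            # arithmetic: first value (scaled)
    step: int = 0             # arithmetic: common difference (scaled)


def _numeric_scale(values: list[str]) -> int | None:
    """Common fixed-point scale of all cells, or None if non-numeric /
    mixed-scale / non-canonical formatting."""
    scale: int | None = None
    for v in values:
        if "." in v:
            head, _, frac = v.partition(".")
            d = len(frac)
        else:
            d = 0
        if scale is None:
            scale = d
        elif scale != d:
            return None
        try:
            parsed = parse_fixed(v, d) if d else int(v)
        except (ProstarError, ValueError):
            return None
        canonical = format_fixed(parsed, d) if d else str(parsed)
        if canonical != v:
            return None
    return scale


def classify_column(values: list[str]) -> ColumnClass:
    """Decide how a column is stored.  Constant columns (numeric or not,
    including the degenerate one-row case) need only their value; numeric
    arithmetic progressions need first and step; other numeric columns are
    delta-coded; everything else is text."""
    if not values:
        return ColumnClass(kind="constant", value="")
    if all(v == values[0] for v in values):
        return ColumnClass(kind="constant", value=values[0])
    scale = _numeric_scale(values)
    if scale is None:
        return ColumnClass(kind="text")
    ints = [parse_fixed(v, scale) if scale else int(v) for v in values]
    step = ints[1] - ints[0]
    if all(ints[i + 1] - ints[i] == step for i in range(len(ints) - 1)):
        return ColumnClass(kind="arithmetic", scale=scale, first=ints[0],
                           step=step)
    return ColumnClass(kind="delta_numeric", scale=scale)


def _format_cell(v: int, scale: int) -> str:
    return format_fixed(v, scale) if scale else str(v)


# --- generic table ------------------------------------------------------------

_KIND_CODE = {"constant": 0, "arithmetic": 1, "delta_numeric": 2, "text": 3,
              "lossy_coordinate": 4}
_KIND_NAME = {v: k for k, v in _KIND_CODE.items()}

# row reassembly styles
_ROWS_RAGGED = 0       # raw text lines stored verbatim
_ROWS_CIF_JOIN = 1     # cells joined with single spaces
_ROWS_PDB_HET = 2      # cells re-formatted through the fixed-width template


def encode_generic_table(section: Section, lossy_sidechain_m: int = 0) -> bytes:
    """Encode a generic/hetatm table section.  ``lossy_sidechain_m`` > 0
    grid-rounds coordinate columns (side-chain grid, per the lossy policy
    for tables that are generic for whatever reason)."""
    w = ByteWriter()
    w.text("".join(section.header_lines))
    if section.rows is None:
        w.u8(_ROWS_RAGGED)
        w.chunk(zstd_compress("".join(section.raw_lines).encode(),
                              ZSTD_TEXT_LEVEL))
        return w.getvalue()
    style = _ROWS_PDB_HET if section.dialect == "pdb" else _ROWS_CIF_JOIN
    w.u8(style)
    rows = section.rows
    ncols = len(section.column_names or (rows[0] if rows else []))
    w.uvarint(len(rows))
    w.uvarint(ncols)
    names = section.column_names or [""] * ncols

    enc = RangeEncoder()
    model = FrequencyModel(RESIDUAL_ALPHABET)
    texts: list[str] = []
    for ci in range(ncols):
        col = [r[ci] for r in rows]
        cls = classify_column(col)
        if (lossy_sidechain_m > 0 and cls.kind in ("delta_numeric", "arithmetic")
                and cls.scale == 3 and names[ci] in COORDINATE_COLUMNS):
            spec = rounding_step(lossy_sidechain_m)
            ints = [round_coord((parse_fixed(v, 3), 0, 0), spec)[0]
                    for v in col]
            w.u8(_KIND_CODE["lossy_coordinate"])
            prev = 0
            for v in ints:
                put_residual(enc, model, v - prev)
                prev = v
            continue
        w.u8(_KIND_CODE[cls.kind])
        if cls.kind == "constant":
            w.text(cls.value or "")
        elif cls.kind == "arithmetic":
            w.u8(cls.scale)
            w.svarint(cls.first)
            w.svarint(cls.step)
        elif cls.kind == "delta_numeric":
            w.u8(cls.scale)
            prev = 0
            for v in col:
                iv = parse_fixed(v, cls.scale) if cls.scale else int(v)
                put_residual(enc, model, iv - prev)
                prev = iv
        else:
            texts.append("\n".join(col))
    w.chunk(enc.finish())
    w.chunk(zstd_compress("\x00".join(texts).encode(), ZSTD_TEXT_LEVEL))
    return w.getvalue()


def decode_generic_table(payload: bytes, dialect: str) -> str:
    """Reconstruct the section text (byte-exact unless coordinates were
    grid-rounded)."""
    r = ByteReader(payload)
    header = r.text()
    style = r.u8()
    if style == _ROWS_RAGGED:
        return header + zstd_decompress(r.chunk()).decode()
    nrows = r.uvarint()
    ncols = r.uvarint()
    specs: list[tuple[int, ColumnClass]] = []
    for _ in range(ncols):
        kind = _KIND_NAME[r.u8()]
        if kind == "constant":
            specs.append((0, ColumnClass(kind=kind, value=r.text())))
        elif kind == "arithmetic":
            scale = r.u8()
            first = r.svarint()
            step = r.svarint()
            specs.append((0, ColumnClass(kind=kind, scale=scale, first=first,
                                         step=step)))
        elif kind == "delta_numeric":
            specs.append((0, ColumnClass(kind=kind, scale=r.u8())))
        elif kind == "lossy_coordinate":
            specs.append((0, ColumnClass(kind=kind, scale=3)))
        else:
            specs.append((0, ColumnClass(kind="text")))
    rc = r.chunk()
    texts = zstd_decompress(r.chunk()).decode()
    text_cols = texts.split("\x00") if texts else []

    dec = RangeDecoder(rc) if any(c.kind in ("delta_numeric", "lossy_coordinate")
                                  for _, c in specs) else None
    model = FrequencyModel(RESIDUAL_ALPHABET)
    cols: list[list[str]] = []
    ti = 0
    for _, cls in specs:
        if cls.kind == "constant":
            cols.append([cls.value or ""] * nrows)
        elif cls.kind == "arithmetic":
            cols.append([_format_cell(cls.first + i * cls.step, cls.scale)
                         for i in range(nrows)])
        elif cls.kind in ("delta_numeric", "lossy_coordinate"):
            vals = []
            prev = 0
            for _ in range(nrows):
                prev += get_residual(dec, model)
                vals.append(_format_cell(prev, cls.scale))
            cols.append(vals)
        else:
            cols.append(text_cols[ti].split("\n") if nrows else [])
            ti += 1
    rows = [[cols[c][i] for c in range(ncols)] for i in range(nrows)]
    if style == _ROWS_CIF_JOIN:
        body = "".join(" ".join(row) + "\n" for row in rows)
    else:
        body = "".join(_format_het_row(row) for row in rows)
    return header + body


def _format_het_row(cells: list[str]) -> str:
    rec = AtomRecord(
        serial=int(cells[1]), atom_name=cells[2],
        alt_loc="" if cells[3] == "." else cells[3], residue_name=cells[4],
        chain_id=cells[5], residue_seq=int(cells[6]),
        insertion_code="" if cells[7] == "?" else cells[7],
        coord=(parse_fixed(cells[8], 3), parse_fixed(cells[9], 3),
               parse_fixed(cells[10], 3)),
        occupancy=parse_fixed(cells[11], 2), b_factor=parse_fixed(cells[12], 2),
        element=cells[13], het=cells[0] == "HETATM")
    return format_pdb_atom_line(rec)


# --- block sections ------------------------------------------------------------

def encode_blocks(block_texts: list[str]) -> bytes:
    """All block sections of a file, length-prefixed and jointly
    Zstandard-compressed."""
    w = ByteWriter()
    for t in block_texts:
        w.text(t)
    out = ByteWriter()
    out.uvarint(len(block_texts))
    out.chunk(zstd_compress(w.getvalue(), ZSTD_TEXT_LEVEL))
    return out.getvalue()


def decode_blocks(payload: bytes) -> list[str]:
    r = ByteReader(payload)
    n = r.uvarint()
    inner = ByteReader(zstd_decompress(r.chunk()))
    return [inner.text() for _ in range(n)]


# --- confidence files -----------------------------------------------------------

def encode_confidence(c: ConfidenceFile) -> bytes:
    return zstd_compress(write_confidence(c).encode(), ZSTD_CONF_LEVEL)


def decode_confidence(payload: bytes) -> ConfidenceFile:
    return parse_confidence(zstd_decompress(payload).decode())
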