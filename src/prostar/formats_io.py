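"""Parsing and serialization of structure-prediction file formats.

Supported inputs:

* **PDB** — fixed-width text; ATOM/HETATM/TER records plus arbitrary
  header/footer lines.
* **mmCIF** — line-oriented; ``loop_`` tables plus key-value blocks.
* **PAE JSON** — an n×n integer matrix with values in [0, 32]
  (AlphaFold v4 object dialect, a singleton list wrapping it, or a bare
  2-D array).
* **confidence JSON** — three equal-length arrays: residue ids, scores,
  single-character categories.

A structure file is split into an ordered list of :class:`Section` objects
(*block* or *table*).  Concatenating ``raw_text`` over the sections
reproduces the input byte for byte; this is the lossless contract every
codec downstream must preserve.  Tables are classified *atom* only when
they contain canonical amino-acid chains, in canonical atom order, with no
missing fields, and when their canonical re-serialization matches the
input exactly — anything else falls back to *hetatm* or *generic*
handling, never to data loss.

Coordinates, occupancies and B-factors are kept as fixed-point integers
(milli-Ångström / hundredths) so that lossless arithmetic is exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .errors import ParseError
from .residues import RESIDUE_ATOMS, TERMINAL_OXYGEN, element_of

# --- fixed-point helpers ----------------------------------------------------

_FIXED_RE = {d: re.compile(rf"^-?\d+\.\d{{{d}}}$") for d in (2, 3)}


def parse_fixed(s: str, decimals: int) -> int:
    """Parse a decimal string with exactly *decimals* fraction digits into a
    scaled integer (e.g. ``"-1.234"`` with 3 decimals -> -1234)."""
    t = s.strip()
    rx = _FIXED_RE.get(decimals) or re.compile(rf"^-?\d+\.\d{{{decimals}}}$")
    if not rx.match(t):
        raise ParseError(f"not a fixed-point({decimals}) value: {s!r}")
    neg = t.startswith("-")
    whole, frac = t.lstrip("-").split(".")
    v = int(whole) * 10 ** decimals + int(frac)
    return -v if neg else v


def format_fixed(v: int, decimals: int) -> str:
    a = abs(v)
    scale = 10 ** decimals
    return f"{'-' if v < 0 else ''}{a // scale}.{a % scale:0{decimals}d}"


# --- data model -------------------------------------------------------------

@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    alt_loc: str            # "" when absent
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str     # "" when absent
    coord: tuple[int, int, int]   # mÅ
    occupancy: int          # hundredths
    b_factor: int           # hundredths
    element: str
    het: bool = False


@dataclass
class ChainData:
    """One polypeptide chain of an atom-classified table."""

    chain_id: str
    residue_names: list[str]
    residue_seqs: list[int]
    has_oxt: bool           # last residue carries a terminal OXT
    has_ter: bool           # PDB TER record closes the chain
    atoms: list[AtomRecord]


@dataclass
class AtomTableData:
    dialect: str            # "pdb" | "mmcif"
    serial_start: int
    chains: list[ChainData]


@dataclass
class Section:
    kind: str                       # "block" | "table"
    raw_text: str
    dialect: str                    # "pdb" | "mmcif"
    table_kind: str = "none"        # "generic" | "atom" | "hetatm" | "none"
    column_names: list[str] | None = None
    rows: list[list[str]] | None = None   # None => ragged: keep raw lines
    raw_lines: list[str] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)  # mmCIF loop_ + tags
    atom_data: AtomTableData | None = None
    demote_reason: str | None = None


@dataclass
class PAEMatrix:
    n: int
    values: list[list[int]]


@dataclass
class ConfidenceFile:
    residue_ids: list[int]
    scores: list[int]        # hundredths
    categories: list[str]

    def __post_init__(self) -> None:
        if not (len(self.residue_ids) == len(self.scores) == len(self.categories)):
            raise ParseError("confidence arrays differ in length")


# --- PDB fixed-width layout -------------------------------------------------

def _pdb_atom_name_field(name: str, element: str) -> str:
    # single-letter elements start in column 14, two-letter in column 13
    if len(element) == 1:
        return (" " + name).ljust(4)
    return name.ljust(4)


def format_pdb_atom_line(r: AtomRecord) -> str:
    return (
        f"{'HETATM' if r.het else 'ATOM  '}"
        f"{r.serial:>5} "
        f"{_pdb_atom_name_field(r.atom_name, r.element)}"
        f"{r.alt_loc or ' '}"
        f"{r.residue_name:>3} "
        f"{r.chain_id}"
        f"{r.residue_seq:>4}"
        f"{r.insertion_code or ' '}   "
        f"{format_fixed(r.coord[0], 3):>8}"
        f"{format_fixed(r.coord[1], 3):>8}"
        f"{format_fixed(r.coord[2], 3):>8}"
        f"{format_fixed(r.occupancy, 2):>6}"
        f"{format_fixed(r.b_factor, 2):>6}"
        f"{'':10}"
        f"{r.element:>2}\n"
    )


def format_pdb_ter_line(serial: int, resname: str, chain: str, resseq: int) -> str:
    return f"TER   {serial:>5}      {resname:>3} {chain}{resseq:>4}\n"


def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    body = line.rstrip("\n")
    if len(body) < 78:
        raise ParseError(f"line {lineno}: ATOM/HETATM record shorter than 78 columns")
    try:
        serial = int(body[6:11])
        resseq = int(body[22:26])
        coord = (parse_fixed(body[30:38], 3), parse_fixed(body[38:46], 3),
                 parse_fixed(body[46:54], 3))
        occupancy = parse_fixed(body[54:60], 2)
        b_factor = parse_fixed(body[60:66], 2)
    except (ValueError, ParseError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    return AtomRecord(
        serial=serial,
        atom_name=body[12:16].strip(),
        alt_loc=body[16].strip(),
        residue_name=body[17:20].strip(),
        chain_id=body[21],
        residue_seq=resseq,
        insertion_code=body[26].strip(),
        coord=coord,
        occupancy=occupancy,
        b_factor=b_factor,
        element=body[76:78].strip(),
        het=body.startswith("HETATM"),
    )


# --- mmCIF canonical atom_site dialect ---------------------------------------

ATOM_SITE_TAGS = (
    "_atom_site.group_PDB",
    "_atom_site.id",
    "_atom_site.type_symbol",
    "_atom_site.label_atom_id",
    "_atom_site.label_alt_id",
    "_atom_site.label_comp_id",
    "_atom_site.label_asym_id",
    "_atom_site.label_entity_id",
    "_atom_site.label_seq_id",
    "_atom_site.pdbx_PDB_ins_code",
    "_atom_site.Cartn_x",
    "_atom_site.Cartn_y",
    "_atom_site.Cartn_z",
    "_atom_site.occupancy",
    "_atom_site.B_iso_or_equiv",
    "_atom_site.pdbx_formal_charge",
    "_atom_site.auth_seq_id",
    "_atom_site.auth_comp_id",
    "_atom_site.auth_asym_id",
    "_atom_site.auth_atom_id",
    "_atom_site.pdbx_PDB_model_num",
)


def format_cif_atom_row(r: AtomRecord) -> str:
    return " ".join((
        "HETATM" if r.het else "ATOM",
        str(r.serial),
        r.element,
        r.atom_name,
        r.alt_loc or ".",
        r.residue_name,
        r.chain_id,
        "1",
        str(r.residue_seq),
        r.insertion_code or "?",
        format_fixed(r.coord[0], 3),
        format_fixed(r.coord[1], 3),
        format_fixed(r.coord[2], 3),
        format_fixed(r.occupancy, 2),
        format_fixed(r.b_factor, 2),
        "?",
        str(r.residue_seq),
        r.residue_name,
        r.chain_id,
        r.atom_name,
        "1",
    )) + "\n"


def _parse_cif_atom_row(cells: list[str], lineno: int) -> AtomRecord:
    try:
        return AtomRecord(
            serial=int(cells[1]),
            atom_name=cells[3],
            alt_loc="" if cells[4] == "." else cells[4],
            residue_name=cells[5],
            chain_id=cells[6],
            residue_seq=int(cells[8]),
            insertion_code="" if cells[9] == "?" else cells[9],
            coord=(parse_fixed(cells[10], 3), parse_fixed(cells[11], 3),
                   parse_fixed(cells[12], 3)),
            occupancy=parse_fixed(cells[13], 2),
            b_factor=parse_fixed(cells[14], 2),
            element=cells[2],
            het=cells[0] == "HETATM",
        )
    except (ValueError, ParseError, IndexError) as exc:
        raise ParseError(f"row {lineno}: {exc}") from exc


# --- section splitting -------------------------------------------------------

def _split_lines(text: str) -> list[str]:
    return text.splitlines(keepends=True)


def _parse_pdb_sections(text: str) -> list[Section]:
    sections: list[Section] = []
    cur_kind: str | None = None
    cur: list[str] = []

    def flush() -> None:
        nonlocal cur, cur_kind
        if cur:
            kind = "block" if cur_kind == "block" else "table"
            sections.append(Section(kind=kind, raw_text="".join(cur),
                                    dialect="pdb", raw_lines=cur))
            cur = []
        cur_kind = None

    for line in _split_lines(text):
        rec = line[:6]
        if rec == "ATOM  " or (rec.startswith("TER") and cur_kind == "atom"):
            group = "atom"
        elif rec == "HETATM":
            group = "het"
        else:
            group = "block"
        if group != cur_kind:
            flush()
            cur_kind = group
        cur.append(line)
    flush()
    return sections


_CIF_ROW_END = ("loop_", "data_", "#", "_")


def _parse_mmcif_sections(text: str) -> list[Section]:
    lines = _split_lines(text)
    sections: list[Section] = []
    i = 0
    block: list[str] = []

    def flush_block() -> None:
        nonlocal block
        if block:
            sections.append(Section(kind="block", raw_text="".join(block),
                                    dialect="mmcif", raw_lines=block))
            block = []

    n = len(lines)
    while i < n:
        stripped = lines[i].strip()
        if stripped == "loop_":
            flush_block()
            header = [lines[i]]
            i += 1
            tags: list[str] = []
            while i < n and lines[i].strip().startswith("_"):
                tags.append(lines[i].strip())
                header.append(lines[i])
                i += 1
            rows_raw: list[str] = []
            while i < n:
                s = lines[i].strip()
                if not s or any(s.startswith(p) for p in _CIF_ROW_END):
                    break
                rows_raw.append(lines[i])
                i += 1
            sections.append(Section(
                kind="table",
                raw_text="".join(header) + "".join(rows_raw),
                dialect="mmcif",
                column_names=tags,
                raw_lines=rows_raw,
                header_lines=header,
            ))
        else:
            block.append(lines[i])
            i += 1
    flush_block()
    return sections


def parse_structure(text: str, dialect: str) -> list[Section]:
    """Split a PDB/mmCIF file into sections and classify the tables.

    The concatenation of ``raw_text`` over the result equals *text*;
    tables that withstand classification carry parsed atom data.
    """
    if dialect == "pdb":
        sections = _parse_pdb_sections(text)
    elif dialect == "mmcif":
        sections = _parse_mmcif_sections(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for sec in sections:
        if sec.kind == "table":
            classify_table(sec)
    return sections


def serialize_sections(sections: list[Section]) -> str:
    return "".join(s.raw_text for s in sections)


# --- table classification ----------------------------------------------------

def _build_chains(records: list[AtomRecord], ter_flags: list[bool],
                  ordering: dict[str, tuple[str, ...]]) -> list[ChainData]:
    """Group records into chains/residues and verify canonical atom order.

    Raises ParseError on any violation (caller demotes to generic).
    """
    chains: list[ChainData] = []
    i = 0
    n = len(records)
    while i < n:
        chain_id = records[i].chain_id
        atoms: list[AtomRecord] = []
        has_ter = False
        while i < n and records[i].chain_id == chain_id:
            atoms.append(records[i])
            if ter_flags[i]:
                has_ter = True
                i += 1
                break
            i += 1
        # split into residues by residue_seq boundaries
        res_names: list[str] = []
        res_seqs: list[int] = []
        has_oxt = False
        j = 0
        na = len(atoms)
        while j < na:
            a0 = atoms[j]
            if a0.alt_loc or a0.insertion_code:
                raise ParseError("alternate location or insertion code present")
            rname = a0.residue_name
            expected = ordering.get(rname)
            if expected is None:
                raise ParseError(f"non-canonical residue {rname!r}")
            for name in expected:
                if j >= na:
                    raise ParseError("residue truncated")
                a = atoms[j]
                if (a.atom_name != name or a.residue_name != rname
                        or a.residue_seq != a0.residue_seq
                        or a.alt_loc or a.insertion_code
                        or a.element != element_of(name)):
                    raise ParseError("atom order violation")
                j += 1
            res_names.append(rname)
            res_seqs.append(a0.residue_seq)
            # OXT may only close the chain's final residue
            if (j == na - 1 and atoms[j].atom_name == TERMINAL_OXYGEN
                    and atoms[j].residue_seq == a0.residue_seq
                    and atoms[j].residue_name == rname
                    and atoms[j].element == "O"
                    and not atoms[j].alt_loc and not atoms[j].insertion_code):
                has_oxt = True
                j += 1
        chains.append(ChainData(chain_id=chain_id, residue_names=res_names,
                                residue_seqs=res_seqs, has_oxt=has_oxt,
                                has_ter=has_ter, atoms=atoms))
    return chains


def classify_table(section: Section,
                   ordering: dict[str, tuple[str, ...]] | None = None) -> str:
    """Assign ``table_kind`` to a table section.

    *atom*: canonical amino-acid chains, canonical atom order, no missing
    fields, and byte-exact canonical serialization.  *hetatm*: all rows are
    HETATM records with no missing data (still encoded generically).
    Everything else: *generic*.
    """
    if section.kind != "table":
        raise ValueError("classify_table needs a table section")
    ordering = ordering or RESIDUE_ATOMS
    if section.dialect == "pdb":
        kind = _classify_pdb_table(section, ordering)
    else:
        kind = _classify_cif_table(section, ordering)
    section.table_kind = kind
    return kind


def _classify_pdb_table(section: Section,
                        ordering: dict[str, tuple[str, ...]]) -> str:
    lines = section.raw_lines
    is_het = lines[0].startswith("HETATM")
    records: list[AtomRecord] = []
    ter_flags: list[bool] = []
    try:
        for idx, line in enumerate(lines):
            if line.startswith("TER"):
                if not records or ter_flags[-1] or is_het:
                    raise ParseError("stray TER record")
                ter_flags[-1] = True
                continue
            records.append(_parse_pdb_atom(line, idx + 1))
            ter_flags.append(False)
    except ParseError as exc:
        section.demote_reason = str(exc)
        _make_ragged(section)
        return "generic"

    if is_het:
        if _verify_pdb_serialization(section, records, ter_flags):
            _extract_het_columns(section, records)
            return "hetatm"
        _make_ragged(section)
        return "generic"

    try:
        chains = _build_chains(records, ter_flags, ordering)
        _check_serials(records, ter_flags)
    except ParseError as exc:
        section.demote_reason = str(exc)
        _make_ragged(section)
        return "generic"
    if not _verify_pdb_serialization(section, records, ter_flags):
        section.demote_reason = "non-canonical formatting"
        _make_ragged(section)
        return "generic"
    section.atom_data = AtomTableData(dialect="pdb",
                                      serial_start=records[0].serial,
                                      chains=chains)
    return "atom"


def _check_serials(records: list[AtomRecord], ter_flags: list[bool]) -> None:
    expected = records[0].serial
    for rec, ter in zip(records, ter_flags):
        if rec.serial != expected:
            raise ParseError("serial numbers not consecutive")
        expected += 2 if ter else 1  # TER consumes a serial in PDB


def _verify_pdb_serialization(section: Section, records: list[AtomRecord],
                              ter_flags: list[bool]) -> bool:
    out: list[str] = []
    for rec, ter in zip(records, ter_flags):
        out.append(format_pdb_atom_line(rec))
        if ter:
            out.append(format_pdb_ter_line(rec.serial + 1, rec.residue_name,
                                           rec.chain_id, rec.residue_seq))
    return "".join(out) == section.raw_text


def _extract_het_columns(section: Section, records: list[AtomRecord]) -> None:
    section.column_names = ["group_PDB", "id", "atom_id", "alt_id", "comp_id",
                            "asym_id", "seq_id", "ins_code", "Cartn_x",
                            "Cartn_y", "Cartn_z", "occupancy",
                            "B_iso_or_equiv", "type_symbol"]
    section.rows = [[
        "HETATM" if r.het else "ATOM", str(r.serial), r.atom_name,
        r.alt_loc or ".", r.residue_name, r.chain_id, str(r.residue_seq),
        r.insertion_code or "?", format_fixed(r.coord[0], 3),
        format_fixed(r.coord[1], 3), format_fixed(r.coord[2], 3),
        format_fixed(r.occupancy, 2), format_fixed(r.b_factor, 2), r.element,
    ] for r in records]


def _make_ragged(section: Section) -> None:
    """Fall back to storing the table's data rows as opaque text lines."""
    section.rows = None


def _classify_cif_table(section: Section,
                        ordering: dict[str, tuple[str, ...]]) -> str:
    tags = section.column_names or []
    rows: list[list[str]] = []
    for idx, line in enumerate(section.raw_lines):
        cells = line.split()
        if len(cells) != len(tags) or " ".join(cells) + "\n" != line:
            section.demote_reason = f"row {idx + 1}: non-canonical cells"
            _make_ragged(section)
            return "generic"
        rows.append(cells)
    section.rows = rows
    if tuple(tags) != ATOM_SITE_TAGS or not rows:
        return "generic"
    if not _canonical_cif_header(section):
        return "generic"

    records: list[AtomRecord] = []
    try:
        for idx, cells in enumerate(rows):
            rec = _parse_cif_atom_row(cells, idx + 1)
            records.append(rec)
            if format_cif_atom_row(rec) != section.raw_lines[idx]:
                raise ParseError(f"row {idx + 1}: non-canonical values")
    except ParseError as exc:
        section.demote_reason = str(exc)
        return "hetatm" if all(c[0] == "HETATM" for c in rows) else "generic"

    if all(r.het for r in records):
        return "hetatm"
    if any(r.het for r in records):
        return "generic"
    ter_flags = [False] * len(records)
    try:
        chains = _build_chains(records, ter_flags, ordering)
        _check_serials(records, ter_flags)
    except ParseError as exc:
        section.demote_reason = str(exc)
        return "generic"
    section.atom_data = AtomTableData(dialect="mmcif",
                                      serial_start=records[0].serial,
                                      chains=chains)
    return "atom"


def _canonical_cif_header(section: Section) -> bool:
    want = ["loop_\n"] + [t + "\n" for t in ATOM_SITE_TAGS]
    return section.header_lines == want


# --- atom table serialization (decode side) ----------------------------------

def serialize_atom_table(data: AtomTableData) -> str:
    """Canonical text of an atom table, as verified during classification."""
    out: list[str] = []
    if data.dialect == "mmcif":
        out.append("loop_\n")
        out.extend(t + "\n" for t in ATOM_SITE_TAGS)
    serial = data.serial_start
    for chain in data.chains:
        for rec in chain.atoms:
            rec.serial = serial
            if data.dialect == "pdb":
                out.append(format_pdb_atom_line(rec))
            else:
                out.append(format_cif_atom_row(rec))
            serial += 1
        if chain.has_ter and data.dialect == "pdb":
            last = chain.atoms[-1]
            out.append(format_pdb_ter_line(serial, last.residue_name,
                                           chain.chain_id, last.residue_seq))
            serial += 1
    return "".join(out)


# --- PAE JSON -----------------------------------------------------------------

PAE_KEY = "predicted_aligned_error"
PAE_MAX_VALUE = 32


def parse_pae(json_text: str) -> PAEMatrix:
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid PAE JSON: {exc}") from exc
    if isinstance(obj, list) and len(obj) == 1 and isinstance(obj[0], dict):
        obj = obj[0]
    if isinstance(obj, dict):
        if PAE_KEY not in obj:
            raise ParseError(f"PAE JSON object lacks {PAE_KEY!r}")
        matrix = obj[PAE_KEY]
    else:
        matrix = obj
    if not isinstance(matrix, list) or not matrix:
        raise ParseError("PAE matrix must be a non-empty 2-D array")
    n = len(matrix)
    values: list[list[int]] = []
    for i, row in enumerate(matrix):
        if not isinstance(row, list) or len(row) != n:
            raise ParseError(f"PAE matrix is not square at row {i}")
        out_row: list[int] = []
        for j, v in enumerate(row):
            if isinstance(v, float):
                if not v.is_integer():
                    raise ParseError(f"non-integer PAE value at ({i}, {j})")
                v = int(v)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ParseError(f"non-integer PAE value at ({i}, {j})")
            if not 0 <= v <= PAE_MAX_VALUE:
                raise ParseError(
                    f"PAE value {v} at ({i}, {j}) outside [0, {PAE_MAX_VALUE}]")
            out_row.append(v)
        values.append(out_row)
    return PAEMatrix(n=n, values=values)


def write_pae(m: PAEMatrix) -> str:
    """Canonical PAE dialect: compact AlphaFold-style object, no whitespace."""
    rows = ",".join("[" + ",".join(map(str, row)) + "]" for row in m.values)
    return f'{{"{PAE_KEY}":[{rows}]}}'


# --- confidence JSON ----------------------------------------------------------

def parse_confidence(json_text: str) -> ConfidenceFile:
    try:
        obj = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid confidence JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ParseError("confidence JSON must be an object")
    try:
        ids = obj["residueNumber"]
        scores = obj["confidenceScore"]
        cats = obj["confidenceCategory"]
    except KeyError as exc:
        raise ParseError(f"confidence JSON lacks key {exc}") from exc
    if not (len(ids) == len(scores) == len(cats)):
        raise ParseError("confidence arrays differ in length")
    try:
        ids = [int(i) for i in ids]
        scores_c = [_score_to_cents(s) for s in scores]
    except (TypeError, ValueError) as exc:
        raise ParseError(f"bad confidence value: {exc}") from exc
    for c in cats:
        if not (isinstance(c, str) and len(c) == 1):
            raise ParseError(f"confidence category must be one character: {c!r}")
    return ConfidenceFile(residue_ids=ids, scores=scores_c, categories=cats)


def _score_to_cents(s: float) -> int:
    c = round(float(s) * 100)
    if abs(c - float(s) * 100) > 1e-6:
        raise ValueError(f"score {s!r} has more than 2 decimals")
    return int(c)


def write_confidence(c: ConfidenceFile) -> str:
    """Canonical dialect: compact JSON, scores printed with 2 decimals."""
    ids = ",".join(map(str, c.residue_ids))
    scores = ",".join(format_fixed(s, 2) for s in c.scores)
    cats = ",".join(f'"{x}"' for x in c.categories)
    return ('{"residueNumber":[%s],"confidenceScore":[%s],'
            '"confidenceCategory":[%s]}' % (ids, scores, cats))
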