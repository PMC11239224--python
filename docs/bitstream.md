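# Bitstream formats (version 1)

All multi-byte integers are little-endian; `uvarint` is LEB128;
`svarint` is zig-zag LEB128; `chunk` is `uvarint length` + bytes.

## Range-coded streams

Byte-wise renormalizing range coder: 32-bit range, 64-bit low with carry
propagation (cache + pending-0xFF scheme).  Encoding finishes with five
forced shift-outs, so every stream carries a 5-byte tail and an empty
stream is exactly 5 bytes.  Decoders read exactly as many bytes as the
encoder wrote; a missing byte raises a truncation error.

Adaptive frequency models: per-symbol counts start at 1, increment 32
per coded symbol, halve (rounding up) when the total reaches 2^16.
Raw bits (residual offsets) are coded at a fixed cost of 1 bit each.

Residual binarization: bucket 0 = zero; buckets 1..31 = positive
magnitude classes `c = floor(log2 v)` (class c covers [2^c, 2^(c+1)));
buckets 32..62 the same for negatives; `c` raw offset bits follow the
bucket symbol.

## Atom-table stream (`coord_codec`)

One range-coded stream, in order:

1. lossy m_backbone, m_sidechain (residuals; 0 = lossless)
2. dialect flag (1 = pdb), serial_start, chain count
3. per chain: chain-id length + bytes (byte model); residue count;
   residue-type symbols (alphabet 20); residue-number deltas; OXT flag;
   TER flag; coordinates; B-factor block; occupancy deltas.

Coordinates per chain, atoms in canonical order: the first three atoms
(and any atom whose references are unavailable) are delta-coded per axis
against the previous atom (the first against the origin).  Every other
atom: centroid-id symbol (model per (residue, atom) slot), mirror flag,
then per-axis residuals in (backbone|side-chain, axis) models.

B-factors: mode flag (0 = constant per residue -> one delta-coded value
per residue; 1 = per atom).

## Generic-table payload (`table_codec`)

`chunk header-text`, `u8 row-style` (0 verbatim text, 1 space-joined
cells, 2 PDB fixed-width), then for columnar styles: `uvarint rows`,
`uvarint cols`, per column a kind byte (0 constant: `chunk value`;
1 arithmetic: `u8 scale, svarint first, svarint step`; 2 delta-numeric:
`u8 scale`; 3 text; 4 lossy-coordinate), then one `chunk` with the
range-coded deltas of all numeric columns in order and one `chunk` with
the Zstandard-compressed text columns (NUL-separated newline-joined).

## Structure payload (`structure_codec`)

`u8 dialect`, `uvarint section count`, one kind byte per section
(0 block, 1 generic table, 2 atom table), `chunk` of jointly
Zstandard-compressed length-prefixed block texts, then one `chunk` per
table in order.

## PAE payload (`pae_codec`)

`uvarint n`, `u8 level`, `chunk` of the range-coded residual symbols
(row-major; alphabet `2g-1` for g groups; context ids in [0, 8100)).

## Archive file (`archive`)

`"PSARv001"`, payloads, Zstandard-compressed JSON directory, 32-byte
footer = `u64 dir_offset, u64 dir_length, u64 dir_checksum(BLAKE2b-8),
"PSARDIR!"`.  Per-entry directory fields: name, file type, offset,
length, payload checksum, model fingerprint (structures), lossy
parameters, PAE level, minimal/fast/bf-average/opaque-fallback flags.
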