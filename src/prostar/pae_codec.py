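"""Compression of Predicted Aligned Error matrices.

A PAE file is an n×n matrix of integers in [0, 32].  Borrowing from
lossless image coding, each cell is predicted from its causal neighborhood
(row-major scan) either *horizontally* (from the left neighbor) or
*vertically* (from the upper neighbor); the direction is chosen per cell
from running statistics of which neighbor difference has been smaller in
this row vs this column so far.  The prediction rules encode PAE-specific
structure: the diagonal is 0, the first off-diagonals are 1, and a large
contrast between the two neighbors nudges the prediction by one.

The prediction error is entropy-coded in one of 8100 contexts formed from
five quantized neighbor differences (cardinalities 5, 5, 3, 3, 3), the
quantized left-neighbor value (6) and the direction flag (2).

Lossy levels 1-4 first map values onto coarser groups; the pipeline is
unchanged except that it operates on group indices (thresholds applied to
group representatives), and decoding yields each group's representative
``floor((lo+hi)/2)``.
"""

from __future__ import annotations

from .entropy import ContextedModelBank, RangeDecoder, RangeEncoder
from .errors import ProstarError
from .formats_io import PAEMatrix
from .framing import ByteReader, ByteWriter

PAE_CONTEXT_COUNT = 5 * 5 * 3 * 3 * 3 * 6 * 2  # = 8100
PAE_MAX = 32

#: value groupings of the lossy levels; level 0 is the 33 singletons
LEVEL_GROUPS: dict[int, tuple[tuple[int, int], ...]] = {
    0: tuple((v, v) for v in range(33)),
    1: tuple((v, v) for v in range(20)) + ((20, 21), (22, 23), (24, 27),
                                           (28, 32)),
    2: tuple((v, v) for v in range(10)) + ((10, 12), (13, 15), (16, 19),
                                           (20, 23), (24, 27), (28, 32)),
    3: tuple((v, v) for v in range(6)) + ((6, 7), (8, 10), (11, 14),
                                          (15, 19), (20, 25), (26, 32)),
    4: tuple((v, v) for v in range(4)) + ((4, 5), (6, 8), (9, 12), (13, 17),
                                          (18, 24), (25, 32)),
}


def group_representative(lo: int, hi: int) -> int:
    return (lo + hi) // 2


def level_tables(level: int) -> tuple[list[int], list[int]]:
    """(value -> group index, group index -> representative)."""
    if level not in LEVEL_GROUPS:
        raise ProstarError(f"PAE lossy level must be 0..4, got {level}")
    groups = LEVEL_GROUPS[level]
    to_idx = [0] * (PAE_MAX + 1)
    reps = []
    for gi, (lo, hi) in enumerate(groups):
        for v in range(lo, hi + 1):
            to_idx[v] = gi
        reps.append(group_representative(lo, hi))
    return to_idx, reps


def _quant5(d: int) -> int:
    if d < -1:
        return 0
    if d > 1:
        return 4
    return d + 2  # -1, 0, 1 -> 1, 2, 3


def _quant3(d: int) -> int:
    return 0 if d < 0 else (1 if d == 0 else 2)


def _quant6(v: int) -> int:
    if v <= 7:
        return 0
    if v <= 26:
        return 1
    if v <= 28:
        return 2
    if v == 29:
        return 3
    if v == 30:
        return 4
    return 5


def context_id(q1: int, q2: int, q3: int, q4: int, q5: int, q6: int,
               horizontal: int) -> int:
    """Mixed-radix combination of the seven quantized components."""
    return ((((((q1 * 5 + q2) * 3 + q3) * 3 + q4) * 3 + q5) * 6 + q6) * 2
            + horizontal)


class DirectionStats:
    """Causal per-row / per-column counts of which neighbor difference was
    strictly smaller; ties increment neither."""

    def __init__(self, n: int) -> None:
        self.row_wins = [0] * n   # |v - left| smaller
        self.col_wins = [0] * n   # |v - up| smaller

    def choose(self, i: int, j: int) -> bool:
        """True => horizontal.  Borders are forced horizontal; otherwise
        vertical only when the column has strictly more wins than the row."""
        if i == 0 or j == 0:
            return True
        return not self.col_wins[j] > self.row_wins[i]

    def update(self, v: int, left: int, up: int, i: int, j: int) -> None:
        dh = abs(v - left)
        dv = abs(v - up)
        if dh < dv:
            self.row_wins[i] += 1
        elif dv < dh:
            self.col_wins[j] += 1


def predict_pae(grid: list[list[int]], reps: list[int], i: int, j: int,
                horizontal: bool, idx0: int, idx1: int) -> int:
    """Predicted group index of cell (i, j) from already-coded cells.

    Horizontal: diagonal -> group of 0; first off-diagonal -> group of 1;
    otherwise compare the left and upper neighbors (representative values):
    a contrast > 4 shifts the left neighbor's index by -1/+1, else it is
    used as-is.  Vertical is the transpose-symmetric rule.  Missing
    neighbors fall back to the one available, or to the group of 0.
    """
    if i == j:
        return idx0
    if abs(i - j) == 1:
        return idx1
    left = grid[i][j - 1] if j > 0 else None
    up = grid[i - 1][j] if i > 0 else None
    a, b = (left, up) if horizontal else (up, left)
    if a is None and b is None:
        return idx0
    if a is None:
        return b
    if b is None:
        return a
    if reps[a] - reps[b] > 4:
        return max(a - 1, 0)
    if reps[b] - reps[a] > 4:
        return min(a + 1, len(reps) - 1)
    return a


def pae_context(grid: list[list[int]], reps: list[int], i: int, j: int,
                horizontal: bool) -> int:
    """Context id of cell (i, j); missing neighbors contribute difference 0
    and value 0."""
    def val(a: int, b: int):
        if horizontal:
            r, c = i + a, j + b
        else:
            r, c = i + b, j + a
        if r < 0 or c < 0:
            return None
        return reps[grid[r][c]]

    def diff(p, q) -> int:
        if p is None or q is None:
            return 0
        return p - q

    v01 = val(0, -1)
    v10 = val(-1, 0)
    v11 = val(-1, -1)
    q1 = _quant5(diff(v10, v11))
    q2 = _quant5(diff(v01, val(0, -2)))
    q3 = _quant3(diff(val(0, -2), val(0, -3)))
    q4 = _quant3(diff(v01, v10))
    q5 = _quant3(diff(v11, val(-1, -2)))
    q6 = _quant6(v01 if v01 is not None else 0)
    return context_id(q1, q2, q3, q4, q5, q6, int(horizontal))


def _code_matrix(n: int, level: int, enc, dec,
                 values: list[list[int]] | None) -> list[list[int]]:
    """Symmetric scan shared by encoder and decoder, in group-index space."""
    to_idx, reps = level_tables(level)
    ng = len(reps)
    idx0 = to_idx[0]
    idx1 = to_idx[1]
    bank = ContextedModelBank(PAE_CONTEXT_COUNT, 2 * ng - 1)
    stats = DirectionStats(n)
    grid: list[list[int]] = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            horizontal = stats.choose(i, j)
            e = predict_pae(grid, reps, i, j, horizontal, idx0, idx1)
            ctx = pae_context(grid, reps, i, j, horizontal)
            model = bank.model(ctx)
            if enc is not None:
                v = to_idx[values[i][j]]
                enc.encode_symbol(model, (e - v) + (ng - 1))
            else:
                v = e - (dec.decode_symbol(model) - (ng - 1))
                if not 0 <= v < ng:
                    raise ProstarError("corrupt PAE stream")
            grid[i][j] = v
            if i > 0 and j > 0:
                stats.update(reps[v], reps[grid[i][j - 1]],
                             reps[grid[i - 1][j]], i, j)
    return grid


def encode_pae(m: PAEMatrix, level: int = 0) -> bytes:
    w = ByteWriter()
    w.uvarint(m.n)
    w.u8(level)
    enc = RangeEncoder()
    _code_matrix(m.n, level, enc, None, m.values)
    w.chunk(enc.finish())
    return w.getvalue()


def decode_pae(payload: bytes) -> PAEMatrix:
    """Reconstruct the matrix: exact for level 0, group representatives for
    levels 1-4."""
    r = ByteReader(payload)
    n = r.uvarint()
    level = r.u8()
    _, reps = level_tables(level)
    dec = RangeDecoder(r.chunk())
    grid = _code_matrix(n, level, None, dec, None)
    return PAEMatrix(n=n, values=[[reps[v] for v in row] for row in grid])
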