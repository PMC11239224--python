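"""PAE prediction, context model, and lossless/lossy coding."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from prostar.errors import ProstarError
from prostar.fixtures import gen_pae
from prostar.formats_io import PAEMatrix
from prostar.pae_codec import (DirectionStats, LEVEL_GROUPS,
                               PAE_CONTEXT_COUNT, context_id, decode_pae,
                               encode_pae, level_tables, pae_context,
                               predict_pae, _quant3, _quant5, _quant6)

_IDENTITY = list(range(33))


def test_context_space_cardinality():
    """5*5*3*3*3*6*2 quantizer outputs combine into exactly 8100 ids."""
    card5 = len({_quant5(d) for d in range(-40, 41)})
    card3 = len({_quant3(d) for d in range(-40, 41)})
    card6 = len({_quant6(v) for v in range(33)})
    assert (card5, card3, card6) == (5, 3, 6)
    assert card5 * card5 * card3 * card3 * card3 * card6 * 2 == 8100
    assert PAE_CONTEXT_COUNT == 8100
    assert context_id(4, 4, 2, 2, 2, 5, 1) == 8099


def test_context_id_of_flat_neighborhood():
    """All-zero differences, left value 15, horizontal: the mixed-radix
    formula gives ((((2*5+2)*3+1)*3+1)*3+1)*6+1)*2+1 = 4047."""
    grid = [[15] * 6 for _ in range(6)]
    assert pae_context(grid, _IDENTITY, 4, 4, True) == 4047
    assert context_id(2, 2, 1, 1, 1, 1, 1) == 4047


def test_prediction_rules():
    grid = [[0] * 8 for _ in range(8)]
    # diagonal and first off-diagonal
    assert predict_pae(grid, _IDENTITY, 4, 4, True, 0, 1) == 0
    assert predict_pae(grid, _IDENTITY, 4, 5, True, 0, 1) == 1
    assert predict_pae(grid, _IDENTITY, 5, 4, True, 0, 1) == 1
    # contrast rules: v(i,j-1)=12, v(i-1,j)=3 -> 12-3 > 4 -> predict 11
    grid[6][3] = 12
    grid[5][4] = 3
    assert predict_pae(grid, _IDENTITY, 6, 4, True, 0, 1) == 11
    # opposite contrast -> v(i,j-1)+1
    grid[6][3] = 3
    grid[5][4] = 12
    assert predict_pae(grid, _IDENTITY, 6, 4, True, 0, 1) == 4
    # small contrast -> copy left
    grid[6][3] = 9
    grid[5][4] = 7
    assert predict_pae(grid, _IDENTITY, 6, 4, True, 0, 1) == 9
    # vertical is transpose-symmetric: copies the upper neighbor
    assert predict_pae(grid, _IDENTITY, 6, 4, False, 0, 1) == 7


def test_direction_choice():
    stats = DirectionStats(8)
    assert stats.choose(3, 3) is True          # fresh stats tie -> horizontal
    assert stats.choose(0, 5) is True          # borders forced horizontal
    assert stats.choose(5, 0) is True
    stats.col_wins[3] = 5
    stats.row_wins[3] = 4
    assert stats.choose(3, 3) is False         # column strictly ahead
    stats.row_wins[3] = 5
    assert stats.choose(3, 3) is True          # tie again -> horizontal


def test_column_constant_matrix_goes_vertical():
    """v(i,j) = f(j): column differences are all zero and must win."""
    n = 12
    m = [[(7 * j) % 33 for j in range(n)] for _ in range(n)]
    stats = DirectionStats(n)
    for i in range(1, n):
        for j in range(1, n):
            stats.update(m[i][j], m[i][j - 1], m[i - 1][j], i, j)
    assert stats.choose(6, 6) is False


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(1, 20), st.integers(0, 2**31))
def test_lossless_roundtrip_random(n, seed):
    rng = random.Random(seed)
    m = PAEMatrix(n=n, values=[[rng.randint(0, 32) for _ in range(n)]
                               for _ in range(n)])
    assert decode_pae(encode_pae(m, 0)).values == m.values


def test_lossless_roundtrip_structured():
    for seed in range(4):
        m = gen_pae(35, smoothness=1.0, seed=seed)
        assert decode_pae(encode_pae(m, 0)).values == m.values


def test_level_groups_partition_range():
    for level, groups in LEVEL_GROUPS.items():
        covered = [v for lo, hi in groups for v in range(lo, hi + 1)]
        assert covered == list(range(33)), level
    assert len(LEVEL_GROUPS[0]) == 33
    assert [len(LEVEL_GROUPS[l]) for l in (1, 2, 3, 4)] == [24, 16, 12, 10]


@pytest.mark.parametrize("level", [1, 2, 3, 4])
def test_lossy_decodes_to_group_representative(level):
    """Every input value decodes to floor((lo+hi)/2) of its group —
    exhaustive over all 33 values."""
    to_idx, reps = level_tables(level)
    for v in range(33):
        m = PAEMatrix(n=2, values=[[v, v], [v, v]])
        got = decode_pae(encode_pae(m, level))
        assert got.values == [[reps[to_idx[v]]] * 2] * 2


def test_lossy_reference_values():
    to_idx, reps = level_tables(4)
    assert reps[to_idx[27]] == 28     # group [25,32] -> floor(57/2)
    to_idx, reps = level_tables(1)
    assert reps[to_idx[20]] == 20     # group [20,21] -> floor(41/2)


@pytest.mark.parametrize("level", [1, 2, 3, 4])
def test_lossy_roundtrip_elementwise(level):
    m = gen_pae(30, smoothness=1.0, seed=9)
    to_idx, reps = level_tables(level)
    got = decode_pae(encode_pae(m, level))
    assert got.values == [[reps[to_idx[v]] for v in row] for row in m.values]


def test_invalid_level_rejected():
    m = PAEMatrix(n=1, values=[[0]])
    with pytest.raises(ProstarError):
        encode_pae(m, 5)


def test_truncated_stream_rejected():
    m = gen_pae(20, seed=1)
    payload = encode_pae(m, 0)
    from prostar.errors import TruncatedStream
    with pytest.raises((TruncatedStream, ProstarError)):
        decode_pae(payload[:len(payload) // 2])


def test_single_cell_matrix():
    m = PAEMatrix(n=1, values=[[0]])
    assert decode_pae(encode_pae(m, 0)).values == [[0]]


def test_constant_matrix_compresses_to_near_nothing():
    m = PAEMatrix(n=100, values=[[7] * 100 for _ in range(100)])
    payload = encode_pae(m, 0)
    assert len(payload) < 500          # 10^4 cells, residuals all zero


def test_context_ids_stay_in_range():
    """The bank rejects out-of-range ids, so a successful encode of a
    worst-case matrix certifies every emitted context id < 8100."""
    rng = random.Random(2)
    m = PAEMatrix(n=25, values=[[rng.choice([0, 1, 31, 32, 15])
                                 for _ in range(25)] for _ in range(25)])
    assert decode_pae(encode_pae(m, 0)).values == m.values
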