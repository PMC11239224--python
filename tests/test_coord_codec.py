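"""Atom-table coding: prediction, lossless/lossy roundtrips, B-factors."""

import numpy as np
import pytest

from prostar.coord_codec import (LossyParams, coordinate_stream_size,
                                 decode_atom_table, decode_bfactors,
                                 delta_stream_size, encode_atom_table,
                                 encode_bfactors, predict_fast, predict_full)
from prostar.fixtures import FixtureSpec, gen_structure
from prostar.formats_io import serialize_atom_table
from prostar.geometry import dist, observation_of
from prostar.residues import is_backbone
from prostar.training import CentroidSet, ModelEntry, ReferenceSpec


def _entry(centroids):
    return ModelEntry(
        ref_spec=ReferenceSpec("HIS", "CE1",
                               (("ND1", 0), ("CD2", 0), ("CG", 0))),
        centroid_set=CentroidSet("HIS", "CE1",
                                 np.asarray(centroids, dtype=float)))


_BASE = ((0, 0, 0), (1500, 0, 0), (400, 1400, 0))


def _centroid_for(target):
    o = observation_of(*_BASE, target)
    return list(o.as_tuple())


def test_exact_centroid_gives_zero_residual():
    target = (700, 600, 900)
    entry = _entry([_centroid_for(target)])
    out = predict_full(entry, _BASE, target)
    assert out.residual == (0, 0, 0)
    assert out.est_cost == 0.0
    assert not out.fallback


def test_cheaper_residual_beats_smaller_euclidean_error():
    """Residual (3,3,3) costs 6 bits, (7,0,0) costs 3: the geometrically
    farther prediction must win."""
    target = (700, 600, 900)
    near = (target[0] - 3, target[1] - 3, target[2] - 3)   # ||.|| = 5.2
    far = (target[0] - 7, target[1], target[2])            # ||.|| = 7
    entry = _entry([_centroid_for(near), _centroid_for(far)])
    out = predict_full(entry, _BASE, target)
    assert out.centroid_id == 1
    assert out.est_cost == pytest.approx(3.0)


def test_collinear_references_fall_back():
    entry = _entry([[1.0, 2.0, 1.0, 1.2, 1.2, 1.2]])
    base = ((0, 0, 0), (1000, 0, 0), (2000, 0, 0))
    out = predict_full(entry, base, (100, 100, 100))
    assert out.fallback
    # mirror 0 predicts reference 1, mirror 1 predicts reference 2
    res0 = (100, 100, 100)
    res1 = (-900, 100, 100)
    assert out.residual == (res0 if out.mirror_id == 0 else res1)


def test_fast_equals_full_for_single_centroid():
    target = (705, 612, 893)
    entry = _entry([_centroid_for((700, 600, 900))])
    assert predict_fast(entry, _BASE, target) == predict_full(entry, _BASE,
                                                              target)


def test_fast_never_beats_full():
    rng = np.random.default_rng(3)
    cents = [_centroid_for(tuple(int(v) for v in rng.integers(300, 1500, 3)))
             for _ in range(4)]
    entry = _entry(cents)
    for _ in range(50):
        target = tuple(int(v) for v in rng.integers(200, 1600, 3))
        assert (predict_fast(entry, _BASE, target).est_cost
                >= predict_full(entry, _BASE, target).est_cost - 1e-12)


# --- table roundtrips ---------------------------------------------------------

SPEC = FixtureSpec(n_structures=12, residues_per_chain=20, seed=21)


@pytest.mark.parametrize("fast", [False, True])
def test_lossless_roundtrip(model, fast):
    for i in range(6):
        table = gen_structure(SPEC, i).atom_table
        stream = encode_atom_table(table, model, fast=fast)
        back = decode_atom_table(stream, model)
        assert serialize_atom_table(back) == serialize_atom_table(table)


def test_empty_table_roundtrip(model):
    from prostar.formats_io import AtomTableData
    empty = AtomTableData(dialect="pdb", serial_start=1, chains=[])
    back = decode_atom_table(encode_atom_table(empty, model), model)
    assert back.chains == [] and back.dialect == "pdb"


@pytest.mark.parametrize("m_bb,m_sc", [(10, 10), (80, 140), (100, 100),
                                       (200, 300)])
def test_lossy_error_bound(model, m_bb, m_sc):
    """Maximum per-atom Euclidean error never exceeds the class bound."""
    lossy = LossyParams(m_backbone=m_bb, m_sidechain=m_sc)
    for i in range(3):
        table = gen_structure(SPEC, i).atom_table
        back = decode_atom_table(encode_atom_table(table, model, lossy), model)
        for c0, c1 in zip(table.chains, back.chains):
            for a0, a1 in zip(c0.atoms, c1.atoms):
                err = dist(a0.coord, a1.coord) * 1000.0
                bound = m_bb if is_backbone(a0.atom_name) else m_sc
                assert err <= bound + 1e-9


def test_multichain_roundtrip(model):
    spec = FixtureSpec(n_structures=1, residues_per_chain=8, chains=3, seed=2)
    table = gen_structure(spec, 0).atom_table
    back = decode_atom_table(encode_atom_table(table, model), model)
    assert serialize_atom_table(back) == serialize_atom_table(table)


def test_predictor_not_worse_than_delta_coding(model):
    tables = [gen_structure(SPEC, i).atom_table for i in range(6)]
    assert coordinate_stream_size(tables, model) <= delta_stream_size(tables)


# --- B-factors ----------------------------------------------------------------

def test_bfactors_constant_per_residue_compact(model):
    table = gen_structure(SPEC, 0).atom_table   # pLDDT-style constant
    n_atoms = sum(len(c.atoms) for c in table.chains)
    n_res = sum(len(c.residue_names) for c in table.chains)
    stream = encode_bfactors(table)
    assert len(stream) < n_res * 3 + 32       # ~ one value per residue
    got = decode_bfactors(stream, table)
    assert got == [[a.b_factor for a in c.atoms] for c in table.chains]
    assert n_atoms > n_res                    # compaction was real


def test_bfactors_varying_exact(model):
    table = gen_structure(SPEC, 1).atom_table
    rng = np.random.default_rng(0)
    for c in table.chains:
        for a in c.atoms:
            a.b_factor = int(rng.integers(1000, 9900))
    got = decode_bfactors(encode_bfactors(table), table)
    assert got == [[a.b_factor for a in c.atoms] for c in table.chains]


def test_bf_average_is_residue_mean(model):
    table = gen_structure(FixtureSpec(n_structures=1, residues_per_chain=1,
                                      residue_alphabet=("GLY",), seed=0),
                          0).atom_table
    atoms = table.chains[0].atoms[:4]
    for a, v in zip(atoms, (1000, 2000, 3000, 2000)):
        a.b_factor = v
    stream = encode_bfactors(table, LossyParams(bf_average=True))
    got = decode_bfactors(stream, table)
    assert set(got[0]) == {2000}


def test_decoder_prediction_matches_encoder(model):
    """Coordinates decode to the exact encoder values — the shared
    reconstructed-reference discipline at work (lossy case included)."""
    table = gen_structure(SPEC, 3).atom_table
    lossy = LossyParams(m_backbone=80, m_sidechain=140)
    from prostar.coord_codec import round_table
    rounded = round_table(table, lossy)
    back = decode_atom_table(encode_atom_table(table, model, lossy), model)
    for c0, c1 in zip(rounded.chains, back.chains):
        for a0, a1 in zip(c0.atoms, c1.atoms):
            assert a0.coord == a1.coord
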