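"""Reference selection, observation collection, clustering and k selection."""

import math

import numpy as np
import pytest

from prostar.errors import ProstarError
from prostar.fixtures import FixtureSpec, training_tables
from prostar.geometry import rounding_step
from prostar.training import (TrainingConfig, choose_references,
                              collect_observations, estimate_cost,
                              fit_centroids, load_model, prune_model,
                              save_model, select_k)


@pytest.fixture(scope="module")
def refs(small_tables):
    return choose_references(small_tables)


@pytest.fixture(scope="module")
def observations(small_tables, refs):
    return collect_observations(small_tables, refs)


def test_ca_references_include_bonded_nitrogen(refs):
    """The N-CA bond (~1.46 Å) is the shortest mean distance, so N of the
    same residue must be among CA's references."""
    for res in ("ALA", "HIS", "GLU"):
        assert ("N", 0) in refs[(res, "CA")].refs


def test_cb_references_drawn_from_candidates(refs):
    allowed = {("N", 0), ("CA", 0), ("C", 0), ("O", 0),
               ("N", -1), ("CA", -1), ("C", -1), ("O", -1)}
    assert set(refs[("HIS", "CB")].refs) <= allowed
    assert ("CA", 0) in refs[("HIS", "CB")].refs  # the 1.53 Å bond


def test_references_precede_atom_in_encode_order(refs):
    from prostar.residues import RESIDUE_ATOMS
    for (res, atom), spec in refs.items():
        order = RESIDUE_ATOMS[res]
        slot = order.index(atom) if atom in order else len(order)
        for name, off in spec.refs:
            assert off in (0, -1)
            if off == 0:
                assert order.index(name) < slot


def test_missing_pair_reported():
    # single-residue chains never expose N/CA/C as predictable slots
    tables = training_tables(FixtureSpec(n_structures=2, residues_per_chain=1,
                                         residue_alphabet=("GLY",), seed=0))
    with pytest.raises(ProstarError, match="GLY"):
        choose_references(tables)


def test_collect_truncates_to_n_max(small_tables, refs):
    capped = collect_observations(small_tables, refs, TrainingConfig(n_max=5))
    full = collect_observations(small_tables, refs)
    for key, arr in capped.items():
        assert len(arr) == min(5, len(full[key]))
        assert np.array_equal(arr, full[key][:len(arr)])  # first-N policy


def test_fit_centroids_k1_is_mean(observations):
    obs = observations[("HIS", "CE1")]
    c = fit_centroids(obs, 1, seed=0)
    assert np.allclose(c[0], obs.mean(axis=0))


def test_fit_centroids_recovers_two_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.01, size=(200, 6)) + np.arange(6)
    b = rng.normal(0.0, 0.01, size=(200, 6)) + np.arange(6) + 3.0
    obs = np.vstack([a, b])
    cents = fit_centroids(obs, 2, seed=1)
    cents = cents[np.argsort(cents[:, 0])]
    assert np.allclose(cents[0], a.mean(axis=0), atol=0.01)
    assert np.allclose(cents[1], b.mean(axis=0), atol=0.01)


def test_fit_centroids_deterministic(observations):
    obs = observations[("GLU", "CD")]
    c1 = fit_centroids(obs, 3, seed=11)
    c2 = fit_centroids(obs, 3, seed=11)
    assert np.array_equal(c1, c2)


def test_fit_centroids_requires_enough_observations():
    with pytest.raises(ProstarError):
        fit_centroids(np.ones((2, 6)), 3, seed=0)


def test_estimate_cost_zero_residual_is_id_cost_only(observations):
    """An observation identical to the single centroid costs exactly
    log2(1+1) = 1 bit (the centroid id)."""
    obs = observations[("ALA", "CB")][:1]
    assert estimate_cost(obs, obs.copy()) == pytest.approx(1.0)


def test_estimate_cost_id_term_scales_with_k(observations):
    """Duplicating the centroid set leaves residuals unchanged and raises
    the per-observation cost by log2(1+2k) - log2(1+k)."""
    obs = observations[("ALA", "CB")][:20]
    c1 = obs.mean(axis=0, keepdims=True)
    c2 = np.vstack([c1, c1 + 100.0])  # far twin never wins
    d = (estimate_cost(obs, c2) - estimate_cost(obs, c1)) / len(obs)
    assert d == pytest.approx(math.log2(3) - math.log2(2), abs=1e-9)


@pytest.mark.parametrize("conformers", [1, 2, 3])
def test_select_k_recovers_conformer_count(conformers):
    """Point-mass observations (noise-free translation-symmetric chains):
    the cost criterion selects exactly one centroid per conformer, and the
    centroids coincide with the conformer tuples."""
    spec = FixtureSpec(n_structures=8, residues_per_chain=20,
                       residue_alphabet=("HIS",), coordinate_noise_sd=0.0,
                       conformer_count=conformers, seed=11, helical=False)
    tables = training_tables(spec)
    refs = choose_references(tables)
    obs = collect_observations(tables, refs)[("HIS", "CE1")]
    cents = select_k(obs, TrainingConfig(), seed=0)
    assert len(cents) == conformers
    uniq = np.unique(np.round(obs, 6), axis=0)
    assert len(uniq) == conformers
    got = cents[np.argsort(cents[:, 3])]
    want = uniq[np.argsort(uniq[:, 3])]
    assert np.allclose(got, want, atol=1e-3)


def test_select_k_is_argmin_of_exhaustive_scan(observations):
    cfg = TrainingConfig(k_max=6)
    obs = observations[("LEU", "CD1")]
    chosen = select_k(obs, cfg, seed=3)
    chosen_cost = estimate_cost(obs, chosen)
    for k in range(1, 7):
        cost = estimate_cost(obs, fit_centroids(obs, k, 3, cfg))
        assert chosen_cost <= cost + 1e-9


def test_select_k_clamps_to_observation_count():
    obs = np.array([[1.5, 1.5, 2.1, 1.0, 1.0, 1.0],
                    [2.5, 2.5, 3.1, 2.0, 2.0, 2.0]])
    cents = select_k(obs, TrainingConfig(), seed=0)
    assert len(cents) <= 2


def test_prune_model(small_model):
    lossless = rounding_step(0)
    assert prune_model(small_model, lossless, lossless) is small_model
    coarse = rounding_step(2000)
    pruned = prune_model(small_model, coarse, coarse)
    for key, e in pruned.entries.items():
        assert e.centroid_set.k <= small_model.entries[key].centroid_set.k
    again = prune_model(pruned, coarse, coarse)
    for key in pruned.entries:
        assert np.array_equal(again.entries[key].centroid_set.centroids,
                              pruned.entries[key].centroid_set.centroids)


def test_model_save_load_fingerprint(small_model, tmp_path):
    p = tmp_path / "m.json"
    save_model(small_model, p)
    back = load_model(p)
    assert back.canonical_json() == small_model.canonical_json()
    assert back.fingerprint == small_model.fingerprint
    save_model(back, p)  # re-save stability
    assert load_model(p).fingerprint == small_model.fingerprint


def test_model_fingerprint_tracks_content(small_model):
    import copy
    other = copy.deepcopy(small_model)
    key = next(iter(other.entries))
    other.entries[key].centroid_set.centroids[0][0] += 1.0
    other.invalidate()
    assert other.fingerprint != small_model.fingerprint


def test_train_model_covers_all_slots(small_tables, small_model):
    from prostar.residues import RESIDUE_ATOMS
    for res in ("ALA", "HIS", "GLU", "LEU", "GLY"):
        for atom in RESIDUE_ATOMS[res]:
            assert (res, atom) in small_model.entries
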