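"""Training of the per-(residue type, atom type) coordinate predictor.

For every atom slot the trainer

1. picks the three *reference* atoms that are on average the closest among
   the already-coded candidates (earlier atoms of the same residue and the
   backbone of the previous residue),
2. collects up to ``n_max`` distance 6-tuples ``(r12, r13, r23, f1, f2, f3)``
   describing the tetrahedron formed by the references and the atom,
3. clusters them with k-means for k = 1..20 and keeps the k that minimizes
   the estimated encoding cost: the best achievable residual cost
   ``log2(1+|dx|) + log2(1+|dy|) + log2(1+|dz|)`` plus ``log2(1+k)`` bits
   for the centroid id — the same trade-off the encoder faces.

The resulting :class:`PredictionModel` is serialized as versioned JSON; a
fingerprint of the canonical serialization is embedded in every archive so
that archives and models can never be mixed (see docs/model_format.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .errors import ProstarError
from .formats_io import AtomTableData
from .framing import checksum64
from .geometry import RoundingSpec, round_coord
from .residues import (BACKBONE_ATOMS, RESIDUE_ATOMS, RESIDUE_INDEX,
                       TERMINAL_OXYGEN, is_backbone)

MODEL_MAGIC = "PROSTAR-MODEL"
MODEL_VERSION = 1

Key = tuple[str, str]  # (residue type, atom type)
Ref = tuple[str, int]  # (atom name, residue offset: 0 current, -1 previous)


@dataclass(frozen=True)
class ReferenceSpec:
    residue_type: str
    atom_type: str
    refs: tuple[Ref, Ref, Ref]


@dataclass
class CentroidSet:
    residue_type: str
    atom_type: str
    centroids: np.ndarray  # (k, 6) float64, Å

    @property
    def k(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class TrainingConfig:
    n_max: int = 1_000_000
    k_min: int = 1
    k_max: int = 20
    kmeans_restarts: int = 4
    kmeans_iters: int = 50
    seed: int = 7


@dataclass
class ModelEntry:
    ref_spec: ReferenceSpec
    centroid_set: CentroidSet


@dataclass
class PredictionModel:
    entries: dict[Key, ModelEntry]
    version: int = MODEL_VERSION
    _fingerprint: int | None = field(default=None, repr=False)

    def canonical_json(self) -> str:
        obj = {
            "magic": MODEL_MAGIC,
            "version": self.version,
            "entries": {
                f"{res}:{atom}": {
                    "refs": [[n, o] for n, o in e.ref_spec.refs],
                    "centroids": [[round(float(v), 6) for v in row]
                                  for row in e.centroid_set.centroids],
                }
                for (res, atom), e in sorted(self.entries.items())
            },
        }
        return json.dumps(obj, sort_keys=True, separators=(",", ":"))

    @property
    def fingerprint(self) -> int:
        if self._fingerprint is None:
            self._fingerprint = checksum64(self.canonical_json().encode())
        return self._fingerprint

    def invalidate(self) -> None:
        self._fingerprint = None


# --- candidate enumeration ----------------------------------------------------

def candidate_refs(residue_type: str, atom_type: str) -> list[Ref]:
    """Already-coded atoms eligible as references for *atom_type*: earlier
    atoms of the current residue plus the previous residue's backbone."""
    order = RESIDUE_ATOMS[residue_type]
    if atom_type == TERMINAL_OXYGEN:
        slot = len(order)
    else:
        slot = order.index(atom_type)
    current = [(name, 0) for name in order[:slot]]
    previous = [(name, -1) for name in BACKBONE_ATOMS]
    return current + previous


def _iter_predictable(table: AtomTableData):
    """Yield (key, ref_positions_or_None, target AtomRecord) for every atom
    after a chain's first three.  ``None`` ref positions mean a reference
    falls outside the chain (first residue, previous-residue reference)."""
    for chain in table.chains:
        # positions by (residue index, atom name)
        by_res: list[dict[str, tuple[int, int, int]]] = []
        flat: list[tuple[int, str, object]] = []  # (res idx, name, record)
        ri = -1
        last_seq = None
        for rec in chain.atoms:
            if rec.residue_seq != last_seq:
                ri += 1
                last_seq = rec.residue_seq
                by_res.append({})
            by_res[ri][rec.atom_name] = rec.coord
            flat.append((ri, rec.atom_name, rec))
        for idx, (ri, name, rec) in enumerate(flat):
            if idx < 3:
                continue
            yield (rec.residue_name, name), ri, by_res, rec


def resolve_refs(refs: tuple[Ref, Ref, Ref], ri: int,
                 by_res: list[dict[str, tuple[int, int, int]]],
                 ) -> tuple[tuple[int, int, int], ...] | None:
    out = []
    for name, off in refs:
        r = ri + off
        if r < 0:
            return None
        pos = by_res[r].get(name)
        if pos is None:
            return None
        out.append(pos)
    return tuple(out)


# --- step 1: reference selection ----------------------------------------------

def choose_references(corpus: list[AtomTableData],
                      ) -> dict[Key, ReferenceSpec]:
    """Pick, for every (residue type, atom type) slot seen in *corpus*, the
    three candidate atoms with the smallest mean distance (ascending).

    Raises :class:`ProstarError` listing any slot of an observed residue
    type that never occurs in the corpus (OXT, being optional chain
    termination, is exempt).
    """
    sums: dict[Key, dict[Ref, float]] = {}
    counts: dict[Key, dict[Ref, int]] = {}
    seen_residues: set[str] = set()

    for table in corpus:
        for key, ri, by_res, rec in _iter_predictable(table):
            res, atom = key
            seen_residues.add(res)
            if key not in sums:
                cands = candidate_refs(res, atom)
                sums[key] = {c: 0.0 for c in cands}
                counts[key] = {c: 0 for c in cands}
            s = sums[key]
            c = counts[key]
            x, y, z = rec.coord
            for cand in s:
                r = ri + cand[1]
                if r < 0:
                    continue
                pos = by_res[r].get(cand[0])
                if pos is None:
                    continue
                s[cand] += math.sqrt((x - pos[0]) ** 2 + (y - pos[1]) ** 2
                                     + (z - pos[2]) ** 2)
                c[cand] += 1

    missing: list[Key] = []
    for res in sorted(seen_residues):
        for atom in RESIDUE_ATOMS[res]:
            if (res, atom) not in sums and RESIDUE_ATOMS[res].index(atom) >= 3:
                # slots 0..2 of the first residue are delta-coded, but the
                # same slots of later residues are predictable; if the
                # corpus has >= 2 residues per chain every slot appears
                missing.append((res, atom))
    # slots 0..2 (N, CA, C) appear as predictable atoms from residue 1 on
    for res in sorted(seen_residues):
        for atom in RESIDUE_ATOMS[res][:3]:
            if (res, atom) not in sums:
                missing.append((res, atom))
    if missing:
        raise ProstarError("corpus lacks instances of: "
                           + ", ".join(f"{r}/{a}" for r, a in sorted(missing)))

    out: dict[Key, ReferenceSpec] = {}
    for key, s in sums.items():
        means = []
        for cand, total in s.items():
            n = counts[key][cand]
            if n > 0:
                means.append((total / n, cand))
        if len(means) < 3:
            raise ProstarError(f"fewer than 3 usable reference candidates "
                               f"for {key[0]}/{key[1]}")
        means.sort(key=lambda t: (t[0], t[1][1], t[1][0]))
        refs = tuple(cand for _, cand in means[:3])
        out[key] = ReferenceSpec(residue_type=key[0], atom_type=key[1],
                                 refs=refs)  # type: ignore[arg-type]
    return out


# --- step 2: observation collection ---------------------------------------------

def collect_observations(corpus: list[AtomTableData],
                         refs: dict[Key, ReferenceSpec],
                         config: TrainingConfig = TrainingConfig(),
                         ) -> dict[Key, np.ndarray]:
    """First ``n_max`` distance 6-tuples per key, in corpus order;
    degenerate tuples (non-positive distance or triangle violation) are
    skipped.  Returns float64 arrays of shape (n, 6) in Å."""
    obs: dict[Key, list[tuple[float, ...]]] = {k: [] for k in refs}
    for table in corpus:
        for key, ri, by_res, rec in _iter_predictable(table):
            spec = refs.get(key)
            if spec is None:
                continue
            lst = obs[key]
            if len(lst) >= config.n_max:
                continue
            pos = resolve_refs(spec.refs, ri, by_res)
            if pos is None:
                continue
            from .geometry import observation_of
            o = observation_of(pos[0], pos[1], pos[2], rec.coord)
            if o.is_degenerate():
                continue
            lst.append(o.as_tuple())
    return {k: np.asarray(v, dtype=np.float64).reshape(-1, 6)
            for k, v in obs.items()}


# --- steps 3-4: clustering and cost-based k selection ----------------------------

def fit_centroids(obs: np.ndarray, k: int, seed: int,
                  config: TrainingConfig = TrainingConfig()) -> np.ndarray:
    """k-means in the 6-D tuple space (k-means++ init, deterministic given
    *seed*); duplicate centroids are collapsed."""
    if len(obs) < k:
        raise ProstarError(f"{len(obs)} observations < k={k}")
    if k == 1:
        return obs.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, n_init=config.kmeans_restarts,
                max_iter=config.kmeans_iters, random_state=seed & 0x7FFFFFFF,
                init="k-means++")
    km.fit(obs)
    cents = km.cluster_centers_
    _, idx = np.unique(np.round(cents, 9), axis=0, return_index=True)
    return cents[np.sort(idx)]


def _embed_fourth(r12, x3, y3, f1, f2, f3):
    """Apex coordinates over a canonically embedded base (vectorized).

    Returns (x, y, z2): z2 may be negative where the spheres cannot meet.
    """
    x = (f1 * f1 - f2 * f2 + r12 * r12) / (2.0 * r12)
    y = (f1 * f1 - f3 * f3 + x3 * x3 + y3 * y3 - 2.0 * x3 * x) / (2.0 * y3)
    z2 = f1 * f1 - x * x - y * y
    return x, y, z2


def per_observation_costs(obs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Estimated bits per observation for a given centroid set.

    Mimics compression: each observation's base triangle is embedded
    canonically (p1 at the origin, p2 on +x, p3 in the xy-plane) and the
    true fourth point placed from its own f-distances (+z mirror).  Every
    centroid predicts the fourth point by trilateration from the same base
    using the centroid's f-distances; both mirrors are tried; a centroid
    whose spheres cannot meet falls back to predicting the first (mirror 0)
    or second (mirror 1) reference position, as the encoder does.  The cost
    of an observation is the cheapest residual under the printed
    log2(1+|d|)-per-axis formula plus log2(1+k) bits for the centroid id.
    """
    n = len(obs)
    k = len(centroids)
    r12, r13, r23 = obs[:, 0], obs[:, 1], obs[:, 2]
    x3 = (r12 ** 2 + r13 ** 2 - r23 ** 2) / (2.0 * r12)
    y3 = np.sqrt(np.maximum(r13 ** 2 - x3 ** 2, 1e-30))

    ax, ay, az2 = _embed_fourth(r12, x3, y3, obs[:, 3], obs[:, 4], obs[:, 5])
    az = np.sqrt(np.maximum(az2, 0.0))
    actual = np.stack([ax, ay, az], axis=1)  # (n, 3)

    f1 = centroids[:, 3][None, :]  # (1, k)
    f2 = centroids[:, 4][None, :]
    f3 = centroids[:, 5][None, :]
    px, py, pz2 = _embed_fourth(r12[:, None], x3[:, None], y3[:, None],
                                f1, f2, f3)
    fail = pz2 < -1e-9
    pz = np.sqrt(np.maximum(pz2, 0.0))

    preds = np.empty((n, k, 2, 3))
    preds[:, :, 0, 0] = px
    preds[:, :, 0, 1] = py
    preds[:, :, 0, 2] = pz
    preds[:, :, 1, 0] = px
    preds[:, :, 1, 1] = py
    preds[:, :, 1, 2] = -pz
    # fallback: mirror 0 -> reference 1 (origin), mirror 1 -> reference 2
    if fail.any():
        fi, fk = np.nonzero(fail)
        preds[fi, fk, 0, :] = 0.0
        preds[fi, fk, 1, :] = 0.0
        preds[fi, fk, 1, 0] = r12[fi]

    resid = np.rint((preds - actual[:, None, None, :]) * 1000.0)
    bits = np.log2(1.0 + np.abs(resid)).sum(axis=3)  # (n, k, 2)
    return bits.min(axis=(1, 2)) + math.log2(1 + k)


def estimate_cost(obs: np.ndarray, centroids: np.ndarray) -> float:
    """Total estimated bits to encode *obs* with *centroids*."""
    if len(obs) == 0:
        raise ProstarError("estimate_cost needs at least one observation")
    return float(per_observation_costs(obs, centroids).sum())


def select_k(obs: np.ndarray, config: TrainingConfig = TrainingConfig(),
             seed: int = 0) -> np.ndarray:
    """Exhaustive scan over k: the centroid set minimizing
    :func:`estimate_cost` (ties favour smaller k)."""
    if len(obs) == 0:
        raise ProstarError("select_k needs at least one observation")
    best = None
    best_cost = math.inf
    for k in range(config.k_min, min(config.k_max, len(obs)) + 1):
        cents = fit_centroids(obs, k, seed, config)
        cost = estimate_cost(obs, cents)
        if cost < best_cost:
            best, best_cost = cents, cost
    return best


# --- full training ----------------------------------------------------------------

def _key_seed(config_seed: int, key: Key) -> int:
    order = RESIDUE_ATOMS[key[0]]
    slot = len(order) if key[1] == TERMINAL_OXYGEN else order.index(key[1])
    return (config_seed * 1009 + RESIDUE_INDEX[key[0]] * 64 + slot) & 0x7FFFFFFF


def train_model(corpus: list[AtomTableData],
                config: TrainingConfig = TrainingConfig()) -> PredictionModel:
    refs = choose_references(corpus)
    all_obs = collect_observations(corpus, refs, config)
    entries: dict[Key, ModelEntry] = {}
    for key, spec in refs.items():
        obs = all_obs[key]
        if len(obs) == 0:
            continue
        cents = select_k(obs, config, seed=_key_seed(config.seed, key))
        cents = np.round(cents, 6)  # stable under save/load roundtrip
        entries[key] = ModelEntry(
            ref_spec=spec,
            centroid_set=CentroidSet(residue_type=key[0], atom_type=key[1],
                                     centroids=cents))
    return PredictionModel(entries=entries)


# --- lossy pruning ----------------------------------------------------------------

def centroid_placement(row: np.ndarray) -> tuple[int, int, int]:
    """Canonical fourth-point placement of a centroid (integer mÅ): its own
    base embedded canonically, apex on the +z mirror."""
    r12, r13, r23, f1, f2, f3 = (float(v) for v in row)
    x3 = (r12 * r12 + r13 * r13 - r23 * r23) / (2.0 * r12)
    y3 = math.sqrt(max(r13 * r13 - x3 * x3, 1e-30))
    x = (f1 * f1 - f2 * f2 + r12 * r12) / (2.0 * r12)
    y = (f1 * f1 - f3 * f3 + x3 * x3 + y3 * y3 - 2.0 * x3 * x) / (2.0 * y3)
    z = math.sqrt(max(f1 * f1 - x * x - y * y, 0.0))
    return (round(x * 1000), round(y * 1000), round(z * 1000))


def prune_model(model: PredictionModel, backbone: RoundingSpec,
                sidechain: RoundingSpec) -> PredictionModel:
    """Drop centroids whose canonical placements land on the same lossy grid
    point (the first one is kept), shrinking the centroid-id alphabet.
    With unit grids the model is returned unchanged (same object)."""
    if backbone.r == 1 and sidechain.r == 1:
        return model
    entries: dict[Key, ModelEntry] = {}
    for key, e in model.entries.items():
        spec = backbone if is_backbone(key[1]) else sidechain
        if spec.r == 1:
            entries[key] = e
            continue
        seen: set[tuple[int, int, int]] = set()
        keep: list[int] = []
        for i, row in enumerate(e.centroid_set.centroids):
            cell = round_coord(centroid_placement(row), spec)
            if cell not in seen:
                seen.add(cell)
                keep.append(i)
        entries[key] = ModelEntry(
            ref_spec=e.ref_spec,
            centroid_set=CentroidSet(residue_type=key[0], atom_type=key[1],
                                     centroids=e.centroid_set.centroids[keep]))
    return PredictionModel(entries=entries, version=model.version)


# --- persistence -------------------------------------------------------------------

def save_model(model: PredictionModel, path: str | Path) -> None:
    Path(path).write_text(model.canonical_json())


def load_model(path: str | Path) -> PredictionModel:
    return loads_model(Path(path).read_text())


def loads_model(text: str) -> PredictionModel:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProstarError(f"invalid model file: {exc}") from exc
    if obj.get("magic") != MODEL_MAGIC:
        raise ProstarError("not a prediction-model file")
    if obj.get("version") != MODEL_VERSION:
        raise ProstarError(f"unsupported model version {obj.get('version')!r}")
    entries: dict[Key, ModelEntry] = {}
    for name, rec in obj["entries"].items():
        res, atom = name.split(":")
        refs = tuple((n, int(o)) for n, o in rec["refs"])
        if len(refs) != 3:
            raise ProstarError(f"model entry {name} must have 3 references")
        cents = np.asarray(rec["centroids"], dtype=np.float64).reshape(-1, 6)
        entries[(res, atom)] = ModelEntry(
            ref_spec=ReferenceSpec(residue_type=res, atom_type=atom, refs=refs),
            centroid_set=CentroidSet(residue_type=res, atom_type=atom,
                                     centroids=cents))
    return PredictionModel(entries=entries, version=obj["version"])
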