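"""Predictive coding of atom tables.

Per chain the stream carries: the chain metadata (id, entropy-coded residue
types, delta-coded residue numbering), the first three atoms delta-coded
(the first against the origin, then against the previous atom), and for
every following atom the centroid id, the mirror id and the residual
``(dx, dy, dz)`` between the atom and the trilaterated prediction.
B-factors and occupancies follow as delta-coded fixed-point columns.

The encoder predicts from *reconstructed* positions, so in lossy mode all
coordinates are snapped to their error grid first (backbone and side-chain
grids separately) and the pipeline then runs losslessly on the rounded
values — this is what makes the maximum reconstruction error a hard bound
rather than an average.  Predictions are rounded to integer mÅ (half away
from zero) before residuals are formed, so encoder and decoder agree
bit-exactly despite floating-point trilateration.

A trilateration failure (degenerate base or unmeetable spheres) makes a
centroid predict the first (mirror 0) or second (mirror 1) reference
position instead.  Atoms whose references do not exist at all — slots of a
chain's first residue whose trained references sit in the previous
residue — are delta-coded against the previous atom; the decoder detects
the situation from the same information, so no flag is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .entropy import (FrequencyModel, RangeDecoder, RangeEncoder,
                      RESIDUAL_ALPHABET, get_residual, put_residual)
from .errors import ProstarError
from .formats_io import AtomRecord, AtomTableData, ChainData
from .geometry import (Coord3, eq1_cost, round_coord, round_prediction,
                       rounding_step, trilaterate)
from .residues import (RESIDUE_ATOMS, RESIDUE_INDEX, RESIDUE_NAMES,
                       TERMINAL_OXYGEN, element_of, is_backbone)
from .training import PredictionModel, prune_model, resolve_refs


@dataclass(frozen=True)
class LossyParams:
    """User-facing lossy knobs; 0 mÅ means lossless."""

    m_backbone: int = 0      # max Euclidean error of backbone atoms, mÅ
    m_sidechain: int = 0     # max Euclidean error of side-chain atoms, mÅ
    bf_average: bool = False  # replace B-factors by their residue mean
    minimal: bool = False     # archive only header + atom tables

    @property
    def is_lossy(self) -> bool:
        return self.m_backbone > 0 or self.m_sidechain > 0


LOSSLESS = LossyParams()


@dataclass(frozen=True)
class PredictionOutcome:
    centroid_id: int
    mirror_id: int
    residual: Coord3
    est_cost: float
    fallback: bool


def _centroid_predictions(centroid, p1: Coord3, p2: Coord3, p3: Coord3,
                          ) -> tuple[Coord3, Coord3, bool]:
    """Both mirror predictions (integer mÅ) of one centroid over an actual
    base; falls back to the reference positions when the tetrahedron cannot
    be built."""
    sol = trilaterate(p1, p2, p3, float(centroid[3]), float(centroid[4]),
                      float(centroid[5]))
    if sol is None:
        return p1, p2, True
    return round_prediction(sol[0]), round_prediction(sol[1]), False


def predict_full(entry, ref_pos, target: Coord3) -> PredictionOutcome:
    """Examine every centroid and both mirrors; keep the prediction whose
    residual is cheapest under the log2(1+|d|)-per-axis cost (a farther
    prediction wins if it encodes cheaper).  Ties: lower centroid id, then
    mirror 0."""
    cents = entry.centroid_set.centroids
    p1, p2, p3 = ref_pos
    best = None
    for ci in range(len(cents)):
        q0, q1, fb = _centroid_predictions(cents[ci], p1, p2, p3)
        for mi, q in ((0, q0), (1, q1)):
            res = (target[0] - q[0], target[1] - q[1], target[2] - q[2])
            cost = eq1_cost(*res)
            if best is None or cost < best[0]:
                best = (cost, ci, mi, res, fb)
    cost, ci, mi, res, fb = best
    return PredictionOutcome(centroid_id=ci, mirror_id=mi, residual=res,
                             est_cost=cost, fallback=fb)


def predict_fast(entry, ref_pos, target: Coord3) -> PredictionOutcome:
    """Pick the single centroid nearest (6-D Euclidean) to the atom's own
    distance tuple, then choose the cheaper mirror."""
    from .geometry import observation_of
    cents = entry.centroid_set.centroids
    p1, p2, p3 = ref_pos
    o = observation_of(p1, p2, p3, target).as_tuple()
    best_ci = 0
    best_d = math.inf
    for ci in range(len(cents)):
        c = cents[ci]
        d = sum((float(c[m]) - o[m]) ** 2 for m in range(6))
        if d < best_d:
            best_d = d
            best_ci = ci
    q0, q1, fb = _centroid_predictions(cents[best_ci], p1, p2, p3)
    best = None
    for mi, q in ((0, q0), (1, q1)):
        res = (target[0] - q[0], target[1] - q[1], target[2] - q[2])
        cost = eq1_cost(*res)
        if best is None or cost < best[0]:
            best = (cost, mi, res)
    cost, mi, res = best
    return PredictionOutcome(centroid_id=best_ci, mirror_id=mi, residual=res,
                             est_cost=cost, fallback=fb)


def decode_prediction(entry, ref_pos, centroid_id: int,
                      mirror_id: int) -> Coord3:
    """The decoder's reconstruction of the chosen prediction."""
    q0, q1, _ = _centroid_predictions(entry.centroid_set.centroids[centroid_id],
                                      *ref_pos)
    return q0 if mirror_id == 0 else q1


# --- model coverage -----------------------------------------------------------

def model_covers(model: PredictionModel, table: AtomTableData) -> bool:
    """True if every atom slot occurring in *table* has a model entry.

    Chain-leading atoms and the optional terminal OXT are exempt: both are
    delta-coded when no entry applies, at negligible cost (at most four
    atoms per chain)."""
    for chain in table.chains:
        seen_first = 0
        for rec in chain.atoms:
            if seen_first < 3:
                seen_first += 1
                continue
            if rec.atom_name == TERMINAL_OXYGEN:
                continue
            if (rec.residue_name, rec.atom_name) not in model.entries:
                return False
    return True


# --- shared model bank ---------------------------------------------------------

class _Models:
    """Identically-initialized adaptive models on both coder sides."""

    def __init__(self) -> None:
        self.meta = FrequencyModel(RESIDUAL_ALPHABET)
        self.byte = FrequencyModel(256)
        self.restype = FrequencyModel(len(RESIDUE_NAMES))
        self.flag_oxt = FrequencyModel(2)
        self.flag_ter = FrequencyModel(2)
        self.bf_mode = FrequencyModel(2)
        self.mirror = FrequencyModel(2)
        self.resnum = FrequencyModel(RESIDUAL_ALPHABET)
        self.bfac = FrequencyModel(RESIDUAL_ALPHABET)
        self.occ = FrequencyModel(RESIDUAL_ALPHABET)
        # residual buckets per (atom class, axis); class 2 = chain-leading deltas
        self.residual = [[FrequencyModel(RESIDUAL_ALPHABET) for _ in range(3)]
                         for _ in range(3)]
        self.centroid: dict[tuple[str, str], FrequencyModel] = {}

    def centroid_model(self, key: tuple[str, str], k: int) -> FrequencyModel:
        m = self.centroid.get(key)
        if m is None:
            m = self.centroid[key] = FrequencyModel(k)
        return m


def _atom_class(name: str) -> int:
    return 0 if is_backbone(name) else 1


def _put_coord_delta(enc, models: _Models, cls: int, prev: Coord3,
                     cur: Coord3) -> None:
    for ax in range(3):
        put_residual(enc, models.residual[cls][ax], cur[ax] - prev[ax])


def _get_coord_delta(dec, models: _Models, cls: int, prev: Coord3) -> Coord3:
    return tuple(prev[ax] + get_residual(dec, models.residual[cls][ax])
                 for ax in range(3))  # type: ignore[return-value]


def _chain_atom_names(res_names: list[str], has_oxt: bool):
    """Atom names of a chain, derived from the residue sequence alone."""
    for ri, res in enumerate(res_names):
        for name in RESIDUE_ATOMS[res]:
            yield ri, res, name
        if has_oxt and ri == len(res_names) - 1:
            yield ri, res, TERMINAL_OXYGEN


# --- lossy preprocessing --------------------------------------------------------

def round_table(table: AtomTableData, lossy: LossyParams) -> AtomTableData:
    """Snap every coordinate to its class grid (and average B-factors per
    residue when requested).  Returns a new table; lossless params return
    the input unchanged."""
    if not lossy.is_lossy and not lossy.bf_average:
        return table
    spec_bb = rounding_step(lossy.m_backbone)
    spec_sc = rounding_step(lossy.m_sidechain)
    chains = []
    for chain in table.chains:
        atoms = []
        for rec in chain.atoms:
            spec = spec_bb if is_backbone(rec.atom_name) else spec_sc
            atoms.append(AtomRecord(
                serial=rec.serial, atom_name=rec.atom_name,
                alt_loc=rec.alt_loc, residue_name=rec.residue_name,
                chain_id=rec.chain_id, residue_seq=rec.residue_seq,
                insertion_code=rec.insertion_code,
                coord=round_coord(rec.coord, spec),
                occupancy=rec.occupancy, b_factor=rec.b_factor,
                element=rec.element, het=rec.het))
        if lossy.bf_average:
            _average_bfactors(atoms)
        chains.append(ChainData(chain_id=chain.chain_id,
                                residue_names=chain.residue_names,
                                residue_seqs=chain.residue_seqs,
                                has_oxt=chain.has_oxt, has_ter=chain.has_ter,
                                atoms=atoms))
    return AtomTableData(dialect=table.dialect, serial_start=table.serial_start,
                         chains=chains)


def _average_bfactors(atoms: list[AtomRecord]) -> None:
    i = 0
    n = len(atoms)
    while i < n:
        j = i
        total = 0
        while j < n and atoms[j].residue_seq == atoms[i].residue_seq:
            total += atoms[j].b_factor
            j += 1
        na = j - i
        mean = (2 * total + na) // (2 * na)  # round half away (values >= 0)
        for k in range(i, j):
            atoms[k].b_factor = mean
        i = j


# --- B-factor / occupancy columns ------------------------------------------------

def _encode_bfactors_chain(enc, models: _Models, atoms: list[AtomRecord]) -> None:
    """Mode 0: one value per residue (the AlphaFold pLDDT case); mode 1:
    one per atom.  Values are delta-coded hundredths."""
    residues: list[list[int]] = []
    for rec in atoms:
        if not residues or rec.residue_seq != residues[-1][0]:
            residues.append([rec.residue_seq, []])  # type: ignore[list-item]
        residues[-1][1].append(rec.b_factor)       # type: ignore[union-attr]
    constant = all(len(set(vals)) == 1 for _, vals in residues)
    enc.encode_symbol(models.bf_mode, 0 if constant else 1)
    prev = 0
    if constant:
        for _, vals in residues:
            put_residual(enc, models.bfac, vals[0] - prev)
            prev = vals[0]
    else:
        for rec in atoms:
            put_residual(enc, models.bfac, rec.b_factor - prev)
            prev = rec.b_factor


def _decode_bfactors_chain(dec, models: _Models, atoms: list[AtomRecord]) -> None:
    constant = dec.decode_symbol(models.bf_mode) == 0
    prev = 0
    if constant:
        cur_seq = None
        for rec in atoms:
            if rec.residue_seq != cur_seq:
                cur_seq = rec.residue_seq
                prev += get_residual(dec, models.bfac)
            rec.b_factor = prev
    else:
        for rec in atoms:
            prev += get_residual(dec, models.bfac)
            rec.b_factor = prev


def encode_bfactors(table: AtomTableData, lossy: LossyParams = LOSSLESS) -> bytes:
    """Standalone B-factor stream (chains concatenated); used directly by
    tests, and inlined by the atom-table codec."""
    table = round_table(table, LossyParams(bf_average=lossy.bf_average))
    enc = RangeEncoder()
    models = _Models()
    for chain in table.chains:
        _encode_bfactors_chain(enc, models, chain.atoms)
    return enc.finish()


def decode_bfactors(stream: bytes, table: AtomTableData) -> list[list[int]]:
    """Decode a stream from :func:`encode_bfactors` against the same chain
    layout; returns per-chain B-factor lists (hundredths)."""
    dec = RangeDecoder(stream)
    models = _Models()
    out = []
    for chain in table.chains:
        shadow = [AtomRecord(serial=a.serial, atom_name=a.atom_name,
                             alt_loc=a.alt_loc, residue_name=a.residue_name,
                             chain_id=a.chain_id, residue_seq=a.residue_seq,
                             insertion_code=a.insertion_code, coord=a.coord,
                             occupancy=a.occupancy, b_factor=0,
                             element=a.element, het=a.het)
                  for a in chain.atoms]
        _decode_bfactors_chain(dec, models, shadow)
        out.append([a.b_factor for a in shadow])
    return out


# --- atom-table codec --------------------------------------------------------------

def encode_atom_table(table: AtomTableData, model: PredictionModel,
                      lossy: LossyParams = LOSSLESS,
                      fast: bool = False) -> bytes:
    """Full atom-table stream.  Raises :class:`ProstarError` when the model
    does not cover the table (callers demote to generic handling)."""
    if not model_covers(model, table):
        raise ProstarError("atom table outside model coverage")
    table = round_table(table, lossy)
    work = prune_model(model, rounding_step(lossy.m_backbone),
                       rounding_step(lossy.m_sidechain))
    predict = predict_fast if fast else predict_full

    enc = RangeEncoder()
    models = _Models()
    put_residual(enc, models.meta, lossy.m_backbone)
    put_residual(enc, models.meta, lossy.m_sidechain)
    put_residual(enc, models.meta, 1 if table.dialect == "pdb" else 0)
    put_residual(enc, models.meta, table.serial_start)
    put_residual(enc, models.meta, len(table.chains))
    for chain in table.chains:
        cid = chain.chain_id.encode("utf-8")
        put_residual(enc, models.meta, len(cid))
        for b in cid:
            enc.encode_symbol(models.byte, b)
        put_residual(enc, models.meta, len(chain.residue_names))
        for res in chain.residue_names:
            enc.encode_symbol(models.restype, RESIDUE_INDEX[res])
        prev_seq = 0
        for seq in chain.residue_seqs:
            put_residual(enc, models.resnum, seq - prev_seq)
            prev_seq = seq
        enc.encode_symbol(models.flag_oxt, int(chain.has_oxt))
        enc.encode_symbol(models.flag_ter, int(chain.has_ter))

        _code_chain_coords(chain, work, predict, models,
                           enc=enc, dec=None)
        _encode_bfactors_chain(enc, models, chain.atoms)
        prev_occ = 0
        for rec in chain.atoms:
            put_residual(enc, models.occ, rec.occupancy - prev_occ)
            prev_occ = rec.occupancy
    return enc.finish()


def decode_atom_table(stream: bytes, model: PredictionModel) -> AtomTableData:
    dec = RangeDecoder(stream)
    models = _Models()
    m_bb = get_residual(dec, models.meta)
    m_sc = get_residual(dec, models.meta)
    work = prune_model(model, rounding_step(m_bb), rounding_step(m_sc))
    dialect = "pdb" if get_residual(dec, models.meta) == 1 else "mmcif"
    serial_start = get_residual(dec, models.meta)
    n_chains = get_residual(dec, models.meta)
    chains: list[ChainData] = []
    for _ in range(n_chains):
        cid_len = get_residual(dec, models.meta)
        chain_id = bytes(dec.decode_symbol(models.byte)
                         for _ in range(cid_len)).decode("utf-8")
        n_res = get_residual(dec, models.meta)
        res_names = [RESIDUE_NAMES[dec.decode_symbol(models.restype)]
                     for _ in range(n_res)]
        res_seqs = []
        prev_seq = 0
        for _ in range(n_res):
            prev_seq += get_residual(dec, models.resnum)
            res_seqs.append(prev_seq)
        has_oxt = bool(dec.decode_symbol(models.flag_oxt))
        has_ter = bool(dec.decode_symbol(models.flag_ter))

        chain = ChainData(chain_id=chain_id, residue_names=res_names,
                          residue_seqs=res_seqs, has_oxt=has_oxt,
                          has_ter=has_ter, atoms=[])
        for ri, res, name in _chain_atom_names(res_names, has_oxt):
            chain.atoms.append(AtomRecord(
                serial=0, atom_name=name, alt_loc="", residue_name=res,
                chain_id=chain_id, residue_seq=res_seqs[ri],
                insertion_code="", coord=(0, 0, 0), occupancy=0, b_factor=0,
                element=element_of(name), het=False))
        _code_chain_coords(chain, work, None, models, enc=None, dec=dec)
        _decode_bfactors_chain(dec, models, chain.atoms)
        prev_occ = 0
        for rec in chain.atoms:
            prev_occ += get_residual(dec, models.occ)
            rec.occupancy = prev_occ
        chains.append(chain)
    return AtomTableData(dialect=dialect, serial_start=serial_start,
                         chains=chains)


def _code_chain_coords(chain: ChainData, model: PredictionModel, predict,
                       models: _Models, enc, dec) -> None:
    """Symmetric coordinate coder: with *enc* set it encodes ``chain``'s
    coordinates; with *dec* set it fills them in.  Both sides walk the same
    reconstructed state, which is what guarantees prediction symmetry."""
    by_res: list[dict[str, Coord3]] = [dict() for _ in chain.residue_names]
    prev: Coord3 = (0, 0, 0)
    for idx, rec in enumerate(chain.atoms):
        ri = _residue_index_of(chain, idx)
        key = (rec.residue_name, rec.atom_name)
        entry = model.entries.get(key) if idx >= 3 else None
        ref_pos = (resolve_refs(entry.ref_spec.refs, ri, by_res)
                   if entry is not None else None)
        if ref_pos is None:
            # chain-leading atoms and unresolvable references: delta coding
            if enc is not None:
                _put_coord_delta(enc, models, 2, prev, rec.coord)
            else:
                rec.coord = _get_coord_delta(dec, models, 2, prev)
        else:
            cls = _atom_class(rec.atom_name)
            k = entry.centroid_set.k
            cmodel = models.centroid_model(key, k)
            if enc is not None:
                out = predict(entry, ref_pos, rec.coord)
                enc.encode_symbol(cmodel, out.centroid_id)
                enc.encode_symbol(models.mirror, out.mirror_id)
                for ax in range(3):
                    put_residual(enc, models.residual[cls][ax],
                                 out.residual[ax])
            else:
                ci = dec.decode_symbol(cmodel)
                mi = dec.decode_symbol(models.mirror)
                pred = decode_prediction(entry, ref_pos, ci, mi)
                rec.coord = tuple(
                    pred[ax] + get_residual(dec, models.residual[cls][ax])
                    for ax in range(3))  # type: ignore[assignment]
        by_res[ri][rec.atom_name] = rec.coord
        prev = rec.coord


def _residue_index_of(chain: ChainData, atom_idx: int) -> int:
    # cache the flat-index -> residue-index map on the chain object
    cache = getattr(chain, "_ri_cache", None)
    if cache is None:
        cache = []
        for ri, res in enumerate(chain.residue_names):
            cache.extend([ri] * len(RESIDUE_ATOMS[res]))
        if chain.has_oxt:
            cache.append(len(chain.residue_names) - 1)
        chain._ri_cache = cache  # type: ignore[attr-defined]
    return cache[atom_idx]


# --- coordinate-stream size accounting (predictor-utility checks) -----------------

def coordinate_stream_size(tables: list[AtomTableData],
                           model: PredictionModel, fast: bool = False) -> int:
    """Bytes to code only the coordinates of *tables* with the predictor."""
    enc = RangeEncoder()
    models = _Models()
    predict = predict_fast if fast else predict_full
    for table in tables:
        for chain in table.chains:
            _code_chain_coords(chain, model, predict, models, enc=enc, dec=None)
    return len(enc.finish())


def delta_stream_size(tables: list[AtomTableData]) -> int:
    """Bytes to code the same coordinates as plain per-axis deltas between
    consecutive atoms, through the same entropy coder."""
    enc = RangeEncoder()
    models = _Models()
    for table in tables:
        for chain in table.chains:
            prev: Coord3 = (0, 0, 0)
            for rec in chain.atoms:
                _put_coord_delta(enc, models, 2, prev, rec.coord)
                prev = rec.coord
    return len(enc.finish())
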