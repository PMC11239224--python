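"""Seeded generators of synthetic structures, PAE matrices and confidence
files.

The structure generator emulates what the coordinate codec and the model
trainer exercise in real prediction databases: polypeptide chains with the
canonical per-residue atom composition and ordering, near-rigid local
geometry (bond lengths ~1.2-1.6 Å), and per-residue-constant B-factors.
Backbones follow an idealized alpha-helix, so each residue carries the same
local frame; side-chain atoms sit at fixed template offsets in that frame,
with ``conformer_count`` discrete rotamer-like variants per residue type
plus isotropic Gaussian noise.  Distance 6-tuples collected from such
chains therefore form ``conformer_count`` tight clusters per atom slot,
which is exactly the regime the centroid trainer is designed for.

No sterics or Ramachandran statistics are modelled — only the geometry the
codec relies on.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path

from .formats_io import (AtomRecord, AtomTableData, ChainData, ConfidenceFile,
                         PAEMatrix, serialize_atom_table, write_confidence,
                         write_pae)
from .residues import RESIDUE_ATOMS, RESIDUE_INDEX, RESIDUE_NAMES, element_of

# helix parameters (Å): radius, rise per residue, turn per residue
_HELIX_R = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)

# backbone template offsets in the local (tangent, normal, binormal) frame
_BB_OFFSETS = {
    "N": (-1.2, -0.8, 0.2),    # |.| = 1.46  (N-CA)
    "CA": (0.0, 0.0, 0.0),
    "C": (1.25, -0.8, 0.25),   # |.| = 1.51  (CA-C)
}
_O_FROM_C = (0.2, -1.05, -0.6)    # |.| = 1.23  (C=O)
_OXT_FROM_C = (-0.3, -1.05, 0.55)
_CB_FROM_CA = (-0.25, 1.0, 1.1)   # |.| = 1.51  (CA-CB)
_SIDE_BOND = 1.5


@dataclass(frozen=True)
class FixtureSpec:
    n_structures: int = 10
    residues_per_chain: int = 25
    chains: int = 1
    residue_alphabet: tuple[str, ...] = RESIDUE_NAMES
    coordinate_noise_sd: float = 0.05   # Å
    conformer_count: int = 2
    seed: int = 7
    #: False: translation-symmetric backbone (identical local frame, 3.8 Å
    #: rise).  With zero noise every conformer's distance tuple is then
    #: *exactly* reproducible (integer-mÅ translations), giving the
    #: point-mass observations the k-recovery analysis assumes.
    helical: bool = True


@dataclass
class SyntheticStructure:
    name: str
    atom_table: AtomTableData
    pdb_text: str
    cif_text: str
    n_residues: int = 0


def _unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
    n = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    return (v[0] / n, v[1] / n, v[2] / n)


def _side_chain_dir(res: str, atom_idx: int, conformer: int,
                    ) -> tuple[float, float, float]:
    """Fixed template direction for a side-chain bond: a deterministic
    function of (residue type, atom slot, conformer), independent of any
    corpus seed — this *is* the synthetic chemistry."""
    rng = random.Random((RESIDUE_INDEX[res] * 131 + atom_idx) * 97 + conformer)
    while True:
        v = (rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(-1, 1))
        n2 = v[0] ** 2 + v[1] ** 2 + v[2] ** 2
        if 0.1 < n2 <= 1.0:
            return _unit(v)


def _residue_template(res: str, conformer: int,
                      with_oxt: bool) -> list[tuple[str, tuple[float, float, float]]]:
    """Atom offsets (local frame, Å) for one residue in one conformer."""
    out = [(name, _BB_OFFSETS[name]) for name in ("N", "CA", "C")]
    c = _BB_OFFSETS["C"]
    out.append(("O", (c[0] + _O_FROM_C[0], c[1] + _O_FROM_C[1],
                      c[2] + _O_FROM_C[2])))
    prev = (0.0, 0.0, 0.0)  # CA
    for idx, name in enumerate(RESIDUE_ATOMS[res][4:], start=4):
        if name == "CB":
            d = _CB_FROM_CA
            step = 1.0
        else:
            d = _side_chain_dir(res, idx, conformer)
            step = _SIDE_BOND
        pos = (prev[0] + d[0] * step, prev[1] + d[1] * step,
               prev[2] + d[2] * step)
        out.append((name, pos))
        prev = pos
    if with_oxt:
        out.append(("OXT", (c[0] + _OXT_FROM_C[0], c[1] + _OXT_FROM_C[1],
                            c[2] + _OXT_FROM_C[2])))
    return out


def _helix_frame(i: int) -> tuple[tuple[float, float, float], ...]:
    """(origin CA, tangent, normal, binormal) of residue *i* on the helix."""
    a = _HELIX_TURN * i
    ca = (_HELIX_R * math.cos(a), _HELIX_R * math.sin(a), _HELIX_RISE * i)
    t = _unit((-_HELIX_R * _HELIX_TURN * math.sin(a),
               _HELIX_R * _HELIX_TURN * math.cos(a), _HELIX_RISE))
    n = (-math.cos(a), -math.sin(a), 0.0)
    b = (t[1] * n[2] - t[2] * n[1], t[2] * n[0] - t[0] * n[2],
         t[0] * n[1] - t[1] * n[0])
    return ca, t, n, b


_EXTENDED_RISE = 3.8  # Å, CA-CA step of the translation-symmetric backbone


def _extended_frame(i: int) -> tuple[tuple[float, float, float], ...]:
    """Identity frame translated along z: residue i at z = i * 3.8 Å."""
    return ((0.0, 0.0, _EXTENDED_RISE * i), (1.0, 0.0, 0.0),
            (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def gen_structure(spec: FixtureSpec, index: int) -> SyntheticStructure:
    """Deterministically generate one synthetic structure."""
    rng = random.Random(spec.seed * 1_000_003 + index)
    chains: list[ChainData] = []
    serial = 1
    for ci in range(spec.chains):
        chain_id = chr(ord("A") + ci)
        nres = spec.residues_per_chain
        res_names = rng.choices(spec.residue_alphabet, k=nres)
        has_oxt = rng.random() < 0.5
        atoms: list[AtomRecord] = []
        bfac_prev = 0
        for ri in range(nres):
            res = res_names[ri]
            conformer = rng.randrange(spec.conformer_count)
            frame = _helix_frame if spec.helical else _extended_frame
            ca, t, n, b = frame(ri + ci * (nres + 8))
            bfac = round(rng.uniform(40.0, 95.0) * 100)
            bfac_prev = bfac
            template = _residue_template(res, conformer,
                                         with_oxt=has_oxt and ri == nres - 1)
            for name, off in template:
                x = ca[0] + off[0] * t[0] + off[1] * n[0] + off[2] * b[0]
                y = ca[1] + off[0] * t[1] + off[1] * n[1] + off[2] * b[1]
                z = ca[2] + off[0] * t[2] + off[1] * n[2] + off[2] * b[2]
                if spec.coordinate_noise_sd > 0:
                    x += rng.gauss(0.0, spec.coordinate_noise_sd)
                    y += rng.gauss(0.0, spec.coordinate_noise_sd)
                    z += rng.gauss(0.0, spec.coordinate_noise_sd)
                atoms.append(AtomRecord(
                    serial=serial,
                    atom_name=name,
                    alt_loc="",
                    residue_name=res,
                    chain_id=chain_id,
                    residue_seq=ri + 1,
                    insertion_code="",
                    coord=(round(x * 1000), round(y * 1000), round(z * 1000)),
                    occupancy=100,
                    b_factor=bfac,
                    element=element_of(name),
                ))
                serial += 1
        chains.append(ChainData(chain_id=chain_id, residue_names=res_names,
                                residue_seqs=list(range(1, nres + 1)),
                                has_oxt=has_oxt, has_ter=True, atoms=atoms))
        serial += 1  # TER consumes a serial in the PDB dialect
    name = f"synth_{index:04d}"
    n_residues = spec.residues_per_chain * spec.chains
    table_pdb = AtomTableData(dialect="pdb", serial_start=1, chains=chains)
    pdb_text = (f"HEADER    SYNTHETIC STRUCTURE {name.upper()}\n"
                f"TITLE     IDEALIZED HELICAL CHAIN FIXTURE\n"
                + serialize_atom_table(table_pdb) + "END\n")
    cif_chains = [ChainData(chain_id=c.chain_id, residue_names=c.residue_names,
                            residue_seqs=c.residue_seqs, has_oxt=c.has_oxt,
                            has_ter=False, atoms=list(c.atoms))
                  for c in chains]
    table_cif = AtomTableData(dialect="mmcif", serial_start=1, chains=cif_chains)
    cif_text = (f"data_{name}\n#\n_entry.id {name}\n#\n"
                + serialize_atom_table(table_cif) + "#\n")
    return SyntheticStructure(name=name, atom_table=table_pdb,
                              pdb_text=pdb_text, cif_text=cif_text,
                              n_residues=n_residues)


def gen_pae(n: int, smoothness: float = 1.0, seed: int = 0) -> PAEMatrix:
    """Synthetic PAE: zero diagonal, 1 on first off-diagonals, smooth banded
    growth toward 32 with seeded integer noise (smaller for smoother
    matrices)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    amp = max(0, round(2.0 / smoothness))
    values: list[list[int]] = []
    for i in range(n):
        row: list[int] = []
        for j in range(n):
            d = abs(i - j)
            if d == 0:
                row.append(0)
            elif d == 1:
                row.append(1)
            else:
                base = 32.0 * (1.0 - math.exp(-d / (6.0 * smoothness)))
                v = round(base) + rng.randint(-amp, amp)
                row.append(min(32, max(0, v)))
        values.append(row)
    return PAEMatrix(n=n, values=values)


def gen_confidence(n: int, seed: int = 0) -> ConfidenceFile:
    rng = random.Random(seed)
    scores = [round(rng.uniform(30.0, 99.0) * 100) for _ in range(n)]
    def cat(c: int) -> str:
        return "D" if c < 5000 else "L" if c < 7000 else "M" if c < 9000 else "H"
    return ConfidenceFile(residue_ids=list(range(1, n + 1)),
                          scores=scores,
                          categories=[cat(c) for c in scores])


def gen_corpus(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write structure+PAE+confidence triples (one per structure; the
    structure dialect alternates between mmCIF and PDB).  Deterministic
    given an equal spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for i in range(spec.n_structures):
        s = gen_structure(spec, i)
        if i % 2 == 0:
            p = out / f"{s.name}.cif"
            p.write_text(s.cif_text)
        else:
            p = out / f"{s.name}.pdb"
            p.write_text(s.pdb_text)
        paths.append(p)
        pae = gen_pae(s.n_residues, smoothness=1.0, seed=spec.seed * 7919 + i)
        pp = out / f"{s.name}.pae.json"
        pp.write_text(write_pae(pae))
        paths.append(pp)
        conf = gen_confidence(s.n_residues, seed=spec.seed * 104729 + i)
        cp = out / f"{s.name}.confidence.json"
        cp.write_text(write_confidence(conf))
        paths.append(cp)
    return paths


def training_tables(spec: FixtureSpec) -> list[AtomTableData]:
    """Atom tables of the corpus, for the model trainer."""
    return [gen_structure(spec, i).atom_table for i in range(spec.n_structures)]
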