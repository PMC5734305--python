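"""Side-chain placement: promote a backbone model to all-atom.

Two strategies:

``ideal_rotamer``
    Each residue type gets its single most-populated backbone-independent
    rotamer, built from ideal internal coordinates (NeRF placement).  Clashes
    between side-chain atoms closer than 2.0 Å are then resolved greedily by
    cycling the offending residues through the remaining rotamers of their
    type, for a bounded number of passes.  This keeps the whole pipeline
    hermetic and fast; it is a deliberate simplification, not an attempt at
    combinatorial repacking.

``external_packer``
    Write the model as PDB, hand it to a user-configured packing binary
    (e.g. a SCWRL-style tool), and read the result back.  Any failure is
    surfaced with the subprocess diagnostics — never a silent fallback.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._errors import SidechainError
from .geometry import StructureModel
from .residues import ROTAMERS, SIDECHAIN_TEMPLATES

__all__ = ["place_sidechains", "nerf", "CLASH_CUTOFF", "MAX_CLASH_PASSES"]

CLASH_CUTOFF = 2.0   # A, heavy-atom pair distance treated as a clash
MAX_CLASH_PASSES = 3


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame: place atom d bonded to c with the
    given c-d bond length, b-c-d angle and a-b-c-d torsion.  Works on single
    points or (M, 3) batches."""
    a, b, c = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)  # IUPAC sign: tor equals the a-b-c-d dihedral
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    out = c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
    return out[0] if out.shape[0] == 1 else out


def _build_sidechain(res_name: str, frame: dict[str, np.ndarray],
                     chis: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Coordinates of the side-chain atoms of one residue (or a batch of
    same-type residues) given its backbone frame atoms N/CA/C."""
    placed = dict(frame)
    out: dict[str, np.ndarray] = {}
    for atom, (ref_a, ref_b, parent), bond, ang, tor in SIDECHAIN_TEMPLATES[res_name]:
        if isinstance(tor, tuple):
            _, k, offset = tor
            torsion = chis[k] + offset
        else:
            torsion = tor
        pos = nerf(placed[ref_a], placed[ref_b], placed[parent], bond, ang, torsion)
        placed[atom] = pos
        out[atom] = pos
    return out


def _place_all(model: StructureModel, rotamer_choice: dict[tuple[int, int], int]) -> None:
    """Write side-chain atoms into the model in place, batched per residue
    type/rotamer for speed."""
    groups: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for ci, chain in enumerate(model.chains):
        for ri, res in enumerate(chain.residues):
            if res.name not in SIDECHAIN_TEMPLATES:
                raise SidechainError(f"unknown residue type {res.name!r} "
                                     f"(chain {chain.chain_id} residue {res.number})")
            rot = rotamer_choice.get((ci, ri), 0)
            groups.setdefault((res.name, rot), []).append((ci, ri))

    for (name, rot), members in groups.items():
        if not SIDECHAIN_TEMPLATES[name]:
            continue
        chis = ROTAMERS[name][rot % len(ROTAMERS[name])]
        frame = {
            atom: np.array([model.chains[ci].residues[ri].atoms[atom]
                            for ci, ri in members])
            for atom in ("N", "CA", "C")
        }
        built = _build_sidechain(name, frame, chis)
        for atom, coords in built.items():
            coords = np.atleast_2d(coords)
            for k, (ci, ri) in enumerate(members):
                model.chains[ci].residues[ri].atoms[atom] = coords[k]


def _clash_counts(model: StructureModel) -> dict[tuple[int, int], int]:
    """Clashes per residue: heavy-atom pairs < CLASH_CUTOFF where at least
    one atom is a side-chain atom and the atoms belong to different
    residues."""
    rows, xyz = model.atom_table()
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(CLASH_CUTOFF, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    backbone = {"N", "CA", "C", "O"}
    for i, j in pairs:
        ci, ri, ai = rows[i]
        cj, rj, aj = rows[j]
        if (ci, ri) == (cj, rj):
            continue
        if ai in backbone and aj in backbone:
            continue  # bonded/adjacent backbone geometry is not a clash
        if ai not in backbone:
            counts[(ci, ri)] = counts.get((ci, ri), 0) + 1
        if aj not in backbone:
            counts[(cj, rj)] = counts.get((cj, rj), 0) + 1
    return counts


def _run_external_packer(model: StructureModel, binary: str) -> StructureModel:
    from .pdbio import read_pdb, write_pdb

    exe = shutil.which(binary)
    if exe is None:
        raise SidechainError(
            f"external packer binary {binary!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.pdb"
        out = Path(tmp) / "out.pdb"
        write_pdb(model, inp)
        proc = subprocess.run([exe, "-i", str(inp), "-o", str(out)],
                              capture_output=True, text=True)
        if proc.returncode != 0 or not out.exists():
            raise SidechainError(
                f"external packer {binary!r} failed (exit {proc.returncode}):\n"
                f"stdout: {proc.stdout}\nstderr: {proc.stderr}")
        return read_pdb(out)


def place_sidechains(model: StructureModel, strategy: str = "ideal_rotamer",
                     packer_binary: str = "scwrl4",
                     resolve_clashes: bool = True) -> StructureModel:
    """Return an all-atom copy of a backbone model.

    Raises SidechainError if the model already carries side-chain atoms
    (explicitly no silent re-packing), if a residue type is unknown, or if
    the external packer fails.
    """
    if not model.is_backbone_only():
        raise SidechainError(
            "model already carries side-chain atoms; side chains are placed "
            "exactly once on a backbone model")
    for chain in model.chains:
        for res in chain.residues:
            if not res.has_backbone():
                raise SidechainError(
                    f"chain {chain.chain_id} residue {res.number} is missing "
                    "backbone atoms")

    if strategy == "external_packer":
        return _run_external_packer(model, packer_binary)
    if strategy != "ideal_rotamer":
        raise SidechainError(f"unknown strategy {strategy!r}")

    out = model.transformed()  # deep copy
    choice: dict[tuple[int, int], int] = {}
    _place_all(out, choice)

    if resolve_clashes:
        for _ in range(MAX_CLASH_PASSES):
            counts = _clash_counts(out)
            if not counts:
                break
            rows, xyz = out.atom_table()
            tree = cKDTree(xyz)
            res_of = np.array([(ci, ri) for ci, ri, _ in rows])
            improved = False
            for (ci, ri), n_clash in sorted(counts.items(),
                                            key=lambda kv: -kv[1]):
                res = out.chains[ci].residues[ri]
                n_rot = len(ROTAMERS[res.name])
                if n_rot < 2:
                    continue
                current = choice.get((ci, ri), 0)
                best_rot, best_n = current, n_clash
                frame = {a: res.atoms[a] for a in ("N", "CA", "C")}
                for step in range(1, n_rot):
                    rot = (current + step) % n_rot
                    built = _build_sidechain(res.name, frame,
                                             ROTAMERS[res.name][rot])
                    n_new = 0
                    for pos in built.values():
                        for idx in tree.query_ball_point(pos, CLASH_CUTOFF):
                            if tuple(res_of[idx]) != (ci, ri):
                                n_new += 1
                    if n_new < best_n:
                        best_rot, best_n = rot, n_new
                if best_rot != current:
                    choice[(ci, ri)] = best_rot
                    improved = True
            if not improved:
                break
            _place_all(out, choice)
    return out
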