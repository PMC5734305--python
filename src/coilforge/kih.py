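"""SOCKET-style knobs-into-holes packing analysis.

A residue is a *knob* into a partner chain when at least four side-chain
centers on that chain lie within the packing cutoff (default 7.0 Å) of its
own side-chain center; the four nearest such residues form the *hole*.  A
knob is *complementary* when one of its hole residues is itself a knob whose
hole contains the original residue — the reciprocal arrangement that defines
genuine coiled-coil packing.  Knob Crick angles then classify knobs as
heptad ``a`` or ``d`` and the register of each chain is reconstructed by
heptad periodicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import AnalysisError
from .geometry import ALPHA_PHI_STEP, StructureModel, crick_angles
from .residues import SIDECHAIN_ATOMS

__all__ = ["KihContact", "sidechain_center", "find_kih", "assign_register",
           "DEFAULT_KIH_CUTOFF"]

DEFAULT_KIH_CUTOFF = 7.0  # A, SOCKET's packing cutoff

_HEPTAD = "abcdefg"


@dataclass
class KihContact:
    """One knob with its 4-residue hole."""

    knob: tuple          # (chain_id, residue_number)
    hole: list           # 4 x (chain_id, residue_number)
    packing_cutoff: float
    complementarity: str     # "isolated" | "complementary"
    orientation: str         # "parallel" | "antiparallel"
    knob_register: str = "?"


def sidechain_center(residue) -> np.ndarray:
    """Centroid of the side-chain heavy atoms (incl. CB); the Cα position
    for glycine."""
    if residue.name == "GLY":
        return np.asarray(residue.atoms["CA"], dtype=float)
    side = residue.sidechain_atoms()
    if not side:
        expected = SIDECHAIN_ATOMS.get(residue.name, ())
        raise AnalysisError(
            f"residue {residue.name} {residue.number} has no side-chain "
            f"atoms (expected {', '.join(expected)}); run place_sidechains "
            "first")
    return np.mean(list(side.values()), axis=0)


def _chain_direction(chain, index: int, half_window: int = 2) -> np.ndarray:
    lo = max(index - half_window, 0)
    hi = min(index + half_window, len(chain.residues) - 1)
    v = (np.asarray(chain.residues[hi].atoms["CA"])
         - np.asarray(chain.residues[lo].atoms["CA"]))
    return v / np.linalg.norm(v)


def find_kih(model: StructureModel,
             cutoff: float = DEFAULT_KIH_CUTOFF) -> list[KihContact]:
    """Detect all knobs-into-holes contacts in an all-atom model.

    Contacts are sorted by (knob chain, residue number).  The first and last
    residue of each chain are not knob candidates (insufficient hole
    context).  Raises AnalysisError on backbone-only models.
    """
    if len(model.chains) < 2:
        raise AnalysisError("knobs-into-holes analysis needs >= 2 chains")
    if model.is_backbone_only():
        raise AnalysisError(
            "model has no side chains; run place_sidechains before "
            "knobs-into-holes analysis")

    centers: dict[str, np.ndarray] = {}
    for chain in model.chains:
        centers[chain.chain_id] = np.array(
            [sidechain_center(r) for r in chain.residues])

    hole_map: dict[tuple, tuple[str, list]] = {}
    contacts: list[KihContact] = []
    for chain in model.chains:
        cid = chain.chain_id
        for ri in range(1, len(chain.residues) - 1):
            knob_center = centers[cid][ri]
            for other in model.chains:
                if other.chain_id == cid:
                    continue
                d = np.linalg.norm(centers[other.chain_id] - knob_center,
                                   axis=1)
                within = np.where(d <= cutoff)[0]
                if len(within) < 4:
                    continue
                hole_idx = within[np.argsort(d[within])[:4]]
                hole = [(other.chain_id, other.residues[k].number)
                        for k in hole_idx]
                knob_dir = _chain_direction(chain, ri)
                hole_dir = _chain_direction(other, int(hole_idx[0]))
                orientation = ("parallel" if float(knob_dir @ hole_dir) >= 0
                               else "antiparallel")
                key = (cid, chain.residues[ri].number)
                hole_map[key] = (other.chain_id, hole)
                contacts.append(KihContact(
                    knob=key, hole=hole, packing_cutoff=cutoff,
                    complementarity="isolated", orientation=orientation))

    for contact in contacts:
        for hole_res in contact.hole:
            partner = hole_map.get(hole_res)
            if partner is not None and contact.knob in partner[1]:
                contact.complementarity = "complementary"
                break

    contacts.sort(key=lambda c: (c.knob[0], c.knob[1]))
    return contacts


def assign_register(contacts: list[KihContact], model: StructureModel):
    """Reconstruct each chain's heptad register from its complementary knobs.

    Knobs are labelled ``a`` or ``d`` from their Crick angle about the fitted
    super-helical axis (``a`` sits just clockwise of the inward direction,
    ``d`` just counter-clockwise; boundary at half the per-residue advance),
    the remaining positions follow by heptad periodicity, and the confidence
    is the fraction of classified knobs consistent with the final assignment.

    Returns {chain_id: {"register": str | None, "confidence": float,
    "status": "assigned" | "unassigned"}}.  Chains with fewer than two
    complementary knobs are reported unassigned, not raised.
    """
    half_step = ALPHA_PHI_STEP / 2.0
    out = {}
    for chain in model.chains:
        cid = chain.chain_id
        knobs = [c for c in contacts
                 if c.knob[0] == cid and c.complementarity == "complementary"]
        if len(knobs) < 2:
            out[cid] = {"register": None, "confidence": 0.0,
                        "status": "unassigned"}
            continue
        phis = crick_angles(model, cid)
        number_to_index = {r.number: i for i, r in enumerate(chain.residues)}
        votes = []   # (residue index, heptad position)
        for c in knobs:
            idx = number_to_index[c.knob[1]]
            phi = phis[idx]
            if 0.0 <= phi < half_step:
                pos = 0                       # a
            elif -half_step <= phi < 0.0:
                pos = 3                       # d
            else:
                continue
            votes.append((idx, pos))
        if len(votes) < 2:
            out[cid] = {"register": None, "confidence": 0.0,
                        "status": "unassigned"}
            continue
        offsets = [(idx - pos) % 7 for idx, pos in votes]
        best_offset = max(set(offsets), key=offsets.count)
        register = "".join(_HEPTAD[(i - best_offset) % 7]
                           for i in range(len(chain.residues)))
        consistent = sum(1 for (idx, pos), off in zip(votes, offsets)
                         if off == best_offset)
        for c in knobs:
            idx = number_to_index[c.knob[1]]
            c.knob_register = register[idx]
        out[cid] = {"register": register,
                    "confidence": consistent / len(votes),
                    "status": "assigned"}
    return out
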