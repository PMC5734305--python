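"""PDB v3.3 read/write over gemmi.

Dialect contract: fixed-column ATOM records, hydroxyproline (HYP) emitted as
HETATM, TER between chains, END at the end; occupancy 1.00 and B-factor 0.00;
1-based residue numbering restarting per chain.  Coordinates survive a
write/read round-trip to the format's 3-decimal precision.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from ._errors import PdbFormatError
from .geometry import Chain, Residue, StructureModel

__all__ = ["write_pdb", "read_pdb", "MAX_RESIDUES_PER_CHAIN"]

MAX_RESIDUES_PER_CHAIN = 9999   # PDB residue-number field width

_HETERO_RESIDUES = {"HYP"}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    raise PdbFormatError(f"cannot infer element for atom {atom_name!r}")


def write_pdb(model: StructureModel, destination: str | Path) -> None:
    """Write the model as PDB; raises PdbFormatError if a chain exceeds the
    residue-number field (serial overflow)."""
    for chain in model.chains:
        if len(chain.residues) > MAX_RESIDUES_PER_CHAIN:
            raise PdbFormatError(
                f"chain {chain.chain_id} has {len(chain.residues)} residues; "
                f"the PDB residue-number field holds at most "
                f"{MAX_RESIDUES_PER_CHAIN}")

    st = gemmi.Structure()
    st.name = "coilforge model"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            gres.het_flag = "H" if res.name in _HETERO_RESIDUES else "A"
            for atom_name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_element_of(atom_name))
                atom.pos = gemmi.Position(*map(float, pos))
                atom.occ = 1.0
                atom.b_iso = 0.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    doc_path = str(destination)
    st.write_pdb(doc_path)


def _prevalidate(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbFormatError(
                f"line {lineno}: coordinate record too short "
                f"({len(line)} chars)")
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PdbFormatError(
                    f"line {lineno}: unparseable {label} coordinate "
                    f"{line[lo:hi]!r}") from None


def read_pdb(source: str | Path) -> StructureModel:
    """Read a PDB file into a StructureModel (first model only).  Malformed
    coordinate records raise PdbFormatError naming the line."""
    path = Path(source)
    try:
        text = path.read_text()
    except OSError as exc:
        raise PdbFormatError(f"cannot read {path}: {exc}") from exc
    _prevalidate(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PdbFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PdbFormatError(f"{path}: no models found")

    chains = []
    for gchain in st[0]:
        residues = []
        for gres in gchain:
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z])
                     for a in gres}
            residues.append(Residue(gres.name, gres.seqid.num, atoms))
        chains.append(Chain(gchain.name, residues))
    if not chains or not any(c.residues for c in chains):
        raise PdbFormatError(f"{path}: no ATOM/HETATM records")
    return StructureModel(chains)
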