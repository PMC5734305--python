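"""Residue-level chemical data: name maps, side-chain topology templates and a
small backbone-independent rotamer library.

Side-chain atoms are described in internal coordinates.  Each template entry
places one atom by a bond length to its parent, a bond angle through the parent
to a second reference atom, and a torsion through parent/reference to a third.
Torsions are either fixed (ring and planar-group closure) or tied to a chi
angle of the active rotamer via ``("chi", index, offset_degrees)``.

The rotamer library holds, per residue type, a short list of chi-angle tuples
ordered by population; the first entry is the default and the remainder are
cycled through during greedy clash resolution.  Values are rounded canonical
rotamer modes, adequate for hermetic model building — the library makes no
claim to reproduce a statistical rotamer distribution.
"""

from __future__ import annotations

ONE_TO_THREE: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    # hydroxyproline: collagen build mode only (enforced by the builder)
    "O": "HYP",
}
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# torsion spec: float (fixed, degrees) or ("chi", k, offset_deg)
Torsion = "float | tuple[str, int, float]"

# CB is placed identically for every non-Gly type: bond CA-CB 1.530 A,
# angle N-CA-CB 110.4 deg, improper torsion C-N-CA-CB fixed at the value
# giving L-chirality.
_CB = ("CB", ("C", "N", "CA"), 1.530, 110.4, -122.6)

# entry: (atom, (tor_ref, ang_ref, parent), bond, angle, torsion)
SIDECHAIN_TEMPLATES: dict[str, list] = {
    "GLY": [],
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi", 0, 0.0))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, ("chi", 0, 0.0))],
    "VAL": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.527, 110.7, ("chi", 0, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.4, ("chi", 0, 122.3))],
    "THR": [_CB,
            ("OG1", ("N", "CA", "CB"), 1.433, 109.5, ("chi", 0, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 111.1, ("chi", 0, -120.5))],
    "ILE": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 0, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 0, -122.6)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.9, ("chi", 1, 0.0))],
    "LEU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.4, ("chi", 1, 122.6))],
    "MET": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 1, 0.0)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.2, ("chi", 2, 0.0))],
    "ASP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 0, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 1, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 1, 180.0))],
    "ASN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 0, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 1, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 1, 180.0))],
    "GLU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 2, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 2, 180.0))],
    "GLN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 1, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 2, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 2, 180.0))],
    "LYS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 1, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.508, 111.9, ("chi", 2, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.486, 111.7, ("chi", 3, 0.0))],
    "ARG": [_CB,
            ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 1, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.460, 112.0, ("chi", 2, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, ("chi", 3, 0.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.492, 113.8, ("chi", 0, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.380, 122.7, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.354, 131.0, ("chi", 1, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.323, 109.2, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
    "PHE": [_CB,
            ("CG", ("N", "CA", "CB"), 1.505, 113.8, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.7, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.391, 120.7, ("chi", 1, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.393, 120.7, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.393, 120.7, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.383, 120.0, 0.0)],
    "TYR": [_CB,
            ("CG", ("N", "CA", "CB"), 1.505, 113.8, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.391, 120.9, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.391, 120.9, ("chi", 1, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.393, 121.1, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.393, 121.1, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 0, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 1, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, ("chi", 1, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.3, 180.0),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.3, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.7, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.4, 0.0)],
    "PRO": [_CB,
            ("CG", ("N", "CA", "CB"), 1.495, 104.2, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.507, 105.5, ("chi", 1, 0.0))],
    "HYP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.495, 104.2, ("chi", 0, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.507, 105.5, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.420, 110.0, ("chi", 1, -120.0))],
}

#: heavy side-chain atoms (incl. CB) per residue type, in placement order
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    name: tuple(entry[0] for entry in tmpl)
    for name, tmpl in SIDECHAIN_TEMPLATES.items()
}

# chi tuples ordered by rotamer population (rounded canonical modes)
ROTAMERS: dict[str, list[tuple[float, ...]]] = {
    "GLY": [()],
    "ALA": [()],
    "SER": [(64.0,), (-65.0,), (180.0,)],
    "CYS": [(-65.0,), (64.0,), (180.0,)],
    "VAL": [(175.0,), (-60.0,), (63.0,)],
    "THR": [(62.0,), (-60.0,), (180.0,)],
    "ILE": [(-65.0, 170.0), (-57.0, -60.0), (62.0, 170.0)],
    "LEU": [(-65.0, 175.0), (177.0, 65.0), (-85.0, 65.0)],
    "MET": [(-65.0, -65.0, -70.0), (-65.0, 180.0, 75.0), (180.0, 180.0, 75.0)],
    "ASP": [(-70.0, -15.0), (-177.0, 0.0), (62.0, 0.0)],
    "ASN": [(-65.0, -20.0), (-177.0, 30.0), (62.0, -10.0)],
    "GLU": [(-65.0, 180.0, -10.0), (-67.0, -65.0, -40.0), (180.0, 65.0, 0.0)],
    "GLN": [(-65.0, 180.0, 0.0), (-67.0, -65.0, -40.0), (180.0, 65.0, 0.0)],
    "LYS": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
            (-90.0, -60.0, 180.0, 180.0)],
    "ARG": [(-65.0, 180.0, 180.0, 180.0), (-67.0, 180.0, -65.0, -85.0),
            (180.0, 180.0, 180.0, 180.0)],
    "HIS": [(-65.0, -70.0), (62.0, -85.0), (180.0, 60.0)],
    "PHE": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TYR": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0)],
    "TRP": [(-65.0, 95.0), (180.0, -105.0), (62.0, -90.0)],
    # pyrrolidine ring: single pucker, chi2 chosen for approximate ring closure
    "PRO": [(-26.0, 38.0)],
    "HYP": [(-26.0, 38.0)],
}


def heavy_atom_count(residue_name: str) -> int:
    """Total heavy atoms (backbone + side chain) for a residue type."""
    if residue_name not in SIDECHAIN_ATOMS:
        raise KeyError(f"unknown residue type {residue_name!r}")
    return len(BACKBONE_ATOMS) + len(SIDECHAIN_ATOMS[residue_name])
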