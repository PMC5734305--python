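"""Inter-chain interaction energy: a soft-core pairwise potential in the
spirit of soft docking force fields.

Three additive terms over inter-chain heavy-atom pairs within a cutoff:

steric
    Finite soft-core: quadratic repulsion inside the contact distance
    (sum of the two atom radii), a shallow attractive well decaying linearly
    to exactly zero at the cutoff outside it.
desolvation
    A linear burial reward for hydrophobic-hydrophobic pairs, also reaching
    exactly zero at the cutoff.
charge
    Screened Coulomb between formal charges (reduced to single side-chain
    atoms: Lys NZ, Arg CZ, Asp CG, Glu CD), damped to zero at the cutoff.

Energies are reported in arbitrary units (a.u.); the functional forms and
constants are a documented stand-in chosen to give a physically sensible
single packing minimum for canonical coiled coils, not a published force
field.  All per-atom parameters live in ``data/forcefield.tsv`` so they can
be swapped without touching code.  Intra-chain pairs are excluded entirely:
this is an *interaction* energy between chains, used as the optimization
objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._errors import ScoringError
from .geometry import StructureModel

__all__ = ["AtomParameters", "EnergyBreakdown", "load_atom_parameters",
           "interaction_energy", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 10.0  # A


@dataclass(frozen=True)
class AtomParameters:
    """Per-(residue, atom) force-field parameters plus the global term
    constants parsed from the table header."""

    radii: dict[tuple[str, str], float]
    hydrophobic: dict[tuple[str, str], bool]
    charges: dict[tuple[str, str], float]
    constants: dict[str, float]


@dataclass
class EnergyBreakdown:
    """Additive decomposition of the inter-chain energy (arbitrary units)."""

    steric: float
    desolvation: float
    charge: float
    pairs: int

    @property
    def total(self) -> float:
        return self.steric + self.desolvation + self.charge


_DEFAULT_PARAMS: AtomParameters | None = None


def load_atom_parameters(path: str | Path | None = None) -> AtomParameters:
    """Parse the force-field table (TSV: residue, atom, radius, hydrophobic,
    charge; ``#set key value`` lines carry the global constants)."""
    if path is None:
        source = resources.files("coilforge").joinpath("data/forcefield.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    radii, hydro, charges, constants = {}, {}, {}, {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#set"):
            _, key, value = line.split()
            constants[key] = float(value)
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ScoringError(
                f"forcefield table line {lineno}: expected 5 fields, got "
                f"{len(fields)}")
        res, atom, radius, hphob, charge = fields
        key = (res, atom)
        radii[key] = float(radius)
        hydro[key] = hphob == "1"
        charges[key] = float(charge)
    return AtomParameters(radii, hydro, charges, constants)


def default_parameters() -> AtomParameters:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_atom_parameters()
    return _DEFAULT_PARAMS


def _gather(model: StructureModel, params: AtomParameters):
    chain_idx, xyz, radius, hydro, charge = [], [], [], [], []
    missing = []
    for ci, chain in enumerate(model.chains):
        for res in chain.residues:
            for atom, pos in res.atoms.items():
                key = (res.name, atom)
                if key not in params.radii:
                    missing.append(key)
                    continue
                chain_idx.append(ci)
                xyz.append(pos)
                radius.append(params.radii[key])
                hydro.append(params.hydrophobic[key])
                charge.append(params.charges[key])
    if missing:
        raise ScoringError(
            "no force-field parameters for atoms: "
            + ", ".join(f"{r}:{a}" for r, a in sorted(set(missing))))
    return (np.array(chain_idx), np.array(xyz, dtype=float),
            np.array(radius), np.array(hydro, dtype=bool), np.array(charge))


def interaction_energy(model: StructureModel,
                       params: AtomParameters | None = None,
                       cutoff: float = DEFAULT_CUTOFF) -> EnergyBreakdown:
    """Sum the soft-core potential over all inter-chain heavy-atom pairs
    within ``cutoff`` Å.  Every term reaches exactly zero at the cutoff, so
    the energy is continuous in the coordinates and exactly zero for chains
    separated beyond it."""
    if len(model.chains) < 2:
        raise ScoringError("interaction energy needs at least two chains")
    if params is None:
        params = default_parameters()
    ci, xyz, rad, hyd, chg = _gather(model, params)

    k_rep = params.constants.get("steric_repulsion", 10.0)
    w_well = params.constants.get("steric_well_depth", 0.05)
    g_desolv = params.constants.get("desolvation_strength", 0.4)
    c_elec = params.constants.get("charge_strength", 15.0)
    d_min = params.constants.get("charge_min_distance", 1.0)

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        inter = ci[pairs[:, 0]] != ci[pairs[:, 1]]
        pairs = pairs[inter]
    if pairs.size == 0:
        return EnergyBreakdown(0.0, 0.0, 0.0, 0)

    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    contact = rad[i] + rad[j]
    contact = np.minimum(contact, 0.99 * cutoff)

    # steric: -w at contact, quadratic inside, linear to 0 at the cutoff
    inside = d < contact
    steric = np.where(
        inside,
        -w_well + k_rep * (contact - d) ** 2,
        -w_well * (cutoff - d) / (cutoff - contact),
    )

    # desolvation: hydrophobic pairs, linear burial reward clamped at contact
    hh = hyd[i] & hyd[j]
    burial = np.clip((cutoff - d) / (cutoff - contact), 0.0, 1.0)
    desolv = np.where(hh, -g_desolv * burial, 0.0)

    # screened charge: qq/d scaled by a quadratic switch that vanishes at
    # the cutoff; distances floored to keep the term finite
    qq = chg[i] * chg[j]
    nz = qq != 0
    coul = np.zeros_like(d)
    dd = np.maximum(d, d_min)
    switch = (1.0 - d / cutoff) ** 2
    coul[nz] = c_elec * qq[nz] / dd[nz] * switch[nz]

    return EnergyBreakdown(float(steric.sum()), float(desolv.sum()),
                           float(coul.sum()), int(len(d)))
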