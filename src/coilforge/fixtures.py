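"""Canonical example assemblies.

Named, complete AssemblySpecs that recreate the classical coiled-coil
topologies (parallel homo-oligomers from dimer to heptamer, an antiparallel
dimer, a slipped heptamer, acidic/basic heterodimers) and homo-/heterotypic
collagen triple helices.  Parameters are rounded values typical of designed
and natural structures of each state; sequences follow the Ile-at-a /
Leu-at-d convention with charged e/g flanks.

These are first-class library objects (and the test fixtures): every one of
them builds, scores and analyzes end to end.
"""

from __future__ import annotations

from dataclasses import replace

from ._errors import ValidationError
from .builder import basic_spec
from .geometry import AssemblySpec, HelixParameters, default_shr, normalize_angle

__all__ = ["fixture_names", "get_fixture"]

_HEPTAD_SEQ = "EIAALKQ"     # g a b c d e f: Ile@a, Leu@d, charged flanks
_HEPTAD_REG = "gabcdef"

# per-state super-helical radii (A) and interface angles (deg); pitch -180 A
# left-handed.  Dimer-tetramer values track known structures; the barrel
# radii sit at this package's own packing optimum, which lies a little wide
# of crystallographic barrels because single-rotamer side chains are bulkier
# than relaxed ones.
_RADII = {2: 4.9, 3: 6.3, 4: 6.8, 5: 8.75, 6: 11.25, 7: 12.5}
_PHI = {2: 26.0, 3: 26.0, 4: 26.0, 5: 13.0, 6: 13.0, 7: 13.0}

_ACIDIC = "EIAALEQ" * 4
_BASIC = "KIAALKQ" * 4
_COLLAGEN_SEQ = "GPO" * 9


def _cc(n: int, heptads: int = 4) -> AssemblySpec:
    return basic_spec(n, _RADII[n], -180.0, _PHI[n], _HEPTAD_SEQ * heptads,
                      _HEPTAD_REG * heptads)


def _advanced(spec: AssemblySpec, per_chain_changes: dict) -> AssemblySpec:
    helices = list(spec.helices)
    for idx, changes in per_chain_changes.items():
        helices[idx] = replace(helices[idx], **changes)
    return AssemblySpec(mode="advanced", fold=spec.fold,
                        oligomer_state=spec.oligomer_state, helices=helices)


def _collagen(sequences: list[str]) -> AssemblySpec:
    helices = [
        HelixParameters(radius=3.0, pitch=85.0, interface_angle=0.0,
                        super_helical_rotation=normalize_angle(default_shr(i + 1, 3)),
                        z_shift=2.86 * i,   # one-residue stagger per strand
                        sequence=seq, register="", helix_index=i + 1)
        for i, seq in enumerate(sequences)
    ]
    return AssemblySpec(mode="advanced", fold="collagen", oligomer_state=3,
                        helices=helices)


def _build_registry() -> dict:
    reg = {
        "cc-di": lambda: _cc(2),
        "cc-tri": lambda: _cc(3),
        "cc-tet": lambda: _cc(4),
        "cc-pent": lambda: _cc(5),
        "cc-hex": lambda: _cc(6),
        "cc-hept": lambda: _cc(7),
        # antiparallel dimers pack best slightly wider and axially offset by
        # about half a helix turn, which interdigitates the a/d seams
        "cc-di-ap": lambda: _advanced(_cc(2), {
            0: {"radius": 5.8},
            1: {"radius": 5.8, "orientation": "antiparallel",
                "z_shift": 3.0}}),
        "cc-hept-slipped": lambda: _advanced(_cc(7), {
            1: {"z_shift": 2.5}}),
        "cc-hetero-a4b4": lambda: _advanced(_cc(2), {
            0: {"sequence": _ACIDIC}, 1: {"sequence": _BASIC}}),
        "cc-hetero-a3b4": lambda: _advanced(_cc(2), {
            0: {"sequence": _ACIDIC[:21], "register": (_HEPTAD_REG * 3)},
            1: {"sequence": _BASIC}}),
        "collagen-homo": lambda: _collagen([_COLLAGEN_SEQ] * 3),
        "collagen-hetero": lambda: _collagen(
            [_COLLAGEN_SEQ, "GPOGAOGPO" * 3, "GPOGPKGEO" * 3]),
    }
    return reg


_REGISTRY = _build_registry()


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def get_fixture(name: str) -> AssemblySpec:
    """Return a fresh AssemblySpec for the named example."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise ValidationError(
            f"unknown example {name!r}; available: {', '.join(fixture_names())}"
        ) from None
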