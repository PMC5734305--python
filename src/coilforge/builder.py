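"""Turn an AssemblySpec into a backbone StructureModel.

Validation, basic-mode symmetry expansion, chain placement and sequence
threading live here; the pure math is in :mod:`coilforge.geometry`.  All
per-helix parameters are defined relative to the super-helical axis, so the
chains are completely decoupled: there is no reference helix.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field, replace

from ._errors import BuildError, ValidationError
from .geometry import (
    ALPHA_MINOR_RADIUS, ALPHA_PHI_STEP, ALPHA_RISE_PER_RESIDUE,
    COLLAGEN_MINOR_RADIUS, COLLAGEN_PHI_STEP, COLLAGEN_RISE_PER_RESIDUE,
    AssemblySpec, HelixParameters, StructureModel, build_collagen_strand,
    build_helix_backbone, default_shr, normalize_angle,
)
from .residues import ONE_TO_THREE

__all__ = ["BuildReport", "basic_spec", "validate_spec", "build_assembly",
           "spec_from_json", "spec_to_json", "chain_id_for"]

_COILED_COIL_LETTERS = set(ONE_TO_THREE) - {"O"}
_COLLAGEN_LETTERS = set(ONE_TO_THREE)
_HEPTAD = "abcdefg"


@dataclass
class BuildReport:
    """What was built: spec echo, per-chain residue counts, warnings (never
    silent fixes) and a snapshot of the geometric constants used."""

    spec: AssemblySpec
    chain_residue_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    constants: dict[str, float] = field(default_factory=dict)


def chain_id_for(index: int) -> str:
    """Chain id for the ``index``-th helix (0-based): A..Z then AA, AB, ..."""
    letters = string.ascii_uppercase
    if index < 26:
        return letters[index]
    index -= 26
    return letters[index // 26] + letters[index % 26]


def basic_spec(oligomer_state: int, radius: float, pitch: float,
               interface_angle: float, sequence: str, register: str = "",
               fold: str = "coiled_coil") -> AssemblySpec:
    """Convenience factory for a basic-mode (symmetric, parallel) spec: one
    parameter set replicated over all helices with the symmetric default
    super-helical rotations."""
    helices = [
        HelixParameters(radius=radius, pitch=pitch,
                        interface_angle=interface_angle,
                        super_helical_rotation=normalize_angle(
                            default_shr(i + 1, oligomer_state)),
                        sequence=sequence, register=register,
                        helix_index=i + 1)
        for i in range(oligomer_state)
    ]
    return AssemblySpec(mode="basic", fold=fold,
                        oligomer_state=oligomer_state, helices=helices)


def _check_sequence(seq: str, fold: str, where: str) -> str:
    seq = seq.upper()
    allowed = _COLLAGEN_LETTERS if fold == "collagen" else _COILED_COIL_LETTERS
    bad = sorted(set(seq) - allowed)
    if bad:
        if "O" in bad and fold != "collagen":
            raise ValidationError(
                f"{where}: residue letter 'O' (hydroxyproline) is allowed in "
                "the collagen build mode only")
        raise ValidationError(f"{where}: unknown residue letters {bad}")
    return seq


def _validate(spec: AssemblySpec) -> tuple[AssemblySpec, list[str]]:
    warnings: list[str] = []
    if spec.oligomer_state < 2:
        raise ValidationError(f"oligomer state must be >= 2, got {spec.oligomer_state}")
    if spec.fold == "collagen" and spec.oligomer_state != 3:
        raise ValidationError("collagen builds are locked to oligomer state 3")
    if not spec.helices:
        raise ValidationError("spec has no helices")
    if len(spec.helices) != spec.oligomer_state:
        raise ValidationError(
            f"{len(spec.helices)} helices for oligomer state {spec.oligomer_state}")

    helices: list[HelixParameters] = []
    for idx, h in enumerate(spec.helices):
        where = f"helix {idx + 1}"
        seq = _check_sequence(h.sequence, spec.fold, where)
        register = h.register
        if spec.fold == "collagen":
            if register:
                raise ValidationError(
                    f"{where}: collagen strands carry no heptad register")
        else:
            if not register:
                reps = (len(seq) + 6) // 7
                register = (_HEPTAD * reps)[: len(seq)]
                warnings.append(
                    f"{where}: no register given; assigned repeating "
                    f"'abcdefg' from the first residue")
            elif len(register) != len(seq):
                raise ValidationError(
                    f"{where}: register length {len(register)} != sequence "
                    f"length {len(seq)}")
        helices.append(replace(h, sequence=seq, register=register,
                               helix_index=idx + 1))

    if spec.mode == "basic":
        first = helices[0]
        for idx, h in enumerate(helices):
            expected_shr = normalize_angle(default_shr(idx + 1, spec.oligomer_state))
            same = (h.radius == first.radius and h.pitch == first.pitch
                    and h.interface_angle == first.interface_angle
                    and h.sequence == first.sequence
                    and h.orientation == "parallel"
                    and abs(normalize_angle(h.super_helical_rotation
                                            - expected_shr)) < 1e-9)
            if not same:
                raise ValidationError(
                    f"basic mode requires identical parallel helices with the "
                    f"symmetric default super-helical rotations; helix "
                    f"{idx + 1} deviates (use advanced mode to break symmetry)")

    out = AssemblySpec(mode=spec.mode, fold=spec.fold,
                       oligomer_state=spec.oligomer_state, helices=helices)
    return out, warnings


def validate_spec(spec: AssemblySpec) -> AssemblySpec:
    """Normalize and validate a spec: sequences upper-cased, registers
    auto-assigned where missing, collagen and basic-mode rules enforced.
    Raises ValidationError on any violation."""
    normalized, _ = _validate(spec)
    return normalized


def build_assembly(spec: AssemblySpec) -> tuple[StructureModel, BuildReport]:
    """Build the full backbone model: one chain per helix, ids A, B, C, ...;
    each chain placed independently with its own parameters."""
    normalized, warnings = _validate(spec)
    chains = []
    counts: dict[str, int] = {}
    for idx, h in enumerate(normalized.helices):
        cid = chain_id_for(idx)
        try:
            if normalized.fold == "collagen":
                sub = build_collagen_strand(h, chain_id=cid)
            else:
                sub = build_helix_backbone(h, chain_id=cid)
        except BuildError as exc:
            raise BuildError(f"chain {cid}: {exc}") from exc
        chains.append(sub.chains[0])
        counts[cid] = len(sub.chains[0].residues)

    constants = {
        "alpha_rise_per_residue": ALPHA_RISE_PER_RESIDUE,
        "alpha_minor_radius": ALPHA_MINOR_RADIUS,
        "alpha_phi_step_deg": ALPHA_PHI_STEP,
        "collagen_rise_per_residue": COLLAGEN_RISE_PER_RESIDUE,
        "collagen_minor_radius": COLLAGEN_MINOR_RADIUS,
        "collagen_phi_step_deg": COLLAGEN_PHI_STEP,
    }
    report = BuildReport(spec=normalized, chain_residue_counts=counts,
                         warnings=warnings, constants=constants)
    return StructureModel(chains), report


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------

_TOP_KEYS = {"mode", "fold", "oligomer_state", "helices"}
_HELIX_KEYS = {"radius", "pitch", "interface_angle", "super_helical_rotation",
               "z_shift", "orientation", "sequence", "register"}
_REQUIRED_HELIX_KEYS = {"radius", "pitch", "sequence"}


def _coerce_number(value, path: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{path}: expected a number, got {value!r}") from None


def spec_from_json(document: str | dict) -> AssemblySpec:
    """Parse the JSON parameter document into an AssemblySpec.

    Unknown keys are rejected with the list of accepted keys; missing
    required keys are named with their path; numeric strings are coerced.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed JSON: {exc}") from None
    if not isinstance(document, dict):
        raise ValidationError("spec document must be a JSON object")

    unknown = set(document) - _TOP_KEYS
    if unknown:
        raise ValidationError(
            f"unknown keys {sorted(unknown)}; accepted keys: {sorted(_TOP_KEYS)}")
    for key in ("oligomer_state", "helices"):
        if key not in document:
            raise ValidationError(f"missing required key {key!r}")

    helices = []
    raw_helices = document["helices"]
    if not isinstance(raw_helices, list) or not raw_helices:
        raise ValidationError("helices: expected a non-empty list")
    for i, raw in enumerate(raw_helices):
        path = f"helices[{i}]"
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: expected an object")
        unknown = set(raw) - _HELIX_KEYS
        if unknown:
            raise ValidationError(
                f"{path}: unknown keys {sorted(unknown)}; accepted keys: "
                f"{sorted(_HELIX_KEYS)}")
        missing = _REQUIRED_HELIX_KEYS - set(raw)
        if missing:
            raise ValidationError(f"{path}: missing required keys {sorted(missing)}")
        helices.append(HelixParameters(
            radius=_coerce_number(raw["radius"], f"{path}.radius"),
            pitch=_coerce_number(raw["pitch"], f"{path}.pitch"),
            interface_angle=_coerce_number(raw.get("interface_angle", 26.0),
                                           f"{path}.interface_angle"),
            super_helical_rotation=_coerce_number(
                raw.get("super_helical_rotation", 0.0),
                f"{path}.super_helical_rotation"),
            z_shift=_coerce_number(raw.get("z_shift", 0.0), f"{path}.z_shift"),
            orientation=raw.get("orientation", "parallel"),
            sequence=str(raw.get("sequence", "")),
            register=str(raw.get("register", "")),
            helix_index=i + 1,
        ))

    return AssemblySpec(
        mode=document.get("mode", "advanced"),
        fold=document.get("fold", "coiled_coil"),
        oligomer_state=int(_coerce_number(document["oligomer_state"],
                                          "oligomer_state")),
        helices=helices,
    )


def spec_to_json(spec: AssemblySpec, indent: int | None = 2) -> str:
    """Serialize a spec to the JSON parameter document (lossless round-trip
    with spec_from_json)."""
    doc = {
        "mode": spec.mode,
        "fold": spec.fold,
        "oligomer_state": spec.oligomer_state,
        "helices": [
            {k: v for k, v in asdict(h).items() if k != "helix_index"}
            for h in spec.helices
        ],
    }
    return json.dumps(doc, indent=indent)
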