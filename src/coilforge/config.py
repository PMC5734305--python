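"""Optional TOML configuration.

A config file can override the force-field table path, optimizer defaults
and the collagen minor-helix constants::

    [forcefield]
    table = "/path/to/forcefield.tsv"

    [optimizer]
    steps = 800
    temperature = 5.0
    seed = 1

    [collagen]
    rise_per_residue = 2.86
    minor_radius = 1.60
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from . import geometry
from ._errors import ValidationError

__all__ = ["load_config", "apply_collagen_overrides"]

_SECTIONS = {"forcefield", "optimizer", "collagen"}


def load_config(path: str | Path) -> dict:
    try:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise ValidationError(f"cannot read config {path}: {exc}") from exc
    unknown = set(doc) - _SECTIONS
    if unknown:
        raise ValidationError(
            f"unknown config sections {sorted(unknown)}; accepted: "
            f"{sorted(_SECTIONS)}")
    return doc


def apply_collagen_overrides(section: dict) -> None:
    """Override the collagen strand constants for subsequent builds."""
    mapping = {"rise_per_residue": "COLLAGEN_RISE_PER_RESIDUE",
               "minor_radius": "COLLAGEN_MINOR_RADIUS",
               "phi_step_deg": "COLLAGEN_PHI_STEP"}
    for key, value in section.items():
        if key not in mapping:
            raise ValidationError(
                f"unknown collagen constant {key!r}; accepted: "
                f"{sorted(mapping)}")
        setattr(geometry, mapping[key], float(value))
    if "minor_radius" in section:
        scale = float(section["minor_radius"]) / 1.60
        geometry.COLLAGEN_BACKBONE_OFFSETS = {
            name: (r * scale, dphi, dz)
            for name, (r, dphi, dz) in geometry.COLLAGEN_BACKBONE_OFFSETS.items()
        }
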