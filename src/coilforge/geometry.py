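"""Crick-style parametric geometry for coiled coils and collagen triple helices.

A coiled coil is described by a small set of parameters per helix: the
super-helical radius r (Å), the pitch P (Å, one full turn of the super helix;
its sign encodes handedness, negative = left-handed), the interface angle
(the Crick angle φCα of the reference heptad-``a`` residue, degrees), a
super-helical rotation about the assembly axis, an axial z-shift, and the
helix orientation.  Backbone atoms are placed on minor helices wound about the
super-helical path: each atom type carries fixed cylindrical offsets (radius,
phase, axial shift) relative to the Cα minor helix, frozen from an ideal
α-helix (or polyproline-II strand for collagen) built from standard internal
coordinates.

The module also measures those parameters back from coordinates
(`measure_parameters`), which is the package's central self-consistency
check: ``measure(build(p)) ≈ p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import AnalysisError, BuildError, DomainError, ValidationError
from .residues import ONE_TO_THREE

__all__ = [
    "HelixParameters", "AssemblySpec", "Residue", "Chain", "StructureModel",
    "MeasuredParameters", "default_shr", "pitch_angle", "superhelix_point",
    "build_helix_backbone", "build_collagen_strand", "measure_parameters",
    "crick_angles", "normalize_angle",
]

# ---------------------------------------------------------------------------
# Minor-helix constants.
#
# Alpha helix: rise per residue along the minor-helix axis, minor radius, and
# the per-residue Crick-angle advance.  The advance is fixed at 720/7 deg so a
# heptad spans exactly two minor-helix turns, the convention that aligns the
# a/d positions into a continuous hydrophobic seam.  Per-atom offsets were
# obtained by building an ideal alpha helix (phi=-57.8, psi=-47.0) from
# standard internal coordinates, fitting its axis, and expressing each
# backbone atom in cylindrical coordinates relative to the Calpha helix;
# radii are scaled so the Calpha minor radius is exactly 2.26 A.
# ---------------------------------------------------------------------------

ALPHA_RISE_PER_RESIDUE = 1.495       # A, along the minor-helix axis
ALPHA_MINOR_RADIUS = 2.26            # A, Calpha
ALPHA_RESIDUES_PER_TURN = 3.617      # uncoiled limit, documentation constant
ALPHA_PHI_STEP = 720.0 / 7.0         # deg per residue about the minor axis

# atom -> (minor radius A, phase offset deg vs CA, axial offset A vs CA)
ALPHA_BACKBONE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "N":  (1.544, -26.78, -0.913),
    "CA": (2.260,   0.00,  0.000),
    "C":  (1.662,  26.84,  1.064),
    "O":  (1.919,  20.53,  2.250),
}

# Collagen strand: left-handed polyproline-II-like minor helix with 7/2
# symmetry (720/7 deg per residue, opposite sense to the alpha helix) and a
# rise of 2.86 A per residue.  The minor radius 1.60 A is chosen so that the
# consecutive Calpha-Calpha distance is ~3.80 A at that rise and twist; the
# N/C/O offsets come from the same fitting procedure applied to an ideal
# PPII strand (phi=-75, psi=+160), radii scaled to the 1.60 A Calpha radius.
COLLAGEN_RISE_PER_RESIDUE = 2.86
COLLAGEN_MINOR_RADIUS = 1.60
COLLAGEN_PHI_STEP = -720.0 / 7.0

COLLAGEN_BACKBONE_OFFSETS: dict[str, tuple[float, float, float]] = {
    "N":  (1.397,  42.50, -1.111),
    "CA": (1.600,   0.00,  0.000),
    "C":  (0.405, -14.89,  1.115),
    "O":  (1.094, 127.59,  1.194),
}

#: fitted |pitch| above this is reported as "no supercoiling detected"
PITCH_CEILING = 1500.0  # A

_HEPTAD = "abcdefg"


def normalize_angle(angle_deg: float) -> float:
    """Map an angle in degrees onto [-180, 180)."""
    return (float(angle_deg) + 180.0) % 360.0 - 180.0


def default_shr(i: int, n: int) -> float:
    """Default super-helical rotation (degrees, on [0, 360)) of helix ``i``
    in a symmetric ``n``-helix bundle: (i - 1) * 360 / n.

    Helix indices are 1-based; e.g. helix 1 of any bundle sits at 0° and
    helix 3 of a tetramer at 180°.
    """
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise DomainError(f"oligomer state n must be an integer >= 2, got {n!r}")
    if not isinstance(i, (int, np.integer)) or not 1 <= i <= n:
        raise DomainError(f"helix index i must satisfy 1 <= i <= n={n}, got {i!r}")
    return ((i - 1) * 360.0 / n) % 360.0


def pitch_angle(radius: float, pitch: float) -> float:
    """Pitch angle α = atan(2π r / |P|) in degrees, signed like the pitch."""
    if radius <= 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    if pitch == 0:
        raise DomainError("pitch must be nonzero (sign encodes handedness)")
    return math.copysign(math.degrees(math.atan(2 * math.pi * radius / abs(pitch))), pitch)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_ORIENTATIONS = ("parallel", "antiparallel")


@dataclass
class HelixParameters:
    """Crick parameters plus sequence/register for one helix (or collagen
    strand).

    radius, pitch and z_shift are in Å; interface_angle and
    super_helical_rotation in degrees (normalized to [-180, 180) on
    construction).  ``helix_index`` is the 1-based symbol *i* used by the
    symmetric super-helical-rotation default.
    """

    radius: float
    pitch: float
    interface_angle: float = 26.0
    super_helical_rotation: float = 0.0
    z_shift: float = 0.0
    orientation: str = "parallel"
    sequence: str = ""
    register: str = ""
    helix_index: int = 1

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError(f"radius must be > 0 A, got {self.radius}")
        if self.pitch == 0:
            raise ValidationError("pitch must be nonzero")
        if self.orientation not in _ORIENTATIONS:
            raise ValidationError(
                f"orientation must be one of {_ORIENTATIONS}, got {self.orientation!r}")
        if self.helix_index < 1:
            raise ValidationError(f"helix_index must be >= 1, got {self.helix_index}")
        self.interface_angle = normalize_angle(self.interface_angle)
        self.super_helical_rotation = normalize_angle(self.super_helical_rotation)
        if self.register:
            bad = set(self.register) - set(_HEPTAD)
            if bad:
                raise ValidationError(
                    f"register may only contain a-g, found {sorted(bad)}")
            if self.sequence and len(self.register) != len(self.sequence):
                raise ValidationError(
                    f"register length {len(self.register)} != sequence length "
                    f"{len(self.sequence)}")


@dataclass
class AssemblySpec:
    """A complete build request: mode, fold, oligomer state and one
    HelixParameters per helix."""

    mode: str = "basic"                 # "basic" | "advanced"
    fold: str = "coiled_coil"           # "coiled_coil" | "collagen"
    oligomer_state: int = 2
    helices: list[HelixParameters] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("basic", "advanced"):
            raise ValidationError(f"mode must be basic|advanced, got {self.mode!r}")
        if self.fold not in ("coiled_coil", "collagen"):
            raise ValidationError(
                f"fold must be coiled_coil|collagen, got {self.fold!r}")
        if self.oligomer_state < 2:
            raise ValidationError(
                f"oligomer state must be >= 2, got {self.oligomer_state}")
        if self.fold == "collagen" and self.oligomer_state != 3:
            raise ValidationError(
                "collagen mode requires oligomer state 3 "
                f"(got {self.oligomer_state}); the triple helix is locked to 3 chains")
        if self.helices and len(self.helices) != self.oligomer_state:
            raise ValidationError(
                f"{len(self.helices)} helices given for oligomer state "
                f"{self.oligomer_state}")


@dataclass
class Residue:
    name: str                       # three-letter code
    number: int                     # 1-based within chain
    atoms: dict[str, np.ndarray]    # atom name -> xyz (A)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))

    def sidechain_atoms(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.atoms.items()
                if k not in ("N", "CA", "C", "O", "OXT")}


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])


@dataclass
class StructureModel:
    """Chains → residues → named atoms with coordinates in Å.

    The build product and the input of every analysis.  The frame is
    right-handed with the super-helical axis along +z for freshly built
    models; analyses must not rely on that (rigid-motion invariance).
    """

    chains: list[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def atom_table(self):
        """Flat arrays: (chain_index, residue_index, atom_name) rows and an
        (N, 3) coordinate array."""
        rows, xyz = [], []
        for ci, chain in enumerate(self.chains):
            for ri, res in enumerate(chain.residues):
                for name, pos in res.atoms.items():
                    rows.append((ci, ri, name))
                    xyz.append(pos)
        return rows, np.asarray(xyz, dtype=float)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "StructureModel":
        """Return a rigidly transformed copy (rotation applied first)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        out = []
        for chain in self.chains:
            residues = [
                Residue(r.name, r.number,
                        {a: R @ p + t for a, p in r.atoms.items()})
                for r in chain.residues
            ]
            out.append(Chain(chain.chain_id, residues))
        return StructureModel(out)

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def is_backbone_only(self) -> bool:
        return all(not r.sidechain_atoms()
                   for c in self.chains for r in c.residues)


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def superhelix_point(z: float, params: HelixParameters) -> np.ndarray:
    """Point on the super-helical path at axial coordinate ``z`` (Å, before
    z-shift): x = r cosθ, y = r sinθ with θ = shr + 2π z / P; the returned z
    is translated by the helix's z_shift."""
    theta = math.radians(params.super_helical_rotation) + 2 * math.pi * z / params.pitch
    return np.array([params.radius * math.cos(theta),
                     params.radius * math.sin(theta),
                     z + params.z_shift])


def _resolve_names(params: HelixParameters, n_residues: int) -> list[str]:
    if params.sequence:
        if len(params.sequence) != n_residues:
            raise BuildError(
                f"sequence length {len(params.sequence)} != n_residues {n_residues}")
        try:
            return [ONE_TO_THREE[c] for c in params.sequence.upper()]
        except KeyError as exc:
            raise BuildError(f"unknown residue letter {exc.args[0]!r}") from None
    return ["ALA"] * n_residues


def _strand_coordinates(params: HelixParameters, n_residues: int, rise: float,
                        phi_step_deg: float, offsets: dict[str, tuple[float, float, float]],
                        minor_radius_scale: float = 1.0) -> dict[str, np.ndarray]:
    """Backbone atom coordinates for one chain, parallel convention, before
    orientation flip / super-helical rotation / z-shift.

    Each atom type lies on its own minor helix about the super-helical path;
    the path is parameterized by arc length s so atom axial offsets stay
    metrically correct for any pitch.
    """
    r0 = params.radius
    alpha = math.atan(2 * math.pi * r0 / abs(params.pitch))
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    sgn = 1.0 if params.pitch > 0 else -1.0
    # minor-helix phase of the Calpha of residue t; the interface angle is the
    # phase of the reference register-'a' residue
    t_ref = params.register.find("a") if params.register else 0
    if t_ref < 0:
        t_ref = 0
    t = np.arange(n_residues, dtype=float)
    psi_ca = np.radians(params.interface_angle + (t - t_ref) * phi_step_deg)

    out: dict[str, np.ndarray] = {}
    for name, (ra, dphi, dz) in offsets.items():
        s = t * rise + dz                     # arc length along the minor axis
        z = s * cos_a                         # axial coordinate
        theta = 2 * math.pi * z / params.pitch
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        # local frame on the path: inward normal n, binormal b = T x n
        nx, ny = -cos_t, -sin_t
        bx, by, bz = cos_a * sin_t, -cos_a * cos_t, sin_a * sgn
        psi = psi_ca + math.radians(dphi)
        ra_s = ra * minor_radius_scale
        cp, sp = np.cos(psi), np.sin(psi)
        x = r0 * cos_t + ra_s * (cp * nx + sp * bx)
        y = r0 * sin_t + ra_s * (cp * ny + sp * by)
        zz = z + ra_s * sp * bz
        out[name] = np.column_stack([x, y, zz])
    return out

def _assemble_chain(params: HelixParameters, n_residues: int, rise: float,
                    phi_step_deg: float,
                    offsets: dict[str, tuple[float, float, float]],
                    chain_id: str = "A") -> StructureModel:
    names = _resolve_names(params, n_residues)
    coords = _strand_coordinates(params, n_residues, rise, phi_step_deg, offsets)
    alpha = math.atan(2 * math.pi * params.radius / abs(params.pitch))
    span = (n_residues - 1) * rise * math.cos(alpha)

    stack = np.stack([coords[a] for a in offsets], axis=1)  # (nres, natom, 3)
    if params.orientation == "antiparallel":
        # proper 180-deg rotation about x: chirality preserved, axial
        # direction reversed; then shift so the chain occupies [0, span]
        # with its N terminus at the top of the z range
        stack = stack * np.array([1.0, -1.0, -1.0])
        stack[..., 2] += span
    shr = math.radians(params.super_helical_rotation)
    c, s = math.cos(shr), math.sin(shr)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    stack = stack @ R.T
    stack[..., 2] += params.z_shift

    atom_names = list(offsets)
    residues = [
        Residue(names[i], i + 1,
                {a: stack[i, j].copy() for j, a in enumerate(atom_names)})
        for i in range(n_residues)
    ]
    return StructureModel([Chain(chain_id, residues)])


def build_helix_backbone(params: HelixParameters, n_residues: int | None = None,
                         chain_id: str = "A") -> StructureModel:
    """Build one α-helical chain (backbone N/CA/C/O only) on the
    super-helical path defined by ``params``.

    ``n_residues`` defaults to the sequence length; at least 4 residues are
    required (the carbonyl-oxygen placement and the smallest knobs-into-holes
    hole both need that much context).
    """
    if n_residues is None:
        n_residues = len(params.sequence)
    if n_residues < 4:
        raise BuildError(f"an alpha-helical chain needs >= 4 residues, got {n_residues}")
    return _assemble_chain(params, n_residues, ALPHA_RISE_PER_RESIDUE,
                           ALPHA_PHI_STEP, ALPHA_BACKBONE_OFFSETS, chain_id)


def build_collagen_strand(params: HelixParameters, n_residues: int | None = None,
                          chain_id: str = "A") -> StructureModel:
    """Build one collagen strand (backbone only): a left-handed PPII-like
    minor helix wound on the (conventionally right-handed) triple-helical
    path."""
    if n_residues is None:
        n_residues = len(params.sequence)
    if n_residues < 3:
        raise BuildError(f"a collagen strand needs >= 3 residues, got {n_residues}")
    return _assemble_chain(params, n_residues, COLLAGEN_RISE_PER_RESIDUE,
                           COLLAGEN_PHI_STEP, COLLAGEN_BACKBONE_OFFSETS, chain_id)


# ---------------------------------------------------------------------------
# Measuring parameters back from coordinates
# ---------------------------------------------------------------------------

@dataclass
class MeasuredParameters:
    """Result of fitting super-helical parameters to a chain."""

    radius: float                   # A
    pitch: float                    # A, signed; +/- inf when undetectable
    interface_angle: float | None   # deg, Crick angle of the reference residue
    supercoiling_detected: bool
    residuals: dict

    def __str__(self) -> str:  # pragma: no cover - convenience only
        if not self.supercoiling_detected:
            return f"radius {self.radius:.2f} A, no supercoiling detected"
        return (f"radius {self.radius:.2f} A, pitch {self.pitch:.1f} A, "
                f"interface angle {self.interface_angle:.1f} deg")


_SMOOTH_WINDOW = 7  # one heptad: cancels the minor helix exactly (two turns)


def _smoothed_axis_points(ca: np.ndarray) -> np.ndarray:
    """Running 7-residue mean of Cα positions.  Because a heptad spans two
    full minor-helix turns, the minor-helix component cancels and the result
    tracks the super-helical path."""
    n = len(ca)
    if n < _SMOOTH_WINDOW + 1:
        raise AnalysisError(
            f"need >= {_SMOOTH_WINDOW + 1} residues to trace the axis, got {n}")
    kernel = np.full(_SMOOTH_WINDOW, 1.0 / _SMOOTH_WINDOW)
    out = np.empty((n - _SMOOTH_WINDOW + 1, 3))
    for k in range(3):
        out[:, k] = np.convolve(ca[:, k], kernel, mode="valid")
    return out


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _cylinder_fit(pts: np.ndarray, d0: np.ndarray):
    """Least-squares cylinder through ``pts`` seeded with axis direction
    ``d0``; returns (center, unit direction, cost)."""
    from scipy.optimize import least_squares

    d0 = d0 / np.linalg.norm(d0)
    e1, e2 = _orthonormal_frame(d0)
    centroid = pts.mean(axis=0)
    X = pts - centroid

    def unpack(x):
        a, b, u, v = x[:4]
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        c = centroid + u * e1 + v * e2
        return c, d, x[4]

    def resid(x):
        c, d, r = unpack(x)
        rel = pts - c
        radial = rel - np.outer(rel @ d, d)
        return np.linalg.norm(radial, axis=1) - r

    # seed the center with an algebraic (Kasa) circle fit of the projected
    # points, otherwise the optimizer can start far off-axis (the centroid of
    # an antiparallel bundle is displaced) and stall in a tilted minimum
    u0, v0 = X @ e1, X @ e2
    A = np.column_stack([2 * u0, 2 * v0, np.ones_like(u0)])
    sol_k, *_ = np.linalg.lstsq(A, u0 ** 2 + v0 ** 2, rcond=None)
    uc, vc = float(sol_k[0]), float(sol_k[1])
    r_seed = float(np.sqrt(max(sol_k[2] + uc ** 2 + vc ** 2, 1e-12)))
    sol = least_squares(resid, x0=[0.0, 0.0, uc, vc, r_seed],
                        max_nfev=200)
    c, d, _ = unpack(sol.x)
    if d[2] < 0:
        d = -d
    return c, d, float(np.sum(sol.fun ** 2))


def _global_axis(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Super-helical axis as (point, unit direction).

    The heptad-smoothed Cα points of every chain lie on a common cylinder of
    radius r about the super-helical axis; the axis is recovered by a
    least-squares cylinder fit.  Two seeds are tried — the principal axis of
    the smoothed cloud and the mean chain-chord direction (whose tangential
    tilts cancel across a symmetric bundle) — and the better fit wins.  This
    stays well-conditioned for wide assemblies whose radial spread rivals
    their axial extent, where plain PCA picks the wrong direction.
    """
    per_chain = [_smoothed_axis_points(c.ca_coords()) for c in model.chains]
    pts = np.vstack(per_chain)
    centroid = pts.mean(axis=0)
    X = pts - centroid
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    seed_pca = Vt[0]

    chords = []
    ref = per_chain[0][-1] - per_chain[0][0]
    for sm in per_chain:
        chord = sm[-1] - sm[0]
        chords.append(chord if chord @ ref >= 0 else -chord)
    seed_chord = np.sum(chords, axis=0)

    # curvature seed: second differences of the smoothed points are radial
    # (perpendicular to the axis) for a helical path, so the axis is their
    # smallest principal direction — robust even when chain-chord tilts add
    # up (antiparallel bundles) instead of cancelling
    curv = np.vstack([sm[2:] - 2 * sm[1:-1] + sm[:-2]
                      for sm in per_chain if len(sm) >= 3])
    seed_curv = None
    if len(curv) >= 3:
        _, sv, Vc = np.linalg.svd(curv, full_matrices=False)
        if sv[1] > 1e-9 * max(sv[0], 1e-30):
            seed_curv = Vc[-1]

    best = None
    for seed in (seed_pca, seed_chord, seed_curv):
        if seed is None:
            continue
        if np.linalg.norm(seed) < 1e-8:
            continue
        fit = _cylinder_fit(pts, seed)
        if best is None or fit[2] < best[2]:
            best = fit
    center, d, _ = best
    return center, d


def _chain_fit(ca: np.ndarray, center: np.ndarray, d: np.ndarray):
    """Fit (radius, pitch, phase at z=0) of one chain about a given axis.

    Returns (radius, pitch, theta0, direction_sign, rms_residual).  The
    radius is de-attenuated for the 7-residue smoothing window.
    """
    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    sm = _smoothed_axis_points(ca)
    rel = sm - center
    z = rel @ d
    u, v = rel @ e1, rel @ e2
    r_smooth = float(np.hypot(u, v).mean())
    phi = np.unwrap(np.arctan2(v, u))
    # direction of chain progression along the axis
    zca = (ca - center) @ d
    direction = 1.0 if zca[-1] >= zca[0] else -1.0

    if len(z) >= 2 and np.ptp(z) > 1e-9:
        A = np.column_stack([z, np.ones_like(z)])
        (slope, intercept), res_arr, *_ = np.linalg.lstsq(A, phi, rcond=None)
        rms = math.sqrt(res_arr[0] / len(z)) if res_arr.size else 0.0
    else:
        slope, intercept, rms = 0.0, float(phi.mean()), 0.0

    if abs(slope) < 2 * math.pi / (PITCH_CEILING * 10) or r_smooth < 0.4:
        return r_smooth, math.inf, intercept, direction, rms

    pitch = 2 * math.pi / slope
    # de-attenuate the smoothing: a window of w residues with axial spacing dz
    # shrinks the apparent super-helical radius by sin(w q/2)/(w sin(q/2)),
    # q = 2 pi dz / P
    dz = float(np.abs(np.diff(zca)).mean())
    q = 2 * math.pi * dz / abs(pitch)
    w = _SMOOTH_WINDOW
    atten = math.sin(w * q / 2) / (w * math.sin(q / 2)) if q > 1e-9 else 1.0
    radius = r_smooth / max(atten, 0.2)

    # Refine (r, P, theta0) against the smoothed points using a model that is
    # itself smoothed the same way, which removes the residual curvature bias
    # of the analytic de-attenuation at strong supercoiling.
    from scipy.optimize import least_squares

    obs = sm
    w_idx = np.arange(_SMOOTH_WINDOW)

    def model_points(r_fit, p_fit, th0):
        th = th0 + 2 * math.pi * zca[:, None] / p_fit  # per-residue azimuth
        path = (r_fit * (np.cos(th) * e1 + np.sin(th) * e2)
                + zca[:, None] * d + center)
        return np.stack([path[k + w_idx].mean(axis=0)
                         for k in range(len(obs))])

    def resid(x):
        return (model_points(*x) - obs).ravel()

    try:
        sol = least_squares(resid, x0=[radius, pitch, intercept], max_nfev=100)
        radius, pitch, intercept = map(float, sol.x)
        rms = math.sqrt(np.mean(sol.fun ** 2))
    except Exception:
        pass  # keep the analytic estimates
    return radius, pitch, intercept, direction, rms


def crick_angles(model: StructureModel, chain_id: str) -> np.ndarray:
    """Per-residue Crick angle (degrees, [-180, 180)) of a chain's Cα atoms
    about the fitted global super-helical axis.

    Zero points at the axis ("inward"); the sign convention follows the local
    frame built from the chain's own direction of propagation, which makes
    the values rigid-motion invariant and orientation-independent.
    """
    center, d = _global_axis(model)
    ca = model.chain(chain_id).ca_coords()
    radius, pitch, theta0, direction, _ = _chain_fit(ca, center, d)

    e1 = np.cross(d, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(d, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    rel = ca - center
    z = rel @ d
    out = np.empty(len(ca))
    slope = 0.0 if not math.isfinite(pitch) else 2 * math.pi / pitch
    for i in range(len(ca)):
        theta = theta0 + slope * z[i]
        radial = math.cos(theta) * e1 + math.sin(theta) * e2
        path_pt = center + radius * radial + z[i] * d
        # tangent along the chain direction
        t_vec = (-radius * slope * math.sin(theta) * e1
                 + radius * slope * math.cos(theta) * e2 + d) * direction
        t_vec /= np.linalg.norm(t_vec)
        n_vec = -radial
        n_vec -= (n_vec @ t_vec) * t_vec
        n_vec /= np.linalg.norm(n_vec)
        b_vec = np.cross(t_vec, n_vec)
        vv = ca[i] - path_pt
        out[i] = math.degrees(math.atan2(vv @ b_vec, vv @ n_vec))
    return out


def measure_parameters(model: StructureModel, chain_id: str | None = None,
                       register: str | None = None) -> MeasuredParameters:
    """Fit super-helical radius, pitch and interface angle of one chain.

    The axis is the principal axis of the heptad-smoothed Cα cloud over all
    chains; the radius is the mean axis distance of the smoothed points
    (de-attenuated for the smoothing window), the pitch comes from the axial
    period of the azimuthal advance, and the interface angle is the circular
    mean Crick angle referred to the reference register-``a`` residue (the
    first residue when no register is given).

    A fitted |pitch| above ``PITCH_CEILING`` (or a vanishing super-helical
    radius) is reported as "no supercoiling detected": pitch is ±inf and the
    interface angle is still referred to the minor-helix phase.
    """
    if not model.chains:
        raise AnalysisError("empty model")
    if chain_id is None:
        chain_id = model.chains[0].chain_id
    chain = model.chain(chain_id)
    if len(chain.residues) < 14:
        raise AnalysisError(
            f"chain {chain_id} has {len(chain.residues)} residues; "
            "need at least two heptads (14) to fit parameters")
    center, d = _global_axis(model)
    ca = chain.ca_coords()
    radius, pitch, _, _, rms = _chain_fit(ca, center, d)
    detected = math.isfinite(pitch) and abs(pitch) <= PITCH_CEILING

    # Crick angle of the reference residue, averaged over all residues after
    # removing the ideal per-residue advance (robust to end effects)
    phis = crick_angles(model, chain_id)
    t_ref = register.find("a") if register else 0
    if t_ref < 0:
        t_ref = 0
    t = np.arange(len(phis))
    dev = np.radians(phis - (t - t_ref) * ALPHA_PHI_STEP)
    interface = math.degrees(math.atan2(np.sin(dev).mean(), np.cos(dev).mean()))
    resultant = float(np.hypot(np.sin(dev).mean(), np.cos(dev).mean()))

    return MeasuredParameters(
        radius=float(radius),
        pitch=float(pitch) if detected else math.copysign(math.inf, pitch),
        interface_angle=normalize_angle(interface),
        supercoiling_detected=detected,
        residuals={
            "azimuth_fit_rms_rad": float(rms),
            "crick_angle_resultant": resultant,
        },
    )


def replace_parameters(params: HelixParameters, **changes) -> HelixParameters:
    """Functional update helper (dataclasses.replace with validation)."""
    return replace(params, **changes)
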