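"""Metropolis Monte Carlo optimization of coiled-coil parameters and
oligomer-state scanning.

Each step perturbs one uniformly chosen parameter of a basic-mode (symmetric)
assembly by a Gaussian step, clamps it to its bounds, rebuilds the model end
to end (backbone → ideal-rotamer side chains → inter-chain energy) and applies
the Metropolis criterion: downhill moves are always accepted, uphill moves
with probability exp(-ΔE/T).  Everything is reproducible from the seed.

The oligomer-state scan repeats the optimization for each candidate state n
(with a few seeded restarts) and predicts the state with the lowest *mean
interface energy*: the best total divided by the number of chain pairs that
actually interact (any atom pair within the scoring cutoff).  A pairwise-
additive potential rewards every additional neighbour, so raw totals — and
even per-helix totals — grow mechanically with n; dividing by the number of
live interfaces compares packing quality instead of interface count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import OptimizationError
from .builder import basic_spec, build_assembly
from .geometry import AssemblySpec, normalize_angle
from .scoring import interaction_energy
from .sidechains import place_sidechains

__all__ = ["OptimizerConfig", "OptimizationResult", "ScanRow", "ScanResult",
           "optimize", "scan_oligomer_states", "MAX_OPTIMIZATION_RESIDUES"]

#: default cap on the total residue count of an optimization request
MAX_OPTIMIZATION_RESIDUES = 300

_DEFAULT_STEPS = {"radius": 0.3, "pitch": 10.0, "interface_angle": 5.0,
                  "z_shift": 0.5}
_DEFAULT_BOUNDS = {"radius": (3.0, 16.0), "pitch": (60.0, 1000.0),
                   "interface_angle": (-180.0, 180.0), "z_shift": (-10.0, 10.0)}


@dataclass
class OptimizerConfig:
    """Metropolis MC settings.

    ``temperature`` is in the same arbitrary units as the energy.  ``pitch``
    bounds apply to the magnitude; the sign (supercoil handedness) of the
    starting spec is preserved.  ``max_residues`` defaults to 300 total
    across the assembly; pass ``None`` to lift the cap for local runs.
    """

    steps: int = 500
    temperature: float = 5.0
    linear_cooling: bool = False
    step_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_STEPS))
    bounds: dict = field(default_factory=lambda: dict(_DEFAULT_BOUNDS))
    parameters: tuple = ("radius", "pitch", "interface_angle")
    seed: int = 0
    max_residues: int | None = MAX_OPTIMIZATION_RESIDUES
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise OptimizationError(f"steps must be >= 1, got {self.steps}")
        for name in self.parameters:
            if name not in self.step_sizes:
                raise OptimizationError(f"no step size for parameter {name!r}")
            if self.step_sizes[name] <= 0:
                raise OptimizationError(f"step size for {name!r} must be > 0")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise OptimizationError(f"bounds for {name!r} must be finite")


@dataclass
class OptimizationResult:
    best_parameters: dict
    best_energy: float
    initial_energy: float
    trace: list            # (step, parameter, proposed_delta_e, accepted)
    seed: int
    models_evaluated: int


@dataclass
class ScanRow:
    oligomer_state: int
    best_energy: float
    interacting_pairs: int
    energy_per_interface: float
    best_parameters: dict


@dataclass
class ScanResult:
    rows: list
    predicted_state: int
    seed: int


def metropolis_accept(delta_e: float, temperature: float, rng) -> bool:
    """The Metropolis criterion: accept downhill moves always, uphill moves
    with probability exp(-ΔE/T).  At T = 0 only downhill moves pass."""
    if delta_e <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < math.exp(-delta_e / temperature))


def _spec_parameters(spec: AssemblySpec) -> dict:
    h = spec.helices[0]
    return {"radius": h.radius, "pitch": h.pitch,
            "interface_angle": h.interface_angle, "z_shift": h.z_shift}


def _rebuild(spec: AssemblySpec, values: dict) -> float:
    h0 = spec.helices[0]
    new = basic_spec(spec.oligomer_state, values["radius"], values["pitch"],
                     values["interface_angle"], h0.sequence, h0.register,
                     fold=spec.fold)
    if values.get("z_shift"):
        new = AssemblySpec(
            mode=new.mode, fold=new.fold, oligomer_state=new.oligomer_state,
            helices=[replace(h, z_shift=values["z_shift"]) for h in new.helices])
    model, _ = build_assembly(new)
    allatom = place_sidechains(model)
    return interaction_energy(allatom).total


def _clamp(name: str, value: float, bounds: dict, pitch_sign: float) -> float:
    lo, hi = bounds[name]
    if name == "pitch":
        return pitch_sign * min(max(abs(value), lo), hi)
    if name == "interface_angle":
        return normalize_angle(value)
    return min(max(value, lo), hi)


def optimize(spec: AssemblySpec, config: OptimizerConfig) -> OptimizationResult:
    """Metropolis MC over the shared Crick parameters of a basic-mode spec.

    Raises OptimizationError for advanced-mode specs (symmetry is required so
    one parameter vector describes the whole assembly) and for requests whose
    total residue count exceeds ``config.max_residues``.
    """
    if spec.mode != "basic":
        raise OptimizationError(
            "optimization is restricted to basic-mode (symmetric) models; "
            "rebuild the request in basic mode or optimize parameters "
            "manually in advanced mode")
    total = sum(len(h.sequence) for h in spec.helices)
    if config.max_residues is not None and total > config.max_residues:
        raise OptimizationError(
            f"assembly has {total} residues, above the optimization cap of "
            f"{config.max_residues}; raise or disable max_residues to run "
            "larger jobs locally")

    rng = np.random.default_rng(config.seed)
    pitch_sign = math.copysign(1.0, spec.helices[0].pitch)
    current = _spec_parameters(spec)
    current_e = _rebuild(spec, current)
    initial_e = current_e
    best, best_e = dict(current), current_e
    trace = []
    evaluated = 1

    for step in range(config.steps):
        temp = config.temperature
        if config.linear_cooling:
            temp = config.temperature * max(1.0 - step / config.steps, 0.05)
        name = config.parameters[rng.integers(len(config.parameters))]
        proposal = dict(current)
        proposal[name] = _clamp(name,
                                proposal[name]
                                + rng.normal(0.0, config.step_sizes[name]),
                                config.bounds, pitch_sign)
        prop_e = _rebuild(spec, proposal)
        evaluated += 1
        delta = prop_e - current_e
        accept = metropolis_accept(delta, temp, rng)
        trace.append((step, name, float(delta), bool(accept)))
        if accept:
            current, current_e = proposal, prop_e
            if current_e < best_e:
                best, best_e = dict(current), current_e

    return OptimizationResult(best_parameters=best, best_energy=float(best_e),
                              initial_energy=float(initial_e), trace=trace,
                              seed=config.seed, models_evaluated=evaluated)


def _start_radius(n: int) -> float:
    # rough empirical growth of bundle radius with oligomer state
    return 4.9 + 1.0 * (n - 2)


def _interacting_pairs(spec: AssemblySpec, values: dict) -> int:
    """Number of chain pairs with at least one atom pair inside the scoring
    cutoff in the model rebuilt at ``values``."""
    h0 = spec.helices[0]
    rebuilt = basic_spec(spec.oligomer_state, values["radius"],
                         values["pitch"], values["interface_angle"],
                         h0.sequence, h0.register, fold=spec.fold)
    model, _ = build_assembly(rebuilt)
    allatom = place_sidechains(model)
    from .geometry import StructureModel
    count = 0
    n = len(allatom.chains)
    for i in range(n):
        for j in range(i + 1, n):
            sub = StructureModel([allatom.chains[i], allatom.chains[j]])
            if interaction_energy(sub).pairs > 0:
                count += 1
    return max(count, 1)


def scan_oligomer_states(sequence: str, register: str = "",
                         n_range=range(2, 9),
                         config: OptimizerConfig | None = None) -> ScanResult:
    """Optimize the sequence as an n-mer for each candidate n and predict
    the state minimizing the mean interface energy."""
    n_list = list(n_range)
    if not n_list:
        raise OptimizationError("empty oligomer-state range")
    if config is None:
        config = OptimizerConfig()
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for n in n_list:
        spec = basic_spec(n, _start_radius(n), -180.0, 26.0, sequence, register)
        best_row = None
        for child in seed_seq.spawn(max(config.restarts, 1)):
            sub = replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
            result = optimize(spec, sub)
            if best_row is None or result.best_energy < best_row.best_energy:
                best_row = result
        pairs = _interacting_pairs(spec, best_row.best_parameters)
        rows.append(ScanRow(oligomer_state=n,
                            best_energy=best_row.best_energy,
                            interacting_pairs=pairs,
                            energy_per_interface=best_row.best_energy / pairs,
                            best_parameters=best_row.best_parameters))
    predicted = min(rows, key=lambda r: r.energy_per_interface).oligomer_state
    return ScanResult(rows=rows, predicted_state=predicted, seed=config.seed)
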