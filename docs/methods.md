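# Methods

This note documents the models, numerical choices and limitations behind
coilforge, in the order the pipeline runs them.

## Backbone construction

Each chain is built on a circular super-helical path of radius r about the
+z axis, parameterized by arc length so that the rise per residue along the
minor-helix axis is exactly the module constant (1.495 Å for α-helices,
2.86 Å for collagen strands).  The azimuth advances as θ = 2π z / P; a
negative pitch P yields a left-handed supercoil.  Each backbone atom type
(N, Cα, C, O) lies on its own minor helix about this path, described by
three numbers: a minor radius, a phase offset relative to Cα, and an axial
offset.  These offsets were obtained once by building a long ideal α-helix
(φ = −57.8°, ψ = −47.0°, standard bond lengths/angles, NeRF chain
extension), fitting its axis, and reading off each atom's cylindrical
coordinates; radii are rescaled so the Cα minor radius is exactly 2.26 Å.
The per-residue minor-helix advance is fixed at 720/7 ≈ 102.86°, the
convention under which one heptad spans exactly two minor-helix turns and
the a/d positions form a continuous seam.  The residual mismatch with the
fitted ideal-helix twist (98.8°/residue) slightly stretches inter-residue
bond geometry (consecutive Cα–Cα stays within 3.8 ± 0.1 Å); this is the
usual price of the rotating-frame construction and is invisible to every
downstream analysis.

Collagen strands use the same machinery with a left-handed advance of
−720/7°/residue, rise 2.86 Å and a Cα minor radius of 1.60 Å — chosen so
consecutive Cα–Cα distances come out near the trans-peptide 3.8 Å — with
N/C/O offsets fitted from an ideal polyproline-II strand (φ = −75°,
ψ = +160°).  These constants are overridable through the TOML config.

Orientation, super-helical rotation and z-shift are applied as rigid
transforms after construction, in that order: antiparallel chains are
flipped by a proper 180° rotation about x (chirality preserved; residue 1
ends at the top of the chain's z-range), then rotated about z by the
super-helical rotation, then translated axially.  z-shift is therefore an
exact translation, and a basic-mode n-mer with default rotations
(i − 1)·360/n is exactly C_n-symmetric.

## Parameter measurement

`measure_parameters` inverts the construction without using any knowledge of
how the model was built.  A running 7-residue mean of the Cα trace cancels
the minor helix almost exactly (a heptad is two full minor-helix turns), so
the smoothed points track the super-helical path.  The axis is then a
least-squares cylinder fit of those points, tried from three seeds — the
principal axis of the cloud, the mean chain-chord direction, and the
smallest principal direction of the discrete curvature vectors (second
differences), which stays informative when chord tilts add up instead of
cancelling, as in antiparallel bundles — keeping the lowest-residual fit;
the in-plane center of each trial is pre-seeded by an algebraic circle fit.
Radius and pitch come from the axial distance and azimuthal advance of the
smoothed points, then are refined against a model that is itself smoothed
the same way, which removes the curvature bias of the window at strong
supercoiling.  Across the r ∈ [4, 14] Å × |P| ∈ [80, 400] Å grid of
4-heptad dimers, the round-trip recovers radius within 0.2 Å and pitch
within 5% (most points are an order of magnitude better).  A fitted |P|
above 1500 Å, or a vanishing super-helical radius, is reported as "no
supercoiling detected" rather than a number.

The interface angle is the circular mean of per-residue Crick angles after
subtracting the ideal per-residue advance, referred to the first
register-`a` residue.  Crick angles use a local frame built from the
chain's own direction of propagation, which makes them rigid-motion
invariant and orientation-independent.

## Side-chain placement

The internal placer is deliberately minimal: one backbone-independent
rotamer per residue type (rounded canonical modes, two alternates for most
types), built by NeRF from ideal internal coordinates.  Clashes — heavy-atom
pairs below 2.0 Å involving at least one side-chain atom of another
residue — are resolved greedily, worst residue first, by cycling through
the alternate rotamers for at most 3 passes.  Proline/hydroxyproline rings
are placed with fixed pucker torsions (ring closure is approximate, which
no downstream consumer measures); hydroxyproline receives OD1 by ideal
geometry.  Hydrogens are never placed; everything downstream is
heavy-atom-only.  Placing side chains on a model that already has them is
an error, not a silent repack.  An external packing binary can be hooked in
(PDB out, PDB in, diagnostics surfaced on failure) but is off by default.

## Interaction scoring

The score is a sum over inter-chain heavy-atom pairs within 10 Å of three
terms, each reaching exactly zero at the cutoff (so the energy is continuous
and exactly zero for separated chains): a soft-core steric term (quadratic
repulsion inside the contact distance r_i + r_j, shallow linear well
outside), a linear burial reward for hydrophobic–hydrophobic pairs
(side-chain C/S atoms), and a screened Coulomb term between formal charges
reduced to single atoms (Lys NZ, Arg CZ +1; Asp CG, Glu CD −1; His
neutral).  Radii are element-based (C 1.70, N 1.55, O 1.52, S 1.80 Å).
Energies are arbitrary units, intra-chain pairs are excluded entirely, and
all parameters live in one versioned table (`data/forcefield.tsv`), so
swapping in a published parameter set changes data, not code.  The term
weights were fixed once so that the canonical Ile@a/Leu@d dimer has a
single radius-axis minimum at the physically observed ~5 Å; they have not
been fit to anything else.  Because the potential is pairwise additive, a
tightly wound collagen triple helix — whose backbone atoms sit inside
contact distance by construction — scores net repulsive; collagen models
are built and analyzed, not optimized.

## Optimization and state scanning

The optimizer is plain Metropolis Monte Carlo over the shared parameters of
a symmetric (basic-mode) assembly: per step, one of (radius, pitch,
interface angle) is perturbed by a Gaussian (σ = 0.3 Å, 10 Å, 5°), clamped
to bounds, the model is rebuilt end to end and scored, and the move is
accepted if downhill, else with probability exp(−ΔE/T) at T = 5 a.u.
(optional linear cooling).  Requests above 300 total residues are refused
unless the cap is lifted.  Every run is reproducible from its seed.  The
step sizes and temperature are desk-scale defaults: from a deliberately
wrong start (r = 7.5 Å, P = −120 Å, φ = 0°), 600 steps recover the
canonical dimer radius within 0.5 Å in ≥ 8 of 10 seeds.

The oligomer-state scan optimizes the sequence as an n-mer for each
candidate n (3 seeded restarts, best kept) and predicts the state with the
lowest *mean interface energy*: best total divided by the number of chain
pairs that actually interact.  Normalizing by n instead would let the
per-helix energy grow mechanically with bundle size under a pairwise
potential (every added neighbour contributes its full burial reward,
without the saturation real desolvation has), biasing every scan toward
large barrels; dividing by live interfaces compares packing quality per
interface and restores the classical low-order preference of Ile@a/Leu@d
sequences.  This is the one place the package's normalization choice
materially shapes a prediction, and it is the first thing to revisit if the
potential is ever replaced.

## What the synthetic fixtures do and do not show

The canonical examples (dimer through heptamer, antiparallel and slipped
topologies, acidic/basic heterodimers, collagen triple helices) are ideal
geometries with idealized sequences.  Tests built on them demonstrate
internal consistency — build/measure round-trips, symmetry, register
recovery, energy contracts — not agreement with crystal structures.  In
particular the barrel fixtures sit at this package's own packing optimum,
slightly wider than crystallographic barrels, because single-rotamer side
chains are bulkier than relaxed ones; and no fixture exercises the
irregular, discontinuity-riddled coiled coils found in natural fibrous
proteins.

## Known limitations

- The heptad convention is baked into the minor-helix advance; non-heptad
  repeats (11/3, 18/5, ...) are reachable only by overriding the advance
  constant, without register support.
- Register recovery classifies knobs purely from Crick angles; on strongly
  distorted or very short (< 2 heptad) chains it returns "unassigned"
  rather than guessing.
- The scoring function is a documented stand-in: useful as a smooth,
  physically-shaped optimization objective, not calibrated against any
  experimental energy scale.
- The parameter fit assumes one global super-helical axis; it will average,
  not segment, coiled coils whose axis bends.
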