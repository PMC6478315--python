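# Methods

This note records the model, the numerical choices, and what the bundled
synthetic systems do and do not establish.

## Mixed-resolution potential

The receptor is partitioned per residue into an *atomistic* and a *coarse*
region. A residue is atomistic iff it belongs to an explicitly listed range
or has a non-hydrogen atom within 3 Å of any ligand non-hydrogen atom in any
reference complex (`assign_regions`); the ligand is always atomistic. All
atom positions are tracked in both regions.

Energy components and their atom bases:

- **U_bb** — bond/angle/dihedral terms restricted to backbone atoms
  (N, H, Cα, HA, C, O and terminal variants) of coarse residues. Harmonic
  convention `k(x − x0)²`; dihedrals `Σ (V_n/2)(1 + cos(nφ − γ))`. No 1-4
  nonbonded terms in the coarse region.
- **U_Gō** — 12-10 native wells / hard-core repulsion on Cα–Cα distances over
  coarse–coarse residue pairs with sequence separation ≥ 3. Smaller
  separations are excluded to avoid double counting with the backbone terms
  (standard structure-based-model practice; the separation threshold is a
  package choice). Nonnative pairs are truncated at the 10 Å nonbonded
  cutoff, where the term is ≈ 1e-8 kcal/mol; native wells are not truncated.
- **U_AA, U_CG/AA, U_ligand, interaction terms** — 12-6 LJ with
  `rmin = rmin_half_i + rmin_half_j`, `ε = √(ε_i ε_j)`; 1-2/1-3 pairs
  excluded, 1-4 pairs scaled (vdW ÷ 2.0, elec ÷ 1.2) by bond-graph distance.
  Nonbonded pairs internal to the coarse region (including its side chains)
  are omitted entirely — the Gō term represents them — while coarse side
  chains do interact across the region boundary and with the ligand.
  Coarse-residue side-chain *bonded* terms are omitted: every move that
  touches a coarse residue transports it rigidly, so those terms are
  configuration-independent by construction.

Units: Å, kcal/mol, elementary charges; degrees at user-facing surfaces,
radians internally. k_B = 0.0019872041 kcal/mol/K, K_coul = 332.0636
kcal·Å/(mol·e²). Default temperature 300 K; nonbonded cutoff 10 Å (plain
truncation — the growing dielectric already damps electrostatics at range);
Gō parameters ε = 3.0 kcal/mol, r_HC = 1.7 Å, native cutoff 8 Å.

## SEDDD electrostatics and hydration volumes

`ε_ij = r_ij[ε₀ + (1 − s_kl)(ε₁ − ε₀)]` with `s_kl = c(v_k + v_l)` clamped to
[0, 1 − 1e-9], defaults ε₀ = 2, ε₁ = 8, c = 0.625. SEDDD groups default to
one group per atom (the intent is one heavy atom with its bonded hydrogens;
the toy systems are heavy-atom-only, so the two coincide).

The hydration fraction v_k is an EEF1-style exclusion sum: each non-member
atom contributes `(V_j/V_ref)·g(r)` with `g = 1` inside the shell radius
(3.5 Å) and a Gaussian falloff (width 1.5 Å) beyond, truncated at 9 Å and
capped at v_max = 1. Element-based occlusion volumes (C 20, N 15, O 14, S 22,
H 0 …) and V_ref = 22 are package defaults; the calculator is pluggable
(coordinates + occluder mask in, one scalar per group out), and the tests pin
its qualitative contract (zero when isolated, capped at complete overlap,
monotone in neighbour distance) rather than specific values.

**Occluder sets.** Protein-internal electrostatics use protein-only
occlusion, ligand-internal use ligand-only occlusion, and the λ-scaled
protein–ligand term uses all atoms. This keeps `U_protein` and `U_ligand`
rigorously independent of the partner's coordinates, which (a) realizes the
decoupled limit exactly — at λ = (0,0) the total does not change when the
ligand moves — and (b) makes the alchemical work accounting well-defined,
since only the scaled interaction components depend on λ.

**Numerical guards.** Pair distances floored at 1e-6 Å; individual pair
energies capped at ±1e6 kcal/mol so `exp(−βΔU)` stays finite in deliberate
clashes (capped configurations are rejected in practice, so the cap value is
immaterial to sampling).

## Monte Carlo engine

Six move kinds (max sizes: backbone 2°, side chain 180°, backrub 2°, ligand
torsion 180°, ligand translation 1 Å uniform-in-ball, ligand rotation 180°)
mixed per flexibility mode: fully flexible (0.1/0.2/0.1/0.2/0.2/0.2), fixed
protein (ligand moves only, exact thirds), side chains only (0.25 × 4).
Rotations use a uniformly distributed axis where one is needed and an angle
uniform in (−max, +max]; for a 180° maximum this is deliberately *not* the
Haar measure on SO(3), but the same convention is used by the engine and the
random-pose generator, and as a symmetric proposal it preserves detailed
balance. Backbone pivots are the φ/ψ bonds (both regions); side-chain
rotations are restricted to atomistic residues; backrub pairs are drawn with
sequence separation 2–10 so the move stays local. Moves drawn without an
applicable degree of freedom count as logged no-op attempts.

Energies are maintained by accumulating accepted ΔU values over full
vectorized component recomputation; a fresh recomputation every 1000 moves
guards the bookkeeping (drift beyond 1e-4 kcal/mol is a hard error — it would
indicate a restore bug, not a physics outcome). At the bundled system sizes
(≲ 200 atoms) full recomputation costs ~1 ms, so no neighbour-list or
partial-update machinery is used; the drift guard still exercises the
accumulate/restore path that such machinery would rely on.

## NCMC

Default schedule: four phases (elec↓, vdw↓, vdw↑, elec↑), λ changed by 0.05
every 5 interior moves, hence 100 interior moves per phase and 400 per
compound move (`moves_per_phase` is configurable). Interior moves use the
standard Metropolis rule under the λ-scaled potential and the same move mix
as regular MC. Each λ update contributes `Δλ · U_component` evaluated at the
configuration current when the update is applied; the compound move is
accepted with min[1, exp(−βw)] and otherwise the pre-move configuration is
restored exactly. λ scaling is linear on both channels (no soft core).
Production mixing alternates one NCMC move with 400 regular MC moves, putting
the conventional 80000-elementary-move budget at 100 cycles; every elementary
trial move (interior or regular) counts toward the budget.

## Docking protocol

A run scatters 1000 random poses (centre of mass uniform in a 4 Å ball
around the site centre, uniform random orientation, every rotatable bond at
an independent uniform angle), evaluates each pose's total energy, and starts
MC (40000 moves) or mixed NCMC/MC (80000 moves) from the lowest-energy pose.
Seeding by total energy is the default ("lowest energy pose"); interaction
energy is available as an option. Clash-capped poses are admissible — energy
selection avoids them naturally and no resampling filter is applied.
Campaigns fan out over receptor variants (e.g. protonation states, prepared
upstream) with per-run seeds spawned deterministically from a master seed.

Rotatable bonds are acyclic single bonds between non-terminal heavy atoms,
excluding amide C–N — a deterministic graph rule, applied identically to
file-read and generated ligands.

## Pose analysis

Ligand RMSD: rigid backbone superposition (Kabsch) onto the reference using
the shared backbone atoms — ligand atoms never enter the fit — then the
minimum heavy-atom RMSD over all element-preserving graph automorphisms of
the ligand connection table. Automorphism enumeration is exact and capped at
10⁴ mappings (an explicit error beyond, rather than silent truncation).
Clustering is complete-linkage with the tree cut at the 10th percentile
(linear interpolation) of the *off-diagonal* pairwise distances; including
the zero self-distances would bias the cutoff down. Ranking method 1 is the
global interaction-energy argmin; method 2 picks the largest cluster (size
ties broken by lower mean energy — a package choice); method 3 picks the
lowest-mean-energy cluster. Effective NCMC move sizes are reported as the
ligand centroid shift and rotation angle (from the trace of the optimal
rotation, in [0°, 180°]) after backbone alignment of the end configurations.

## Synthetic systems, and what the tests do and do not show

`make_toy_receptor` builds a helix-like chain with full backbone atoms and
bead side chains whose bonded equilibrium values equal the constructed
geometry (plus a 0.01 Å seeded jitter), so the reference structure is a
bonded-term minimum with a well-defined native-contact set.
`make_toy_ligand` builds chain or para-disubstituted-ring ligands with an
exactly controllable rotatable-bond count and, for the ring, a nontrivial
automorphism group. Parameter magnitudes were chosen so ligand moves at
300 K have acceptance in a useful range (≈ 0.1–0.9).

`make_two_state_toy` is the sampling oracle: a single zero-charge ligand bead
inside a repulsive spherical cage (radius 5 Å, 140 atoms) with two attractive
anchors at (±1.8, 0, 0) whose 12-6 pair depths are configurable (defaults
1.2 and 2.0 kcal/mol), plus a flat-bottom restraint (radius 4.5 Å,
k = 10 kcal/mol/Å², part of U_ligand and never λ-scaled) that bounds the
ligand while it is alchemically decoupled. Because the bead is rigid and
unchanged, its Boltzmann basin weights reduce to a 3-D integral, evaluated by
dense quadrature (0.25 Å grid) through an independent closed-form energy
path. The zero charge keeps the quadrature exact in 3-D (SEDDD would
otherwise couple the electrostatics to configuration-dependent hydration
volumes); the electrostatic channel is validated separately by closed-form
pair tests, and the λ_elec phases of NCMC are exercised structurally (work
bookkeeping, schedule traversal) rather than thermodynamically on this toy.

Statistical tests compare MC and mixed NCMC/MC occupancies against the
quadrature weights at 3σ, with the standard error estimated by batch means
(30 batches), which is robust to sample autocorrelation. Problem sizes
(1.5e5 MC moves; 1000 mixed cycles of 80 interior + 80 regular moves with a
0.1-step schedule) were chosen to give standard errors well below the basin
probability gap on these toys.

What passing does **not** show: the toys have no protonation chemistry, no
rugged ligand torsional landscape, no solvent granularity, and receptor
strain far milder than a real binding site; they validate the *machinery*
(energies against oracles, samplers against exact distributions, protocol
plumbing end-to-end), not docking accuracy on real receptors.

## Known limitations

- No neighbour lists: energy evaluation is O(n²) per move; fine at fixture
  scale, not tuned for full-size receptors.
- Plain cutoff truncation (no switching function) for LJ and electrostatics.
- The linear distance dependence of the dielectric is an empirical
  convenience, not a physical limit; no hydrophobic-effect term.
- Hydrogens are expected in real inputs (added upstream); no hydrogen
  building, no protonation-state prediction, no GAFF-style ligand
  parameterization — charges and LJ parameters come from the native YAML
  parameter schema.
- Single chain assumed by the backbone-torsion enumeration; no crystal
  symmetry or biological-assembly handling.
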