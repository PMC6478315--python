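"""Metropolis Monte Carlo engine: move set, flexibility modes, bookkeeping.

Six move kinds sample the ligand's rigid-body and torsional degrees of freedom
and — depending on the flexibility mode — the protein backbone and side
chains:

===================  ======================================================
backbone_rotation    rotate all atoms downstream of a random φ/ψ bond
sidechain_rotation   rotate about a side-chain bond (atomistic residues)
backrub              rotate the segment strictly between two residues about
                     their Cα–Cα axis (the flanking Cα atoms stay fixed)
ligand_bond_rotation rotate one side of a random ligand rotatable bond
ligand_translation   displace the ligand by a vector uniform in a ball
ligand_rotation      rotate the ligand about its centre of mass
===================  ======================================================

Rotations draw a uniformly distributed axis where one is needed and an angle
uniform in (−max, +max]; translations are uniform in the ball of radius
``max_size``.  Coarse-region side chains ride rigidly with their residue;
their internal rotamer never changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from mrdock.energy import EnergyBreakdown, EnergyModel, LambdaState
from mrdock.errors import BookkeepingError, ValidationError
from mrdock.geometry import random_point_in_ball, random_unit_vector, rotate_about_axis
from mrdock.system import MolecularSystem, SimulationSettings

__all__ = [
    "MoveSpec",
    "MoveMix",
    "MCTrajectory",
    "ExternalPotential",
    "propose_move",
    "metropolis_accept",
    "run_mc",
]

MOVE_KINDS = (
    "backbone_rotation",
    "sidechain_rotation",
    "backrub",
    "ligand_bond_rotation",
    "ligand_translation",
    "ligand_rotation",
)

#: Default maximum move sizes (degrees, except ligand_translation in Å).
DEFAULT_MAX_SIZES = {
    "backbone_rotation": 2.0,
    "sidechain_rotation": 180.0,
    "backrub": 2.0,
    "ligand_bond_rotation": 180.0,
    "ligand_translation": 1.0,
    "ligand_rotation": 180.0,
}

#: Backrub pairs are drawn with sequence separation in this (inclusive) range.
BACKRUB_SEPARATION = (2, 10)


@dataclass(frozen=True)
class MoveSpec:
    """One move kind with its maximum size and mixing fraction."""

    kind: str
    max_size: float
    fraction: float

    def __post_init__(self):
        if self.kind not in MOVE_KINDS:
            raise ValidationError(f"unknown move kind {self.kind!r}")
        if self.max_size < 0 or self.fraction < 0:
            raise ValidationError("move size and fraction must be non-negative")


_DEFAULT_FRACTIONS = {
    "fully_flexible": {
        "backbone_rotation": 0.1,
        "sidechain_rotation": 0.2,
        "backrub": 0.1,
        "ligand_bond_rotation": 0.2,
        "ligand_translation": 0.2,
        "ligand_rotation": 0.2,
    },
    "fixed_protein": {
        "ligand_bond_rotation": 1.0 / 3.0,
        "ligand_translation": 1.0 / 3.0,
        "ligand_rotation": 1.0 / 3.0,
    },
    "sidechain_only": {
        "sidechain_rotation": 0.25,
        "ligand_bond_rotation": 0.25,
        "ligand_translation": 0.25,
        "ligand_rotation": 0.25,
    },
}

_LIGAND_KINDS = {"ligand_bond_rotation", "ligand_translation", "ligand_rotation"}


@dataclass
class MoveMix:
    """A flexibility mode and its (normalized) move specifications."""

    mode: str
    specs: list[MoveSpec]

    def __post_init__(self):
        if self.mode not in _DEFAULT_FRACTIONS:
            raise ValidationError(f"unknown flexibility mode {self.mode!r}")
        total = sum(s.fraction for s in self.specs)
        if total <= 0:
            raise ValidationError("move fractions must sum to a positive value")
        self.specs = [
            MoveSpec(s.kind, s.max_size, s.fraction / total) for s in self.specs
        ]
        kinds = {s.kind for s in self.specs}
        if self.mode == "fixed_protein" and not kinds <= _LIGAND_KINDS:
            raise ValidationError("fixed_protein mode admits only ligand moves")
        if self.mode == "sidechain_only" and not kinds <= (_LIGAND_KINDS | {"sidechain_rotation"}):
            raise ValidationError("sidechain_only mode admits ligand + sidechain moves")

    @classmethod
    def default(cls, mode: str = "fully_flexible") -> "MoveMix":
        if mode not in _DEFAULT_FRACTIONS:
            raise ValidationError(f"unknown flexibility mode {mode!r}")
        specs = [
            MoveSpec(kind, DEFAULT_MAX_SIZES[kind], frac)
            for kind, frac in _DEFAULT_FRACTIONS[mode].items()
        ]
        return cls(mode=mode, specs=specs)

    def fractions(self) -> np.ndarray:
        return np.array([s.fraction for s in self.specs])


# ---------------------------------------------------------------------------
# Move proposals
# ---------------------------------------------------------------------------

def _backbone_torsions(system: MolecularSystem) -> list[tuple[int, int, frozenset]]:
    """All φ/ψ pivots: (axis_a, axis_b, moved-atom set), cached on the system."""
    cached = getattr(system, "_backbone_torsion_cache", None)
    if cached is not None:
        return cached
    graph = system.bond_graph()
    torsions = []
    for res in system.residues:
        if res.is_ligand:
            continue
        names = {system.atoms[ai].name: ai for ai in res.atom_indices}
        for a_name, b_name in (("N", "CA"), ("CA", "C")):  # φ then ψ
            if a_name not in names or b_name not in names:
                continue
            a, b = names[a_name], names[b_name]
            if not graph.has_edge(a, b):
                continue
            g2 = graph.copy()
            g2.remove_edge(a, b)
            import networkx as nx

            comp_b = nx.node_connected_component(g2, b)
            if a in comp_b:  # ring through the pivot: not rotatable
                continue
            moved = frozenset(comp_b - {b})
            if moved:
                torsions.append((a, b, moved))
    system._backbone_torsion_cache = torsions
    return torsions


def _ligand_indices(system: MolecularSystem) -> np.ndarray:
    return np.array(system.ligand_atom_indices, dtype=int)


def propose_move(
    kind: str,
    system: MolecularSystem,
    coords: np.ndarray,
    max_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict] | None:
    """Propose a trial configuration; ``None`` if the move has no degrees of freedom.

    Returns ``(new_coords, info)`` with provenance in ``info`` (kind, moved
    atom indices, and the drawn size — degrees for rotations, Å for
    translations).
    """
    new = coords.copy()
    if kind == "ligand_translation":
        lig = _ligand_indices(system)
        if len(lig) == 0:
            return None
        shift = random_point_in_ball(rng, max_size)
        new[lig] += shift
        return new, {"kind": kind, "moved": lig, "size": float(np.linalg.norm(shift))}

    if kind == "ligand_rotation":
        lig = _ligand_indices(system)
        if len(lig) == 0:
            return None
        masses = system.masses[lig]
        com = np.average(coords[lig], axis=0, weights=masses)
        axis = random_unit_vector(rng)
        angle = rng.uniform(-max_size, max_size)
        new[lig] = rotate_about_axis(coords[lig], com, axis, math.radians(angle))
        return new, {"kind": kind, "moved": lig, "size": float(abs(angle))}

    if kind == "ligand_bond_rotation":
        if not system.rotatable_bonds:
            return None
        rb = system.rotatable_bonds[rng.integers(len(system.rotatable_bonds))]
        a, b = rb.atoms
        moved = np.array(sorted(rb.moved), dtype=int)
        angle = rng.uniform(-max_size, max_size)
        new[moved] = rotate_about_axis(
            coords[moved], coords[a], coords[b] - coords[a], math.radians(angle)
        )
        return new, {"kind": kind, "moved": moved, "size": float(abs(angle))}

    if kind == "backbone_rotation":
        torsions = _backbone_torsions(system)
        if not torsions:
            return None
        a, b, moved_set = torsions[rng.integers(len(torsions))]
        moved = np.array(sorted(moved_set), dtype=int)
        angle = rng.uniform(-max_size, max_size)
        new[moved] = rotate_about_axis(
            coords[moved], coords[a], coords[b] - coords[a], math.radians(angle)
        )
        return new, {"kind": kind, "moved": moved, "size": float(abs(angle))}

    if kind == "sidechain_rotation":
        region = {r.index: r.region for r in system.residues}
        candidates = [
            rb
            for rb in system.sidechain_bonds
            if region[system.atoms[rb.atoms[0]].residue_index] == "atomistic"
            and not system.atoms[rb.atoms[0]].is_ligand
        ]
        if not candidates:
            return None
        rb = candidates[rng.integers(len(candidates))]
        a, b = rb.atoms
        moved = np.array(sorted(rb.moved), dtype=int)
        angle = rng.uniform(-max_size, max_size)
        new[moved] = rotate_about_axis(
            coords[moved], coords[a], coords[b] - coords[a], math.radians(angle)
        )
        return new, {"kind": kind, "moved": moved, "size": float(abs(angle))}

    if kind == "backrub":
        protein_res = [
            r for r in system.residues if not r.is_ligand and r.calpha_index is not None
        ]
        lo, hi = BACKRUB_SEPARATION
        pairs = [
            (ra, rb)
            for idx, ra in enumerate(protein_res)
            for rb in protein_res[idx + 1:]
            if lo <= rb.index - ra.index <= hi
        ]
        if not pairs:
            return None
        ra, rb = pairs[rng.integers(len(pairs))]
        moved_list: list[int] = []
        for r in system.residues:
            if not r.is_ligand and ra.index < r.index < rb.index:
                moved_list.extend(r.atom_indices)
        if not moved_list:
            return None
        moved = np.array(sorted(moved_list), dtype=int)
        pivot_a = coords[ra.calpha_index]
        axis = coords[rb.calpha_index] - pivot_a
        angle = rng.uniform(-max_size, max_size)
        new[moved] = rotate_about_axis(coords[moved], pivot_a, axis, math.radians(angle))
        return new, {"kind": kind, "moved": moved, "size": float(abs(angle))}

    raise ValidationError(f"unknown move kind {kind!r}")


def metropolis_accept(delta_u: float, beta: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: accept with probability min{1, exp(−β ΔU)}."""
    if delta_u <= 0.0:
        return True
    return rng.uniform() < math.exp(-beta * delta_u)


# ---------------------------------------------------------------------------
# Trajectories and the engine loop
# ---------------------------------------------------------------------------

@dataclass
class MCTrajectory:
    """Snapshots + acceptance bookkeeping from one MC run."""

    snapshots: list[tuple[int, np.ndarray, EnergyBreakdown]] = field(default_factory=list)
    attempted: dict[str, int] = field(default_factory=dict)
    accepted: dict[str, int] = field(default_factory=dict)
    move_log: list[tuple[str, float, bool]] = field(default_factory=list)
    final_coords: np.ndarray | None = None
    final_energy: EnergyBreakdown | None = None

    def record_attempt(self, kind: str, size: float, accepted: bool) -> None:
        self.attempted[kind] = self.attempted.get(kind, 0) + 1
        if accepted:
            self.accepted[kind] = self.accepted.get(kind, 0) + 1
        self.move_log.append((kind, size, accepted))

    def acceptance_rate(self, kind: str | None = None) -> float:
        if kind is None:
            att = sum(self.attempted.values())
            acc = sum(self.accepted.values())
        else:
            att = self.attempted.get(kind, 0)
            acc = self.accepted.get(kind, 0)
        return acc / att if att else float("nan")

    def size_binned_acceptance(self, kind: str, bins: np.ndarray):
        """(bin_edges, attempts, acceptances) histogram for move-size diagnostics."""
        sizes = np.array([s for k, s, _ in self.move_log if k == kind])
        accs = np.array([a for k, _, a in self.move_log if k == kind], dtype=bool)
        att, edges = np.histogram(sizes, bins=bins)
        acc, _ = np.histogram(sizes[accs], bins=bins)
        return edges, att, acc


def write_trajectory(
    trajectory: "MCTrajectory",
    system: MolecularSystem,
    pdb_path: str,
    log_path: str | None = None,
) -> None:
    """Write snapshots as a multi-model PDB and an energy/acceptance TSV log."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    from mrdock.system import write_structure

    if not trajectory.snapshots:
        raise ValidationError("trajectory has no snapshots to write")
    # reuse write_structure's atom annotation by round-tripping the first model
    write_structure(system, pdb_path, coords=trajectory.snapshots[0][1])
    first = pdbio.PDBFile.read(pdb_path).get_structure(model=1)
    stack = struc.stack([first.copy() for _ in trajectory.snapshots])
    for k, (_, coords, _) in enumerate(trajectory.snapshots):
        stack.coord[k] = np.asarray(coords, dtype=np.float32)
    out = pdbio.PDBFile()
    out.set_structure(stack)
    out.write(pdb_path)
    if log_path is not None:
        with open(log_path, "w") as fh:
            keys = ["move", "u_bb", "u_go", "u_cg", "u_aa", "u_cg_aa", "u_protein",
                    "u_ligand", "u_vdw_int", "u_elec_int", "total"]
            fh.write("\t".join(keys) + "\n")
            for step, _, bd in trajectory.snapshots:
                row = bd.as_dict()
                fh.write("\t".join([str(step)] + [f"{row[k]:.6f}" for k in keys[1:]]) + "\n")
            fh.write("# acceptance: " + ", ".join(
                f"{k}={trajectory.accepted.get(k, 0)}/{v}"
                for k, v in sorted(trajectory.attempted.items())) + "\n")


class ExternalPotential:
    """Adapter exposing a plain ``f(coords) -> kcal/mol`` as an energy model.

    Used for diagnostic systems (harmonic wells, 1-D double wells) whose
    potential is not a molecular force field.  λ scaling is a no-op.
    """

    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn

    def compute(self, coords: np.ndarray, lam: LambdaState = LambdaState()) -> EnergyBreakdown:
        return EnergyBreakdown(u_ligand=float(self.fn(coords)), lambda_state=lam)


def run_mc(
    system: MolecularSystem,
    mix: MoveMix,
    n_moves: int,
    settings: SimulationSettings = SimulationSettings(),
    rng: np.random.Generator | int | None = None,
    model: EnergyModel | ExternalPotential | None = None,
    start_coords: np.ndarray | None = None,
    lam: LambdaState = LambdaState(),
    snapshot_stride: int = 100,
    recompute_interval: int = 1000,
    drift_tolerance: float = 1.0e-4,
    trajectory: MCTrajectory | None = None,
) -> MCTrajectory:
    """Run ``n_moves`` Metropolis trials and return the trajectory.

    The running total energy is maintained by accumulating accepted ΔU values
    and is checked against a full recomputation every ``recompute_interval``
    moves; drift beyond ``drift_tolerance`` raises :class:`BookkeepingError`
    (it indicates a restore/accumulation bug, not a physics outcome).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(settings.rng_seed if rng is None else int(rng))
    if model is None:
        model = EnergyModel(system, settings=settings)
    coords = (system.coords if start_coords is None else np.asarray(start_coords, float)).copy()
    current = model.compute(coords, lam)
    running_total = current.total
    traj = MCTrajectory() if trajectory is None else trajectory
    fractions = mix.fractions()
    kinds = [s.kind for s in mix.specs]
    sizes = {s.kind: s.max_size for s in mix.specs}

    for step in range(1, n_moves + 1):
        kind = kinds[rng.choice(len(kinds), p=fractions)]
        proposal = propose_move(kind, system, coords, sizes[kind], rng)
        if proposal is None:
            traj.record_attempt(kind, 0.0, False)  # no applicable DOF: logged no-op
        else:
            new_coords, info = proposal
            trial = model.compute(new_coords, lam)
            delta = trial.total - current.total
            if metropolis_accept(delta, settings.beta, rng):
                coords = new_coords
                current = trial
                running_total += delta
                traj.record_attempt(kind, info["size"], True)
            else:
                traj.record_attempt(kind, info["size"], False)
        if recompute_interval and step % recompute_interval == 0:
            fresh = model.compute(coords, lam)
            if abs(fresh.total - running_total) > drift_tolerance:
                raise BookkeepingError(
                    f"energy drift {abs(fresh.total - running_total):.3e} kcal/mol "
                    f"after {step} moves exceeds {drift_tolerance:g}"
                )
            current = fresh
            running_total = fresh.total
        if snapshot_stride and step % snapshot_stride == 0:
            traj.snapshots.append((step, coords.copy(), current))

    if not traj.snapshots or traj.snapshots[-1][0] != n_moves:
        traj.snapshots.append((n_moves, coords.copy(), current))
    traj.final_coords = coords
    traj.final_energy = current
    return traj
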