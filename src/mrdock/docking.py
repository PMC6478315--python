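"""Docking campaign orchestration.

A docking run is: (1) scatter ``n_initial_poses`` random ligand placements —
centre of mass uniform in a ball around the site centre, uniform random
orientation, every rotatable bond at an independent random angle; (2) start a
Metropolis MC (or mixed NCMC/MC) refinement from the lowest-energy pose;
(3) record the final configuration, its energies and its RMSD against any
reference poses.  A campaign fans this out over independent seeded runs and
receptor variants (e.g. alternative protonation states, prepared upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from mrdock.energy import EnergyModel, LambdaState
from mrdock.errors import ValidationError
from mrdock.geometry import random_point_in_ball, random_unit_vector, rotate_about_axis
from mrdock.mc import MoveMix, run_mc
from mrdock.ncmc import LambdaSchedule, run_mixed_protocol
from mrdock.system import MolecularSystem, SimulationSettings

__all__ = [
    "DockingRunSpec",
    "PoseRecord",
    "generate_initial_poses",
    "select_seed_pose",
    "run_campaign",
    "campaign_table",
]


@dataclass
class DockingRunSpec:
    """Configuration of one docking run (defaults follow the production protocol)."""

    protocol: str = "mc"  # "mc" | "ncmc_mixed"
    n_trial_moves: int | None = None  # default 40000 (mc) / 80000 (ncmc_mixed)
    n_initial_poses: int = 1000
    placement_radius: float = 4.0
    site_center: np.ndarray | None = None
    mode: str = "fully_flexible"
    rng_seed: int = 0
    protonation_variant: str = "default"
    seed_selection: str = "total"  # "total" | "interaction"
    regular_moves_per_cycle: int = 400
    snapshot_stride: int = 100

    def __post_init__(self):
        if self.protocol not in ("mc", "ncmc_mixed"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")
        if self.n_trial_moves is None:
            self.n_trial_moves = 40000 if self.protocol == "mc" else 80000
        if self.site_center is not None:
            self.site_center = np.asarray(self.site_center, dtype=float)


@dataclass
class PoseRecord:
    """Final pose of one docking run."""

    run_id: str
    variant: str
    final_coords: np.ndarray
    interaction_energy: float
    total_energy: float
    rmsd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (math.isfinite(self.interaction_energy) and math.isfinite(self.total_energy)):
            raise ValidationError(f"run {self.run_id}: non-finite energies")


def generate_initial_poses(
    system: MolecularSystem,
    site_center: np.ndarray,
    spec: DockingRunSpec,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Random initial ligand placements as full-system coordinate arrays.

    Each pose randomizes every ligand rotatable bond, applies a uniform random
    rigid rotation about the ligand centre of mass, and places the centre of
    mass uniformly inside the placement ball.
    """
    lig = np.array(system.ligand_atom_indices, dtype=int)
    if len(lig) == 0:
        raise ValidationError("system has no ligand atoms")
    site_center = np.asarray(site_center, dtype=float)
    masses = system.masses[lig]
    poses = []
    for _ in range(spec.n_initial_poses):
        coords = system.copy_coords()
        for rb in system.rotatable_bonds:
            a, b = rb.atoms
            moved = np.array(sorted(rb.moved), dtype=int)
            angle = rng.uniform(-180.0, 180.0)
            coords[moved] = rotate_about_axis(
                coords[moved], coords[a], coords[b] - coords[a], math.radians(angle)
            )
        com = np.average(coords[lig], axis=0, weights=masses)
        axis = random_unit_vector(rng)
        angle = rng.uniform(-180.0, 180.0)
        coords[lig] = rotate_about_axis(coords[lig], com, axis, math.radians(angle))
        target = site_center + random_point_in_ball(rng, spec.placement_radius)
        coords[lig] += target - com
        poses.append(coords)
    return poses


def select_seed_pose(
    poses: Sequence[np.ndarray], energy_function: Callable[[np.ndarray], float]
) -> tuple[int, np.ndarray]:
    """Index and coordinates of the lowest-energy pose (ties: lowest index)."""
    if len(poses) == 0:
        raise ValidationError("no poses to select from")
    energies = [float(energy_function(p)) for p in poses]
    best = int(np.argmin(energies))  # argmin returns the first minimum
    return best, poses[best]


def _run_one(
    system: MolecularSystem,
    model: EnergyModel,
    spec: DockingRunSpec,
    settings: SimulationSettings,
    seed: np.random.SeedSequence,
    site_center: np.ndarray,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    poses = generate_initial_poses(system, site_center, spec, rng)
    if spec.seed_selection == "interaction":
        energy_fn = model.interaction_energy
    else:
        energy_fn = lambda c: model.compute(c, LambdaState()).total  # noqa: E731
    _, start = select_seed_pose(poses, energy_fn)
    mix = MoveMix.default(spec.mode)
    if spec.protocol == "mc":
        traj = run_mc(
            system, mix, spec.n_trial_moves, settings, rng, model,
            start_coords=start, snapshot_stride=spec.snapshot_stride,
        )
    else:
        schedule = LambdaSchedule()
        per_cycle = schedule.total_interior_moves + spec.regular_moves_per_cycle
        n_cycles = max(1, spec.n_trial_moves // per_cycle)
        traj = run_mixed_protocol(
            system, n_cycles, settings, rng, model, mix, schedule,
            regular_moves_per_cycle=spec.regular_moves_per_cycle,
            start_coords=start, snapshot_stride=spec.snapshot_stride,
        )
    return traj.final_coords


def run_campaign(
    variants: Mapping[str, tuple[MolecularSystem, EnergyModel]],
    spec: DockingRunSpec,
    n_runs_per_variant: int,
    settings: SimulationSettings = SimulationSettings(),
    site_center: np.ndarray | None = None,
    rmsd_function: Callable[[str, np.ndarray], dict[str, float]] | None = None,
) -> list[PoseRecord]:
    """Fan out independent seeded docking runs over receptor variants.

    ``variants`` maps a label (e.g. a protonation state) to a prepared
    (system, energy model) pair; variants are inputs, never computed here.
    ``rmsd_function(variant, coords)`` may supply per-reference RMSDs for each
    final pose.  Per-run seeds derive deterministically from ``spec.rng_seed``.
    A failed run is recorded as skipped, not fatal.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(len(variants) * n_runs_per_variant)
    records: list[PoseRecord] = []
    k = 0
    for variant, (system, model) in variants.items():
        for run in range(n_runs_per_variant):
            seed = children[k]
            k += 1
            center = site_center if site_center is not None else spec.site_center
            if center is None:
                raise ValidationError("no site_center provided")
            try:
                final = _run_one(system, model, spec, settings, seed, center)
                bd = model.compute(final, LambdaState())
                rmsd = rmsd_function(variant, final) if rmsd_function else {}
                records.append(
                    PoseRecord(
                        run_id=f"{variant}/{run}",
                        variant=variant,
                        final_coords=final,
                        interaction_energy=bd.interaction,
                        total_energy=bd.total,
                        rmsd=rmsd,
                    )
                )
            except Exception as exc:  # a failed run is skipped, not fatal
                import warnings

                warnings.warn(f"docking run {variant}/{run} failed: {exc}")
    return records


def campaign_table(records: Sequence[PoseRecord]) -> pd.DataFrame:
    """Tabular campaign report (one row per successful run)."""
    rows = []
    for r in records:
        row = {
            "run_id": r.run_id,
            "variant": r.variant,
            "interaction_energy": r.interaction_energy,
            "total_energy": r.total_energy,
        }
        for name, value in r.rmsd.items():
            row[f"rmsd_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
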