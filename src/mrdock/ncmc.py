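"""Nonequilibrium candidate Monte Carlo (NCMC).

An NCMC move is a short driven simulation: the protein–ligand coupling factors
(λ_elec, λ_VDW) are walked down to zero and back up over four phases
(elec↓, vdw↓, vdw↑, elec↑) while ordinary Metropolis moves run under the
scaled potential.  Every λ update contributes to the nonequilibrium work

    w = Σ_i [ Δλ_VDW(i) · U_VDW(r_i) + Δλ_elec(i) · U_elec(r_i) ]

with the interaction components evaluated at the configuration current when
the change is applied.  The whole compound move is finally accepted with
probability min[1, exp(−βw)]; on rejection the pre-move configuration is
restored exactly.  Because NCMC acceptance is low, production protocols
alternate each NCMC move with a block of regular MC moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mrdock.energy import EnergyBreakdown, EnergyModel, LambdaState
from mrdock.errors import ValidationError
from mrdock.mc import MCTrajectory, MoveMix, metropolis_accept, propose_move
from mrdock.system import MolecularSystem, SimulationSettings

__all__ = [
    "LambdaSchedule",
    "NCMCMoveResult",
    "build_schedule",
    "ncmc_move",
    "run_mixed_protocol",
]

DEFAULT_PHASES = (("elec", "down"), ("vdw", "down"), ("vdw", "up"), ("elec", "up"))


@dataclass(frozen=True)
class LambdaSchedule:
    """Piecewise-constant λ trajectory: 4 phases, each fully traversing [0, 1].

    Defaults: step 0.05 applied every 5 interior moves ⇒ 20 updates and 100
    moves per phase, 400 interior moves per NCMC move.
    """

    phases: tuple[tuple[str, str], ...] = DEFAULT_PHASES
    lambda_step: float = 0.05
    moves_per_step: int = 5

    def __post_init__(self):
        n = 1.0 / self.lambda_step
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(f"lambda_step {self.lambda_step} must divide 1 exactly")
        if self.moves_per_step < 0:
            raise ValidationError("moves_per_step must be >= 0")
        for param, direction in self.phases:
            if param not in ("vdw", "elec") or direction not in ("down", "up"):
                raise ValidationError(f"bad phase ({param}, {direction})")

    @property
    def steps_per_phase(self) -> int:
        return round(1.0 / self.lambda_step)

    @property
    def moves_per_phase(self) -> int:
        return self.steps_per_phase * self.moves_per_step

    @property
    def total_interior_moves(self) -> int:
        return self.moves_per_phase * len(self.phases)

    @property
    def n_lambda_updates(self) -> int:
        return self.steps_per_phase * len(self.phases)

    def lambda_trajectory(self) -> list[LambdaState]:
        """λ state after each update, starting from (1, 1)."""
        lam = {"vdw": 1.0, "elec": 1.0}
        out = [LambdaState(lam["vdw"], lam["elec"])]
        for param, direction in self.phases:
            delta = -self.lambda_step if direction == "down" else self.lambda_step
            for _ in range(self.steps_per_phase):
                lam[param] = min(max(lam[param] + delta, 0.0), 1.0)
                out.append(LambdaState(lam["vdw"], lam["elec"]))
        return out


def build_schedule(
    phases: tuple[tuple[str, str], ...] = DEFAULT_PHASES,
    lambda_step: float = 0.05,
    moves_per_step: int = 5,
    moves_per_phase: int | None = None,
) -> LambdaSchedule:
    """Construct a validated :class:`LambdaSchedule`.

    ``moves_per_phase``, if given, must equal ``moves_per_step / lambda_step``;
    it is accepted as a consistency cross-check for configuration files.
    """
    sched = LambdaSchedule(phases=tuple(phases), lambda_step=lambda_step,
                           moves_per_step=moves_per_step)
    if moves_per_phase is not None and moves_per_phase != sched.moves_per_phase:
        raise ValidationError(
            f"moves_per_phase={moves_per_phase} inconsistent with "
            f"step {lambda_step} every {moves_per_step} moves "
            f"(implies {sched.moves_per_phase})"
        )
    return sched


@dataclass
class NCMCMoveResult:
    """Outcome of one compound NCMC move."""

    work: float
    accepted: bool
    interior_accept_count: int
    interior_attempts: int
    pre_coords: np.ndarray
    post_coords: np.ndarray
    final_energy: EnergyBreakdown | None = None
    #: per-λ-update log: (parameter, Δλ, interaction component at that moment)
    work_log: list[tuple[str, float, float]] = field(default_factory=list)


def _interior_mc(
    system, mix, n, model, lam, coords, current, settings, rng, traj=None
):
    """Run n Metropolis moves at fixed λ; returns (coords, breakdown, n_accepted)."""
    n_acc = 0
    kinds = [s.kind for s in mix.specs]
    fractions = mix.fractions()
    sizes = {s.kind: s.max_size for s in mix.specs}
    for _ in range(n):
        kind = kinds[rng.choice(len(kinds), p=fractions)]
        proposal = propose_move(kind, system, coords, sizes[kind], rng)
        if proposal is None:
            if traj is not None:
                traj.record_attempt(kind, 0.0, False)
            continue
        new_coords, info = proposal
        trial = model.compute(new_coords, lam)
        delta = trial.scaled_total(lam) - current.scaled_total(lam)
        ok = metropolis_accept(delta, settings.beta, rng)
        if ok:
            coords, current = new_coords, trial
            n_acc += 1
        if traj is not None:
            traj.record_attempt(kind, info["size"], ok)
    return coords, current, n_acc


def ncmc_move(
    system: MolecularSystem,
    coords: np.ndarray,
    schedule: LambdaSchedule,
    mix: MoveMix,
    settings: SimulationSettings,
    rng: np.random.Generator,
    model: EnergyModel,
    interior_trajectory: MCTrajectory | None = None,
) -> NCMCMoveResult:
    """One compound NCMC move starting (and, on rejection, ending) at ``coords``."""
    pre = np.asarray(coords, dtype=float).copy()
    cur_coords = pre.copy()
    lam = {"vdw": 1.0, "elec": 1.0}
    current = model.compute(cur_coords, LambdaState(**{"lambda_vdw": 1.0, "lambda_elec": 1.0}))
    work = 0.0
    work_log: list[tuple[str, float, float]] = []
    n_acc = 0
    n_att = 0
    for param, direction in schedule.phases:
        delta_lam = -schedule.lambda_step if direction == "down" else schedule.lambda_step
        for _ in range(schedule.steps_per_phase):
            lam_state = LambdaState(lam["vdw"], lam["elec"])
            cur_coords, current, acc = _interior_mc(
                system, mix, schedule.moves_per_step, model, lam_state,
                cur_coords, current, settings, rng, interior_trajectory,
            )
            n_acc += acc
            n_att += schedule.moves_per_step
            # work contribution at the configuration current when λ changes
            component = current.u_vdw_int if param == "vdw" else current.u_elec_int
            work += delta_lam * component
            work_log.append((param, delta_lam, component))
            lam[param] = min(max(lam[param] + delta_lam, 0.0), 1.0)
    if lam["vdw"] != 1.0 or lam["elec"] != 1.0:
        raise ValidationError("λ schedule does not return to full coupling")
    p = min(1.0, math.exp(-settings.beta * work)) if work > 0 else 1.0
    accepted = rng.uniform() < p if p < 1.0 else True
    post = cur_coords if accepted else pre.copy()
    return NCMCMoveResult(
        work=work,
        accepted=accepted,
        interior_accept_count=n_acc,
        interior_attempts=n_att,
        pre_coords=pre,
        post_coords=post,
        final_energy=current if accepted else None,
        work_log=work_log,
    )


def run_mixed_protocol(
    system: MolecularSystem,
    n_cycles: int,
    settings: SimulationSettings = SimulationSettings(),
    rng: np.random.Generator | int | None = None,
    model: EnergyModel | None = None,
    mix: MoveMix | None = None,
    schedule: LambdaSchedule | None = None,
    regular_moves_per_cycle: int = 400,
    start_coords: np.ndarray | None = None,
    snapshot_stride: int = 100,
) -> MCTrajectory:
    """Alternate one NCMC move with a block of regular MC moves per cycle.

    With the default schedule (400 interior moves) and 400 regular moves per
    cycle, 100 cycles spend the production budget of 80000 elementary trial
    moves.  The returned trajectory carries per-cycle NCMC results in
    ``trajectory.ncmc_results`` (work, acceptance, interior acceptance).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(settings.rng_seed if rng is None else int(rng))
    if model is None:
        model = EnergyModel(system, settings=settings)
    if mix is None:
        mix = MoveMix.default("fixed_protein")
    if schedule is None:
        schedule = LambdaSchedule()
    rng_ncmc, rng_regular = rng.spawn(2)

    coords = (system.coords if start_coords is None else np.asarray(start_coords, float)).copy()
    lam_full = LambdaState(1.0, 1.0)
    current = model.compute(coords, lam_full)
    traj = MCTrajectory()
    traj.ncmc_results = []  # type: ignore[attr-defined]
    move_counter = 0
    for _ in range(n_cycles):
        result = ncmc_move(
            system, coords, schedule, mix, settings, rng_ncmc, model,
            interior_trajectory=traj,
        )
        traj.ncmc_results.append(result)  # type: ignore[attr-defined]
        move_counter += result.interior_attempts
        if result.accepted:
            coords = result.post_coords
            current = result.final_energy
        traj.snapshots.append((move_counter, coords.copy(), current))
        coords, current, _ = _interior_mc(
            system, mix, regular_moves_per_cycle, model, lam_full,
            coords, current, settings, rng_regular, traj,
        )
        move_counter += regular_moves_per_cycle
        traj.snapshots.append((move_counter, coords.copy(), current))
    traj.final_coords = coords
    traj.final_energy = current
    return traj
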