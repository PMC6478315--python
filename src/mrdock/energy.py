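"""Atomistic and cross-region energies; total mixed-resolution potential.

The all-atom terms follow the AMBER functional form: harmonic bonds/angles,
Fourier dihedrals, 12-6 Lennard-Jones with Lorentz-like combining on
``rmin/2`` (rmin_pair = rmin_half_i + rmin_half_j, ε_pair = √(ε_i ε_j)) and
1-4 scaling (vdW ÷ 2.0, electrostatics ÷ 1.2).  Electrostatics use a
solvent-exposure-dependent distance-dependent dielectric:

    U_elec(i,j) = K_coul q_i q_j / (ε_ij r_ij)
    ε_ij = r_ij [ε₀ + (1 − s_kl)(ε₁ − ε₀)]          (grows with distance)
    s_kl = c (v_k + v_l),  clamped to [0, 1)          (burial overlap)

where v_k is the occluded fraction of group k's first hydration shell,
computed with an EEF1-style Gaussian exclusion sum.  Fully exposed pairs
(s = 0) at 10 Å see an effective dielectric of 80; deeply buried pairs
approach the low dielectric ε₀.

Protein–ligand van der Waals and electrostatic sums are kept separate so they
can be scaled by the alchemical coupling factors (λ_VDW, λ_elec):

    U = U_protein + U_ligand + λ_VDW U_VDW + λ_elec U_elec

At λ = (1, 1) this equals the region decomposition U_CG + U_AA + U_CG/AA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from mrdock.constants import COULOMB_KCAL
from mrdock.errors import DomainError, ParameterError, ValidationError
from mrdock.gomodel import MIN_SEQUENCE_SEPARATION, GoParameters, NativeContact
from mrdock.system import MolecularSystem, SimulationSettings

__all__ = [
    "SedddParameters",
    "HydrationParameters",
    "HydrationState",
    "LambdaState",
    "EnergyBreakdown",
    "EnergyModel",
    "seddd_dielectric",
    "pair_overlap",
    "compute_hydration_volumes",
]

#: Per-pair energy cap (kcal/mol) so exp(−βΔU) stays well defined in clashes.
PAIR_ENERGY_CAP = 1.0e6
#: Distance floor for overlapping atoms.
MIN_PAIR_DISTANCE = 1.0e-6
#: Upper clamp for the hydration overlap s_kl.
S_MAX = 1.0 - 1.0e-9

VDW_14_SCALE = 1.0 / 2.0
ELEC_14_SCALE = 1.0 / 1.2

#: Occlusion volumes (Å**3-like weights) per element for the hydration model.
DEFAULT_OCCLUSION_VOLUMES = {"H": 0.0, "C": 20.0, "N": 15.0, "O": 14.0, "S": 22.0, "F": 12.0,
                             "CL": 24.0, "BR": 30.0, "I": 37.0, "P": 25.0}


@dataclass(frozen=True)
class SedddParameters:
    """Low/high dielectric constants and the hydration-overlap constant c."""

    eps0: float = 2.0
    eps1: float = 8.0
    c: float = 0.625

    def __post_init__(self):
        if not (self.eps1 > self.eps0 > 0):
            raise ValidationError("require eps1 > eps0 > 0")


@dataclass(frozen=True)
class HydrationParameters:
    """EEF1-style hydration-shell exclusion parameters.

    ``shell_radius`` is the first-hydration-shell radius from the group centre;
    neighbours inside it occlude fully, beyond it the occlusion falls off as a
    Gaussian of width ``gaussian_width``.  ``reference_volume`` normalizes the
    neighbour occlusion volumes; ``v_max`` caps the occluded fraction.
    """

    shell_radius: float = 3.5
    gaussian_width: float = 1.5
    reference_volume: float = 22.0
    v_max: float = 1.0
    cutoff: float = 9.0


@dataclass
class HydrationState:
    """Per-group occluded hydration-shell fractions v_k."""

    group_volumes: np.ndarray

    def overlap(self, k: int, l: int, c: float) -> float:
        return pair_overlap(self.group_volumes[k], self.group_volumes[l], c)


@dataclass(frozen=True)
class LambdaState:
    """Protein–ligand coupling factors, each in [0, 1]."""

    lambda_vdw: float = 1.0
    lambda_elec: float = 1.0

    def __post_init__(self):
        for name in ("lambda_vdw", "lambda_elec"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} outside [0, 1]")


def seddd_dielectric(r_ij: float, s_kl: float, params: SedddParameters = SedddParameters()):
    """Effective dielectric ε_ij = r_ij [ε₀ + (1 − s_kl)(ε₁ − ε₀)].

    Accepts scalars or arrays.
    """
    r = np.asarray(r_ij, dtype=float)
    s = np.asarray(s_kl, dtype=float)
    if np.any(r <= 0):
        raise DomainError("pair distance must be positive")
    if np.any((s < 0) | (s >= 1)):
        raise DomainError("hydration overlap s_kl must lie in [0, 1)")
    out = r * (params.eps0 + (1.0 - s) * (params.eps1 - params.eps0))
    return float(out) if np.isscalar(r_ij) and np.isscalar(s_kl) else out


def pair_overlap(v_k, v_l, c: float = 0.625):
    """s_kl = c (v_k + v_l), clamped below 1; symmetric in its arguments."""
    v_k = np.asarray(v_k, dtype=float)
    v_l = np.asarray(v_l, dtype=float)
    if np.any(v_k < 0) or np.any(v_l < 0):
        raise DomainError("hydration volumes must be non-negative")
    s = np.minimum(c * (v_k + v_l), S_MAX)
    return float(s) if s.ndim == 0 else s


def compute_hydration_volumes(
    coords: np.ndarray,
    groups: Sequence[Sequence[int]],
    occlusion_volumes: np.ndarray,
    params: HydrationParameters = HydrationParameters(),
    occluder_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Occluded first-hydration-shell fraction v_k per group.

    The group centre is its first (heavy) atom.  Each non-member atom j within
    the cutoff contributes (V_j / V_ref) · g(r), with g = 1 inside the shell
    radius and a Gaussian falloff beyond it; the sum is capped at ``v_max``.
    ``occluder_mask`` restricts which atoms may occlude (used to keep, e.g.,
    protein-internal solvation independent of a decoupled ligand).
    """
    coords = np.asarray(coords, dtype=float)
    vol = np.asarray(occlusion_volumes, dtype=float)
    if len(vol) != len(coords):
        raise ParameterError("need one occlusion volume per atom")
    allowed = np.ones(len(coords), bool) if occluder_mask is None else np.asarray(occluder_mask, bool)
    v = np.zeros(len(groups))
    for k, members in enumerate(groups):
        members = list(members)
        center = coords[members[0]]
        mask = allowed.copy()
        mask[members] = False
        d = np.linalg.norm(coords[mask] - center, axis=1)
        w = vol[mask] / params.reference_volume
        g = np.where(
            d <= params.shell_radius,
            1.0,
            np.exp(-(((d - params.shell_radius) / params.gaussian_width) ** 2)),
        )
        g[d > params.cutoff] = 0.0
        v[k] = min(float(np.sum(w * g)), params.v_max)
    return v


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Half-harmonic spherical restraint on the centroid of a set of atoms.

    Zero inside ``radius`` of ``center``; k·(d − radius)² outside.  Used to
    bound ligand diffusion in open model systems; it is *not* scaled by λ.
    """

    atom_indices: tuple[int, ...]
    center: tuple[float, float, float]
    radius: float
    k: float

    def energy(self, coords: np.ndarray) -> float:
        com = coords[list(self.atom_indices)].mean(axis=0)
        d = float(np.linalg.norm(com - np.asarray(self.center)))
        excess = max(0.0, d - self.radius)
        return self.k * excess * excess


@dataclass
class EnergyBreakdown:
    """All energy components of one configuration, kcal/mol.

    ``u_aa`` and ``u_cg_aa`` follow the region decomposition (the all-atom
    region includes the ligand); ``u_protein``/``u_ligand``/``u_vdw_int``/
    ``u_elec_int`` follow the alchemical decomposition.  ``total`` is
    evaluated at the λ the breakdown was computed with.
    """

    u_bb: float = 0.0
    u_go: float = 0.0
    u_aa_protein: float = 0.0
    u_cross_protein: float = 0.0
    u_ligand: float = 0.0
    u_int_aa_vdw: float = 0.0
    u_int_aa_elec: float = 0.0
    u_int_cg_vdw: float = 0.0
    u_int_cg_elec: float = 0.0
    lambda_state: LambdaState = field(default_factory=LambdaState)

    @property
    def u_cg(self) -> float:
        return self.u_bb + self.u_go

    @property
    def u_protein(self) -> float:
        return self.u_cg + self.u_aa_protein + self.u_cross_protein

    @property
    def u_vdw_int(self) -> float:
        return self.u_int_aa_vdw + self.u_int_cg_vdw

    @property
    def u_elec_int(self) -> float:
        return self.u_int_aa_elec + self.u_int_cg_elec

    @property
    def u_aa(self) -> float:
        """All-atom-region energy (protein atomistic + ligand + their interaction)."""
        return self.u_aa_protein + self.u_ligand + self.u_int_aa_vdw + self.u_int_aa_elec

    @property
    def u_cg_aa(self) -> float:
        """Cross-region energy (incl. ligand–coarse interactions)."""
        return self.u_cross_protein + self.u_int_cg_vdw + self.u_int_cg_elec

    @property
    def interaction(self) -> float:
        """Unscaled protein–ligand interaction energy (the ranking score)."""
        return self.u_vdw_int + self.u_elec_int

    def scaled_total(self, lam: LambdaState) -> float:
        return (
            self.u_protein
            + self.u_ligand
            + lam.lambda_vdw * self.u_vdw_int
            + lam.lambda_elec * self.u_elec_int
        )

    @property
    def total(self) -> float:
        return self.scaled_total(self.lambda_state)

    def as_dict(self) -> dict[str, float]:
        return {
            "u_bb": self.u_bb,
            "u_go": self.u_go,
            "u_cg": self.u_cg,
            "u_aa": self.u_aa,
            "u_cg_aa": self.u_cg_aa,
            "u_protein": self.u_protein,
            "u_ligand": self.u_ligand,
            "u_vdw_int": self.u_vdw_int,
            "u_elec_int": self.u_elec_int,
            "total": self.total,
        }


class EnergyModel:
    """Precompiled mixed-resolution potential for one topology.

    Builds static pair lists, exclusions and 1-4 scalings once; each call to
    :meth:`compute` evaluates the full potential for a coordinate array.
    The hydration-volume calculator is pluggable: any callable mapping a
    coordinate array to one scalar per SEDDD group.
    """

    # pair-class codes
    _LIG_LIG, _LIG_AA, _LIG_CG, _AA_AA, _AA_CG = range(5)

    def __init__(
        self,
        system: MolecularSystem,
        contacts: Sequence[NativeContact] = (),
        go_params: GoParameters = GoParameters(),
        seddd: SedddParameters = SedddParameters(),
        hydration: HydrationParameters = HydrationParameters(),
        settings: SimulationSettings = SimulationSettings(),
        hydration_calculator: Callable[[np.ndarray], np.ndarray] | None = None,
        restraints: Sequence[FlatBottomRestraint] = (),
    ):
        self.system = system
        self.go_params = go_params
        self.seddd = seddd
        self.hydration = hydration
        self.settings = settings
        self.restraints = list(restraints)
        self.contacts = list(contacts)
        n = system.n_atoms

        charges = system.charges
        rmin_half = system.array("lj_rmin_half").astype(float)
        eps = system.array("lj_epsilon").astype(float)
        is_lig = system.is_ligand_mask
        region = system.region_of_atoms()
        in_cg = (region == "coarse") & ~is_lig
        in_aa = (region == "atomistic") & ~is_lig

        # SEDDD groups: compact re-index of seddd_group_id
        gid = system.array("seddd_group_id").astype(int)
        unique_gids = sorted(set(gid.tolist()))
        gid_map = {g: k for k, g in enumerate(unique_gids)}
        self.atom_group = np.array([gid_map[g] for g in gid])
        self.groups = [np.where(self.atom_group == k)[0].tolist() for k in range(len(unique_gids))]
        elements = [a.element.upper() for a in system.atoms]
        self.occlusion_volumes = np.array(
            [DEFAULT_OCCLUSION_VOLUMES.get(el, 18.0) for el in elements]
        )
        # vectorized default calculator: group representatives + membership mask
        self._group_reps = np.array([g[0] for g in self.groups], dtype=int)
        self._member_mask = np.zeros((len(self.groups), n), dtype=bool)
        for k, members in enumerate(self.groups):
            self._member_mask[k, members] = True
        self._is_lig_atom = is_lig.copy()
        self._occ_w = self.occlusion_volumes / self.hydration.reference_volume
        if hydration_calculator is None:
            hydration_calculator = self._default_hydration
        self.hydration_calculator = hydration_calculator

        # graph distances up to 3 bonds for exclusions / 1-4 scaling
        graph = system.bond_graph()
        excl12_13: set[frozenset] = set()
        pairs14: set[frozenset] = set()
        for src in range(n):
            lengths = nx.single_source_shortest_path_length(graph, src, cutoff=3)
            for dst, dist in lengths.items():
                if dst <= src:
                    continue
                if dist in (1, 2):
                    excl12_13.add(frozenset((src, dst)))
                elif dist == 3:
                    pairs14.add(frozenset((src, dst)))

        ii, jj, cls, vscale, escale = [], [], [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if in_cg[i] and in_cg[j]:
                    continue  # CG–CG handled by the Gō term
                key = frozenset((i, j))
                if key in excl12_13:
                    continue
                if is_lig[i] and is_lig[j]:
                    c = self._LIG_LIG
                elif is_lig[i] or is_lig[j]:
                    other = j if is_lig[i] else i
                    c = self._LIG_CG if in_cg[other] else self._LIG_AA
                elif in_aa[i] and in_aa[j]:
                    c = self._AA_AA
                else:
                    c = self._AA_CG
                ii.append(i)
                jj.append(j)
                cls.append(c)
                if key in pairs14:
                    vscale.append(VDW_14_SCALE)
                    escale.append(ELEC_14_SCALE)
                else:
                    vscale.append(1.0)
                    escale.append(1.0)
        self.pair_i = np.array(ii, dtype=int)
        self.pair_j = np.array(jj, dtype=int)
        self.pair_class = np.array(cls, dtype=int)
        order = np.argsort(self.pair_class, kind="stable")  # class-contiguous storage
        self.pair_i = self.pair_i[order]
        self.pair_j = self.pair_j[order]
        self.pair_class = self.pair_class[order]
        self.pair_vdw_scale = np.array(vscale)[order]
        self.pair_elec_scale = np.array(escale)[order]
        self.pair_rmin = rmin_half[self.pair_i] + rmin_half[self.pair_j]
        self.pair_eps = np.sqrt(eps[self.pair_i] * eps[self.pair_j])
        self.pair_qq = COULOMB_KCAL * charges[self.pair_i] * charges[self.pair_j]
        self.pair_gi = self.atom_group[self.pair_i] if len(self.pair_i) else np.array([], int)
        self.pair_gj = self.atom_group[self.pair_j] if len(self.pair_j) else np.array([], int)
        self._class_bounds = np.searchsorted(self.pair_class, np.arange(6))

        # Gō pair list on α-carbons (sequence separation ≥ 3)
        native = {(c.residue_i, c.residue_j): c.r0 for c in contacts}
        coarse = [r for r in system.residues if r.region == "coarse"]
        ca_i, ca_j, r0s = [], [], []
        for a_pos, ra in enumerate(coarse):
            for rb in coarse[a_pos + 1:]:
                if abs(rb.index - ra.index) < MIN_SEQUENCE_SEPARATION:
                    continue
                key = tuple(sorted((ra.index, rb.index)))
                ca_i.append(ra.calpha_index)
                ca_j.append(rb.calpha_index)
                r0s.append(native.get(key, np.nan))
        self.go_ca_i = np.array(ca_i, dtype=int)
        self.go_ca_j = np.array(ca_j, dtype=int)
        self.go_r0 = np.array(r0s)  # NaN ⇒ nonnative

        # bonded-term ownership
        is_bb = system.is_backbone_mask

        def owner(idx: tuple[int, ...]) -> str:
            if all(is_lig[i] for i in idx):
                return "ligand"
            if any(is_lig[i] for i in idx):
                raise ValidationError("bonded term spans ligand and protein")
            if all(in_cg[i] for i in idx):
                return "bb" if all(is_bb[i] for i in idx) else "cg_side"
            if all(in_aa[i] for i in idx):
                return "aa"
            return "cross"

        self._bonds = {k: [] for k in ("ligand", "aa", "bb", "cross")}
        self._angles = {k: [] for k in ("ligand", "aa", "bb", "cross")}
        self._dihedrals = {k: [] for k in ("ligand", "aa", "bb", "cross")}
        for b in system.bonds:
            o = owner((b.i, b.j))
            if o != "cg_side":
                self._bonds[o].append(b)
        for a in system.angles:
            o = owner((a.i, a.j, a.k))
            if o != "cg_side":
                self._angles[o].append(a)
        for d in system.dihedrals:
            o = owner((d.i, d.j, d.k, d.l))
            if o != "cg_side":
                self._dihedrals[o].append(d)
        # vectorized bonded arrays per owner
        self._bond_arrays = {}
        self._angle_arrays = {}
        self._dihedral_arrays = {}
        for key in ("ligand", "aa", "bb", "cross"):
            bs = self._bonds[key]
            self._bond_arrays[key] = (
                np.array([b.i for b in bs], int),
                np.array([b.j for b in bs], int),
                np.array([b.k for b in bs]),
                np.array([b.r0 for b in bs]),
            )
            ans = self._angles[key]
            self._angle_arrays[key] = (
                np.array([a.i for a in ans], int),
                np.array([a.j for a in ans], int),
                np.array([a.k for a in ans], int),
                np.array([a.k_theta for a in ans]),
                np.array([a.theta0 for a in ans]),
            )
            ds = self._dihedrals[key]
            term_d, heights, ns, gammas = [], [], [], []
            for idx, d in enumerate(ds):
                for h, nper, g in d.terms:
                    term_d.append(idx)
                    heights.append(h)
                    ns.append(nper)
                    gammas.append(g)
            self._dihedral_arrays[key] = (
                np.array([d.i for d in ds], int),
                np.array([d.j for d in ds], int),
                np.array([d.k for d in ds], int),
                np.array([d.l for d in ds], int),
                np.array(term_d, int),
                np.array(heights),
                np.array(ns),
                np.array(gammas),
            )

    # -- component evaluators ------------------------------------------------

    def _occlusion_kernel(self, coords: np.ndarray) -> np.ndarray:
        """Group × atom occlusion kernel g(r) with members zeroed."""
        hp = self.hydration
        centers = coords[self._group_reps]
        d = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=-1)
        g = np.where(
            d <= hp.shell_radius,
            1.0,
            np.exp(-(((d - hp.shell_radius) / hp.gaussian_width) ** 2)),
        )
        g[d > hp.cutoff] = 0.0
        g[self._member_mask] = 0.0
        return g

    def _default_hydration(
        self, coords: np.ndarray, occluder_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Vectorized form of :func:`compute_hydration_volumes` for this topology."""
        g = self._occlusion_kernel(coords)
        w = self._occ_w if occluder_mask is None else self._occ_w * occluder_mask
        return np.minimum(g @ w, self.hydration.v_max)

    def hydration_state(
        self, coords: np.ndarray, occluder_mask: np.ndarray | None = None
    ) -> HydrationState:
        return HydrationState(
            group_volumes=np.asarray(self.hydration_calculator(coords, occluder_mask))
        )

    def _hydration_three(self, coords: np.ndarray):
        """(v_ligand-only, v_all, v_protein-only) occlusion volumes per group.

        Protein-internal electrostatics must not feel a (possibly decoupled)
        ligand and vice versa, so each interaction class gets the matching
        occluder set; the λ-scaled protein–ligand term sees all atoms.
        """
        if self.hydration_calculator is self._default_hydration:
            g = self._occlusion_kernel(coords)
            vmax = self.hydration.v_max
            v_all = np.minimum(g @ self._occ_w, vmax)
            v_prot = np.minimum(g @ (self._occ_w * ~self._is_lig_atom), vmax)
            v_lig = np.minimum(g @ (self._occ_w * self._is_lig_atom), vmax)
            return v_lig, v_all, v_prot
        return (
            np.asarray(self.hydration_calculator(coords, self._is_lig_atom)),
            np.asarray(self.hydration_calculator(coords, None)),
            np.asarray(self.hydration_calculator(coords, ~self._is_lig_atom)),
        )

    def _bonded(self, coords: np.ndarray, key: str) -> float:
        bi, bj, bk, br0 = self._bond_arrays[key]
        u = 0.0
        if len(bi):
            r = np.linalg.norm(coords[bi] - coords[bj], axis=1)
            u += float(np.sum(bk * (r - br0) ** 2))
        ai, aj, ak, kth, th0 = self._angle_arrays[key]
        if len(ai):
            u1 = coords[ai] - coords[aj]
            v1 = coords[ak] - coords[aj]
            cosang = np.sum(u1 * v1, axis=1) / (
                np.linalg.norm(u1, axis=1) * np.linalg.norm(v1, axis=1)
            )
            th = np.arccos(np.clip(cosang, -1.0, 1.0))
            u += float(np.sum(kth * (th - th0) ** 2))
        di, dj, dk, dl, term_d, heights, ns, gammas = self._dihedral_arrays[key]
        if len(di):
            b1 = coords[dj] - coords[di]
            b2 = coords[dk] - coords[dj]
            b3 = coords[dl] - coords[dk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
            m1 = np.cross(n1, b2n)
            phi = np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))
            u += float(np.sum(heights * (1.0 + np.cos(ns * phi[term_d] - gammas))))
        return u

    def _go(self, coords: np.ndarray) -> float:
        if len(self.go_ca_i) == 0:
            return 0.0
        r = np.linalg.norm(coords[self.go_ca_i] - coords[self.go_ca_j], axis=1)
        r = np.maximum(r, MIN_PAIR_DISTANCE)
        eps = self.go_params.epsilon
        nat = ~np.isnan(self.go_r0)
        u = np.zeros(len(r))
        if np.any(nat):
            q = self.go_r0[nat] / r[nat]
            u[nat] = eps * (5.0 * q**12 - 6.0 * q**10)
        non = ~nat
        if np.any(non):
            q = self.go_params.r_hc / r[non]
            un = 5.0 * eps * q**12
            un[r[non] > self.settings.nonbonded_cutoff] = 0.0
            u[non] = un
        return float(np.sum(np.minimum(u, PAIR_ENERGY_CAP)))

    def _nonbonded(self, coords: np.ndarray) -> dict[int, tuple[float, float]]:
        """Per-pair-class (vdw, elec) sums with cutoff, SEDDD and capping."""
        out = {c: (0.0, 0.0) for c in range(5)}
        if len(self.pair_i) == 0:
            return out
        dr = coords[self.pair_i] - coords[self.pair_j]
        r2 = np.maximum(np.einsum("ij,ij->i", dr, dr), MIN_PAIR_DISTANCE**2)
        outside = r2 > self.settings.nonbonded_cutoff**2
        # van der Waals (12-6 from squared distances)
        q2 = self.pair_rmin * self.pair_rmin / r2
        q6 = q2 * q2 * q2
        e_vdw = self.pair_eps * (q6 * q6 - 2.0 * q6) * self.pair_vdw_scale
        np.clip(e_vdw, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP, out=e_vdw)
        e_vdw[outside] = 0.0
        # SEDDD electrostatics: K q_i q_j / (ε_ij r) with ε_ij ∝ r ⇒ 1/r² overall
        if np.any(self.pair_qq):
            v_lig, v_all, v_prot = self._hydration_three(coords)
            # interaction class picks the matching occluder set
            v_by_class = (v_lig, v_all, v_all, v_prot, v_prot)
            vsum = np.empty(len(r2))
            for c in range(5):
                lo, hi = self._class_bounds[c], self._class_bounds[c + 1]
                vc = v_by_class[c]
                vsum[lo:hi] = vc[self.pair_gi[lo:hi]] + vc[self.pair_gj[lo:hi]]
            s = np.minimum(self.seddd.c * vsum, S_MAX)
            eps_over_r = self.seddd.eps0 + (1.0 - s) * (self.seddd.eps1 - self.seddd.eps0)
            e_elec = self.pair_qq / (eps_over_r * r2) * self.pair_elec_scale
            np.clip(e_elec, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP, out=e_elec)
            e_elec[outside] = 0.0
        else:
            e_elec = None
        for c in range(5):
            lo, hi = self._class_bounds[c], self._class_bounds[c + 1]
            out[c] = (
                float(np.sum(e_vdw[lo:hi])),
                float(np.sum(e_elec[lo:hi])) if e_elec is not None else 0.0,
            )
        return out

    # -- public API ----------------------------------------------------------

    def compute(
        self, coords: np.ndarray | None = None, lam: LambdaState = LambdaState()
    ) -> EnergyBreakdown:
        """Full energy breakdown of a configuration at coupling ``lam``."""
        coords = self.system.coords if coords is None else np.asarray(coords, dtype=float)
        nb = self._nonbonded(coords)
        lig_v, lig_e = nb[self._LIG_LIG]
        aa_v, aa_e = nb[self._AA_AA]
        x_v, x_e = nb[self._AA_CG]
        ia_v, ia_e = nb[self._LIG_AA]
        ic_v, ic_e = nb[self._LIG_CG]
        return EnergyBreakdown(
            u_bb=self._bonded(coords, "bb"),
            u_go=self._go(coords),
            u_aa_protein=self._bonded(coords, "aa") + aa_v + aa_e,
            u_cross_protein=self._bonded(coords, "cross") + x_v + x_e,
            u_ligand=self._bonded(coords, "ligand") + lig_v + lig_e
            + sum(r.energy(coords) for r in self.restraints),
            u_int_aa_vdw=ia_v,
            u_int_aa_elec=ia_e,
            u_int_cg_vdw=ic_v,
            u_int_cg_elec=ic_e,
            lambda_state=lam,
        )

    def total_energy(
        self, coords: np.ndarray | None = None, lam: LambdaState = LambdaState()
    ) -> float:
        return self.compute(coords, lam).total

    def interaction_energy(self, coords: np.ndarray | None = None) -> float:
        """Protein–ligand vdW + electrostatic energy at full coupling (ranking score)."""
        return self.compute(coords, LambdaState(1.0, 1.0)).interaction
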