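"""Synthetic receptor–ligand fixtures with complete force-field parameters.

Everything here is generated programmatically and deterministically per seed,
so every stage of the pipeline — region assignment, mixed-resolution energies,
MC/NCMC sampling, docking and analysis — can be exercised without any
external structure downloads.  The fixtures do not emulate any particular
receptor quantitatively; parameter magnitudes are tuned so that ligand moves
at 300 K land in a useful acceptance range.

``make_two_state_toy`` builds a single-bead ligand inside a repulsive
spherical cage containing two attractive anchor sites of configurable depth;
its Boltzmann basin weights are computable by dense quadrature over the
ligand's translational coordinates, which makes it an exact oracle for
sampling-correctness tests of both plain MC and the mixed NCMC/MC protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from mrdock.energy import EnergyModel, FlatBottomRestraint, PAIR_ENERGY_CAP
from mrdock.errors import ValidationError
from mrdock.system import (
    AngleTerm,
    AtomRecord,
    BondTerm,
    DihedralTerm,
    LigandTopology,
    MolecularSystem,
    ResidueRecord,
    RotatableBond,
    SimulationSettings,
    detect_rotatable_bonds,
)
from mrdock.geometry import bond_angle, dihedral_angle

__all__ = ["ToySpec", "make_toy_receptor", "make_toy_ligand", "attach_ligand", "make_two_state_toy"]

# helix geometry (Å / degrees per residue)
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0

_BOND_K = 300.0  # kcal/mol/Å²
_ANGLE_K = 40.0  # kcal/mol/rad²

# per-atom-name (charge, rmin/2, epsilon)
_RECEPTOR_NB = {
    "N": (-0.20, 1.82, 0.17),
    "CA": (0.00, 1.91, 0.11),
    "C": (0.30, 1.91, 0.11),
    "O": (-0.30, 1.66, 0.21),
    "CB": (0.10, 1.95, 0.11),
    "CG": (0.10, 1.95, 0.11),
}


@dataclass
class ToySpec:
    """Size knobs for the synthetic receptor/ligand generators."""

    n_residues: int = 20
    n_atomistic_residues: int = 6
    ligand_size: int = 5
    n_rotatable_bonds: int = 2
    symmetric_ligand: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_residues, self.n_atomistic_residues, self.ligand_size) <= 0:
            raise ValidationError("all toy counts must be positive")
        if self.n_atomistic_residues > self.n_residues:
            raise ValidationError("atomistic residues cannot exceed total residues")


def make_toy_receptor(spec: ToySpec) -> dict:
    """Helix-like receptor with full backbone atoms and bead side chains.

    Backbone bonded terms take their equilibrium values from the constructed
    geometry, so the built configuration is (up to a small seeded jitter) a
    minimum of the bonded terms.  A central block of ``n_atomistic_residues``
    is labelled atomistic and carries two-bead side chains (CB–CG) with a
    rotatable CA–CB bond; all other residues are coarse with a single CB bead.
    Returns ``{"system", "site_center"}``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_residues
    atom_start = (n - spec.n_atomistic_residues) // 2
    atomistic = set(range(atom_start, atom_start + spec.n_atomistic_residues))

    ca = np.array(
        [
            [
                _HELIX_RADIUS * math.cos(math.radians(_HELIX_TWIST * i)),
                _HELIX_RADIUS * math.sin(math.radians(_HELIX_TWIST * i)),
                _HELIX_RISE * i,
            ]
            for i in range(n)
        ]
    )

    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    name_index: list[dict[str, int]] = []

    def radial(i: int) -> np.ndarray:
        v = ca[i].copy()
        v[2] = 0.0
        return v / np.linalg.norm(v)

    for i in range(n):
        res = ResidueRecord(index=i, name="ALA", region="atomistic" if i in atomistic else "coarse")
        prev_dir = (ca[i - 1] - ca[i]) if i > 0 else (ca[i] - ca[i + 1])
        next_dir = (ca[i + 1] - ca[i]) if i < n - 1 else (ca[i] - ca[i - 1])
        prev_dir = prev_dir / np.linalg.norm(prev_dir)
        next_dir = next_dir / np.linalg.norm(next_dir)
        out = radial(i)
        # lateral direction shared by N and C so successive C–N gaps stay short
        lat = np.cross(next_dir, out)
        lat = lat / np.linalg.norm(lat)
        n_dir = 0.82 * prev_dir + 0.57 * lat
        c_dir = 0.82 * next_dir + 0.57 * lat
        c_pos = ca[i] + 1.52 * c_dir / np.linalg.norm(c_dir)
        o_dir = -0.3 * next_dir - out
        positions = {
            "N": ca[i] + 1.46 * n_dir / np.linalg.norm(n_dir),
            "CA": ca[i],
            "C": c_pos,
            "O": c_pos + 1.23 * o_dir / np.linalg.norm(o_dir),
            "CB": ca[i] + 1.53 * out,
        }
        if i in atomistic:
            positions["CG"] = ca[i] + 3.0 * out
        local = {}
        for name, pos in positions.items():
            charge, rmin_half, eps = _RECEPTOR_NB[name]
            idx = len(atoms)
            atoms.append(
                AtomRecord(
                    index=idx,
                    name=name,
                    element=name[0],
                    position=pos + rng.normal(0.0, 0.01, size=3),
                    partial_charge=charge,
                    lj_rmin_half=rmin_half,
                    lj_epsilon=eps,
                    residue_index=i,
                    seddd_group_id=idx,
                    is_backbone=name in ("N", "CA", "C", "O"),
                )
            )
            res.atom_indices.append(idx)
            local[name] = idx
        res.calpha_index = local["CA"]
        residues.append(res)
        name_index.append(local)

    coords = np.array([a.position for a in atoms])
    bonds, angles, dihedrals, sidechain_bonds = [], [], [], []

    def add_bond(i, j):
        bonds.append(BondTerm(i, j, _BOND_K, float(np.linalg.norm(coords[i] - coords[j]))))

    def add_angle(i, j, k):
        angles.append(AngleTerm(i, j, k, _ANGLE_K, bond_angle(coords[i], coords[j], coords[k])))

    def add_dihedral(i, j, k, l):
        phi0 = dihedral_angle(coords[i], coords[j], coords[k], coords[l])
        dihedrals.append(DihedralTerm(i, j, k, l, terms=((1.0, 1, phi0 + math.pi),)))

    for i in range(n):
        loc = name_index[i]
        add_bond(loc["N"], loc["CA"])
        add_bond(loc["CA"], loc["C"])
        add_bond(loc["C"], loc["O"])
        add_bond(loc["CA"], loc["CB"])
        add_angle(loc["N"], loc["CA"], loc["C"])
        add_angle(loc["CA"], loc["C"], loc["O"])
        add_angle(loc["N"], loc["CA"], loc["CB"])
        if "CG" in loc:
            add_bond(loc["CB"], loc["CG"])
            add_angle(loc["CA"], loc["CB"], loc["CG"])
            sidechain_bonds.append(
                RotatableBond(atoms=(loc["CA"], loc["CB"]), moved=frozenset({loc["CG"]}))
            )
        if i < n - 1:
            nxt = name_index[i + 1]
            add_bond(loc["C"], nxt["N"])
            add_angle(loc["CA"], loc["C"], nxt["N"])
            add_angle(loc["C"], nxt["N"], nxt["CA"])
            add_dihedral(loc["N"], loc["CA"], loc["C"], nxt["N"])  # ψ_i
            add_dihedral(loc["C"], nxt["N"], nxt["CA"], nxt["C"])  # φ_{i+1}

    system = MolecularSystem(
        atoms, residues, bonds, angles, dihedrals, sidechain_bonds=sidechain_bonds
    )
    site_atoms = [name_index[i].get("CG", name_index[i]["CB"]) for i in sorted(atomistic)]
    tips = system.coords[site_atoms]
    center = tips.mean(axis=0)
    outward = center - np.array([0.0, 0.0, center[2]])
    outward = outward / np.linalg.norm(outward)
    site_center = center + 2.5 * outward
    return {"system": system, "site_center": site_center}


def make_toy_ligand(spec: ToySpec) -> LigandTopology:
    """Chain (or, for ``symmetric_ligand``, para-disubstituted ring) ligand.

    The chain variant has exactly ``n_rotatable_bonds`` rotatable bonds (extra
    atoms beyond the required chain length become terminal branches); the ring
    variant has none but a nontrivial graph automorphism group.
    """
    if spec.symmetric_ligand:
        elements = ["C"] * 6 + ["O", "O"]
        ring = np.array(
            [
                [1.4 * math.cos(math.radians(60 * i)), 1.4 * math.sin(math.radians(60 * i)), 0.0]
                for i in range(6)
            ]
        )
        subs = np.array([ring[0] * (1.0 + 1.36 / 1.4), ring[3] * (1.0 + 1.36 / 1.4)])
        coords = np.vstack([ring, subs])
        bonds = [(i, (i + 1) % 6, 1) for i in range(6)] + [(0, 6, 1), (3, 7, 1)]
    else:
        chain_len = spec.n_rotatable_bonds + 3
        n_branch = max(0, spec.ligand_size - chain_len)
        elements = ["C"] * (chain_len + n_branch)
        coords = np.array(
            [[1.25 * i, 0.5 * (i % 2), 0.0] for i in range(chain_len)]
            + [[1.25, 0.5 + 1.3 * (k + 1), 0.6 * (k % 2)] for k in range(n_branch)]
        )
        bonds = [(i, i + 1, 1) for i in range(chain_len - 1)] + [
            (1, chain_len + k, 1) for k in range(n_branch)
        ]
    lig = LigandTopology(elements=elements, coords=coords, bonds=bonds, rotatable_bonds=[])
    lig.rotatable_bonds = detect_rotatable_bonds(lig.graph())
    return lig


_LIGAND_NB = {"C": (0.0, 1.91, 0.109), "O": (0.0, 1.66, 0.21)}


def attach_ligand(
    receptor: MolecularSystem,
    ligand: LigandTopology,
    placement_center: np.ndarray,
) -> MolecularSystem:
    """Combine a receptor and a ligand into one parameterized system.

    The ligand is translated so its centroid sits at ``placement_center`` and
    becomes one atomistic ``LIG`` residue with harmonic bonds/angles at the
    built geometry, free torsions, zero charges and carbon/oxygen LJ types.
    """
    offset = receptor.n_atoms
    lig_coords = ligand.coords - ligand.coords.mean(axis=0) + np.asarray(placement_center, float)
    atoms = [
        AtomRecord(
            index=a.index,
            name=a.name,
            element=a.element,
            position=a.position,
            partial_charge=a.partial_charge,
            lj_rmin_half=a.lj_rmin_half,
            lj_epsilon=a.lj_epsilon,
            residue_index=a.residue_index,
            seddd_group_id=a.seddd_group_id,
            is_backbone=a.is_backbone,
            is_ligand=a.is_ligand,
        )
        for a in receptor.atoms
    ]
    residues = [
        ResidueRecord(
            index=r.index,
            name=r.name,
            atom_indices=list(r.atom_indices),
            calpha_index=r.calpha_index,
            region=r.region,
            is_ligand=r.is_ligand,
        )
        for r in receptor.residues
    ]
    lig_res = ResidueRecord(
        index=len(residues), name="LIG", region="atomistic", is_ligand=True
    )
    for k, el in enumerate(ligand.elements):
        _, rmin_half, eps = _LIGAND_NB.get(el.upper(), _LIGAND_NB["C"])
        # small alternating charges (net ~0) keep the electrostatic channel live
        charge = 0.1 if k % 2 == 0 else -0.1
        if len(ligand.elements) % 2 == 1 and k == len(ligand.elements) - 1:
            charge = 0.0
        idx = offset + k
        atoms.append(
            AtomRecord(
                index=idx,
                name=f"{el.upper()}{k + 1}",
                element=el,
                position=lig_coords[k],
                partial_charge=charge,
                lj_rmin_half=rmin_half,
                lj_epsilon=eps,
                residue_index=lig_res.index,
                seddd_group_id=idx,
                is_ligand=True,
            )
        )
        lig_res.atom_indices.append(idx)
    residues.append(lig_res)

    bonds = list(receptor.bonds)
    angles = list(receptor.angles)
    for a, b, _ in ligand.bonds:
        r0 = float(np.linalg.norm(lig_coords[a] - lig_coords[b]))
        bonds.append(BondTerm(offset + a, offset + b, _BOND_K, r0))
    graph = ligand.graph()
    for j in graph.nodes:
        nbrs = sorted(graph.neighbors(j))
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                th0 = bond_angle(lig_coords[i], lig_coords[j], lig_coords[k])
                angles.append(AngleTerm(offset + i, offset + j, offset + k, _ANGLE_K, th0))
    rot = [
        RotatableBond(
            atoms=(offset + rb.atoms[0], offset + rb.atoms[1]),
            moved=frozenset(offset + m for m in rb.moved),
        )
        for rb in ligand.rotatable_bonds
    ]
    return MolecularSystem(
        atoms,
        residues,
        bonds,
        angles,
        list(receptor.dihedrals),
        rotatable_bonds=rot,
        sidechain_bonds=list(receptor.sidechain_bonds),
    )


# ---------------------------------------------------------------------------
# Two-state toy with exact Boltzmann weights
# ---------------------------------------------------------------------------

_CAGE_RADIUS = 5.0
_N_CAGE = 140
_ANCHOR_X = 1.8
_WALL_NB = (0.0, 1.0, 1.0e-4)  # charge, rmin/2, epsilon
_ANCHOR_RMIN_HALF = 1.0
_LIG_BEAD_NB = (0.0, 1.0, 1.0)
_RESTRAINT = {"radius": 4.5, "k": 10.0}


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_two_state_toy(
    depth_a: float = 1.2, depth_b: float = 2.0, settings: SimulationSettings | None = None
) -> dict:
    """Rigid cage with two anchor pockets of depths ``depth_a``/``depth_b`` (kcal/mol).

    The single-bead ligand (zero charge) interacts with two anchors at
    (±1.8, 0, 0) through 12-6 wells whose pair depth equals the requested
    pocket depth, inside a repulsive spherical cage; a flat-bottom restraint
    (part of U_ligand, never λ-scaled) bounds the decoupled ligand.  Returns
    system, model, pocket centres and basin probabilities from quadrature via
    :func:`two_state_quadrature`.
    """
    settings = settings or SimulationSettings()
    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []

    def add_atom(name, element, pos, nb, res):
        charge, rmin_half, eps = nb
        idx = len(atoms)
        atoms.append(
            AtomRecord(
                index=idx,
                name=name,
                element=element,
                position=np.asarray(pos, float),
                partial_charge=charge,
                lj_rmin_half=rmin_half,
                lj_epsilon=eps,
                residue_index=res.index,
                seddd_group_id=idx,
                is_ligand=res.is_ligand,
            )
        )
        res.atom_indices.append(idx)
        return idx

    cage_res = ResidueRecord(index=0, name="CAG", region="atomistic")
    residues.append(cage_res)
    for pos in _fibonacci_sphere(_N_CAGE, _CAGE_RADIUS):
        add_atom("W", "C", pos, _WALL_NB, cage_res)
    pocket_res = ResidueRecord(index=1, name="PKT", region="atomistic")
    residues.append(pocket_res)
    # pair depth = sqrt(eps_anchor * eps_ligand) ⇒ eps_anchor = depth² / eps_lig
    eps_lig = _LIG_BEAD_NB[2]
    add_atom("PA", "C", (-_ANCHOR_X, 0.0, 0.0), (0.0, _ANCHOR_RMIN_HALF, depth_a**2 / eps_lig), pocket_res)
    add_atom("PB", "C", (+_ANCHOR_X, 0.0, 0.0), (0.0, _ANCHOR_RMIN_HALF, depth_b**2 / eps_lig), pocket_res)
    lig_res = ResidueRecord(index=2, name="LIG", region="atomistic", is_ligand=True)
    residues.append(lig_res)
    # start at the pocket-A pair minimum (2 Å above the anchor)
    lig_idx = add_atom("C1", "C", (-_ANCHOR_X, 0.0, 2.0), _LIG_BEAD_NB, lig_res)

    system = MolecularSystem(atoms, residues)
    restraint = FlatBottomRestraint(
        atom_indices=(lig_idx,), center=(0.0, 0.0, 0.0), **_RESTRAINT
    )
    model = EnergyModel(system, settings=settings, restraints=[restraint])
    return {
        "system": system,
        "model": model,
        "ligand_index": lig_idx,
        "pocket_a": np.array([-_ANCHOR_X, 0.0, 0.0]),
        "pocket_b": np.array([+_ANCHOR_X, 0.0, 0.0]),
        "restraint": restraint,
        "settings": settings,
    }


def two_state_quadrature(
    toy: dict, beta: float, spacing: float = 0.25, extent: float = 5.2
) -> tuple[float, float]:
    """Basin probabilities (P_A, P_B) by dense quadrature over ligand translation.

    Independent of :class:`EnergyModel`: the ligand–receptor 12-6 sum,
    truncation, capping and restraint are re-derived in closed form on a cubic
    grid; the basins are the x<0 and x>0 half-spaces.  Grid points straddle
    x = 0 symmetrically so neither basin is favoured by discretization.
    """
    system: MolecularSystem = toy["system"]
    lig = toy["ligand_index"]
    rec = [a for a in system.atoms if a.index != lig]
    rec_xyz = np.array([a.position for a in rec])
    rmin = np.array([a.lj_rmin_half for a in rec]) + system.atoms[lig].lj_rmin_half
    eps = np.sqrt(np.array([a.lj_epsilon for a in rec]) * system.atoms[lig].lj_epsilon)
    restraint: FlatBottomRestraint = toy["restraint"]
    cutoff = toy["settings"].nonbonded_cutoff

    half = np.arange(0.5, extent / spacing + 0.5) * spacing
    axis = np.concatenate([-half[::-1], half])  # symmetric, excludes 0
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    w = np.zeros(len(pts))
    chunk = 20000
    for start in range(0, len(pts), chunk):
        p = pts[start:start + chunk]
        d = np.linalg.norm(p[:, None, :] - rec_xyz[None, :, :], axis=-1)
        d = np.maximum(d, 1e-6)
        q6 = (rmin[None, :] / d) ** 6
        e = eps[None, :] * (q6 * q6 - 2.0 * q6)
        e = np.clip(e, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP)
        e[d > cutoff] = 0.0
        u = e.sum(axis=1)
        r = np.linalg.norm(p - np.asarray(restraint.center), axis=1)
        u += restraint.k * np.maximum(0.0, r - restraint.radius) ** 2
        w[start:start + chunk] = np.exp(-beta * np.minimum(u, 500.0 / beta))
    total = w.sum()
    p_a = float(w[pts[:, 0] < 0].sum() / total)
    return p_a, 1.0 - p_a
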