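"""Mixed-resolution molecular system: containers, structure I/O, region labels.

The topology (atoms, residues, bonded terms, rotatable bonds) is held in a
:class:`MolecularSystem`; simulation *configurations* are plain ``(n_atoms, 3)``
coordinate arrays in Å, so the Monte Carlo engine can copy and restore them
cheaply.  ``system.coords`` holds the configuration the system was built with.

Force-field parameters (partial charges, Lennard-Jones ``rmin/2`` and well
depth, bonded term tables) live on the system and are populated either by the
toy-fixture generator or from the native YAML parameter schema
(:func:`save_parameters` / :func:`load_parameters`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import yaml

from mrdock.constants import BOLTZMANN_KCAL, atomic_mass
from mrdock.errors import ParameterError, StructureFormatError, ValidationError

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "RotatableBond",
    "LigandTopology",
    "MolecularSystem",
    "SimulationSettings",
    "read_structure",
    "write_structure",
    "read_ligand",
    "detect_rotatable_bonds",
    "assign_regions",
    "save_parameters",
    "load_parameters",
]

#: Backbone atom names (plus common terminal variants).
BACKBONE_ATOM_NAMES = frozenset(
    {"N", "H", "H1", "H2", "H3", "CA", "HA", "HA2", "HA3", "C", "O", "OXT"}
)

#: Minimal per-residue template used to validate protein residues on input.
_REQUIRED_PROTEIN_ATOMS = ("N", "CA", "C")


@dataclass
class AtomRecord:
    """One atom: identity, initial position and nonbonded parameters."""

    index: int
    name: str
    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0
    residue_index: int = 0
    seddd_group_id: int = 0
    is_backbone: bool = False
    is_ligand: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.index}: position must be a finite 3-vector")
        if self.lj_epsilon < 0:
            raise ValidationError(f"atom {self.index}: lj_epsilon must be >= 0")


@dataclass
class ResidueRecord:
    """One residue; ``region`` is 'atomistic' or 'coarse'."""

    index: int
    name: str
    atom_indices: list[int] = field(default_factory=list)
    calpha_index: int | None = None
    region: str = "atomistic"
    is_ligand: bool = False


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond U = k (r - r0)^2 (AMBER convention)."""

    i: int
    j: int
    k: float  # kcal/mol/Å²
    r0: float  # Å


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle U = k (θ - θ0)^2, θ0 in radians."""

    i: int
    j: int
    k: int
    k_theta: float  # kcal/mol/rad²
    theta0: float  # rad


@dataclass(frozen=True)
class DihedralTerm:
    """Fourier dihedral U = Σ_n height_n (1 + cos(n φ - γ_n)).

    ``terms`` is a tuple of ``(height, periodicity, phase_rad)`` with
    height = V_n/2 in kcal/mol.
    """

    i: int
    j: int
    k: int
    l: int
    terms: tuple[tuple[float, int, float], ...]


@dataclass(frozen=True)
class RotatableBond:
    """A rotatable single bond: pivot atom pair and the set of atoms rotated."""

    atoms: tuple[int, int]
    moved: frozenset[int]

    def __post_init__(self) -> None:
        a, b = self.atoms
        if a in self.moved or b in self.moved:
            raise ValidationError("rotated-side set must not contain the pivot atoms")
        if not self.moved:
            raise ValidationError("rotated-side set is empty")


@dataclass
class LigandTopology:
    """Ligand connection table as read from SDF/MOL2 (indices local to ligand)."""

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, int]]  # (a, b, order)
    rotatable_bonds: list[RotatableBond]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for idx, el in enumerate(self.elements):
            g.add_node(idx, element=el.upper())
        for a, b, order in self.bonds:
            g.add_edge(a, b, order=order)
        return g


class MolecularSystem:
    """Atoms + residues + bonded parameter tables for a mixed-resolution system."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        residues: Sequence[ResidueRecord],
        bonds: Sequence[BondTerm] = (),
        angles: Sequence[AngleTerm] = (),
        dihedrals: Sequence[DihedralTerm] = (),
        rotatable_bonds: Sequence[RotatableBond] = (),
        sidechain_bonds: Sequence[RotatableBond] = (),
    ):
        self.atoms = list(atoms)
        self.residues = list(residues)
        self.bonds = list(bonds)
        self.angles = list(angles)
        self.dihedrals = list(dihedrals)
        self.rotatable_bonds = list(rotatable_bonds)
        #: per-residue side-chain rotatable bonds (atomistic residues only are used)
        self.sidechain_bonds = list(sidechain_bonds)
        self.coords = np.array([a.position for a in self.atoms], dtype=float)
        self._validate_topology()

    # -- basic queries -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def ligand_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_ligand]

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return self.array("partial_charge").astype(float)

    @property
    def is_ligand_mask(self) -> np.ndarray:
        return self.array("is_ligand").astype(bool)

    @property
    def is_backbone_mask(self) -> np.ndarray:
        return self.array("is_backbone").astype(bool)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(a.element) for a in self.atoms])

    def region_of_atoms(self) -> np.ndarray:
        """Per-atom region label: 'atomistic' or 'coarse'."""
        res_region = {r.index: r.region for r in self.residues}
        return np.array([res_region[a.residue_index] for a in self.atoms])

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((b.i, b.j) for b in self.bonds)
        return g

    def backbone_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_backbone and not a.is_ligand]

    def copy_coords(self) -> np.ndarray:
        return self.coords.copy()

    # -- validation ----------------------------------------------------------

    def _validate_topology(self) -> None:
        n = self.n_atoms
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValidationError(f"bond ({b.i},{b.j}) has out-of-range atom index")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k)):
                raise ValidationError(f"angle ({a.i},{a.j},{a.k}) has out-of-range atom index")
        for d in self.dihedrals:
            if not all(0 <= x < n for x in (d.i, d.j, d.k, d.l)):
                raise ValidationError("dihedral has out-of-range atom index")
        seen = set()
        for r in self.residues:
            for ai in r.atom_indices:
                if ai in seen:
                    raise ValidationError(f"atom {ai} assigned to more than one residue")
                seen.add(ai)
        for r in self.residues:
            if r.region not in ("atomistic", "coarse"):
                raise ValidationError(f"residue {r.index}: unknown region {r.region!r}")
            if r.region == "coarse" and r.calpha_index is None:
                raise ValidationError(f"coarse residue {r.index} has no α-carbon")
            if r.is_ligand and r.region != "atomistic":
                raise ValidationError("ligand residues must be atomistic")
        graph = self.bond_graph()
        for rb in self.rotatable_bonds + self.sidechain_bonds:
            a, b = rb.atoms
            if not graph.has_edge(a, b):
                raise ValidationError(f"rotatable bond {rb.atoms} is not a bond")


@dataclass
class SimulationSettings:
    """Global simulation parameters (defaults: 300 K, 10 Å nonbonded cutoff)."""

    temperature: float = 300.0
    boltzmann_constant: float = BOLTZMANN_KCAL
    nonbonded_cutoff: float = 10.0
    go_native_cutoff: float = 8.0
    rng_seed: int = 0

    @property
    def beta(self) -> float:
        """1/(k_B T), mol/kcal."""
        return 1.0 / (self.boltzmann_constant * self.temperature)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: str) -> None:
    """Check ATOM/HETATM coordinate fields parse, naming the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureFormatError(
                    f"{path}:{lineno}: truncated ATOM/HETATM record"
                )
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureFormatError(
                        f"{path}:{lineno}: unparseable {what} coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def read_structure(
    path: str,
    ligand_resnames: Iterable[str] = ("LIG", "UNL", "UNK"),
    validate_templates: bool = True,
) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem` (topology without parameters).

    Residues whose name is in ``ligand_resnames`` (or that arrive as HETATM
    records other than water) are flagged as ligand.  Only ATOM/HETATM records
    are used.  Partial charges and LJ parameters are left at zero; populate
    them from a parameter file or set them programmatically.
    """
    import biotite.structure.io.pdb as pdbio

    _prevalidate_pdb(path)
    try:
        pdb_file = pdbio.PDBFile.read(path)
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises several types
        raise StructureFormatError(f"{path}: {exc}") from exc

    ligand_resnames = {s.upper() for s in ligand_resnames}
    atoms: list[AtomRecord] = []
    residues: list[ResidueRecord] = []
    res_key_to_idx: dict[tuple, int] = {}
    for i in range(arr.array_length()):
        resname = str(arr.res_name[i]).upper()
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), resname)
        is_lig = resname in ligand_resnames or (
            bool(arr.hetero[i]) and resname not in ("HOH", "WAT")
        )
        if key not in res_key_to_idx:
            res_key_to_idx[key] = len(residues)
            residues.append(
                ResidueRecord(index=len(residues), name=resname, is_ligand=is_lig)
            )
        ridx = res_key_to_idx[key]
        name = str(arr.atom_name[i])
        element = str(arr.element[i]) or name[0]
        atom = AtomRecord(
            index=len(atoms),
            name=name,
            element=element,
            position=np.asarray(arr.coord[i], dtype=float),
            residue_index=ridx,
            seddd_group_id=len(atoms),
            is_backbone=(name in BACKBONE_ATOM_NAMES and not is_lig),
            is_ligand=is_lig,
        )
        atoms.append(atom)
        residues[ridx].atom_indices.append(atom.index)
        if name == "CA" and not is_lig:
            residues[ridx].calpha_index = atom.index

    if validate_templates:
        for r in residues:
            if r.is_ligand:
                continue
            names = {atoms[ai].name for ai in r.atom_indices}
            missing = [n for n in _REQUIRED_PROTEIN_ATOMS if n not in names]
            if missing:
                raise ValidationError(
                    f"residue {r.index} ({r.name}) is missing required atoms: {missing}"
                )
    return MolecularSystem(atoms, residues)


def write_structure(system: MolecularSystem, path: str, coords: np.ndarray | None = None) -> None:
    """Write the system (or an alternative configuration) as a PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    coords = system.coords if coords is None else np.asarray(coords, dtype=float)
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array([system.atoms[i].residue_index + 1 for i in range(n)])
    arr.res_name = np.array(
        [system.residues[system.atoms[i].residue_index].name[:3] or "UNK" for i in range(n)]
    )
    arr.atom_name = np.array([system.atoms[i].name[:4] for i in range(n)])
    arr.element = np.array([system.atoms[i].element.upper() for i in range(n)])
    arr.hetero = np.array([system.atoms[i].is_ligand for i in range(n)])
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Ligand I/O (via RDKit) and rotatable-bond detection
# ---------------------------------------------------------------------------

def detect_rotatable_bonds(graph: nx.Graph, bond_orders: dict | None = None) -> list[RotatableBond]:
    """Rotatable bonds of a molecular graph.

    Rule: acyclic single bonds between heavy atoms where each end has at least
    one further heavy-atom neighbour, excluding amide C–N bonds.  The rotated
    side is the smaller of the two components obtained by deleting the bond
    (ties: the side of the second atom).  Node attribute ``element`` is
    required; edge attribute ``order`` defaults to 1.
    """
    def element(n):
        return graph.nodes[n]["element"].upper()

    def heavy_neighbors(n, exclude):
        return [m for m in graph.neighbors(n) if m != exclude and element(m) != "H"]

    ring_edges = set()
    for cycle in nx.cycle_basis(graph):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add(frozenset((a, b)))

    def is_amide(a, b):
        # C(=O)-N single bond
        for c, n_ in ((a, b), (b, a)):
            if element(c) == "C" and element(n_) == "N":
                for m in graph.neighbors(c):
                    order = graph.edges[c, m].get("order", 1)
                    if m != n_ and element(m) == "O" and order == 2:
                        return True
        return False

    out: list[RotatableBond] = []
    for a, b in sorted(graph.edges()):
        order = graph.edges[a, b].get("order", 1)
        if order != 1 or frozenset((a, b)) in ring_edges:
            continue
        if element(a) == "H" or element(b) == "H":
            continue
        if not heavy_neighbors(a, b) or not heavy_neighbors(b, a):
            continue
        if is_amide(a, b):
            continue
        g2 = graph.copy()
        g2.remove_edge(a, b)
        side_a = nx.node_connected_component(g2, a)
        side_b = nx.node_connected_component(g2, b)
        moved = side_b if len(side_b) <= len(side_a) else side_a
        pivot = (a, b) if moved is side_b else (b, a)
        out.append(RotatableBond(atoms=pivot, moved=frozenset(moved - set(pivot))))
    return out


def read_ligand(path: str) -> LigandTopology:
    """Read a ligand (SDF V2000 or MOL2) into a :class:`LigandTopology`."""
    from rdkit import Chem

    lower = path.lower()
    if lower.endswith(".mol2"):
        mol = Chem.MolFromMol2File(path, removeHs=False, sanitize=True)
    elif lower.endswith((".sdf", ".mol")):
        mol = Chem.MolFromMolFile(path, removeHs=False, sanitize=True)
    else:
        raise StructureFormatError(f"{path}: unsupported ligand format")
    if mol is None:
        raise StructureFormatError(f"{path}: RDKit could not parse the file")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise ValidationError(f"{path}: ligand graph is disconnected ({len(frags)} fragments)")

    conf = mol.GetConformer()
    elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    bonds = []
    for b in mol.GetBonds():
        order = int(round(b.GetBondTypeAsDouble()))
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(order, 1)))
    lig = LigandTopology(elements=elements, coords=coords, bonds=bonds, rotatable_bonds=[])
    lig.rotatable_bonds = detect_rotatable_bonds(lig.graph())
    return lig


# ---------------------------------------------------------------------------
# Region assignment
# ---------------------------------------------------------------------------

def assign_regions(
    system: MolecularSystem,
    references: Sequence[MolecularSystem],
    contact_cutoff: float = 3.0,
    explicit_residues: Iterable[int] = (),
) -> list[str]:
    """Label each residue 'atomistic' or 'coarse' and apply the labels in place.

    A residue is atomistic iff it is in ``explicit_residues``, or any of its
    non-hydrogen atoms lies within ``contact_cutoff`` Å of any ligand
    non-hydrogen atom in any reference complex.  Ligand residues are always
    atomistic.  Returns the per-residue label list.
    """
    explicit = set(explicit_residues)
    n_res = system.n_residues
    for ref in references:
        if ref.n_residues != n_res:
            raise ValidationError(
                f"reference has {ref.n_residues} residues, system has {n_res}"
            )
        for rs, rr in zip(system.residues, ref.residues):
            if rs.name != rr.name:
                raise ValidationError(
                    f"residue {rs.index}: name mismatch with reference "
                    f"({rs.name} vs {rr.name})"
                )

    contact: set[int] = set()
    for ref in references:
        heavy = np.array([a.element.upper() != "H" for a in ref.atoms])
        lig = ref.is_ligand_mask
        lig_xyz = ref.coords[lig & heavy]
        if lig_xyz.size == 0:
            continue
        for res in ref.residues:
            if res.is_ligand:
                continue
            idx = [ai for ai in res.atom_indices if heavy[ai]]
            if not idx:
                continue
            d = np.linalg.norm(ref.coords[idx][:, None, :] - lig_xyz[None, :, :], axis=-1)
            if d.min() <= contact_cutoff:
                contact.add(res.index)

    labels = []
    for res in system.residues:
        if res.is_ligand or res.index in explicit or res.index in contact:
            region = "atomistic"
        else:
            region = "coarse"
        res.region = region
        labels.append(region)
    for res in system.residues:
        if res.region == "coarse" and res.calpha_index is None:
            raise ValidationError(f"coarse residue {res.index} has no α-carbon")
    return labels


# ---------------------------------------------------------------------------
# Native parameter schema (YAML)
# ---------------------------------------------------------------------------

def save_parameters(system: MolecularSystem, path: str) -> None:
    """Write per-atom nonbonded and all bonded parameters as YAML."""
    doc = {
        "atoms": [
            {
                "index": a.index,
                "name": a.name,
                "element": a.element,
                "charge": float(a.partial_charge),
                "rmin_half": float(a.lj_rmin_half),
                "epsilon": float(a.lj_epsilon),
                "group": int(a.seddd_group_id),
            }
            for a in system.atoms
        ],
        "bonds": [[b.i, b.j, float(b.k), float(b.r0)] for b in system.bonds],
        "angles": [
            [a.i, a.j, a.k, float(a.k_theta), math.degrees(a.theta0)] for a in system.angles
        ],
        "dihedrals": [
            {
                "atoms": [d.i, d.j, d.k, d.l],
                "terms": [[float(h), int(n), math.degrees(g)] for h, n, g in d.terms],
            }
            for d in system.dihedrals
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(system: MolecularSystem, path: str) -> MolecularSystem:
    """Populate ``system``'s parameters in place from the native YAML schema."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise ParameterError(f"{path}: not a parameter file (no 'atoms' section)")
    entries = doc["atoms"]
    if len(entries) != system.n_atoms:
        raise ParameterError(
            f"{path}: {len(entries)} atom entries for a {system.n_atoms}-atom system"
        )
    for entry in entries:
        try:
            a = system.atoms[int(entry["index"])]
            a.partial_charge = float(entry["charge"])
            a.lj_rmin_half = float(entry["rmin_half"])
            a.lj_epsilon = float(entry["epsilon"])
            a.seddd_group_id = int(entry.get("group", a.seddd_group_id))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterError(f"{path}: malformed atom entry {entry!r}") from exc
    system.bonds = [BondTerm(int(i), int(j), float(k), float(r0)) for i, j, k, r0 in doc.get("bonds", [])]
    system.angles = [
        AngleTerm(int(i), int(j), int(k), float(kt), math.radians(float(t0)))
        for i, j, k, kt, t0 in doc.get("angles", [])
    ]
    system.dihedrals = [
        DihedralTerm(
            *(int(x) for x in d["atoms"]),
            terms=tuple((float(h), int(n), math.radians(float(g))) for h, n, g in d["terms"]),
        )
        for d in doc.get("dihedrals", [])
    ]
    return system
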