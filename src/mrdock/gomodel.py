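"""Coarse-grained energy: 12-10 Gō pair potential + atomistic backbone terms.

The coarse region's nonbonded interactions are represented on the α-carbons:
residue pairs in contact in the reference ("native") structure get an
attractive 12-10 well at the native distance r0,

    U_native(r)    = ε [5 (r0/r)^12 − 6 (r0/r)^10]          (depth −ε at r = r0)
    U_nonnative(r) = 5 ε (r_hc/r)^12                          (pure repulsion)

while the coarse backbone keeps its atomistic bond/angle/dihedral terms
(harmonic AMBER convention k(x − x0)², Fourier dihedrals; no 1-4 nonbonded
terms).  Side-chain atoms of coarse residues do not contribute here — they
interact only across the region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from mrdock.errors import DomainError, ValidationError
from mrdock.geometry import bond_angle, dihedral_angle
from mrdock.system import MolecularSystem

__all__ = [
    "GoParameters",
    "NativeContact",
    "build_native_contacts",
    "go_pair_energy",
    "backbone_energy",
    "cg_energy",
    "save_contacts",
    "load_contacts",
]

#: Minimum sequence separation for a Gō pair (smaller separations are covered
#: by the backbone bonded terms).
MIN_SEQUENCE_SEPARATION = 3


@dataclass(frozen=True)
class GoParameters:
    """Well depth ε (kcal/mol), hard-core radius (Å), native-contact cutoff (Å)."""

    epsilon: float = 3.0
    r_hc: float = 1.7
    native_cutoff: float = 8.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.r_hc <= 0 or self.native_cutoff <= 0:
            raise ValidationError("Gō parameters must be positive")


@dataclass(frozen=True)
class NativeContact:
    """Residue pair (i < j) in contact in the reference structure, at distance r0."""

    residue_i: int
    residue_j: int
    r0: float

    def __post_init__(self):
        if self.residue_i >= self.residue_j:
            raise ValidationError("native contact requires residue_i < residue_j")
        if self.r0 <= 0:
            raise ValidationError("native distance must be positive")


def build_native_contacts(
    reference: MolecularSystem,
    params: GoParameters = GoParameters(),
    reference_coords: np.ndarray | None = None,
) -> list[NativeContact]:
    """Native contacts between coarse residues of the reference structure.

    A contact is any coarse–coarse residue pair with Cα–Cα distance below the
    native cutoff and sequence separation ≥ 3; r0 is the reference distance.
    """
    coords = reference.coords if reference_coords is None else reference_coords
    coarse = [r for r in reference.residues if r.region == "coarse"]
    for r in coarse:
        if r.calpha_index is None:
            raise ValidationError(f"coarse residue {r.index} has no α-carbon")
    contacts: list[NativeContact] = []
    for a_pos, ra in enumerate(coarse):
        for rb in coarse[a_pos + 1:]:
            if abs(rb.index - ra.index) < MIN_SEQUENCE_SEPARATION:
                continue
            d = float(np.linalg.norm(coords[ra.calpha_index] - coords[rb.calpha_index]))
            if d < params.native_cutoff:
                lo, hi = sorted((ra.index, rb.index))
                contacts.append(NativeContact(lo, hi, d))
    return contacts


def go_pair_energy(
    r: float, is_native: bool, r0: float | None = None, params: GoParameters = GoParameters()
) -> float:
    """12-10 Gō pair energy (kcal/mol) at Cα separation ``r`` Å."""
    if r <= 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    if is_native:
        if r0 is None:
            raise DomainError("native pair requires r0")
        q = r0 / r
        return params.epsilon * (5.0 * q**12 - 6.0 * q**10)
    q = params.r_hc / r
    return 5.0 * params.epsilon * q**12


def backbone_energy(system: MolecularSystem, coords: np.ndarray | None = None) -> float:
    """Bond + angle + dihedral energy over backbone atoms of coarse residues.

    Only terms whose atoms are *all* backbone atoms of coarse residues count;
    1-4 nonbonded terms are deliberately absent from the coarse region.
    """
    coords = system.coords if coords is None else coords
    region = system.region_of_atoms()
    bb = system.is_backbone_mask

    def eligible(*idx: int) -> bool:
        return all(bb[i] and region[i] == "coarse" for i in idx)

    u = 0.0
    for b in system.bonds:
        if eligible(b.i, b.j):
            r = float(np.linalg.norm(coords[b.i] - coords[b.j]))
            u += b.k * (r - b.r0) ** 2
    for a in system.angles:
        if eligible(a.i, a.j, a.k):
            th = bond_angle(coords[a.i], coords[a.j], coords[a.k])
            u += a.k_theta * (th - a.theta0) ** 2
    for d in system.dihedrals:
        if eligible(d.i, d.j, d.k, d.l):
            phi = dihedral_angle(coords[d.i], coords[d.j], coords[d.k], coords[d.l])
            for height, n, gamma in d.terms:
                u += height * (1.0 + np.cos(n * phi - gamma))
    return float(u)


def cg_energy(
    system: MolecularSystem,
    contacts: Sequence[NativeContact],
    params: GoParameters = GoParameters(),
    coords: np.ndarray | None = None,
    nonbonded_cutoff: float = 10.0,
) -> tuple[float, float, float]:
    """(U_bb, U_Gō, U_CG) for a configuration; U_CG = U_bb + U_Gō exactly.

    The Gō sum runs over all coarse–coarse residue pairs with sequence
    separation ≥ 3: native pairs use the 12-10 well at their r0; all other
    pairs use the hard-core repulsion, truncated at ``nonbonded_cutoff``.
    """
    coords = system.coords if coords is None else coords
    u_bb = backbone_energy(system, coords)
    native = {(c.residue_i, c.residue_j): c.r0 for c in contacts}
    coarse = [r for r in system.residues if r.region == "coarse"]
    u_go = 0.0
    for a_pos, ra in enumerate(coarse):
        for rb in coarse[a_pos + 1:]:
            if abs(rb.index - ra.index) < MIN_SEQUENCE_SEPARATION:
                continue
            key = tuple(sorted((ra.index, rb.index)))
            r = float(np.linalg.norm(coords[ra.calpha_index] - coords[rb.calpha_index]))
            if key in native:
                u_go += go_pair_energy(r, True, native[key], params)
            elif r <= nonbonded_cutoff:
                u_go += go_pair_energy(r, False, params=params)
    return u_bb, u_go, u_bb + u_go


def save_contacts(contacts: Sequence[NativeContact], path: str) -> None:
    """Write contacts as a three-column (i, j, r0) tab-separated table."""
    with open(path, "w") as fh:
        fh.write("residue_i\tresidue_j\tr0\n")
        for c in contacts:
            fh.write(f"{c.residue_i}\t{c.residue_j}\t{c.r0:.6f}\n")


def load_contacts(path: str) -> list[NativeContact]:
    """Read a contact table written by :func:`save_contacts`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("residue_i"):
            raise ValidationError(f"{path}: not a contact table")
        for line in fh:
            i, j, r0 = line.split()
            out.append(NativeContact(int(i), int(j), float(r0)))
    return out
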