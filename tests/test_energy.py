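"""Atomistic energies: SEDDD electrostatics, hydration volumes, total assembly."""

import math

import networkx as nx
import numpy as np
import pytest

from mrdock.constants import COULOMB_KCAL
from mrdock.energy import (
    EnergyModel,
    HydrationParameters,
    LambdaState,
    SedddParameters,
    compute_hydration_volumes,
    pair_overlap,
    seddd_dielectric,
)
from mrdock.errors import DomainError, ValidationError
from mrdock.geometry import rotation_matrix
from mrdock.gomodel import GoParameters
from mrdock.system import AtomRecord, MolecularSystem, ResidueRecord, SimulationSettings

DEFAULTS = SedddParameters()

from hypothesis import given, settings, strategies as st  # noqa: E402


class TestSedddProperties:
    """Algebraic properties of Eqs for ε_ij and s_kl over their whole domain."""

    @given(r=st.floats(0.1, 50.0), s=st.floats(0.0, 0.999))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_dielectric_bounds(self, r, s):
        eps = seddd_dielectric(r, s, DEFAULTS)
        assert r * DEFAULTS.eps0 <= eps <= r * DEFAULTS.eps1 + 1e-12

    @given(v1=st.floats(0.0, 5.0), v2=st.floats(0.0, 5.0))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_overlap_symmetric_and_clamped(self, v1, v2):
        s = pair_overlap(v1, v2)
        assert s == pair_overlap(v2, v1)
        assert 0.0 <= s < 1.0


class TestSeddd:
    def test_fully_exposed_at_ten_angstrom(self):
        """ε₁ = 8 with the linear distance dependence gives 80 at 10 Å."""
        assert seddd_dielectric(10.0, 0.0, DEFAULTS) == pytest.approx(80.0)

    def test_fully_buried_limit(self):
        assert seddd_dielectric(1.0, 1.0 - 1e-12, DEFAULTS) == pytest.approx(2.0)

    def test_hand_value(self):
        assert seddd_dielectric(5.0, 0.5, DEFAULTS) == pytest.approx(25.0)

    def test_linear_in_distance_and_monotone_in_overlap(self):
        r = np.linspace(1.0, 12.0, 50)
        eps = seddd_dielectric(r, 0.3, DEFAULTS)
        slopes = np.diff(eps) / np.diff(r)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)
        s = np.linspace(0.0, 0.999, 100)
        eps_s = seddd_dielectric(5.0, s, DEFAULTS)
        assert np.all(np.diff(eps_s) < 0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            seddd_dielectric(0.0, 0.0, DEFAULTS)
        with pytest.raises(DomainError):
            seddd_dielectric(5.0, 1.5, DEFAULTS)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            SedddParameters(eps0=8.0, eps1=2.0)


class TestPairOverlap:
    def test_zero_volumes(self):
        assert pair_overlap(0.0, 0.0) == 0.0

    def test_hand_value(self):
        assert pair_overlap(0.3, 0.5, c=0.625) == pytest.approx(0.5)

    def test_clamped_below_one(self):
        s = pair_overlap(1.0, 1.0, c=0.625)
        assert 0.0 <= s < 1.0

    def test_symmetric(self):
        assert pair_overlap(0.2, 0.7) == pair_overlap(0.7, 0.2)


class TestHydrationVolumes:
    HP = HydrationParameters()

    def test_isolated_group_fully_exposed(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        vols = np.array([20.0, 20.0])
        v = compute_hydration_volumes(coords, [[0], [1]], vols, self.HP)
        np.testing.assert_allclose(v, 0.0)

    def test_complete_overlap_reaches_maximum(self):
        """A group duplicated in place occludes the shell up to the cap."""
        coords = np.zeros((2, 3))
        vols = np.full(2, self.HP.reference_volume * self.HP.v_max)
        v = compute_hydration_volumes(coords, [[0], [1]], vols, self.HP)
        assert v[0] == pytest.approx(self.HP.v_max)

    def test_monotone_in_neighbor_distance(self):
        vols = np.array([20.0, 20.0])
        scan = []
        for d in np.linspace(0.5, 9.5, 40):
            coords = np.array([[0.0, 0, 0], [d, 0, 0]])
            scan.append(compute_hydration_volumes(coords, [[0], [1]], vols, self.HP)[0])
        assert all(a >= b for a, b in zip(scan, scan[1:]))
        assert scan[-1] == 0.0  # beyond cutoff

    def test_occluder_mask_restricts_contributions(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [2.0, 1, 0]])
        vols = np.full(3, 20.0)
        full = compute_hydration_volumes(coords, [[0], [1], [2]], vols, self.HP)
        masked = compute_hydration_volumes(
            coords, [[0], [1], [2]], vols, self.HP, occluder_mask=[True, True, False]
        )
        assert masked[0] < full[0]


def _pair_system(q1, q2, distance, rmin_half=0.0, eps=0.0, both_ligand=False):
    """One protein atom + one atom (ligand or protein) at a given separation."""
    a0 = AtomRecord(index=0, name="X1", element="C", position=[0, 0, 0],
                    partial_charge=q1, lj_rmin_half=rmin_half, lj_epsilon=eps,
                    residue_index=0, seddd_group_id=0, is_ligand=both_ligand)
    a1 = AtomRecord(index=1, name="X2", element="C", position=[distance, 0, 0],
                    partial_charge=q2, lj_rmin_half=rmin_half, lj_epsilon=eps,
                    residue_index=1, seddd_group_id=1, is_ligand=True)
    r0 = ResidueRecord(index=0, name="GLY" if not both_ligand else "LIG",
                       atom_indices=[0], is_ligand=both_ligand)
    r1 = ResidueRecord(index=1, name="LIG", atom_indices=[1], is_ligand=True)
    return MolecularSystem([a0, a1], [r0, r1])


class TestNonbonded:
    def test_exposed_charge_pair_closed_form(self):
        """Two +1e charges 10 Å apart, fully exposed: 332.0636/(80·10) kcal/mol."""
        system = _pair_system(1.0, 1.0, 10.0)
        model = EnergyModel(system)
        bd = model.compute()
        assert bd.u_elec_int == pytest.approx(COULOMB_KCAL / (80.0 * 10.0), rel=1e-12)
        assert bd.u_vdw_int == 0.0

    def test_lj_minimum_depth(self):
        system = _pair_system(0.0, 0.0, 3.8, rmin_half=1.9, eps=0.25)
        bd = EnergyModel(system).compute()
        assert bd.u_vdw_int == pytest.approx(-0.25, rel=1e-12)

    def test_cutoff_truncation(self):
        system = _pair_system(1.0, 1.0, 10.1, rmin_half=1.9, eps=0.25)
        bd = EnergyModel(system).compute()
        assert bd.u_vdw_int == 0.0 and bd.u_elec_int == 0.0

    def test_inverse_square_distance_scaling_when_exposed(self):
        """With s = 0, ε_ij ∝ r makes the pair energy scale as 1/r²."""
        zero_hydration = lambda coords, mask=None: np.zeros(2)  # noqa: E731
        energies = []
        dists = np.array([2.0, 4.0, 8.0])
        for d in dists:
            model = EnergyModel(_pair_system(1.0, 1.0, d),
                                hydration_calculator=zero_hydration)
            energies.append(model.compute().u_elec_int)
        np.testing.assert_allclose(
            np.array(energies) * dists**2, energies[0] * dists[0] ** 2, rtol=1e-9)

    def test_overlapping_atoms_capped_finite(self):
        system = _pair_system(1.0, -1.0, 1e-9, rmin_half=1.9, eps=0.25)
        bd = EnergyModel(system).compute()
        assert np.isfinite(bd.total)


def _graph_distances(system, cutoff=3):
    g = system.bond_graph()
    out = {}
    for src in range(system.n_atoms):
        for dst, dist in nx.single_source_shortest_path_length(g, src, cutoff=cutoff).items():
            if dst > src:
                out[(src, dst)] = dist
    return out


def brute_force_total(system, model, coords, lam=LambdaState()):
    """Naive all-pairs oracle for the full potential (plain Python loops)."""
    from mrdock.gomodel import cg_energy

    settings = model.settings
    region = system.region_of_atoms()
    is_lig = system.is_ligand_mask
    gdist = _graph_distances(system)
    hp, sp = model.hydration, model.seddd
    vols = model.occlusion_volumes
    v_all = compute_hydration_volumes(coords, model.groups, vols, hp)
    v_prot = compute_hydration_volumes(coords, model.groups, vols, hp,
                                       occluder_mask=~is_lig)
    v_lig = compute_hydration_volumes(coords, model.groups, vols, hp,
                                      occluder_mask=is_lig)
    sums = {"lig": 0.0, "int_vdw": 0.0, "int_elec": 0.0, "aa": 0.0, "cross": 0.0}
    n = system.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            cg_i = region[i] == "coarse" and not is_lig[i]
            cg_j = region[j] == "coarse" and not is_lig[j]
            if cg_i and cg_j:
                continue
            d = gdist.get((i, j))
            if d in (1, 2):
                continue
            vs, es = (0.5, 1 / 1.2) if d == 3 else (1.0, 1.0)
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > settings.nonbonded_cutoff:
                continue
            ai, aj = system.atoms[i], system.atoms[j]
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            epsp = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            q6 = (rmin / max(r, 1e-6)) ** 6
            vdw = min(max(epsp * (q6 * q6 - 2 * q6) * vs, -1e6), 1e6)
            if is_lig[i] and is_lig[j]:
                v = v_lig
            elif is_lig[i] or is_lig[j]:
                v = v_all
            else:
                v = v_prot
            s = min(sp.c * (v[model.atom_group[i]] + v[model.atom_group[j]]), 1 - 1e-9)
            eps_ij = r * (sp.eps0 + (1 - s) * (sp.eps1 - sp.eps0))
            elec = min(max(
                COULOMB_KCAL * ai.partial_charge * aj.partial_charge / (eps_ij * max(r, 1e-6)) * es,
                -1e6), 1e6)
            if is_lig[i] and is_lig[j]:
                sums["lig"] += vdw + elec
            elif is_lig[i] or is_lig[j]:
                sums["int_vdw"] += vdw
                sums["int_elec"] += elec
            elif not cg_i and not cg_j:
                sums["aa"] += vdw + elec
            else:
                sums["cross"] += vdw + elec
    # bonded terms via independent evaluation
    from mrdock.geometry import bond_angle, dihedral_angle

    def owner(idx):
        if all(is_lig[k] for k in idx):
            return "lig"
        if all(region[k] == "coarse" for k in idx):
            return None  # backbone handled by cg_energy; sidechain const
        if all(region[k] == "atomistic" and not is_lig[k] for k in idx):
            return "aa"
        return "cross"

    for b in system.bonds:
        o = owner((b.i, b.j))
        if o:
            r = float(np.linalg.norm(coords[b.i] - coords[b.j]))
            sums[o] += b.k * (r - b.r0) ** 2
    for a in system.angles:
        o = owner((a.i, a.j, a.k))
        if o:
            th = bond_angle(coords[a.i], coords[a.j], coords[a.k])
            sums[o] += a.k_theta * (th - a.theta0) ** 2
    for dterm in system.dihedrals:
        o = owner((dterm.i, dterm.j, dterm.k, dterm.l))
        if o:
            phi = dihedral_angle(coords[dterm.i], coords[dterm.j],
                                 coords[dterm.k], coords[dterm.l])
            for h, nper, g in dterm.terms:
                sums[o] += h * (1 + math.cos(nper * phi - g))
    sys_view = MolecularSystem(
        [AtomRecord(index=a.index, name=a.name, element=a.element, position=coords[a.index],
                    residue_index=a.residue_index, seddd_group_id=a.seddd_group_id,
                    is_backbone=a.is_backbone, is_ligand=a.is_ligand)
         for a in system.atoms], system.residues, system.bonds, system.angles,
        system.dihedrals)
    u_bb, u_go, u_cg = cg_energy(
        sys_view, model.contacts, model.go_params,
        nonbonded_cutoff=settings.nonbonded_cutoff)
    u_restraint = sum(res.energy(coords) for res in model.restraints)
    return (
        u_cg + sums["aa"] + sums["cross"] + sums["lig"] + u_restraint
        + lam.lambda_vdw * sums["int_vdw"] + lam.lambda_elec * sums["int_elec"]
    )


class TestTotalEnergy:
    def test_region_and_alchemical_views_agree(self, toy_complex):
        bd = toy_complex["model"].compute()
        lhs = bd.total
        rhs = bd.u_cg + bd.u_aa + bd.u_cg_aa
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_decoupled_total_independent_of_ligand_pose(self, toy_complex):
        system, model = toy_complex["system"], toy_complex["model"]
        lam0 = LambdaState(0.0, 0.0)
        c0 = system.copy_coords()
        c1 = c0.copy()
        c1[system.ligand_atom_indices] += np.array([5.0, 0.0, 0.0])
        t0 = model.compute(c0, lam0).total
        t1 = model.compute(c1, lam0).total
        assert t1 == pytest.approx(t0, abs=1e-8)

    def test_interaction_equals_lambda_difference(self, toy_complex):
        """Linearity: U(λ=1) − U(λ=0) is exactly the interaction energy."""
        model = toy_complex["model"]
        coords = toy_complex["system"].copy_coords()
        full = model.compute(coords, LambdaState(1.0, 1.0))
        off = model.compute(coords, LambdaState(0.0, 0.0))
        assert full.total - off.total == pytest.approx(full.interaction, rel=1e-10)

    def test_interaction_zero_outside_cutoff(self, toy_complex):
        system, model = toy_complex["system"], toy_complex["model"]
        coords = system.copy_coords()
        coords[system.ligand_atom_indices] += np.array([200.0, 0.0, 0.0])
        assert model.interaction_energy(coords) == 0.0

    @pytest.mark.parametrize("seed,lam", [
        (0, LambdaState(1.0, 1.0)),
        (1, LambdaState(0.35, 0.7)),
        (2, LambdaState(0.0, 0.0)),
    ])
    def test_matches_brute_force_oracle(self, toy_complex, seed, lam):
        system, model = toy_complex["system"], toy_complex["model"]
        rng = np.random.default_rng(seed)
        coords = system.copy_coords() + rng.normal(0, 0.15, system.coords.shape)
        expected = brute_force_total(system, model, coords, lam)
        got = model.compute(coords, lam).total
        assert got == pytest.approx(expected, abs=1e-8)

    def test_rigid_motion_invariance(self, toy_complex):
        model = toy_complex["model"]
        coords = toy_complex["system"].copy_coords()
        R = rotation_matrix([0.3, -1.2, 0.8], 1.1)
        moved = coords @ R.T + np.array([5.0, -3.0, 2.0])
        assert model.compute(moved).total == pytest.approx(
            model.compute(coords).total, abs=1e-8)
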