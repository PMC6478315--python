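"""Pose analysis: symmetry-aware RMSD, clustering, ranking, summaries."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from mrdock.analysis import (
    ClusterSet,
    cluster_poses,
    effective_move_size,
    ligand_automorphisms,
    rank_poses,
    rmsd_timeseries,
    summarize_performance,
    symmetry_aware_rmsd,
    system_rmsd_inputs,
)
from mrdock.errors import ValidationError
from mrdock.geometry import rotation_matrix
from mrdock.mc import MCTrajectory
from mrdock.toys import ToySpec, attach_ligand, make_toy_ligand, make_toy_receptor


def _para_ring_graph():
    g = nx.Graph()
    for i in range(6):
        g.add_node(i, element="C")
    g.add_node(6, element="O")
    g.add_node(7, element="O")
    for i in range(6):
        g.add_edge(i, (i + 1) % 6)
    g.add_edge(0, 6)
    g.add_edge(3, 7)
    return g


def _brute_force_automorphisms(g):
    """Exhaustive permutation check — the independent oracle."""
    n = g.number_of_nodes()
    elements = [g.nodes[i]["element"] for i in range(n)]
    edges = {frozenset(e) for e in g.edges}
    out = []
    for perm in itertools.permutations(range(n)):
        if any(elements[i] != elements[perm[i]] for i in range(n)):
            continue
        if {frozenset((perm[a], perm[b])) for a, b in map(tuple, edges)} == edges:
            out.append(perm)
    return {tuple(p) for p in out}


class TestAutomorphisms:
    def test_matches_exhaustive_enumeration(self):
        g = _para_ring_graph()
        got = {tuple(p) for p in ligand_automorphisms(g)}
        assert got == _brute_force_automorphisms(g)
        assert len(got) >= 2
        assert tuple(range(8)) in got

    def test_chain_has_mirror_symmetry(self):
        g = nx.Graph()
        for i in range(4):
            g.add_node(i, element="C")
        for i in range(3):
            g.add_edge(i, i + 1)
        got = {tuple(p) for p in ligand_automorphisms(g)}
        assert got == {(0, 1, 2, 3), (3, 2, 1, 0)}

    def test_cap_raises(self):
        g = nx.Graph()
        for i in range(8):
            g.add_node(i, element="C")  # edgeless: 8! automorphisms
        with pytest.raises(ValidationError, match="automorphisms"):
            ligand_automorphisms(g, cap=100)


@pytest.fixture(scope="module")
def symmetric_complex():
    spec = ToySpec(symmetric_ligand=True)
    receptor = make_toy_receptor(spec)
    system = attach_ligand(receptor["system"], make_toy_ligand(spec),
                           receptor["site_center"])
    return {"system": system, "inputs": system_rmsd_inputs(system)}


class TestSymmetryAwareRmsd:
    def test_identical_pose_is_zero(self, symmetric_complex):
        coords = symmetric_complex["system"].coords
        inp = symmetric_complex["inputs"]
        assert symmetry_aware_rmsd(coords, coords, inp["backbone_atoms"],
                                   inp["ligand_atoms"], inp["automorphisms"]
                                   ) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_flip_gives_zero(self, symmetric_complex):
        """A 180° flip about the para axis is a graph automorphism: RMSD 0."""
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        coords = system.copy_coords()
        lig = np.array(inp["ligand_atoms"])
        xyz = coords[lig]
        centroid = xyz.mean(axis=0)
        axis = xyz[7] - xyz[6]  # through the two para oxygens
        R = rotation_matrix(axis, math.pi)
        flipped = coords.copy()
        flipped[lig] = (xyz - centroid) @ R.T + centroid
        rmsd = symmetry_aware_rmsd(flipped, coords, inp["backbone_atoms"],
                                   inp["ligand_atoms"], inp["automorphisms"])
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        identity_only = [np.arange(len(lig))]
        assert symmetry_aware_rmsd(flipped, coords, inp["backbone_atoms"],
                                   inp["ligand_atoms"], identity_only) > 1.0

    def test_rigid_ligand_shift_reports_distance(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        coords = system.copy_coords()
        shifted = coords.copy()
        shifted[np.array(inp["ligand_atoms"])] += np.array([0.0, 0.0, 3.0])
        rmsd = symmetry_aware_rmsd(shifted, coords, inp["backbone_atoms"],
                                   inp["ligand_atoms"], inp["automorphisms"])
        assert rmsd == pytest.approx(3.0, abs=1e-8)

    def test_invariant_under_global_rigid_motion(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        ref = system.coords
        pose = ref.copy()
        pose[np.array(inp["ligand_atoms"])] += np.array([1.0, -0.5, 0.7])
        base = symmetry_aware_rmsd(pose, ref, inp["backbone_atoms"],
                                   inp["ligand_atoms"], inp["automorphisms"])
        R = rotation_matrix([1.0, 1.0, -0.4], 0.9)
        moved = pose @ R.T + np.array([4.0, 5.0, -6.0])
        again = symmetry_aware_rmsd(moved, ref, inp["backbone_atoms"],
                                    inp["ligand_atoms"], inp["automorphisms"])
        assert again == pytest.approx(base, abs=1e-8)

    def test_mapping_minimum_never_exceeds_identity(self, symmetric_complex, rng):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        ref = system.coords
        for _ in range(10):
            pose = ref + rng.normal(0, 0.5, ref.shape)
            with_maps = symmetry_aware_rmsd(pose, ref, inp["backbone_atoms"],
                                            inp["ligand_atoms"], inp["automorphisms"])
            identity = symmetry_aware_rmsd(pose, ref, inp["backbone_atoms"],
                                           inp["ligand_atoms"],
                                           [np.arange(len(inp["ligand_atoms"]))])
            assert with_maps <= identity + 1e-12


def _oracle_complete_linkage(D, cutoff):
    """Naive agglomerative complete linkage, merging the closest pair each step."""
    clusters = [{i} for i in range(len(D))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters[a] |= clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


class TestClustering:
    def test_single_pose(self):
        cs = cluster_poses(np.zeros((1, 1)))
        assert cs.n_clusters == 1

    def test_zero_poses_rejected(self):
        with pytest.raises(ValidationError):
            cluster_poses(np.zeros((0, 0)))

    def test_two_tight_groups(self, rng):
        """Intra ≤ 0.5, inter ≥ 5, cutoff 2 ⇒ exactly the two groups."""
        pts = np.vstack([rng.uniform(0, 0.2, (4, 3)), 8.0 + rng.uniform(0, 0.2, (4, 3))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cs = cluster_poses(D, cutoff=2.0)
        assert cs.n_clusters == 2
        assert set(map(tuple, [cs.members(0), cs.members(1)])) == {(0, 1, 2, 3), (4, 5, 6, 7)}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        pts = rng.uniform(0, 10, (n, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cs = cluster_poses(D, percentile=30.0)
        got = {frozenset(np.where(cs.assignment == c)[0].tolist())
               for c in range(cs.n_clusters)}
        assert got == _oracle_complete_linkage(D, cs.cutoff)

    @pytest.mark.parametrize("seed", range(5))
    def test_max_intra_cluster_distance_bounded(self, seed):
        rng = np.random.default_rng(100 + seed)
        pts = rng.uniform(0, 6, (8, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cs = cluster_poses(D)
        for c in range(cs.n_clusters):
            members = cs.members(c)
            if len(members) > 1:
                assert D[np.ix_(members, members)].max() <= cs.cutoff + 1e-12

    def test_percentile_uses_offdiagonal_only(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert cluster_poses(D).cutoff == pytest.approx(2.0)


class TestRanking:
    def test_method1_global_argmin(self):
        assert rank_poses([-10.0, -12.0, -5.0], None, 1) == 1

    def test_methods_2_and_3_on_hand_fixture(self):
        """Largest cluster vs lowest-mean cluster pick different winners."""
        energies = [-5.0, -6.0, -7.0, -10.0, -12.0]  # A = {0,1,2}, B = {3,4}
        clusters = ClusterSet(assignment=np.array([0, 0, 0, 1, 1]), cutoff=1.0)
        assert rank_poses(energies, clusters, 2) == 2   # best of largest cluster A
        assert rank_poses(energies, clusters, 3) == 4   # best of lowest-mean cluster B

    def test_single_cluster_all_methods_agree(self):
        energies = [3.0, -1.0, 2.0]
        clusters = ClusterSet(assignment=np.zeros(3, dtype=int), cutoff=1.0)
        assert rank_poses(energies, clusters, 1) == 1
        assert rank_poses(energies, clusters, 2) == 1
        assert rank_poses(energies, clusters, 3) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            rank_poses([], None, 1)


class TestSummaries:
    def test_best_of_n_hand_case(self):
        records = {"drug": [(1.0, 4.0), (2.0, 0.5), (3.0, 2.0)]}
        out = summarize_performance(records, n_max=3)
        np.testing.assert_allclose(out["best_of_n"], [4.0, 0.5, 0.5])

    def test_full_prefix_equals_overall_best(self, rng):
        records = {
            "a": [(float(e), float(r)) for e, r in rng.uniform(0, 10, (7, 2))],
            "b": [(float(e), float(r)) for e, r in rng.uniform(0, 10, (5, 2))],
        }
        out = summarize_performance(records)
        assert out["best_of_n"][-1] == pytest.approx(out["baseline_mean"])

    def test_cdf_monotone_reaching_one(self, rng):
        records = {f"d{i}": [(float(e), float(r)) for e, r in rng.uniform(0, 5, (4, 2))]
                   for i in range(6)}
        out = summarize_performance(records)
        assert np.all(np.diff(out["cdf_prob"]) >= 0)
        assert out["cdf_prob"][-1] == 1.0


class TestEffectiveMoveSize:
    def test_identity(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        t, r = effective_move_size(system.coords, system.coords,
                                   inp["backbone_atoms"], inp["ligand_atoms"])
        assert t == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        post = system.copy_coords()
        post[np.array(inp["ligand_atoms"])] += np.array([2.0, 0.0, 0.0])
        t, r = effective_move_size(system.coords, post,
                                   inp["backbone_atoms"], inp["ligand_atoms"])
        assert t == pytest.approx(2.0, abs=1e-9)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_pure_rotation_about_centroid(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        lig = np.array(inp["ligand_atoms"])
        post = system.copy_coords()
        centroid = post[lig].mean(axis=0)
        R = rotation_matrix([0.0, 0.3, 1.0], math.radians(30.0))
        post[lig] = (post[lig] - centroid) @ R.T + centroid
        t, r = effective_move_size(system.coords, post,
                                   inp["backbone_atoms"], inp["ligand_atoms"])
        assert t == pytest.approx(0.0, abs=1e-6)
        assert r == pytest.approx(30.0, abs=1e-6)


class TestRmsdTimeseries:
    def test_frozen_trajectory_constant(self, symmetric_complex):
        system = symmetric_complex["system"]
        inp = symmetric_complex["inputs"]
        traj = MCTrajectory()
        for step in (100, 200, 300):
            traj.snapshots.append((step, system.copy_coords(), None))
        series = rmsd_timeseries(traj, system.coords, inp["backbone_atoms"],
                                 inp["ligand_atoms"], inp["automorphisms"])
        assert len(series) == 3
        assert all(v == pytest.approx(series[0][1], abs=1e-12) for _, v in series)
        first = symmetry_aware_rmsd(traj.snapshots[0][1], system.coords,
                                    inp["backbone_atoms"], inp["ligand_atoms"],
                                    inp["automorphisms"])
        assert series[0][1] == first
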