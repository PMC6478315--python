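"""Pose analysis: symmetry-corrected ligand RMSD, clustering, ranking, summaries.

Ligand RMSD is measured after a rigid least-squares superposition of the
protein backbone onto the reference (no ligand atoms enter the fit), then
minimized over all graph automorphisms of the ligand's heavy-atom connection
table that preserve element labels — so chemically equivalent atoms (e.g. the
two arms of a para-disubstituted ring) cannot inflate the RMSD.

Pose ensembles are grouped by complete-linkage hierarchical clustering with
the tree cut at a percentile (default the 10th) of the off-diagonal pairwise
distances, which scales cluster size to each ligand's own pose spread.  Three
ranking rules pick a "best" pose: (1) global lowest interaction energy;
(2) lowest-energy member of the largest cluster; (3) lowest-energy member of
the cluster with the lowest mean interaction energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from mrdock.errors import ValidationError
from mrdock.geometry import kabsch, rotation_angle_deg
from mrdock.system import MolecularSystem

__all__ = [
    "ligand_automorphisms",
    "symmetry_aware_rmsd",
    "ClusterSet",
    "cluster_poses",
    "rank_poses",
    "summarize_performance",
    "effective_move_size",
    "ncmc_move_table",
    "rmsd_timeseries",
    "system_rmsd_inputs",
]

#: Hard cap on enumerated automorphisms (pathological symmetry → explicit error).
MAX_AUTOMORPHISMS = 10_000


def ligand_automorphisms(graph: nx.Graph, cap: int = MAX_AUTOMORPHISMS) -> list[np.ndarray]:
    """All graph automorphisms preserving element labels (and bond orders).

    Nodes must be 0..n-1 with an ``element`` attribute; an ``order`` edge
    attribute is honoured when present.  The identity is always included.
    Raises if more than ``cap`` mappings exist.
    """
    n = graph.number_of_nodes()
    if set(graph.nodes) != set(range(n)):
        raise ValidationError("automorphism graph nodes must be 0..n-1")
    nm = nx.algorithms.isomorphism.categorical_node_match("element", None)
    em = nx.algorithms.isomorphism.categorical_edge_match("order", 1)
    gm = nx.algorithms.isomorphism.GraphMatcher(graph, graph, node_match=nm, edge_match=em)
    perms = []
    for mapping in gm.isomorphisms_iter():
        perms.append(np.array([mapping[i] for i in range(n)], dtype=int))
        if len(perms) > cap:
            raise ValidationError(f"more than {cap} ligand automorphisms; refusing to truncate")
    return perms


def symmetry_aware_rmsd(
    pose: np.ndarray,
    reference: np.ndarray,
    backbone_atoms: Sequence[int],
    ligand_atoms: Sequence[int],
    automorphisms: Sequence[np.ndarray] | None = None,
    ligand_graph: nx.Graph | None = None,
) -> float:
    """Ligand heavy-atom RMSD (Å) after backbone superposition, symmetry-corrected.

    ``pose`` and ``reference`` are full coordinate arrays over the same atom
    indexing.  ``backbone_atoms`` are the shared protein backbone atoms used
    for the rigid fit (may be empty for receptor-free comparisons, in which
    case no alignment is applied).  ``ligand_atoms`` are the ligand heavy
    atoms; ``automorphisms`` (permutations of positions within that list) or a
    ``ligand_graph`` over 0..len(ligand_atoms)-1 supply the equivalent-atom
    mappings — by default only the identity is used.
    """
    pose = np.asarray(pose, dtype=float)
    reference = np.asarray(reference, dtype=float)
    backbone_atoms = np.asarray(list(backbone_atoms), dtype=int)
    ligand_atoms = np.asarray(list(ligand_atoms), dtype=int)
    if len(ligand_atoms) == 0:
        raise ValidationError("no ligand atoms for RMSD")
    if len(backbone_atoms) > 0:
        R, t = kabsch(pose[backbone_atoms], reference[backbone_atoms])
        pose = pose @ R.T + t
    lig_pose = pose[ligand_atoms]
    lig_ref = reference[ligand_atoms]
    if automorphisms is None:
        if ligand_graph is not None:
            automorphisms = ligand_automorphisms(ligand_graph)
        else:
            automorphisms = [np.arange(len(ligand_atoms))]
    best = np.inf
    for perm in automorphisms:
        if len(perm) != len(ligand_atoms):
            raise ValidationError("automorphism length does not match ligand atom count")
        d = lig_pose[perm] - lig_ref
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


def system_rmsd_inputs(system: MolecularSystem) -> dict:
    """Backbone indices, ligand heavy-atom indices, graph and automorphisms."""
    backbone = system.backbone_atom_indices()
    lig_heavy = [
        a.index for a in system.atoms if a.is_ligand and a.element.upper() != "H"
    ]
    graph = nx.Graph()
    local = {ai: k for k, ai in enumerate(lig_heavy)}
    for k, ai in enumerate(lig_heavy):
        graph.add_node(k, element=system.atoms[ai].element.upper())
    for b in system.bonds:
        if b.i in local and b.j in local:
            graph.add_edge(local[b.i], local[b.j])
    return {
        "backbone_atoms": backbone,
        "ligand_atoms": lig_heavy,
        "ligand_graph": graph,
        "automorphisms": ligand_automorphisms(graph),
    }


# ---------------------------------------------------------------------------
# Clustering and ranking
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Complete-linkage clusters: per-pose cluster ids (0-based) and the cutoff."""

    assignment: np.ndarray
    cutoff: float
    linkage_matrix: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if len(self.assignment) else 0

    def members(self, cluster_id: int) -> np.ndarray:
        return np.where(self.assignment == cluster_id)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)


def cluster_poses(
    distance_matrix: np.ndarray, percentile: float = 10.0, cutoff: float | None = None
) -> ClusterSet:
    """Complete-linkage clustering cut at a percentile of off-diagonal distances.

    The percentile uses linear interpolation over the off-diagonal entries
    only (self-distances would bias the cutoff down); an explicit ``cutoff``
    overrides it.  Cluster ids are relabelled by first occurrence, which makes
    them deterministic.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    n = D.shape[0]
    if n == 0:
        raise ValidationError("cannot cluster zero poses")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValidationError("need a symmetric non-negative matrix with zero diagonal")
    if n == 1:
        return ClusterSet(assignment=np.zeros(1, dtype=int), cutoff=cutoff or 0.0)
    if cutoff is None:
        offdiag = D[np.triu_indices(n, k=1)]
        cutoff = float(np.percentile(offdiag, percentile, method="linear"))
    Z = linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(Z, t=cutoff, criterion="distance")
    relabel: dict[int, int] = {}
    assignment = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[i] = relabel[c]
    return ClusterSet(assignment=assignment, cutoff=cutoff, linkage_matrix=Z)


def rank_poses(records: Sequence, clusters: ClusterSet | None, method: int) -> int:
    """Index of the best pose under ranking method 1, 2 or 3.

    ``records`` need an ``interaction_energy`` attribute (or be plain floats).
    Method 1 ignores ``clusters``; methods 2 and 3 require it.
    """
    if len(records) == 0:
        raise ValidationError("no poses to rank")
    energies = np.array(
        [getattr(r, "interaction_energy", r) for r in records], dtype=float
    )
    if method == 1:
        return int(np.argmin(energies))
    if clusters is None or len(clusters.assignment) != len(records):
        raise ValidationError("methods 2/3 need clusters consistent with records")
    means = np.array(
        [energies[clusters.members(c)].mean() for c in range(clusters.n_clusters)]
    )
    if method == 2:
        sizes = clusters.sizes()
        best_size = sizes.max()
        candidates = np.where(sizes == best_size)[0]
        chosen = candidates[np.argmin(means[candidates])]  # size ties: lower mean
    elif method == 3:
        chosen = int(np.argmin(means))
    else:
        raise ValidationError(f"unknown ranking method {method}")
    members = clusters.members(int(chosen))
    return int(members[np.argmin(energies[members])])


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize_performance(
    records_by_drug: Mapping[str, Sequence[tuple[float, float]]],
    n_max: int | None = None,
) -> dict:
    """Best-of-N curve, RMSD CDF at N = 1, and the no-energy baseline.

    ``records_by_drug`` maps a drug label to (interaction_energy, rmsd) pairs.
    For each drug the runs are sorted by energy; the best-of-N value is the
    minimum RMSD among the N lowest-energy runs, averaged across drugs.  The
    baseline is each drug's overall best RMSD regardless of energy.
    """
    per_drug_sorted = {}
    for drug, recs in records_by_drug.items():
        if len(recs) == 0:
            continue
        arr = np.array(sorted(recs, key=lambda er: er[0]), dtype=float)
        per_drug_sorted[drug] = arr
    if not per_drug_sorted:
        raise ValidationError("no records to summarize")
    if n_max is None:
        n_max = max(len(a) for a in per_drug_sorted.values())
    curve = []
    for n in range(1, n_max + 1):
        vals = [a[: min(n, len(a)), 1].min() for a in per_drug_sorted.values()]
        curve.append(float(np.mean(vals)))
    top1 = np.sort([a[0, 1] for a in per_drug_sorted.values()])
    cdf_x = top1
    cdf_y = np.arange(1, len(top1) + 1) / len(top1)
    baseline = {drug: float(a[:, 1].min()) for drug, a in per_drug_sorted.items()}
    return {
        "best_of_n": np.array(curve),
        "cdf_rmsd": cdf_x,
        "cdf_prob": cdf_y,
        "baseline": baseline,
        "baseline_mean": float(np.mean(list(baseline.values()))),
    }


def effective_move_size(
    pre: np.ndarray,
    post: np.ndarray,
    backbone_atoms: Sequence[int],
    ligand_atoms: Sequence[int],
) -> tuple[float, float]:
    """Overall ligand translation (Å) and rotation (degrees) between two configs.

    The post configuration is first aligned to the pre configuration on the
    protein backbone; the rigid transform that best maps the pre ligand onto
    the post ligand then supplies the reported translation magnitude (centroid
    shift) and rotation angle (in [0°, 180°]).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float).copy()
    backbone_atoms = np.asarray(list(backbone_atoms), dtype=int)
    ligand_atoms = np.asarray(list(ligand_atoms), dtype=int)
    if len(backbone_atoms) > 0:
        R, t = kabsch(post[backbone_atoms], pre[backbone_atoms])
        post = post @ R.T + t
    R_lig, _ = kabsch(pre[ligand_atoms], post[ligand_atoms])
    translation = float(
        np.linalg.norm(post[ligand_atoms].mean(axis=0) - pre[ligand_atoms].mean(axis=0))
    )
    return translation, rotation_angle_deg(R_lig)


def ncmc_move_table(ncmc_results, system: MolecularSystem):
    """Per-NCMC-move diagnostics table (work, acceptance, effective move size).

    The effective ligand translation/rotation is measured between the pre- and
    post-move configurations after backbone alignment, so rejected moves
    report (0, 0) by the restoration contract.
    """
    import pandas as pd

    backbone = system.backbone_atom_indices()
    lig = [a.index for a in system.atoms if a.is_ligand and a.element.upper() != "H"]
    rows = []
    for k, res in enumerate(ncmc_results):
        t, r = effective_move_size(res.pre_coords, res.post_coords, backbone, lig)
        rows.append({
            "move": k,
            "work": res.work,
            "accepted": res.accepted,
            "interior_accepted": res.interior_accept_count,
            "interior_attempts": res.interior_attempts,
            "translation": t,
            "rotation": r,
        })
    return pd.DataFrame(rows)


def rmsd_timeseries(
    trajectory,
    reference: np.ndarray,
    backbone_atoms: Sequence[int],
    ligand_atoms: Sequence[int],
    automorphisms: Sequence[np.ndarray] | None = None,
) -> list[tuple[int, float]]:
    """Symmetry-corrected ligand RMSD at every trajectory snapshot."""
    return [
        (
            step,
            symmetry_aware_rmsd(
                coords, reference, backbone_atoms, ligand_atoms, automorphisms
            ),
        )
        for step, coords, _ in trajectory.snapshots
    ]
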