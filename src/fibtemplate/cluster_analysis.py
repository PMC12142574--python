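"""Configurational clustering of multi-ligand ensembles.

The procedure mirrors standard conformational cluster analysis of
ligand ensembles: every configuration is rigidly aligned on the heavy
atoms of its first ligand, a pairwise all-ligand heavy-atom RMSD matrix
is built (no further per-pair superposition — the alignment frame is
fixed), and hierarchical centroid-linkage clustering is cut at a flat
distance criterion (default 40.0 Å, large because configurations span
several stacked ligands).  Each cluster is represented by its medoid —
the member minimizing mean RMSD to the other members — and clusters are
ranked by occupancy.

Because the configurations are aligned in a common frame, the RMSD is a
scaled Euclidean metric on the flattened coordinates, so the centroid
linkage computed by the Lance–Williams recurrence on the distance matrix
is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .errors import EmptyInputError, StructureMismatchError
from .io_structures import LigandStructure, superpose

__all__ = [
    "ClusterSummary",
    "ConfigurationClusterer",
    "align_to_first_ligand",
    "pairwise_rmsd_matrix",
    "hierarchical_cluster",
    "population_table",
]


@dataclass
class ClusterSummary:
    """Flat clustering of an ensemble: per-configuration assignments,
    occupancy percentages (descending) and medoid representatives."""

    assignments: np.ndarray  # cluster rank (0 = most populated) per config
    populations: np.ndarray  # percentage per cluster, descending
    centroid_indices: np.ndarray  # configuration index of each cluster medoid
    linkage: str
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def align_to_first_ligand(
    configs: list[np.ndarray], structure: LigandStructure | None = None
) -> list[np.ndarray]:
    """Rigidly superpose every configuration so its first ligand's heavy
    atoms best fit the first configuration's first ligand (Kabsch)."""
    if len(configs) == 0:
        raise EmptyInputError("no configurations to align")
    configs = [np.asarray(c, dtype=float) for c in configs]
    shape = configs[0].shape
    for c in configs:
        if c.shape != shape:
            raise StructureMismatchError(
                f"configuration shapes differ: {c.shape} vs {shape}"
            )
    n_lig_atoms = shape[1]
    heavy = (
        np.flatnonzero(structure.heavy_mask)
        if structure is not None
        else np.arange(n_lig_atoms)
    )
    reference = configs[0][0]  # first ligand of first configuration
    aligned = []
    for c in configs:
        flat = c.reshape(-1, 3)
        fit_idx = heavy  # indices of ligand 1 atoms within the flat array
        # superpose the whole configuration using ligand-1 heavy atoms
        moved = superpose_on_subset(flat, c[0], reference, fit_idx)
        aligned.append(moved.reshape(shape))
    return aligned


def superpose_on_subset(
    all_coords: np.ndarray,
    mobile_sub: np.ndarray,
    target_sub: np.ndarray,
    fit_idx: np.ndarray,
) -> np.ndarray:
    """Apply to ``all_coords`` the rigid transform that least-squares fits
    ``mobile_sub[fit_idx]`` onto ``target_sub[fit_idx]``."""
    from .io_structures import kabsch_rotation

    m_sel = mobile_sub[fit_idx]
    t_sel = target_sub[fit_idx]
    m_c, t_c = m_sel.mean(axis=0), t_sel.mean(axis=0)
    rot = kabsch_rotation(m_sel - m_c, t_sel - t_c)
    return (all_coords - m_c) @ rot.T + t_c


def pairwise_rmsd_matrix(
    configs: list[np.ndarray],
    structure: LigandStructure | None = None,
    heavy_only: bool = True,
) -> np.ndarray:
    """Symmetric all-ligand RMSD matrix (Å) over pre-aligned configurations.

    No per-pair superposition is applied; with a fixed alignment frame
    the RMSD reduces to Euclidean distance on flattened coordinates
    divided by sqrt(number of atoms).
    """
    if len(configs) == 0:
        raise EmptyInputError("no configurations")
    arr = np.stack([np.asarray(c, dtype=float) for c in configs])  # (n, L, A, 3)
    if heavy_only and structure is not None:
        arr = arr[:, :, structure.heavy_mask, :]
    n = arr.shape[0]
    flat = arr.reshape(n, -1)
    n_atoms = flat.shape[1] // 3
    condensed = pdist(flat) / np.sqrt(n_atoms)
    return squareform(condensed)


class ConfigurationClusterer(BaseEstimator):
    """Hierarchical centroid-linkage clustering with a flat distance cut.

    Parameters
    ----------
    threshold : float
        Flat-cut distance criterion on the linkage merge heights (Å).
    linkage : str
        Linkage method (``"centroid"`` by default; any scipy method).
    heavy_only : bool
        Restrict the RMSD matrix to heavy atoms (needs ``structure``).
    metric : str
        ``"configurations"`` to fit on a list of multi-ligand coordinate
        sets (aligned internally), ``"precomputed"`` to fit on an RMSD
        matrix.

    Attributes (after ``fit``)
    ----------
    labels_ : cluster rank per configuration (0 = most populated)
    populations_ : occupancy percentage per cluster, descending
    centroid_indices_ : configuration index of each cluster medoid
    rmsd_matrix_ : the pairwise RMSD matrix used
    summary_ : :class:`ClusterSummary`
    """

    def __init__(
        self,
        threshold: float = 40.0,
        linkage: str = "centroid",
        heavy_only: bool = True,
        metric: str = "configurations",
    ):
        self.threshold = threshold
        self.linkage = linkage
        self.heavy_only = heavy_only
        self.metric = metric

    def fit(self, X, structure: LigandStructure | None = None):
        if self.metric == "precomputed":
            matrix = np.asarray(X, dtype=float)
            if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
                raise StructureMismatchError("precomputed matrix must be square")
            if matrix.size == 0:
                raise EmptyInputError("empty distance matrix")
        else:
            aligned = align_to_first_ligand(list(X), structure)
            matrix = pairwise_rmsd_matrix(aligned, structure, self.heavy_only)
        self.rmsd_matrix_ = matrix
        self.summary_ = _cluster_matrix(matrix, self.threshold, self.linkage)
        self.labels_ = self.summary_.assignments
        self.populations_ = self.summary_.populations
        self.centroid_indices_ = self.summary_.centroid_indices
        return self

    def fit_predict(self, X, structure: LigandStructure | None = None) -> np.ndarray:
        return self.fit(X, structure).labels_


def _cluster_matrix(matrix: np.ndarray, threshold: float, method: str) -> ClusterSummary:
    n = matrix.shape[0]
    if n == 1:
        raw = np.zeros(1, dtype=int)
    else:
        condensed = squareform(matrix, checks=False)
        z = linkage(condensed, method=method)
        raw = fcluster(z, t=threshold, criterion="distance") - 1
    # rank clusters by occupancy, ties broken by first appearance
    ids, first_seen, counts = np.unique(raw, return_index=True, return_counts=True)
    order = np.lexsort((first_seen, -counts))
    rank_of = {ids[o]: rank for rank, o in enumerate(order)}
    assignments = np.array([rank_of[c] for c in raw])
    populations = 100.0 * counts[order] / n
    centroids = np.empty(len(ids), dtype=int)
    for rank in range(len(ids)):
        members = np.flatnonzero(assignments == rank)
        sub = matrix[np.ix_(members, members)]
        centroids[rank] = members[np.argmin(sub.mean(axis=1))]
    return ClusterSummary(
        assignments=assignments,
        populations=populations,
        centroid_indices=centroids,
        linkage=method,
        threshold=threshold,
    )


def hierarchical_cluster(
    matrix: np.ndarray, threshold: float = 40.0, linkage_method: str = "centroid"
) -> ClusterSummary:
    """Flat clusters from a square symmetric RMSD matrix at the distance
    criterion (thin wrapper over :class:`ConfigurationClusterer`)."""
    clusterer = ConfigurationClusterer(
        threshold=threshold, linkage=linkage_method, metric="precomputed"
    )
    return clusterer.fit(matrix).summary_


def population_table(summary: ClusterSummary, top_k: int = 10) -> np.ndarray:
    """Top-``k`` occupancy percentages; any remainder is aggregated into a
    final "other" entry."""
    pops = summary.populations
    if len(pops) <= top_k:
        return pops.copy()
    head = pops[:top_k]
    return np.append(head, pops[top_k:].sum())
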