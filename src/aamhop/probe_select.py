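"""Data-driven selection of representative amino-acid probes.

Each candidate probe produces one descriptor field per reference compound.
For every probe pair the fields are scored with the interaction-field
similarity (identity transform by default — the probes share the reference
frame), scores are averaged over the reference compounds, and the resulting
distance matrix (1 − mean similarity) is clustered hierarchically with
average linkage.  From each cluster the member whose field is closest to
the cluster's voxel-wise mean field is kept as the representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .grids import AAMDescriptor, SearchGrid, SphericalMask, VoxelGrid
from .similarity import aam_score

# probe fields per reference: {reference_id: {probe_name: VoxelGrid}}
ProbeFields = dict[str, dict[str, VoxelGrid]]

IDENTITY_SEARCH = SearchGrid(angle_step=360.0, trans_step=1.0, trans_range=0.0)


@dataclass
class ProbeDistanceMatrix:
    """Symmetric probe-probe distances, 1 − mean similarity over references."""

    probe_names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix, dtype=float)
        n = len(self.probe_names)
        if D.shape != (n, n):
            raise ValueError("matrix shape must match the probe list")
        if np.max(np.abs(D - D.T)) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(D))) > 1e-9:
            raise ValueError("distance matrix diagonal must be zero")
        if D.min() < -1e-9 or D.max() > 2 + 1e-9:
            raise ValueError("distances must lie in [0, 2]")
        self.matrix = D


def _single_probe(field: VoxelGrid, name: str = "probe") -> AAMDescriptor:
    return AAMDescriptor(compound_id=name, fields={"probe": field})


def probe_distance_matrix(
    probe_fields: ProbeFields,
    search: SearchGrid = IDENTITY_SEARCH,
    mask: SphericalMask = SphericalMask(),
    method: str = "bruteforce",
) -> ProbeDistanceMatrix:
    """Pairwise probe distances averaged over reference compounds.

    ``probe_fields`` maps each reference compound to its per-probe fields
    (each probe's descriptor around that reference).  By default the score
    uses only the identity transform; pass a full :class:`SearchGrid` to
    search over poses.
    """
    refs = list(probe_fields)
    if not refs:
        raise ValueError("at least one reference compound is required")
    names = sorted(probe_fields[refs[0]])
    if len(names) < 2:
        raise ValueError("at least two probes are required")
    for r in refs:
        if sorted(probe_fields[r]) != names:
            raise ValueError(f"reference {r!r} is missing probe fields")
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims = []
            for r in refs:
                res = aam_score(
                    _single_probe(probe_fields[r][names[i]]),
                    _single_probe(probe_fields[r][names[j]]),
                    search=search,
                    mask=mask,
                    method=method,
                )
                sims.append(res.score)
            D[i, j] = D[j, i] = 1.0 - float(np.mean(sims))
    D = np.clip(D, 0.0, 2.0)
    return ProbeDistanceMatrix(probe_names=names, matrix=D)


def compute_probe_fields(
    references,
    probes,
    grid_geometry: VoxelGrid | None = None,
    mask_radius: float = 10.0,
    temperature_K: float = 300.0,
    n_orientations: int = 32,
    seed: int = 0,
) -> ProbeFields:
    """Surrogate descriptor fields of every candidate probe around every
    reference conformer (the input to :func:`probe_distance_matrix`)."""
    from .descriptors import default_grid_geometry, surrogate_descriptor_field

    out: ProbeFields = {}
    for mol in references:
        geom = grid_geometry or default_grid_geometry(
            mol, mask_radius=mask_radius, trans_range=0.0
        )
        out[mol.compound_id] = {
            p.name: surrogate_descriptor_field(
                mol, p, geom,
                temperature_K=temperature_K,
                n_orientations=n_orientations,
                seed=seed,
            )
            for p in probes
        }
    return out


def cluster_probes(matrix: ProbeDistanceMatrix, k: int) -> dict[str, int]:
    """Average-linkage hierarchical clustering cut at k clusters.

    Returns probe → cluster label (labels are arbitrary but deterministic
    integers starting at 1).
    """
    n = len(matrix.probe_names)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return {name: i + 1 for i, name in enumerate(matrix.probe_names)}
    Z = linkage(squareform(matrix.matrix, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(matrix.probe_names, (int(c) for c in labels)))


def representative_probe(
    cluster: list[str],
    probe_fields: ProbeFields,
    mask: SphericalMask = SphericalMask(),
) -> str:
    """The cluster member whose field is closest to the cluster mean field.

    The mean descriptor is the voxel-wise average over cluster members,
    taken per reference; each member's identity-transform similarity to the
    mean is averaged over references and the best member wins (ties go to
    the alphabetically first name).
    """
    if not cluster:
        raise ValueError("cluster must be non-empty")
    if len(cluster) == 1:
        return cluster[0]
    refs = list(probe_fields)
    scores = {name: [] for name in cluster}
    for r in refs:
        stack = np.stack([probe_fields[r][name].values for name in cluster])
        mean_field = probe_fields[r][cluster[0]].copy_with(stack.mean(axis=0))
        mean_desc = _single_probe(mean_field, "mean")
        for name in cluster:
            res = aam_score(
                _single_probe(probe_fields[r][name]),
                mean_desc,
                search=IDENTITY_SEARCH,
                mask=mask,
                method="bruteforce",
            )
            scores[name].append(res.score)
    mean_scores = {name: float(np.mean(v)) for name, v in scores.items()}
    best = max(sorted(mean_scores), key=lambda n: mean_scores[n])
    return best


class ProbeClusterer(BaseEstimator, ClusterMixin):
    """Hierarchical probe clustering with representative selection.

    Parameters
    ----------
    n_clusters : int
        Number of clusters to cut the average-linkage dendrogram into.
        The screened probe sets correspond to 4 (monocationic references)
        or 5 (neutral references).
    mask_radius : float
        Radius (Å) of the spherical evaluation mask; must fit inside the
        probe-field grids.

    Attributes
    ----------
    probe_names_ : list of str
    labels_ : ndarray of cluster labels aligned with ``probe_names_``
    clusters_ : dict label → list of probe names
    representatives_ : list of representative probe names (sorted), set when
        probe fields are supplied to :meth:`fit`.
    """

    def __init__(self, n_clusters: int = 4, mask_radius: float = 10.0):
        self.n_clusters = n_clusters
        self.mask_radius = mask_radius

    def fit(self, X, y=None, probe_fields: ProbeFields | None = None):
        """Fit from a :class:`ProbeDistanceMatrix`, a square distance array
        (with ``probe_fields`` supplying names), or raw probe fields."""
        mask = SphericalMask(self.mask_radius)
        if isinstance(X, ProbeDistanceMatrix):
            matrix = X
        elif isinstance(X, dict):
            matrix = probe_distance_matrix(X, mask=mask)
            probe_fields = probe_fields or X
        else:
            D = np.asarray(X, dtype=float)
            names = (
                sorted(next(iter(probe_fields.values())))
                if probe_fields
                else [f"P{i}" for i in range(D.shape[0])]
            )
            matrix = ProbeDistanceMatrix(probe_names=names, matrix=D)
        assignment = cluster_probes(matrix, self.n_clusters)
        self.probe_names_ = matrix.probe_names
        self.labels_ = np.array([assignment[n] for n in matrix.probe_names])
        self.clusters_ = {}
        for name, lab in assignment.items():
            self.clusters_.setdefault(lab, []).append(name)
        for members in self.clusters_.values():
            members.sort()
        if probe_fields is not None:
            self.representatives_ = sorted(
                representative_probe(members, probe_fields, mask=mask)
                for members in self.clusters_.values()
            )
        return self
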