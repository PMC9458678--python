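"""Two-step conformer clustering for minimal-ensemble (basis-set) fitting.

Step one groups trajectory frames by their relative domain arrangement:
density-based hierarchical clustering (HDBSCAN) on pairwise Cα-distance
feature vectors, noise labelled −1 and discarded, and each cluster reduced
to the member with the lowest summed pairwise-RMSD score (its centroid).

Step two makes the retained representatives experimentally distinguishable:
their scattering profiles are agglomerated under Ward's linkage on the
pairwise χ²(i, j) = Σ_q [(Iᵢ − Iⱼ)/σ]² dissimilarity, cut at a flat distance
threshold, and one profile per cluster (nearest to the cluster mean) forms
the basis set handed to weight inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import HDBSCAN

from .saxs_forward import ScatteringCurve
from .structures import FeatureMatrix

__all__ = [
    "ClusterAssignment",
    "BasisSet",
    "cluster_conformers",
    "representative_member",
    "cluster_profiles",
]


@dataclass
class ClusterAssignment:
    """Frame labels (−1 = noise) plus one representative frame per cluster."""

    labels: np.ndarray
    representatives: dict[int, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0].tolist()))

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == -1))

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class BasisSet:
    """Representative profiles for weight inference.

    ``indices`` point back into the profile list (and hence the conformers)
    this set was built from.
    """

    indices: np.ndarray
    profiles: list[ScatteringCurve]
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def q(self) -> np.ndarray:
        return self.profiles[0].q

    @property
    def intensity_matrix(self) -> np.ndarray:
        return np.stack([p.I for p in self.profiles])


def representative_member(features) -> int:
    """Centroid member of a cluster: argmin of summed pairwise RMSD scores.

    The score of member j is Σᵢ R[i, j] over the pairwise feature-RMSD
    matrix; ties break to the lowest index.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if len(x) == 0:
        raise ValueError("empty cluster")
    if len(x) == 1:
        return 0
    diff = x[:, None, :] - x[None, :, :]
    rmsd = np.sqrt(np.mean(diff ** 2, axis=2))
    return int(np.argmin(rmsd.sum(axis=0)))


def cluster_conformers(features: FeatureMatrix | np.ndarray,
                       min_cluster_size: int = 5,
                       **hdbscan_kwargs) -> ClusterAssignment:
    """Density-based structural clustering of frames in Cα-distance space.

    Frames in regions of insufficient density are labelled −1 and excluded
    downstream; every real cluster has at least ``min_cluster_size``
    members.  Degenerate input (all frames identical) is one cluster.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.atleast_2d(features)
    n = len(x)
    if n < min_cluster_size:
        return ClusterAssignment(np.full(n, -1))
    if np.allclose(x, x[0]):
        reps = {0: 0}
        return ClusterAssignment(np.zeros(n, dtype=int), reps)
    hdbscan_kwargs.setdefault("copy", True)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, **hdbscan_kwargs).fit_predict(x)
    reps = {}
    for lab in sorted(set(labels[labels >= 0].tolist())):
        members = np.flatnonzero(labels == lab)
        reps[int(lab)] = int(members[representative_member(x[members])])
    return ClusterAssignment(np.asarray(labels), reps)


def _pairwise_chi2(I: np.ndarray, sigma: np.ndarray, per_point: bool) -> np.ndarray:
    diff = (I[:, None, :] - I[None, :, :]) / sigma
    m = (diff ** 2).sum(axis=2)
    return m / I.shape[1] if per_point else m


def cluster_profiles(
    profiles,
    sigma: np.ndarray,
    distance_threshold: float = 0.15,
    normalize: bool = True,
    per_point: bool = True,
    method: str = "ward",
) -> BasisSet:
    """Ward-linkage clustering of scattering profiles under the χ² metric.

    Profiles are first normalised to I(0) = 1 (first grid point) so the
    dissimilarity reflects shape, then agglomerated and cut at
    ``distance_threshold`` on the per-point χ²/N_q scale.  The member
    nearest (in χ²) to its cluster's mean profile represents the cluster.
    """
    if len(profiles) < 2:
        raise ValueError("profile clustering needs at least two profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if not ref.same_grid(p):
            raise ValueError("profiles are not on a common q grid")
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != ref.q.shape:
        raise ValueError("sigma does not match the profile grid")

    I = np.stack([p.I for p in profiles])
    if normalize:
        I = I / I[:, :1]
    m = _pairwise_chi2(I, sigma, per_point)
    z = linkage(squareform(m, checks=False), method=method)
    flat = fcluster(z, t=distance_threshold, criterion="distance")

    indices, labels = [], np.asarray(flat) - 1
    for lab in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == lab)
        mean_profile = I[members].mean(axis=0)
        d = (((I[members] - mean_profile) / sigma) ** 2).sum(axis=1)
        indices.append(int(members[int(np.argmin(d))]))
    indices = np.asarray(sorted(indices))
    return BasisSet(indices, [profiles[i] for i in indices], labels=labels)
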