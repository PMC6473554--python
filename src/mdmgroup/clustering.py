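"""Group-structure (GS) analysis: pairwise logBF separation and clustering.

The separation between two subjects is the log Bayes factor comparing the
model in which each keeps its own best network against the model in which
both share one network:

    d(i, j) = c_ij(m_I) - c_ij(m_G)

where c_ij(m_I) sums the two subjects' best individual scores and
c_ij(m_G) is the best achievable score when the pair shares a structure
(search on their summed score tables, same search variant).  d is
symmetric, non-negative, and zero whenever the two individual MAP networks
coincide.  Subjects are then clustered on the S x S separation matrix
(agglomerative linkage + a hybrid dynamic tree cut), low-dimensional
structure is inspected with classical MDS, and one network is estimated
per subgroup from the members' summed tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import squareform

from .groups import GroupStudy, _attach_average_strengths, cs_scores
from .search import DirectedNetwork, search_network, sum_tables

logger = logging.getLogger("mdmgroup")

__all__ = [
    "SeparationMatrix",
    "Dendrogram",
    "SubgroupAssignment",
    "pairwise_separation",
    "separation_matrix",
    "hierarchical_cluster",
    "cut_tree_dynamic",
    "classical_mds",
    "subgroup_networks",
]

_NEG_TOL = 1e-9


@dataclass(frozen=True)
class SeparationMatrix:
    """S x S pairwise logBF separations (symmetric, zero diagonal)."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    variant: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("separation matrix must be square")
        if v.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length must match the matrix")
        if not np.allclose(v, v.T):
            raise ValueError("separation matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("separation matrix must have a zero diagonal")
        if np.any(v < -_NEG_TOL):
            raise ValueError("separations must be nonnegative")

    @property
    def S(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree (scipy linkage matrix) plus leaf ids."""

    merge_table: np.ndarray  # scipy (S-1, 4) linkage matrix
    subject_ids: tuple[str, ...]
    linkage: str

    @property
    def heights(self) -> np.ndarray:
        return self.merge_table[:, 2]


@dataclass(frozen=True)
class SubgroupAssignment:
    """Cluster label (1..G) per subject; singleton flags mark subjects the
    tree cut left unassigned and that were promoted to their own subgroup."""

    labels: tuple[int, ...]
    singleton: tuple[bool, ...]

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))
        object.__setattr__(self, "singleton", tuple(bool(x) for x in self.singleton))
        G = self.G
        if sorted(set(self.labels)) != list(range(1, G + 1)):
            raise ValueError("labels must cover 1..G")

    @property
    def G(self) -> int:
        return max(self.labels)

    def members(self, g: int) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == g]


# ---------------------------------------------------------------------------
# Separation
# ---------------------------------------------------------------------------


def pairwise_separation(
    study: GroupStudy,
    i: int,
    j: int,
    variant: str = "ipa",
    clamp: bool = True,
) -> float:
    """Pairwise logBF separation d(i, j) between two subjects."""
    if i == j:
        return 0.0
    net_i = search_network(study.tables(i), variant)
    net_j = search_network(study.tables(j), variant)
    c_individual = net_i.total_score + net_j.total_score
    pair_tables = sum_tables([study.tables(i), study.tables(j)])
    c_shared = search_network(pair_tables, variant).total_score
    d = c_individual - c_shared
    if clamp and d < 0:
        if d < -_NEG_TOL:
            logger.warning("separation d(%d,%d)=%.3e clamped to 0", i, j, d)
        d = 0.0
    return float(d)


def separation_matrix(study: GroupStudy, variant: str = "ipa") -> SeparationMatrix:
    """Fill the full S x S separation matrix (upper triangle mirrored)."""
    S = study.S
    mat = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            d = pairwise_separation(study, i, j, variant)
            mat[i, j] = mat[j, i] = d
    return SeparationMatrix(
        values=mat,
        subject_ids=tuple(s.subject_id for s in study.subjects),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def hierarchical_cluster(sep: SeparationMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of the separation matrix."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError("linkage must be one of average/complete/single")
    if sep.S < 2:
        raise ValueError("need at least two subjects to cluster")
    condensed = squareform(sep.values, checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    return Dendrogram(merge_table=Z, subject_ids=sep.subject_ids, linkage=linkage)


def cut_tree_dynamic(
    dend: Dendrogram,
    min_cluster_size: int = 3,
    cut_height: float | None = None,
    distances: np.ndarray | None = None,
    split_factor: float = 2.0,
) -> SubgroupAssignment:
    """Hybrid adaptive tree cut.

    Follows the outline of the hybrid dynamic tree cut: (1) branches are
    split top-down wherever the joining height exceeds a static cut (99% of
    the merge-height range) *or* — the deep-split stage — wherever both
    sub-branches hold at least ``min_cluster_size`` subjects and the joining
    height exceeds ``split_factor`` times the heights inside them, so nested
    separation scales are resolved; (2) resulting clusters smaller than
    ``min_cluster_size`` are dissolved and their members reassigned to the
    nearest surviving cluster when their average distance to it does not
    exceed the cut height (a PAM-like stage, requiring ``distances``);
    (3) members that remain unassigned become singleton subgroups.  Labels
    are 1..G in decreasing cluster size.
    """
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    Z = dend.merge_table
    heights = Z[:, 2]
    if cut_height is None:
        lo, hi = float(heights.min()), float(heights.max())
        cut_height = lo + 0.99 * (hi - lo)
    root = to_tree(Z)
    S = root.get_count()

    def descend(node) -> list[list[int]]:
        if node.is_leaf():
            return [[node.id]]
        left, right = node.get_left(), node.get_right()
        deep = (
            left.get_count() >= min_cluster_size
            and right.get_count() >= min_cluster_size
            and node.dist > split_factor * max(left.dist, right.dist)
        )
        if node.dist > cut_height or deep:
            return descend(left) + descend(right)
        return [node.pre_order(lambda x: x.id)]

    clusters = descend(root)
    sizes = {c: len(members) for c, members in enumerate(clusters)}
    big = [c for c, sz in sizes.items() if sz >= min_cluster_size]
    labels = np.zeros(S, dtype=int)  # 0 = unassigned
    for new, c in enumerate(
        sorted(big, key=lambda c: (-sizes[c], min(clusters[c])))
    ):
        labels[clusters[c]] = new + 1
    # PAM-like stage: pull small-cluster members into a nearby big cluster.
    if big and distances is not None:
        for i in np.flatnonzero(labels == 0):
            avg = [
                (distances[i, labels == g].mean(), g) for g in range(1, len(big) + 1)
            ]
            best_d, best_g = min(avg)
            if best_d <= cut_height:
                labels[i] = best_g
    # Remaining unassigned subjects become singleton subgroups.
    singleton = np.zeros(S, dtype=bool)
    next_label = labels.max() + 1 if labels.max() > 0 else 1
    for i in np.flatnonzero(labels == 0):
        labels[i] = next_label
        singleton[i] = True
        next_label += 1
    return SubgroupAssignment(labels=tuple(labels), singleton=tuple(singleton))


def classical_mds(sep: SeparationMatrix, k: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared separations, eigendecomposes, and embeds on
    the top-k positive eigenvalues.  Returns (S x k coordinates, fraction
    of positive-eigenvalue variance captured).  An all-zero matrix embeds
    at the origin with variance_explained defined as 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = sep.values
    S = sep.S
    if not np.any(D):
        return np.zeros((S, k)), 1.0
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 0
    total = eigval[pos].sum()
    coords = np.zeros((S, k))
    take = min(k, int(pos.sum()))
    coords[:, :take] = eigvec[:, :take] * np.sqrt(eigval[:take])
    explained = float(eigval[:take][eigval[:take] > 0].sum() / total) if total > 0 else 1.0
    return coords, explained


# ---------------------------------------------------------------------------
# Subgroup networks
# ---------------------------------------------------------------------------


def subgroup_networks(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    variant: str = "ipa",
) -> list[DirectedNetwork]:
    """One network per subgroup: search on the members' summed tables, with
    strengths averaged over the members only."""
    if len(assignment.labels) != study.S:
        raise ValueError("assignment does not cover all subjects")
    nets = []
    for g in range(1, assignment.G + 1):
        members = assignment.members(g)
        net = search_network(cs_scores(study, members), variant)
        nets.append(_attach_average_strengths(study, members, net))
    return nets


def gs_pipeline(
    study: GroupStudy,
    variant: str = "ipa",
    linkage: str = "average",
    min_cluster_size: int = 3,
):
    """Convenience: separation -> dendrogram -> dynamic cut -> subgroup
    networks.  Returns (separation, dendrogram, assignment, networks)."""
    sep = separation_matrix(study, variant)
    dend = hierarchical_cluster(sep, linkage)
    assignment = cut_tree_dynamic(dend, min_cluster_size, distances=sep.values)
    nets = subgroup_networks(study, assignment, variant)
    return sep, dend, assignment, nets
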