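"""Joint estimation of individual, subgroup and group networks.

Two estimators over the three levels of a clustered study:

* IEMN (individual estimation of multiple networks) — every level is
  estimated independently: individual networks by per-subject search,
  subgroup and group networks by searching summed score tables.
* MEMN (marginal estimation of multiple networks) — the levels are coupled
  through a structural prior that penalises disagreement between an
  individual parent set and its subgroup's parent set:

      p(M_i(r) | M_g(r)) ∝ exp(-lambda * SHD(M_i(r), M_g(r)))

  where SHD is the per-node structural Hamming distance (size of the
  symmetric difference of the parent sets).  The per-node posteriors
  marginalise over the unknown centre (mixture sums for individuals,
  products over subjects for subgroup/group centres), all computed in log
  space with log-sum-exp.  exp(lambda) is the prior odds that an edge keeps
  its present/absent status between the two levels; lambda = 0 makes MEMN's
  individual networks coincide with IEMN's, and lambda -> infinity forces
  all members of a subgroup toward a common structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .clustering import SubgroupAssignment
from .groups import GroupStudy, cs_scores, individual_networks
from .search import DirectedNetwork, ScoreTable, search_network, set_to_mask

__all__ = [
    "PenaltySpec",
    "PenalizedPosterior",
    "MultiNetworkResult",
    "shd_parent_sets",
    "lambda_odds",
    "penalty_log_prior",
    "full_powerset_log_normalizer",
    "iemn",
    "memn_individual",
    "memn_subgroup",
    "memn_group",
    "memn",
    "select_lambda",
    "predicted_network",
    "LAMBDA_SWEEP_GRID",
]

#: Default lambda sweep: prior odds exp(lambda) from ~1.1 upward.
LAMBDA_SWEEP_GRID: tuple[float, ...] = (0.1, 0.7, 10.0, 100.0, 1000.0)


@dataclass(frozen=True)
class PenaltySpec:
    """Strength and normalisation of the structural prior."""

    lam: float
    normalized: bool = True
    n: int | None = None
    max_parents: int | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass(frozen=True)
class PenalizedPosterior:
    """Per-node log-posterior over parent sets under the SHD penalty."""

    node: int
    masks: np.ndarray
    log_posterior: np.ndarray  # same order as masks, normalised to sum to 1
    scope: str  # individual | subgroup | group

    def argmax_mask(self) -> int:
        pop = np.bitwise_count(self.masks.astype(np.int64))
        order = np.lexsort((self.masks, pop, -self.log_posterior))
        return int(self.masks[order[0]])

    def as_table(self, subject_id: str, n: int, max_parents: int) -> ScoreTable:
        return ScoreTable(
            subject_id=subject_id,
            node=self.node,
            n=n,
            max_parents=max_parents,
            scores={int(m): float(v) for m, v in zip(self.masks, self.log_posterior)},
        )


@dataclass(frozen=True)
class MultiNetworkResult:
    """All three network levels from one estimator run."""

    individual: tuple[DirectedNetwork, ...]
    subgroup: tuple[DirectedNetwork, ...]
    group: DirectedNetwork
    method: str  # IEMN | MEMN
    lam: float | None = None
    variant: str = "ipa"


# ---------------------------------------------------------------------------
# Penalty primitives
# ---------------------------------------------------------------------------


def shd_parent_sets(a, b) -> int:
    """Structural Hamming distance between two parent sets of one node:
    the number of nodes that are a parent in exactly one of the two."""
    am = a if isinstance(a, int) else set_to_mask(a)
    bm = b if isinstance(b, int) else set_to_mask(b)
    return bin(am ^ bm).count("1")


def lambda_odds(lam: float) -> tuple[float, float]:
    """(probability an edge keeps its status, prior odds exp(lambda))."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return 1.0 / (1.0 + math.exp(-lam)), math.exp(lam)


def full_powerset_log_normalizer(n: int, lam: float) -> float:
    """Closed-form log sum of exp(-lambda*SHD(., center)) over the full
    power set of the n-1 candidate parents; independent of the centre."""
    return (n - 1) * math.log1p(math.exp(-lam))


def penalty_log_prior(
    masks: Sequence[int] | np.ndarray,
    center: int,
    lam: float,
    normalized: bool = True,
) -> np.ndarray:
    """log p(parent set | centre) = -lambda * SHD, optionally normalised
    over the given parent-set space."""
    masks = np.asarray(masks, dtype=np.int64)
    logs = -lam * np.bitwise_count(masks ^ np.int64(center)).astype(float)
    if normalized:
        logs = logs - logsumexp(logs)
    return logs


def _distance_matrix(masks: np.ndarray) -> np.ndarray:
    return np.bitwise_count(masks[:, None] ^ masks[None, :]).astype(float)


# ---------------------------------------------------------------------------
# IEMN
# ---------------------------------------------------------------------------


def iemn(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    variant: str = "ipa",
) -> MultiNetworkResult:
    """Independent estimation: individual searches, subgroup searches on
    member-summed tables, group search on all-summed tables."""
    indiv = individual_networks(study, variant)
    subgroup = [
        search_network(cs_scores(study, assignment.members(g)), variant)
        for g in range(1, assignment.G + 1)
    ]
    group = search_network(cs_scores(study), variant)
    return MultiNetworkResult(
        individual=tuple(indiv),
        subgroup=tuple(subgroup),
        group=group,
        method="IEMN",
        variant=variant,
    )


# ---------------------------------------------------------------------------
# MEMN
# ---------------------------------------------------------------------------


def _node_arrays(tables: Sequence[ScoreTable], r: int) -> tuple[np.ndarray, np.ndarray]:
    return tables[r].arrays()


def _center_log_posterior(
    member_tables: Sequence[Sequence[ScoreTable]], r: int, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """log p(centre parent set | y) over the node-r space, up to the
    normalising constant, for a set of member subjects."""
    masks, _ = member_tables[0][r].arrays()
    A = -lam * _distance_matrix(masks)  # A[P, Q]
    lognorm = logsumexp(A, axis=0)  # per-centre prior normaliser
    out = np.zeros(len(masks))
    for tabs in member_tables:
        m, c = tabs[r].arrays()
        if not np.array_equal(m, masks):
            raise ValueError("member tables span different parent-set spaces")
        out += logsumexp(c[:, None] + A - lognorm[None, :], axis=0)
    return masks, out


def _normalize_log(v: np.ndarray) -> np.ndarray:
    return v - logsumexp(v)


def memn_individual(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    lam: float,
    variant: str = "ipa",
) -> tuple[list[DirectedNetwork], list[list[PenalizedPosterior]]]:
    """Penalised individual networks.

    For subject i in subgroup g, the node-r log posterior marginalises over
    the subgroup centre and over the other members' parent sets:

        log p(M_i(r)|y) = LSE_Q [ c_i(r, P) + log p(P|Q)
                           + sum_{k in S_g \\ {i}} LSE_Pk ( c_k(r,Pk) + log p(Pk|Q) ) ]

    with a uniform prior over centres Q.  The per-node posteriors are fed to
    the chosen search (acyclicity imposed on the argmax, not in the sums).
    """
    if len(assignment.labels) != study.S:
        raise ValueError("assignment does not cover all subjects")
    n = study.n
    networks: list[DirectedNetwork] = []
    posteriors: list[list[PenalizedPosterior]] = []
    for i in range(study.S):
        g = assignment.labels[i]
        members = assignment.members(g)
        others = [k for k in members if k != i]
        node_posts: list[PenalizedPosterior] = []
        node_tables: list[ScoreTable] = []
        for r in range(n):
            masks, c_i = study.tables(i)[r].arrays()
            if lam == 0:
                # Flat penalty: the posterior is proportional to exp(c_i),
                # so the argmax is the likelihood argmax.  Feeding the raw
                # scores to the search keeps exact score ties exact, making
                # the lambda=0 networks identical to IEMN's.
                logpost = _normalize_log(c_i)
                node_tables.append(study.tables(i)[r])
            else:
                A = -lam * _distance_matrix(masks)
                lognorm = logsumexp(A, axis=0)
                others_term = np.zeros(len(masks))
                for k in others:
                    _, c_k = study.tables(k)[r].arrays()
                    others_term += logsumexp(
                        c_k[:, None] + A - lognorm[None, :], axis=0
                    )
                logpost = _normalize_log(
                    logsumexp(
                        c_i[:, None] + A - lognorm[None, :] + others_term[None, :],
                        axis=1,
                    )
                )
            post = PenalizedPosterior(
                node=r, masks=masks, log_posterior=logpost, scope="individual"
            )
            node_posts.append(post)
            if lam != 0:
                node_tables.append(
                    post.as_table(
                        study.subjects[i].subject_id, n, study.tables(i)[r].max_parents
                    )
                )
        networks.append(search_network(node_tables, variant))
        posteriors.append(node_posts)
    return networks, posteriors


def _memn_center_networks(
    study: GroupStudy,
    member_sets: Sequence[Sequence[int]],
    lam: float,
    variant: str,
    scope: str,
) -> tuple[list[DirectedNetwork], list[list[PenalizedPosterior]]]:
    n = study.n
    networks, posteriors = [], []
    for members in member_sets:
        member_tables = [study.tables(i) for i in members]
        node_posts, node_tables = [], []
        for r in range(n):
            masks, logpost = _center_log_posterior(member_tables, r, lam)
            logpost = _normalize_log(logpost)
            post = PenalizedPosterior(
                node=r, masks=masks, log_posterior=logpost, scope=scope
            )
            node_posts.append(post)
            node_tables.append(
                post.as_table(scope, n, member_tables[0][r].max_parents)
            )
        networks.append(search_network(node_tables, variant))
        posteriors.append(node_posts)
    return networks, posteriors


def memn_subgroup(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    lam: float,
    variant: str = "ipa",
) -> tuple[list[DirectedNetwork], list[list[PenalizedPosterior]]]:
    """Penalised subgroup networks: the centre posterior multiplies, over
    the subgroup's members, the member's penalty-weighted evidence."""
    member_sets = [assignment.members(g) for g in range(1, assignment.G + 1)]
    return _memn_center_networks(study, member_sets, lam, variant, "subgroup")


def memn_group(
    study: GroupStudy, lam: float, variant: str = "ipa"
) -> tuple[DirectedNetwork, list[PenalizedPosterior]]:
    """Penalised group network over all S subjects."""
    nets, posts = _memn_center_networks(
        study, [list(range(study.S))], lam, variant, "group"
    )
    return nets[0], posts[0]


def memn(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    lam: float,
    variant: str = "ipa",
) -> MultiNetworkResult:
    """All three MEMN levels at one penalty strength."""
    indiv, _ = memn_individual(study, assignment, lam, variant)
    sub, _ = memn_subgroup(study, assignment, lam, variant)
    grp, _ = memn_group(study, lam, variant)
    return MultiNetworkResult(
        individual=tuple(indiv),
        subgroup=tuple(sub),
        group=grp,
        method="MEMN",
        lam=lam,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# Lambda selection and prediction
# ---------------------------------------------------------------------------


def _network_log_posterior(
    network: DirectedNetwork, posts: Sequence[PenalizedPosterior]
) -> float:
    total = 0.0
    for r, post in enumerate(posts):
        idx = np.flatnonzero(post.masks == network.parents[r])
        if len(idx) == 0:
            return -math.inf
        total += float(post.log_posterior[idx[0]])
    return total


def _table_lpl(tables: Sequence[ScoreTable], network: DirectedNetwork) -> float:
    return sum(tables[r].scores[network.parents[r]] for r in range(len(tables)))


def select_lambda(
    study: GroupStudy,
    assignment: SubgroupAssignment,
    grid: Iterable[float] = LAMBDA_SWEEP_GRID,
    criterion: str = "max_individual_posterior",
    variant: str = "ipa",
) -> tuple[float, list[dict]]:
    """Choose the penalty strength from a grid.

    Criteria: ``max_individual_posterior`` (sum over subjects of the
    estimated individual network's log posterior), ``max_group_posterior``
    (the estimated group network's log posterior), or ``cross_validation``
    (leave-one-subject-out: the held-out subject's LPL under the predicted
    group network).  Ties go to the smallest lambda.  Returns the winner and
    a per-lambda report.
    """
    grid = sorted(set(float(l) for l in grid))
    if not grid:
        raise ValueError("empty lambda grid")
    if any(l < 0 for l in grid):
        raise ValueError("lambda values must be nonnegative")
    report = []
    for lam in grid:
        if criterion == "max_individual_posterior":
            nets, posts = memn_individual(study, assignment, lam, variant)
            value = sum(
                _network_log_posterior(net, p) for net, p in zip(nets, posts)
            )
        elif criterion == "max_group_posterior":
            net, posts = memn_group(study, lam, variant)
            value = _network_log_posterior(net, posts)
        elif criterion == "cross_validation":
            value = 0.0
            for i in range(study.S):
                pred = predicted_network(study, i, "memn", lam, variant)
                value += _table_lpl(study.tables(i), pred)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        result = memn(study, assignment, lam, variant)
        report.append(
            {
                "lambda": lam,
                "criterion": float(value),
                "individual_edges": float(
                    np.mean([m.n_edges for m in result.individual])
                ),
                "subgroup_edges": float(np.mean([m.n_edges for m in result.subgroup])),
                "group_edges": result.group.n_edges,
            }
        )
    best = max(report, key=lambda row: (row["criterion"], -row["lambda"]))
    return best["lambda"], report


def predicted_network(
    study: GroupStudy,
    i: int,
    method: str = "iemn",
    lam: float | None = None,
    variant: str = "ipa",
) -> DirectedNetwork:
    """Leave-one-subject-out predicted network for subject ``i``: the group
    estimate computed from the other S-1 subjects."""
    if study.S < 2:
        raise ValueError("prediction needs at least two subjects")
    rest = study.subset([k for k in range(study.S) if k != i])
    if method == "iemn":
        return search_network(cs_scores(rest), variant)
    if method == "memn":
        if lam is None:
            raise ValueError("memn prediction needs a lambda")
        net, _ = memn_group(rest, lam, variant)
        return net
    raise ValueError(f"unknown method {method!r}")
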