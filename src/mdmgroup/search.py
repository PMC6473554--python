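"""Parent-set score tables and network structure search.

Parent sets are encoded as integer bitmasks over the full node set (bit j
set means node j is a parent); a node's own bit is never set in its masks.
Two searches are provided:

* ``dgm_search`` — per-node maximisation of the local score, with no
  acyclicity constraint (the resulting digraph may be cyclic);
* ``dag_search_exact`` — the globally score-optimal DAG, found by exact
  dynamic programming over the subset lattice (sinkless-vertex recursion),
  which attains the same optimum as integer-programming formulations.

Ties are always broken in favour of smaller parent sets, then smaller
bitmask, so identical inputs yield identical networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .mdm import (
    PriorPolicy,
    SubjectSeries,
    filter_best_delta,
    local_score,
    smooth_node,
)

__all__ = [
    "ScoreTable",
    "DirectedNetwork",
    "mask_to_set",
    "set_to_mask",
    "default_max_parents",
    "score_all_parent_sets",
    "score_tables",
    "dgm_search",
    "dag_search_exact",
    "search_network",
    "fit_network",
    "HARD_NODE_CAP",
]

#: Largest node count accepted by the exact searches without an explicit
#: ``max_parents``; beyond this the subset lattice is intractable.
HARD_NODE_CAP = 20


def mask_to_set(mask: int) -> tuple[int, ...]:
    """Decode a parent bitmask into a sorted tuple of node indices."""
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return tuple(out)


def set_to_mask(parents) -> int:
    mask = 0
    for p in parents:
        mask |= 1 << int(p)
    return mask


def default_max_parents(n: int) -> int:
    """n - 1 for small networks, else a cap of 4 to bound cost."""
    return n - 1 if n <= 12 else 4


@dataclass(frozen=True)
class ScoreTable:
    """Local scores c(r, Pa) for one (subject, node) over all admissible
    parent sets of size <= ``max_parents``."""

    subject_id: str
    node: int
    n: int
    max_parents: int
    scores: dict[int, float]

    def __post_init__(self):
        for mask, s in self.scores.items():
            if mask & (1 << self.node):
                raise ValueError(f"parent set {mask:b} contains node {self.node}")
            if not math.isfinite(s):
                raise ValueError("scores must be finite")

    def masks(self) -> list[int]:
        return sorted(self.scores)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.array(self.masks(), dtype=np.int64)
        return m, np.array([self.scores[k] for k in m], dtype=float)

    def best(self) -> tuple[int, float]:
        """Argmax parent set under the parsimony tie-break."""
        best_mask, best_score = None, -math.inf
        for mask in self.masks():
            s = self.scores[mask]
            if s > best_score or (
                s == best_score and _mask_key(mask) < _mask_key(best_mask)
            ):
                best_mask, best_score = mask, s
        return best_mask, best_score

    def __add__(self, other: "ScoreTable") -> "ScoreTable":
        if (self.node, self.n) != (other.node, other.n) or set(self.scores) != set(
            other.scores
        ):
            raise ValueError("score tables span different parent-set spaces")
        return ScoreTable(
            subject_id=f"{self.subject_id}+{other.subject_id}",
            node=self.node,
            n=self.n,
            max_parents=self.max_parents,
            scores={k: self.scores[k] + other.scores[k] for k in self.scores},
        )


def _mask_key(mask: int) -> tuple[int, int]:
    return (bin(mask).count("1"), mask)


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed network given by one parent set per node.

    ``strengths`` maps (parent, child) -> (theta_bar, sigma2_bar), the
    time-averaged smoothed coefficient mean and variance; ``intercepts``
    holds the same summaries for each node's level term.
    """

    parents: tuple[int, ...]  # parent bitmask per node
    acyclic: bool = field(default=False)
    total_score: float | None = None
    strengths: dict[tuple[int, int], tuple[float, float]] | None = None
    intercepts: dict[int, tuple[float, float]] | None = None
    variant: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "parents", tuple(int(m) for m in self.parents))
        n = len(self.parents)
        for r, mask in enumerate(self.parents):
            if mask & (1 << r):
                raise ValueError(f"self-loop at node {r}")
            if mask >> n:
                raise ValueError(f"parent mask of node {r} references unknown nodes")
        object.__setattr__(self, "acyclic", _is_acyclic(self.parents))

    @property
    def n(self) -> int:
        return len(self.parents)

    def parent_sets(self) -> list[tuple[int, ...]]:
        return [mask_to_set(m) for m in self.parents]

    def edges(self) -> list[tuple[int, int]]:
        """Directed edges as (parent, child) pairs."""
        return [(p, r) for r, m in enumerate(self.parents) for p in mask_to_set(m)]

    @property
    def n_edges(self) -> int:
        return sum(bin(m).count("1") for m in self.parents)

    def __eq__(self, other) -> bool:
        return isinstance(other, DirectedNetwork) and self.parents == other.parents

    def __hash__(self):
        return hash(self.parents)


def _is_acyclic(parents: Sequence[int]) -> bool:
    # Kahn's algorithm on the parent-mask representation.
    n = len(parents)
    remaining = set(range(n))
    masks = list(parents)
    changed = True
    while remaining and changed:
        changed = False
        for r in list(remaining):
            if masks[r] & set_to_mask(remaining) == 0:
                remaining.discard(r)
                changed = True
    return not remaining


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def score_all_parent_sets(
    series: SubjectSeries,
    r: int,
    max_parents: int | None = None,
    policy: PriorPolicy | None = None,
) -> ScoreTable:
    """Score every parent set of node ``r`` up to size ``max_parents``."""
    policy = policy or PriorPolicy()
    n = series.n
    if max_parents is None:
        if n > HARD_NODE_CAP:
            raise ValueError(
                f"n = {n} exceeds the hard cap ({HARD_NODE_CAP}); pass max_parents "
                "to bound the parent-set space"
            )
        max_parents = default_max_parents(n)
    if not (0 <= max_parents <= n - 1):
        raise ValueError("max_parents must lie in [0, n-1]")
    others = [j for j in range(n) if j != r]
    scores: dict[int, float] = {}
    for size in range(max_parents + 1):
        for combo in combinations(others, size):
            scores[set_to_mask(combo)] = local_score(series, r, combo, policy)
    return ScoreTable(
        subject_id=series.subject_id, node=r, n=n, max_parents=max_parents, scores=scores
    )


def score_tables(
    series: SubjectSeries,
    max_parents: int | None = None,
    policy: PriorPolicy | None = None,
) -> list[ScoreTable]:
    """One ScoreTable per node of the subject."""
    return [
        score_all_parent_sets(series, r, max_parents, policy) for r in range(series.n)
    ]


def sum_tables(per_subject: Sequence[Sequence[ScoreTable]]) -> list[ScoreTable]:
    """Entrywise sum of per-subject tables (the common-structure score)."""
    if not per_subject:
        raise ValueError("no tables to sum")
    summed = list(per_subject[0])
    for tabs in per_subject[1:]:
        summed = [a + b for a, b in zip(summed, tabs)]
    return summed


# ---------------------------------------------------------------------------
# Searches
# ---------------------------------------------------------------------------


def dgm_search(tables: Sequence[ScoreTable]) -> DirectedNetwork:
    """Per-node argmax of the local scores (cycles permitted)."""
    _validate_tables(tables)
    parents, total = [], 0.0
    for tab in tables:
        mask, score = tab.best()
        parents.append(mask)
        total += score
    return DirectedNetwork(parents=tuple(parents), total_score=total, variant="dgm")


def dag_search_exact(tables: Sequence[ScoreTable]) -> DirectedNetwork:
    """Globally optimal DAG by dynamic programming over node subsets.

    For every node v and allowed-ancestor set S, the best parent set of v
    within S is precomputed by a subset-lattice sweep; the outer recursion
    then peels off one sink at a time:

        best(S) = max_{v in S} best(S \\ {v}) + bps(v, S \\ {v}).

    The optimum equals exhaustive enumeration over all labelled DAGs.
    """
    _validate_tables(tables)
    n = tables[0].n
    if n > HARD_NODE_CAP:
        raise ValueError(
            f"n = {n} exceeds the hard cap ({HARD_NODE_CAP}); reduce max_parents "
            "or the node count"
        )
    size = 1 << n
    idx = np.arange(size, dtype=np.int64)
    pop = np.bitwise_count(idx).astype(np.int64)

    # bps[v][S]: best score of node v over parent sets P <= S, with the
    # (popcount, mask) tie-break; bset[v][S] the chosen mask.
    bps = np.full((n, size), -np.inf)
    bset = np.zeros((n, size), dtype=np.int64)
    for v, tab in enumerate(tables):
        masks, scores = tab.arrays()
        arr = np.full(size, -np.inf)
        chosen = idx.copy()
        arr[masks] = scores
        for b in range(n):
            if b == v:
                continue
            hi = idx[(idx >> b) & 1 == 1]
            lo = hi ^ (1 << b)
            cand_s, cand_m = arr[lo], chosen[lo]
            cur_s, cur_m = arr[hi], chosen[hi]
            take = (cand_s > cur_s) | (
                (cand_s == cur_s)
                & (
                    (pop[cand_m] < pop[cur_m])
                    | ((pop[cand_m] == pop[cur_m]) & (cand_m < cur_m))
                )
            )
            arr[hi] = np.where(take, cand_s, cur_s)
            chosen[hi] = np.where(take, cand_m, cur_m)
        bps[v] = arr
        bset[v] = chosen

    best = np.full(size, -np.inf)
    best[0] = 0.0
    sink = np.full(size, -1, dtype=np.int64)
    for mask in range(1, size):
        m = mask
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            prev = mask ^ (1 << v)
            s = best[prev] + bps[v, prev]
            if s > best[mask]:
                best[mask] = s
                sink[mask] = v
    parents = [0] * n
    mask = size - 1
    while mask:
        v = int(sink[mask])
        prev = mask ^ (1 << v)
        parents[v] = int(bset[v, prev])
        mask = prev
    net = DirectedNetwork(
        parents=tuple(parents), total_score=float(best[size - 1]), variant="ipa"
    )
    assert net.acyclic
    return net


def search_network(tables: Sequence[ScoreTable], variant: str = "ipa") -> DirectedNetwork:
    """Dispatch to the exact DAG search (``ipa``) or the unconstrained
    per-node search (``dgm``)."""
    if variant == "ipa":
        return dag_search_exact(tables)
    if variant == "dgm":
        return dgm_search(tables)
    raise ValueError(f"unknown search variant {variant!r}; use 'ipa' or 'dgm'")


def _validate_tables(tables: Sequence[ScoreTable]) -> None:
    if not tables:
        raise ValueError("no score tables given")
    n = tables[0].n
    if len(tables) != n or sorted(t.node for t in tables) != list(range(n)):
        raise ValueError("need exactly one table per node, in node order")


# ---------------------------------------------------------------------------
# Fitting a fixed structure
# ---------------------------------------------------------------------------


def fit_network(
    series: SubjectSeries,
    network: DirectedNetwork,
    policy: PriorPolicy | None = None,
) -> DirectedNetwork:
    """Refit a fixed structure to one subject and attach per-edge smoothed
    strength summaries (theta_bar, sigma2_bar)."""
    policy = policy or PriorPolicy()
    if network.n != series.n:
        raise ValueError("network and series disagree on the number of nodes")
    strengths: dict[tuple[int, int], tuple[float, float]] = {}
    intercepts: dict[int, tuple[float, float]] = {}
    total = 0.0
    for r, mask in enumerate(network.parents):
        pa = mask_to_set(mask)
        fr = filter_best_delta(series, r, pa, policy)
        total += fr.total_after(policy.burn_in)
        sm = smooth_node(fr)
        intercepts[r] = (float(sm.theta_bar[0]), float(sm.var_bar[0]))
        for k, p in enumerate(pa):
            strengths[(p, r)] = (float(sm.theta_bar[1 + k]), float(sm.var_bar[1 + k]))
    return replace(
        network, total_score=total, strengths=strengths, intercepts=intercepts
    )
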