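"""Baseline group-network estimators and strength aggregation.

Three classical ways of turning S subjects into one group network:

* VTS (virtual typical subject) — average the observed series pointwise
  across subjects and analyse the average as a single subject;
* CS (common structure) — sum the per-subject local score tables entrywise
  and search once on the summed scores;
* IS (individual structure) — search each subject independently and keep
  the edges present in more than a threshold fraction of the individual
  networks (majority vote by default).

Connectivity strength is summarised per edge by the standardized mean
Z_bar = theta_bar / sqrt(sigma2_bar / (T * S_g)), where theta_bar and
sigma2_bar average the smoothed coefficient mean/variance over time and
over the subjects of the subgroup, and by the Welch-type standardized
difference D_bar between two subgroups.  Edge prevalence within a subgroup
is tested against a binomial null with Benjamini--Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .mdm import PriorPolicy, SubjectSeries, standardize
from .search import (
    DirectedNetwork,
    ScoreTable,
    fit_network,
    score_tables,
    search_network,
    sum_tables,
)

logger = logging.getLogger("mdmgroup")

__all__ = [
    "GroupStudy",
    "EdgeStrength",
    "StrengthSummary",
    "vts_group",
    "cs_scores",
    "cs_group",
    "is_group",
    "individual_networks",
    "strength_zbar",
    "strength_diff",
    "significant_edges",
]


class GroupStudy:
    """A multi-subject study with lazily cached per-subject score tables.

    All subjects must share region names and their order; series lengths
    may differ.  Score tables are the expensive step, so they are computed
    once and reused by every group method and by the clustering.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectSeries],
        policy: PriorPolicy | None = None,
        max_parents: int | None = None,
    ):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("a study needs at least one subject")
        names = subjects[0].region_names
        for s in subjects[1:]:
            if s.region_names != names:
                raise ValueError(
                    f"subject {s.subject_id!r} has different region names/order"
                )
        self.subjects = subjects
        self.policy = policy or PriorPolicy()
        self.max_parents = max_parents
        self._prepared: dict[int, SubjectSeries] = {}
        self._tables: dict[int, list[ScoreTable]] = {}

    @classmethod
    def from_bundle(cls, bundle, policy=None, max_parents=None) -> "GroupStudy":
        return cls(bundle.subjects, policy=policy, max_parents=max_parents)

    @property
    def S(self) -> int:
        return len(self.subjects)

    @property
    def n(self) -> int:
        return self.subjects[0].n

    @property
    def region_names(self) -> tuple[str, ...]:
        return self.subjects[0].region_names

    def prepared(self, i: int) -> SubjectSeries:
        """Subject ``i`` after the policy's standardization step."""
        if i not in self._prepared:
            s = self.subjects[i]
            self._prepared[i] = standardize(s) if self.policy.standardize else s
        return self._prepared[i]

    def tables(self, i: int) -> list[ScoreTable]:
        """Cached per-node score tables of subject ``i``."""
        if i not in self._tables:
            self._tables[i] = score_tables(
                self.prepared(i), self.max_parents, self.policy
            )
        return self._tables[i]

    def ensure_tables(self) -> None:
        for i in range(self.S):
            self.tables(i)

    def subset(self, members: Sequence[int]) -> "GroupStudy":
        """A view-study over a subset of subjects, sharing caches."""
        members = list(members)
        sub = GroupStudy(
            [self.subjects[i] for i in members], self.policy, self.max_parents
        )
        for new_i, old_i in enumerate(members):
            if old_i in self._prepared:
                sub._prepared[new_i] = self._prepared[old_i]
            if old_i in self._tables:
                sub._tables[new_i] = self._tables[old_i]
        return sub


# ---------------------------------------------------------------------------
# Group estimators
# ---------------------------------------------------------------------------


def vts_group(study: GroupStudy, search: str = "ipa") -> DirectedNetwork:
    """Virtual-typical-subject network: search on the across-subject average
    of the raw series, with strengths from the single fitted average."""
    if study.S == 1:
        warnings.warn("VTS with one subject equals the individual search")
    Ts = [s.T for s in study.subjects]
    Tmin = min(Ts)
    if len(set(Ts)) > 1:
        warnings.warn(f"subjects have unequal T; truncating all to T={Tmin}")
    avg = np.mean([s.values[:Tmin] for s in study.subjects], axis=0)
    typical = SubjectSeries("vts-average", avg, study.region_names)
    if study.policy.standardize:
        typical = standardize(typical)
    tabs = score_tables(typical, study.max_parents, study.policy)
    net = search_network(tabs, search)
    return fit_network(typical, net, study.policy)


def cs_scores(
    study: GroupStudy, members: Sequence[int] | None = None
) -> list[ScoreTable]:
    """Entrywise sum of the member subjects' score tables (common-structure
    scores)."""
    members = list(range(study.S)) if members is None else list(members)
    if not members:
        raise ValueError("no members given")
    return sum_tables([study.tables(i) for i in members])


def cs_group(
    study: GroupStudy, search: str = "ipa", members: Sequence[int] | None = None
) -> DirectedNetwork:
    """Common-structure network: search on summed tables; strengths average
    the per-subject smoothed summaries under the shared structure."""
    members = list(range(study.S)) if members is None else list(members)
    net = search_network(cs_scores(study, members), search)
    return _attach_average_strengths(study, members, net)


def individual_networks(study: GroupStudy, search: str = "ipa") -> list[DirectedNetwork]:
    return [search_network(study.tables(i), search) for i in range(study.S)]


def is_group(
    networks: Sequence[DirectedNetwork], threshold: float = 0.5
) -> DirectedNetwork:
    """Individual-structure network: keep each directed edge present in
    strictly more than ``threshold * S`` of the individual networks."""
    networks = list(networks)
    if not networks:
        raise ValueError("no individual networks given")
    n = networks[0].n
    S = len(networks)
    counts: dict[tuple[int, int], int] = {}
    for net in networks:
        if net.n != n:
            raise ValueError("networks are on different node sets")
        for e in net.edges():
            counts[e] = counts.get(e, 0) + 1
    parents = [0] * n
    for (p, r), c in counts.items():
        if c > threshold * S:
            parents[r] |= 1 << p
    net = DirectedNetwork(parents=tuple(parents), variant="is")
    if not net.acyclic:
        logger.info("IS group network contains directed cycles")
    return net


def _attach_average_strengths(
    study: GroupStudy, members: Sequence[int], network: DirectedNetwork
) -> DirectedNetwork:
    """Fit ``network`` to each member and average theta_bar / sigma2_bar."""
    fits = [fit_network(study.prepared(i), network, study.policy) for i in members]
    strengths = {}
    for e in network.edges():
        tb = float(np.mean([f.strengths[e][0] for f in fits]))
        vb = float(np.mean([f.strengths[e][1] for f in fits]))
        strengths[e] = (tb, vb)
    intercepts = {}
    for r in range(network.n):
        tb = float(np.mean([f.intercepts[r][0] for f in fits]))
        vb = float(np.mean([f.intercepts[r][1] for f in fits]))
        intercepts[r] = (tb, vb)
    total = float(np.sum([f.total_score for f in fits]))
    return replace(
        network, strengths=strengths, intercepts=intercepts, total_score=total
    )


# ---------------------------------------------------------------------------
# Strength summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeStrength:
    theta_bar: float
    sigma2_bar: float
    zbar: float
    significant: bool


@dataclass(frozen=True)
class StrengthSummary:
    """Per-edge standardized connectivity strengths for one subgroup."""

    edges: dict[tuple[int, int], EdgeStrength]
    S_g: int
    T: int


def strength_zbar(
    study: GroupStudy,
    members: Sequence[int],
    network: DirectedNetwork,
    z_threshold: float = 2.0,
) -> StrengthSummary:
    """Standardized mean strength Z_bar = theta_bar / sqrt(sigma2_bar/(T*S_g))
    per edge of ``network``, averaging over the subgroup's members."""
    members = list(members)
    if not members:
        raise ValueError("subgroup has no members")
    T = min(study.subjects[i].T for i in members)
    S_g = len(members)
    fitted = _attach_average_strengths(study, members, network)
    edges = {}
    for e, (tb, vb) in fitted.strengths.items():
        z = tb / math.sqrt(vb / (T * S_g))
        edges[e] = EdgeStrength(tb, vb, z, abs(z) >= z_threshold)
    return StrengthSummary(edges=edges, S_g=S_g, T=T)


def strength_diff(
    summary_g: StrengthSummary, summary_l: StrengthSummary
) -> dict[tuple[int, int], float]:
    """Welch-type standardized strength difference D_bar between two
    subgroups, per edge present in both summaries (others are skipped)."""
    out = {}
    for e, sg in summary_g.edges.items():
        sl = summary_l.edges.get(e)
        if sl is None:
            logger.info("edge %s missing in second subgroup; excluded from D_bar", e)
            continue
        se = math.sqrt(
            sg.sigma2_bar / (summary_g.T * summary_g.S_g)
            + sl.sigma2_bar / (summary_l.T * summary_l.S_g)
        )
        out[e] = (sg.theta_bar - sl.theta_bar) / se
    for e in summary_l.edges:
        if e not in summary_g.edges:
            logger.info("edge %s missing in first subgroup; excluded from D_bar", e)
    return out


def significant_edges(
    networks: Sequence[DirectedNetwork],
    p0: float = 0.5,
    fdr_q: float = 0.05,
) -> dict[tuple[int, int], tuple[int, float, bool]]:
    """Exact one-sided binomial test of per-edge prevalence among the
    subgroup's individual networks, BH-corrected over all n(n-1) ordered
    pairs.  Returns edge -> (count, raw p, significant)."""
    networks = list(networks)
    if not networks:
        raise ValueError("no networks given")
    n = networks[0].n
    S_g = len(networks)
    counts = {}
    for p in range(n):
        for r in range(n):
            if p != r:
                counts[(p, r)] = 0
    for net in networks:
        for e in net.edges():
            counts[e] += 1
    edges = sorted(counts)
    pvals = [
        binomtest(counts[e], S_g, p0, alternative="greater").pvalue for e in edges
    ]
    reject, _, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    return {e: (counts[e], float(p), bool(rj)) for e, p, rj in zip(edges, pvals, reject)}
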