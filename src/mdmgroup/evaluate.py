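"""Network-recovery metrics and study-level evaluation harnesses.

Sensitivity/specificity treat directed edges as ordered pairs: sensitivity
is the fraction of true edges recovered, specificity the fraction of the
n(n-1) - |true| absent ordered pairs (self-pairs excluded) left out of the
estimate.  The structural Hamming distance (SHD) between two networks is
the total size of the per-node parent-set symmetric differences, i.e. the
number of directed-edge disagreements.  Networks fitted to the same
subject's data are compared by the log Bayes factor, the difference of
their LPLs.  Proportions carry highest-posterior-density intervals from a
Beta posterior under a uniform prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import beta as beta_dist

from .clustering import (
    cut_tree_dynamic,
    hierarchical_cluster,
    separation_matrix,
    subgroup_networks,
)
from .groups import GroupStudy, cs_group, individual_networks, is_group, vts_group
from .mdm import PriorPolicy, SubjectSeries, local_score
from .multinet import predicted_network
from .search import DirectedNetwork, mask_to_set
from .simulate import TruthBundle

__all__ = [
    "EvalReport",
    "sens_spec",
    "shd_networks",
    "network_logbf",
    "hpd_proportion",
    "popular_edges_graph",
    "rand_index",
    "table1_harness",
    "session_harness",
]


def sens_spec(
    truth: DirectedNetwork, estimate: DirectedNetwork
) -> tuple[float, float]:
    """(sensitivity, specificity) of a directed-edge estimate vs truth.

    Sensitivity is NaN when the true graph has no edges.
    """
    if truth.n != estimate.n:
        raise ValueError("networks are on different node sets")
    n = truth.n
    true_edges = set(truth.edges())
    est_edges = set(estimate.edges())
    tp = len(true_edges & est_edges)
    fp = len(est_edges - true_edges)
    n_pairs = n * (n - 1)
    n_absent = n_pairs - len(true_edges)
    sens = tp / len(true_edges) if true_edges else float("nan")
    spec = (n_absent - fp) / n_absent if n_absent else float("nan")
    return sens, spec


def shd_networks(a: DirectedNetwork, b: DirectedNetwork) -> int:
    """Directed-edge symmetric difference between two networks."""
    if a.n != b.n:
        raise ValueError("networks are on different node sets")
    return sum(bin(x ^ y).count("1") for x, y in zip(a.parents, b.parents))


def network_logbf(
    series: SubjectSeries,
    a: DirectedNetwork,
    b: DirectedNetwork,
    policy: PriorPolicy | None = None,
) -> float:
    """logBF = LPL(a) - LPL(b) on one subject's data (structures
    transferred, priors refit)."""
    policy = policy or PriorPolicy()
    lpl_a = sum(
        local_score(series, r, mask_to_set(m), policy) for r, m in enumerate(a.parents)
    )
    lpl_b = sum(
        local_score(series, r, mask_to_set(m), policy) for r, m in enumerate(b.parents)
    )
    return lpl_a - lpl_b


def hpd_proportion(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Highest-posterior-density interval for a proportion under a uniform
    prior, i.e. of a Beta(successes+1, trials-successes+1) posterior."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    a, b = successes + 1, trials - successes + 1
    if a == 1:  # monotone decreasing posterior
        return 0.0, float(beta_dist.ppf(level, a, b))
    if b == 1:  # monotone increasing posterior
        return float(beta_dist.ppf(1 - level, a, b)), 1.0

    def width(lo: float) -> float:
        hi = beta_dist.ppf(beta_dist.cdf(lo, a, b) + level, a, b)
        return hi - lo

    res = optimize.minimize_scalar(
        width, bounds=(0.0, float(beta_dist.ppf(1 - level, a, b))), method="bounded"
    )
    lo = float(res.x)
    hi = float(beta_dist.ppf(beta_dist.cdf(lo, a, b) + level, a, b))
    return lo, hi


def rand_index(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Plain Rand index between two labelings (pair-counting agreement)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    S = len(a)
    agree = 0
    for i in range(S):
        for j in range(i + 1, S):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    total = S * (S - 1) // 2
    return agree / total if total else 1.0


def popular_edges_graph(
    bundle: TruthBundle, threshold: float = 2.0 / 3.0
) -> DirectedNetwork:
    """Reference graph of edges present in the true networks of strictly
    more than ``threshold`` of the subjects."""
    true_nets = [bundle.true_dag_of(i) for i in range(bundle.S)]
    return is_group(true_nets, threshold)


# ---------------------------------------------------------------------------
# Harnesses
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Recovery metrics of the four group estimators on one study."""

    method_sens_spec: dict[str, tuple[float, float]] = field(default_factory=dict)
    gs_subgroups_found: int = 0
    gs_rand_index: float = float("nan")
    gs_per_subgroup: list[tuple[float, float]] = field(default_factory=list)
    popular_edge_count: int = 0
    session_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["method_sens_spec"] = {k: list(v) for k, v in d["method_sens_spec"].items()}
        d["gs_per_subgroup"] = [list(v) for v in d["gs_per_subgroup"]]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        d["method_sens_spec"] = {
            k: tuple(v) for k, v in d["method_sens_spec"].items()
        }
        d["gs_per_subgroup"] = [tuple(v) for v in d["gs_per_subgroup"]]
        return cls(**d)


def _majority_true_dag(bundle: TruthBundle, members: Sequence[int]) -> DirectedNetwork:
    counts: dict[int, int] = {}
    for i in members:
        counts[bundle.labels[i]] = counts.get(bundle.labels[i], 0) + 1
    label = max(counts, key=lambda k: (counts[k], -k))
    return bundle.dags[label - 1]


def table1_harness(
    bundle: TruthBundle,
    policy: PriorPolicy | None = None,
    max_parents: int | None = None,
    variant: str = "ipa",
    is_threshold: float = 0.5,
    min_cluster_size: int = 3,
) -> EvalReport:
    """Run VTS/CS/IS against the popular-edges reference graph and GS
    against each true subgroup DAG, on a simulated study with known truth.

    VTS, CS and IS each estimate one graph, so they are scored against the
    reference graph of edges shared by more than 2/3 of the subjects' true
    networks; each GS subgroup network is scored against the true DAG of
    the majority of its members.
    """
    if len(set(bundle.labels)) < 2:
        raise ValueError("harness expects at least two true subgroups")
    study = GroupStudy.from_bundle(bundle, policy=policy, max_parents=max_parents)
    reference = popular_edges_graph(bundle)
    report = EvalReport(popular_edge_count=reference.n_edges)

    report.method_sens_spec["VTS"] = sens_spec(reference, vts_group(study, variant))
    report.method_sens_spec["CS"] = sens_spec(reference, cs_group(study, variant))
    indiv = individual_networks(study, variant)
    report.method_sens_spec["IS"] = sens_spec(
        reference, is_group(indiv, is_threshold)
    )

    sep = separation_matrix(study, variant)
    dend = hierarchical_cluster(sep)
    assignment = cut_tree_dynamic(dend, min_cluster_size, distances=sep.values)
    report.gs_subgroups_found = assignment.G
    report.gs_rand_index = rand_index(bundle.labels, assignment.labels)
    nets = subgroup_networks(study, assignment, variant)
    per = []
    for g, net in enumerate(nets, start=1):
        truth = _majority_true_dag(bundle, assignment.members(g))
        per.append(sens_spec(truth, net))
    report.gs_per_subgroup = per
    sens_vals = [s for s, _ in per if not math.isnan(s)]
    spec_vals = [sp for _, sp in per]
    report.method_sens_spec["GS"] = (
        float(np.mean(sens_vals)) if sens_vals else float("nan"),
        float(np.mean(spec_vals)),
    )
    return report


def session_harness(
    condition_studies: dict[str, GroupStudy],
    method: str = "iemn",
    lam: float | None = None,
    metric: str = "shd",
    variant: str = "ipa",
) -> dict[str, float]:
    """Leave-one-subject-out session identification.

    Each condition holds the same subjects.  For every subject and
    condition, the subject's estimated individual network is compared (by
    SHD, or by logBF on the subject's data in that condition) with the
    predicted networks of all conditions, each computed from the other
    subjects.  A prediction is correct when the same condition minimises
    the distance.  Returns per-condition fractions correct plus the chance
    level 1/#conditions under ``"chance"``.
    """
    names = list(condition_studies)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    S = condition_studies[names[0]].S
    for st in condition_studies.values():
        if st.S != S:
            raise ValueError("all conditions must hold the same subjects")
    if metric not in ("shd", "logbf"):
        raise ValueError("metric must be 'shd' or 'logbf'")

    estimated = {
        c: individual_networks(condition_studies[c], variant) for c in names
    }
    predicted = {
        c: [
            predicted_network(condition_studies[c], i, method, lam, variant)
            for i in range(S)
        ]
        for c in names
    }
    fractions = {}
    for c in names:
        correct = 0
        for i in range(S):
            est = estimated[c][i]
            dists = []
            for c2 in names:
                pred = predicted[c2][i]
                if metric == "shd":
                    dist = shd_networks(est, pred)
                else:
                    # logBF of the estimated vs predicted structure on the
                    # subject's data in condition c: closer to 0 is closer.
                    st = condition_studies[c]
                    dist = abs(
                        network_logbf(st.prepared(i), est, pred, st.policy)
                    )
                dists.append((dist, c2))
            best = min(dists)[0]
            winners = [c2 for dist, c2 in dists if dist == best]
            correct += (len(winners) == 1 and winners[0] == c)
        fractions[c] = correct / S
    fractions["chance"] = 1.0 / len(names)
    return fractions
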