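"""Seeded multi-subject generator of networked time series.

Generates studies in which each subgroup of subjects shares one true DAG
and one set of true connection coefficients, mirroring a multi-subject
resting-state design: within a time point every node is the sum of an
intercept, its contemporaneous parents weighted by the (possibly
time-varying) coefficients, and Gaussian observation noise.  Values are
produced in topological order so the contemporaneous structural equations
are well defined.

Two presets are provided: ``full_scale_spec`` (3 subgroups x 10 subjects,
12 nodes, 1158 time points) and ``desk_scale_spec`` (3 x 6 subjects,
8 nodes, 400 time points) for quick runs.  Preset subgroup DAGs are
mutations of a shared base DAG (mean in-degree 2, in-degree capped at 3,
pairwise SHD >= 4), so subgroups share a core of "popular" edges yet stay
structurally distinct; coefficients have magnitude uniform in [0.4, 0.8]
with random sign and, in the presets, drift as a slow random walk so that
edge orientation is identifiable.  Subject seeds derive deterministically
from the master seed, so subgroup ordering never changes a subject's data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mdm import SubjectSeries
from .search import DirectedNetwork, mask_to_set, set_to_mask

__all__ = [
    "CoefficientProcess",
    "SubgroupSpec",
    "GeneratorSpec",
    "TruthBundle",
    "random_dag",
    "random_coefficients",
    "simulate_subject",
    "simulate_group",
    "full_scale_spec",
    "desk_scale_spec",
]


@dataclass(frozen=True)
class CoefficientProcess:
    """How each true edge coefficient evolves over time.

    ``constant`` keeps the drawn value fixed; ``random_walk`` adds i.i.d.
    Gaussian innovations of standard deviation ``innovation_sd`` each step.
    """

    kind: str = "constant"
    innovation_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("constant", "random_walk"):
            raise ValueError("kind must be 'constant' or 'random_walk'")
        if self.kind == "random_walk" and self.innovation_sd < 0:
            raise ValueError("innovation_sd must be nonnegative")


@dataclass(frozen=True)
class SubgroupSpec:
    """One homogeneous subgroup: a true DAG, true coefficients shared by
    all its subjects, and per-node observation noise."""

    n_subjects: int
    dag: DirectedNetwork
    coefficients: dict[tuple[int, int], float]
    obs_sd: tuple[float, ...]
    process: CoefficientProcess = CoefficientProcess()
    seed_key: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.dag.acyclic:
            raise ValueError("true network must be acyclic")
        missing = set(self.dag.edges()) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients for edges {sorted(missing)}")
        object.__setattr__(self, "obs_sd", tuple(float(s) for s in self.obs_sd))
        if len(self.obs_sd) != self.dag.n:
            raise ValueError("obs_sd must have one entry per node")


@dataclass(frozen=True)
class GeneratorSpec:
    """A full study design: node count, series length, subgroups, seed."""

    n: int
    T: int
    subgroups: tuple[SubgroupSpec, ...]
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "subgroups", tuple(self.subgroups))
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for g in self.subgroups:
            if g.dag.n != self.n:
                raise ValueError("subgroup DAG node count must match spec.n")


@dataclass(frozen=True)
class TruthBundle:
    """Generated subjects plus the ground truth that produced them."""

    subjects: tuple[SubjectSeries, ...]
    labels: tuple[int, ...]  # true subgroup label per subject, 1..G
    dags: tuple[DirectedNetwork, ...]
    coefficients: tuple[dict[tuple[int, int], float], ...]
    trajectories: tuple[dict[tuple[int, int], np.ndarray], ...]
    spec: GeneratorSpec

    @property
    def S(self) -> int:
        return len(self.subjects)

    def true_dag_of(self, i: int) -> DirectedNetwork:
        return self.dags[self.labels[i] - 1]


def _topological_order(parents: Sequence[int]) -> list[int]:
    n = len(parents)
    remaining = set(range(n))
    order: list[int] = []
    while remaining:
        ready = [r for r in remaining if parents[r] & set_to_mask(remaining) == 0]
        if not ready:
            raise ValueError("graph is cyclic; cannot simulate contemporaneously")
        for r in sorted(ready):
            order.append(r)
            remaining.discard(r)
    return order


def _edge_prob(n: int, expected_parents: float) -> float:
    """Per-slot inclusion probability giving a mean in-degree of
    ``expected_parents`` under order-restricted sampling (a node in the
    middle of the order has (n-1)/2 admissible parents on average), clipped
    at 1 (``expected_parents = n - 1`` yields the complete DAG)."""
    if n <= 1:
        return 0.0
    return min(1.0, 2.0 * expected_parents / (n - 1))


def random_dag(n: int, expected_parents: float, seed) -> DirectedNetwork:
    """Random DAG: uniform topological order, each admissible edge (earlier
    node -> later node) included independently with a probability calibrated
    so the mean parent count equals ``expected_parents``."""
    if not (0 <= expected_parents <= n - 1):
        raise ValueError("expected_parents must lie in [0, n-1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    prob = _edge_prob(n, expected_parents)
    parents = [0] * n
    for pos, child in enumerate(order):
        for anc_pos in range(pos):
            if rng.random() < prob:
                parents[child] |= 1 << int(order[anc_pos])
    return DirectedNetwork(parents=tuple(parents))


def random_coefficients(
    dag: DirectedNetwork, seed, low: float = 0.4, high: float = 0.8
) -> dict[tuple[int, int], float]:
    """Constant edge coefficients with |beta| ~ U(low, high), random sign."""
    rng = np.random.default_rng(seed)
    coeffs = {}
    for edge in dag.edges():
        mag = rng.uniform(low, high)
        coeffs[edge] = float(mag if rng.random() < 0.5 else -mag)
    return coeffs


def simulate_subject(
    dag: DirectedNetwork,
    coefficients: dict[tuple[int, int], float],
    obs_sd: Sequence[float],
    T: int,
    seed,
    process: CoefficientProcess = CoefficientProcess(),
    subject_id: str = "sim",
    region_names: Sequence[str] | None = None,
) -> tuple[SubjectSeries, dict[tuple[int, int], np.ndarray]]:
    """Simulate one subject from a DAG with the given coefficient process.

    Returns the series and the per-edge coefficient trajectories actually
    used (a (T,) array per edge).
    """
    if not dag.acyclic:
        raise ValueError("dag must be acyclic")
    n = dag.n
    rng = np.random.default_rng(seed)
    order = _topological_order(dag.parents)
    obs_sd = np.asarray(obs_sd, dtype=float)
    edges = dag.edges()
    traj: dict[tuple[int, int], np.ndarray] = {}
    for e in edges:
        base = coefficients[e]
        if process.kind == "random_walk" and process.innovation_sd > 0:
            steps = rng.normal(0.0, process.innovation_sd, size=T)
            traj[e] = base + np.cumsum(steps)
        else:
            traj[e] = np.full(T, base)
    noise = rng.normal(size=(T, n)) * obs_sd
    y = np.zeros((T, n))
    for r in order:
        pa = mask_to_set(dag.parents[r])
        y[:, r] = noise[:, r]
        for p in pa:
            y[:, r] += traj[(p, r)] * y[:, p]
    names = tuple(region_names) if region_names else tuple(f"R{j+1}" for j in range(n))
    return SubjectSeries(subject_id=subject_id, values=y, region_names=names), traj


def simulate_group(spec: GeneratorSpec) -> TruthBundle:
    """Simulate every subject of the design.

    Each subject's RNG seed is derived from the master seed and the pair
    (subgroup seed_key, within-subgroup index), so reordering subgroups in
    the spec leaves every subject's data unchanged.
    """
    subjects: list[SubjectSeries] = []
    labels: list[int] = []
    trajs: list[dict[tuple[int, int], np.ndarray]] = []
    for g_idx, grp in enumerate(spec.subgroups):
        for s_idx in range(grp.n_subjects):
            ss = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(grp.seed_key, s_idx)
            )
            series, traj = simulate_subject(
                grp.dag,
                grp.coefficients,
                grp.obs_sd,
                spec.T,
                ss,
                grp.process,
                subject_id=f"g{g_idx + 1}s{s_idx + 1}",
            )
            subjects.append(series)
            labels.append(g_idx + 1)
            trajs.append(traj)
    return TruthBundle(
        subjects=tuple(subjects),
        labels=tuple(labels),
        dags=tuple(g.dag for g in spec.subgroups),
        coefficients=tuple(dict(g.coefficients) for g in spec.subgroups),
        trajectories=tuple(trajs),
        spec=spec,
    )


def _shd(a: DirectedNetwork, b: DirectedNetwork) -> int:
    return sum(bin(x ^ y).count("1") for x, y in zip(a.parents, b.parents))


def _capped_random_parents(
    rng, order: np.ndarray, prob: float, max_in_degree: int
) -> list[int]:
    n = len(order)
    parents = [0] * n
    for pos, child in enumerate(order):
        child = int(child)
        for anc_pos in range(pos):
            if bin(parents[child]).count("1") >= max_in_degree:
                break
            if rng.random() < prob:
                parents[child] |= 1 << int(order[anc_pos])
    return parents


def _subgroup_dags(
    n: int,
    n_groups: int,
    expected_parents: float,
    seed,
    n_mutations: int,
    min_shd: int,
    max_in_degree: int,
) -> list[DirectedNetwork]:
    """Subgroup DAGs sharing a common core.

    A base DAG is drawn on a shared topological order; each subgroup DAG
    mutates ``n_mutations`` admissible edge slots (toggling presence, never
    violating the order or the in-degree cap), and groups are redrawn until
    every pair differs by at least ``min_shd`` edges.  This mirrors a study
    in which subgroup networks share most ("popular") edges yet remain
    structurally distinct, and keeps true in-degrees within the searched
    parent-set cap.
    """
    for attempt in range(10_000):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(901, attempt))
        )
        order = rng.permutation(n)
        prob = _edge_prob(n, expected_parents)
        base = _capped_random_parents(rng, order, prob, max_in_degree)
        pos = {int(v): k for k, v in enumerate(order)}
        slots = [
            (p, c)
            for p in range(n)
            for c in range(n)
            if p != c and pos[p] < pos[c]
        ]
        dags: list[DirectedNetwork] = []
        ok = True
        for _ in range(n_groups):
            parents = list(base)
            mutated: set[tuple[int, int]] = set()
            guard = 0
            while len(mutated) < n_mutations and guard < 1000:
                guard += 1
                p, c = slots[rng.integers(len(slots))]
                if (p, c) in mutated:
                    continue
                if parents[c] & (1 << p):
                    parents[c] &= ~(1 << p)
                elif bin(parents[c]).count("1") < max_in_degree:
                    parents[c] |= 1 << p
                else:
                    continue
                mutated.add((p, c))
            cand = DirectedNetwork(parents=tuple(parents))
            if cand.n_edges == 0 or any(_shd(cand, d) < min_shd for d in dags):
                ok = False
                break
            dags.append(cand)
        if ok:
            return dags
    raise RuntimeError("could not draw distinct subgroup DAGs")


def _preset(
    seed: int,
    n: int,
    T: int,
    n_groups: int,
    subjects_per_group: int,
    expected_parents: float = 2.0,
    obs_sd: float = 1.0,
    process: CoefficientProcess = CoefficientProcess("random_walk", 0.02),
    n_mutations: int = 4,
    min_shd: int = 4,
    max_in_degree: int = 3,
) -> GeneratorSpec:
    dags = _subgroup_dags(
        n, n_groups, expected_parents, seed, n_mutations, min_shd, max_in_degree
    )
    subgroups = []
    for g, dag in enumerate(dags):
        coeff_seed = np.random.SeedSequence(entropy=seed, spawn_key=(902, g))
        subgroups.append(
            SubgroupSpec(
                n_subjects=subjects_per_group,
                dag=dag,
                coefficients=random_coefficients(dag, coeff_seed),
                obs_sd=(obs_sd,) * n,
                process=process,
                seed_key=g,
            )
        )
    return GeneratorSpec(n=n, T=T, subgroups=tuple(subgroups), seed=seed)


def full_scale_spec(seed: int, **kwargs) -> GeneratorSpec:
    """Full-scale design: 3 distinct 12-node DAGs, 10 subjects each, T=1158."""
    return _preset(seed, n=12, T=1158, n_groups=3, subjects_per_group=10, **kwargs)


def desk_scale_spec(seed: int, **kwargs) -> GeneratorSpec:
    """Scaled-down design for quick runs: 3 distinct 8-node DAGs, 6 subjects
    each, T=400."""
    return _preset(seed, n=8, T=400, n_groups=3, subjects_per_group=6, **kwargs)
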