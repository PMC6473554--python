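"""Plain-text I/O: subject series, manifests, score tables, networks,
separation matrices, assignments and YAML configs.

Subject series travel as delimited text (one column per region, header row
of region names, one file per subject) listed in a manifest mapping
subject ids to paths.  Score tables are columnar (subject, node,
parent-bitmask, score) so the expensive scoring step can be cached and
reused by every group method.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import Dendrogram, SeparationMatrix, SubgroupAssignment
from .mdm import PriorPolicy, SubjectSeries
from .search import DirectedNetwork, ScoreTable
from .simulate import TruthBundle

__all__ = [
    "read_subject_csv",
    "write_subject_csv",
    "read_manifest",
    "write_manifest",
    "read_score_tables",
    "write_score_tables",
    "write_network_csv",
    "read_network_csv",
    "write_adjacency_csv",
    "network_to_dot",
    "write_separation_csv",
    "read_separation_csv",
    "write_assignment_csv",
    "write_dendrogram_csv",
    "write_mds_csv",
    "write_truth_bundle",
    "load_config",
    "policy_from_config",
]


def read_subject_csv(path, subject_id: str | None = None) -> SubjectSeries:
    """Read one subject's T x n series (CSV or TSV, header = region names)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return SubjectSeries(
        subject_id=subject_id or path.stem,
        values=df.to_numpy(dtype=float),
        region_names=tuple(str(c) for c in df.columns),
    )


def write_subject_csv(path, series: SubjectSeries) -> None:
    pd.DataFrame(series.values, columns=list(series.region_names)).to_csv(
        path, index=False
    )


def read_manifest(path) -> list[SubjectSeries]:
    """Manifest CSV with columns subject_id, path (relative to the manifest)."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"subject_id", "path"} <= set(df.columns):
        raise ValueError("manifest needs columns subject_id and path")
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        out.append(read_subject_csv(p, str(row["subject_id"])))
    return out


def write_manifest(path, entries: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"subject_id": list(entries), "path": list(entries.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def write_score_tables(path, tables: Mapping[str, Sequence[ScoreTable]]) -> None:
    """Columnar cache: subject, node, parent_mask, score, n, max_parents."""
    rows = []
    for sid, tabs in tables.items():
        for tab in tabs:
            for mask in tab.masks():
                rows.append(
                    (sid, tab.node, mask, tab.scores[mask], tab.n, tab.max_parents)
                )
    pd.DataFrame(
        rows, columns=["subject_id", "node", "parent_mask", "score", "n", "max_parents"]
    ).to_csv(path, index=False)


def read_score_tables(path) -> dict[str, list[ScoreTable]]:
    df = pd.read_csv(path)
    out: dict[str, list[ScoreTable]] = {}
    for (sid, node), grp in df.groupby(["subject_id", "node"], sort=True):
        n = int(grp["n"].iloc[0])
        mp = int(grp["max_parents"].iloc[0])
        scores = {
            int(m): float(s) for m, s in zip(grp["parent_mask"], grp["score"])
        }
        out.setdefault(str(sid), []).append(
            ScoreTable(subject_id=str(sid), node=int(node), n=n, max_parents=mp,
                       scores=scores)
        )
    for sid in out:
        out[sid].sort(key=lambda t: t.node)
    return out


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def write_network_csv(
    path, network: DirectedNetwork, region_names: Sequence[str] | None = None
) -> None:
    """Directed edge list (parent, child, theta_bar, sigma2_bar)."""
    names = list(region_names) if region_names else [
        str(j) for j in range(network.n)
    ]
    rows = []
    for p, r in network.edges():
        tb, vb = (network.strengths or {}).get((p, r), (np.nan, np.nan))
        rows.append((names[p], names[r], p, r, tb, vb))
    pd.DataFrame(
        rows,
        columns=["parent", "child", "parent_index", "child_index",
                 "theta_bar", "sigma2_bar"],
    ).to_csv(path, index=False)


def read_network_csv(path, n: int) -> DirectedNetwork:
    df = pd.read_csv(path)
    parents = [0] * n
    strengths = {}
    for _, row in df.iterrows():
        p, r = int(row["parent_index"]), int(row["child_index"])
        parents[r] |= 1 << p
        if np.isfinite(row.get("theta_bar", np.nan)):
            strengths[(p, r)] = (float(row["theta_bar"]), float(row["sigma2_bar"]))
    return DirectedNetwork(
        parents=tuple(parents), strengths=strengths or None
    )


def write_adjacency_csv(
    path, network: DirectedNetwork, region_names: Sequence[str] | None = None
) -> None:
    names = list(region_names) if region_names else [
        str(j) for j in range(network.n)
    ]
    adj = np.zeros((network.n, network.n), dtype=int)
    for p, r in network.edges():
        adj[p, r] = 1
    pd.DataFrame(adj, index=names, columns=names).to_csv(path)


def network_to_dot(
    network: DirectedNetwork, region_names: Sequence[str] | None = None
) -> str:
    names = list(region_names) if region_names else [
        str(j) for j in range(network.n)
    ]
    lines = ["digraph network {"]
    for name in names:
        lines.append(f'  "{name}";')
    for p, r in network.edges():
        lines.append(f'  "{names[p]}" -> "{names[r]}";')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Clustering artefacts
# ---------------------------------------------------------------------------


def write_separation_csv(path, sep: SeparationMatrix) -> None:
    pd.DataFrame(
        sep.values, index=list(sep.subject_ids), columns=list(sep.subject_ids)
    ).to_csv(path)


def read_separation_csv(path, variant: str = "ipa") -> SeparationMatrix:
    df = pd.read_csv(path, index_col=0)
    return SeparationMatrix(
        values=df.to_numpy(dtype=float),
        subject_ids=tuple(str(c) for c in df.columns),
        variant=variant,
    )


def write_assignment_csv(
    path, assignment: SubgroupAssignment, subject_ids: Sequence[str]
) -> None:
    pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "subgroup": list(assignment.labels),
            "singleton": list(assignment.singleton),
        }
    ).to_csv(path, index=False)


def write_dendrogram_csv(path, dend: Dendrogram) -> None:
    """Portable merge table: child indices (< S are leaves), merge height,
    merged-cluster size."""
    pd.DataFrame(
        dend.merge_table, columns=["left", "right", "height", "size"]
    ).to_csv(path, index=False)


def write_mds_csv(path, coords: np.ndarray, subject_ids: Sequence[str]) -> None:
    df = pd.DataFrame(
        coords, columns=[f"dim{k + 1}" for k in range(coords.shape[1])]
    )
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Truth bundles and configs
# ---------------------------------------------------------------------------


def write_truth_bundle(outdir, bundle: TruthBundle) -> None:
    """Write subject CSVs + manifest + truth files (labels, true edges)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for series in bundle.subjects:
        fname = f"{series.subject_id}.csv"
        write_subject_csv(outdir / fname, series)
        entries[series.subject_id] = fname
    write_manifest(outdir / "manifest.csv", entries)
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in bundle.subjects],
            "subgroup": list(bundle.labels),
        }
    ).to_csv(outdir / "true_labels.csv", index=False)
    rows = []
    for g, (dag, coeffs) in enumerate(zip(bundle.dags, bundle.coefficients), start=1):
        for p, r in dag.edges():
            rows.append((g, p, r, coeffs[(p, r)]))
    pd.DataFrame(
        rows, columns=["subgroup", "parent_index", "child_index", "coefficient"]
    ).to_csv(outdir / "true_edges.csv", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def policy_from_config(cfg: Mapping) -> PriorPolicy:
    """Build a PriorPolicy from the config's ``prior`` section (all keys
    optional; defaults apply)."""
    prior = dict(cfg.get("prior", {}))
    kwargs = {}
    for key in ("c0_scale", "n0", "d0", "burn_in", "standardize"):
        if key in prior:
            kwargs[key] = prior[key]
    if "delta_grid" in prior:
        kwargs["delta_grid"] = tuple(float(d) for d in prior["delta_grid"])
    return PriorPolicy(**kwargs)
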