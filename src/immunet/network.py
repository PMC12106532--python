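"""Signed correlation networks over cell subsets and group contrasts.

Per group, subset frequencies are correlated pairwise across subjects;
two subsets are connected when their absolute correlation exceeds a
threshold (0.6, strict) and the correlation is statistically significant
(unadjusted two-sided p < 0.05 by default).  Edge weights keep the sign of
the correlation: negative edges are read as regulatory/inhibitory
interactions, and their disappearance in sepsis is one of the headline
contrasts, along with lower density and higher modularity.

Modularity uses Newman's Q on the sign-stripped, unweighted graph.  The
partition is the exact maximum-modularity partition (exhaustive search)
when at most 8 nodes carry edges, otherwise deterministic greedy
agglomeration (Clauset-Newman-Moore).  Density counts isolated nodes:
all retained subsets are network nodes whether or not connected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

SEPSIS, HEALTHY = "sepsis", "healthy"
_EXACT_MODULARITY_LIMIT = 8


def group_correlations(
    freq_table: pd.DataFrame,
    groups: pd.Series | None = None,
    group: str | None = None,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise subset-frequency correlations (+ two-sided p) for one group.

    Zero-variance subsets get NaN correlations (emitted as absent edges)
    with a warning.  Requires at least 4 subjects.
    """
    if groups is not None and group is not None:
        freq = freq_table[(groups.reindex(freq_table.index) == group).to_numpy()]
    else:
        freq = freq_table
    n = len(freq)
    if n < 4:
        raise ValueError(f"need >=4 subjects for correlations, got {n}")
    x = freq.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sd = x.std(axis=0, ddof=1)
    flat = sd <= 1e-12
    if flat.any():
        warnings.warn(
            f"zero-variance subsets {list(freq.columns[flat])}: correlations "
            "undefined, emitted as absent edges"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, 1.0)
    # two-sided p from the t transform of r
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(corr, -0.9999999999, 0.9999999999)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    cols = freq.columns
    return (
        pd.DataFrame(corr, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


@dataclass
class ImmuneNetwork:
    """Signed, weighted graph over all retained subsets for one group."""

    group: str
    graph: nx.Graph
    threshold: float
    alpha_edge: float

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"node_i": u, "node_j": v, "r": d["weight"], "p": d["p"],
             "sign": "+" if d["weight"] > 0 else "-"}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "r", "p", "sign"])


def build_network(
    corr: pd.DataFrame,
    p: pd.DataFrame,
    threshold: float = 0.6,
    alpha_edge: float = 0.05,
    group: str = "unknown",
) -> ImmuneNetwork:
    """Edge iff |r| > threshold (strict) and p < alpha_edge; sign kept."""
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if corr.shape != p.shape or list(corr.index) != list(p.index):
        raise ValueError("correlation and p matrices must match")
    g = nx.Graph()
    nodes = list(corr.index)
    g.add_nodes_from(nodes)
    arr_r, arr_p = corr.to_numpy(), p.to_numpy()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r, pv = arr_r[i, j], arr_p[i, j]
            if np.isnan(r):
                continue
            if abs(r) > threshold and pv < alpha_edge:
                g.add_edge(nodes[i], nodes[j], weight=float(r), p=float(pv))
    return ImmuneNetwork(group=group, graph=g, threshold=threshold, alpha_edge=alpha_edge)


def _modularity_value(adj: dict, degrees: dict, m2: float, partition) -> float:
    """Newman Q for a given partition; m2 = 2E."""
    q = 0.0
    for block in partition:
        block = set(block)
        lc = sum(1 for u in block for v in adj[u] if v in block) / 2
        dc = sum(degrees[u] for u in block)
        q += lc / (m2 / 2) - (dc / m2) ** 2
    return q


def _exact_partition(nodes, adj, degrees, m2):
    """Exhaustive maximum-modularity partition (restricted-growth
    enumeration); feasible up to ~10 nodes."""
    best_q, best = -1.0, [set(nodes)]
    blocks: list[set] = []

    def recurse(i):
        nonlocal best_q, best
        if i == len(nodes):
            q = _modularity_value(adj, degrees, m2, blocks)
            if q > best_q + 1e-12:
                best_q, best = q, [set(b) for b in blocks]
            return
        node = nodes[i]
        for b in blocks:
            b.add(node)
            recurse(i + 1)
            b.remove(node)
        blocks.append({node})
        recurse(i + 1)
        blocks.pop()

    recurse(0)
    return best, best_q


def max_modularity(graph: nx.Graph, exact_limit: int = _EXACT_MODULARITY_LIMIT):
    """(partition, Q) maximising Newman modularity of the sign-stripped,
    unweighted graph.  Exact for small graphs, CNM greedy otherwise;
    isolated nodes are singleton communities (zero contribution)."""
    active = [n for n in graph.nodes if graph.degree(n) > 0]
    isolates = [n for n in graph.nodes if graph.degree(n) == 0]
    if not active:
        return [{n} for n in graph.nodes], 0.0
    sub = nx.Graph()
    sub.add_nodes_from(active)
    sub.add_edges_from((u, v) for u, v in graph.edges)
    if len(active) <= exact_limit:
        adj = {n: set(sub[n]) for n in active}
        degrees = dict(sub.degree())
        partition, q = _exact_partition(active, adj, degrees, 2 * sub.number_of_edges())
    else:
        partition = [
            set(c) for c in nx.community.greedy_modularity_communities(sub)
        ]
        q = nx.community.modularity(sub, partition)
    partition = list(partition) + [{n} for n in isolates]
    return partition, float(q)


@dataclass
class NetworkSummary:
    group: str
    n: int
    e: int
    density: float
    negative_edges: int
    negative_fraction: float
    negative_fraction_defined: bool
    modularity: float
    communities: list[set] = field(repr=False, default_factory=list)
    isolated: int = 0

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "E": self.e,
            "density": self.density,
            "negative_edges": self.negative_edges,
            "negative_fraction": self.negative_fraction,
            "modularity": self.modularity,
            "n_communities": len(self.communities),
            "isolated": self.isolated,
        }


def summarize(network: ImmuneNetwork) -> NetworkSummary:
    """Density (isolates included in n), negative-edge count/fraction,
    maximum-modularity Q, community partition, isolated-node count."""
    g = network.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for networks with < 2 nodes")
    e = g.number_of_edges()
    density = 2 * e / (n * (n - 1))
    negatives = sum(1 for _, _, d in g.edges(data=True) if d["weight"] < 0)
    if e == 0:
        neg_frac, defined = 0.0, False
    else:
        neg_frac, defined = negatives / e, True
    partition, q = max_modularity(g)
    isolated = sum(1 for node in g.nodes if g.degree(node) == 0)
    return NetworkSummary(
        group=network.group,
        n=n,
        e=e,
        density=density,
        negative_edges=negatives,
        negative_fraction=neg_frac,
        negative_fraction_defined=defined,
        modularity=q,
        communities=partition,
        isolated=isolated,
    )


def same_lineage_edge_fraction(network: ImmuneNetwork, lineages: dict) -> float:
    """Fraction of edges whose endpoints share a lineage — the computable
    form of 'restricted communication within a lineage module'.  NaN when
    the network has no edges."""
    e = network.graph.number_of_edges()
    if e == 0:
        return float("nan")
    same = sum(
        1 for u, v in network.graph.edges if lineages.get(u) == lineages.get(v)
    )
    return same / e


def compare_networks(
    healthy: ImmuneNetwork, sepsis: ImmuneNetwork, lineages: dict | None = None
) -> dict:
    """Contrast report: density / modularity / negative-edge deltas and
    (when a lineage map is given) same-lineage edge fractions."""
    if set(healthy.graph.nodes) != set(sepsis.graph.nodes):
        raise ValueError("networks must share the same node set")
    sh, ss = summarize(healthy), summarize(sepsis)
    report = {
        "healthy": sh.to_dict(),
        "sepsis": ss.to_dict(),
        "delta_density": ss.density - sh.density,
        "delta_modularity": ss.modularity - sh.modularity,
        "delta_negative_edges": ss.negative_edges - sh.negative_edges,
        "delta_negative_fraction": ss.negative_fraction - sh.negative_fraction,
    }
    if lineages is not None:
        report["same_lineage_fraction_healthy"] = same_lineage_edge_fraction(
            healthy, lineages
        )
        report["same_lineage_fraction_sepsis"] = same_lineage_edge_fraction(
            sepsis, lineages
        )
    return report


def layout(network: ImmuneNetwork, seed: int = 0) -> dict:
    """Seeded Fruchterman-Reingold coordinates; isolated nodes on a ring."""
    g = network.graph
    isolates = [n for n in g.nodes if g.degree(n) == 0]
    connected = [n for n in g.nodes if g.degree(n) > 0]
    pos = {}
    if connected:
        sub = g.subgraph(connected)
        pos.update(nx.spring_layout(sub, seed=seed, weight=None))
    radius = 1.4
    for k, node in enumerate(isolates):
        angle = 2 * np.pi * k / max(len(isolates), 1)
        pos[node] = np.array([radius * np.cos(angle), radius * np.sin(angle)])
    return pos


@dataclass
class NetworkResults:
    """Fitted per-group networks with summaries and the contrast report."""

    networks: dict[str, ImmuneNetwork]
    summaries: dict[str, NetworkSummary]
    contrast: dict | None = None

    def summary(self) -> str:
        lines = ["Correlation networks (|r| > threshold, p < alpha)"]
        for group, s in self.summaries.items():
            lines.append(
                f"  {group}: n={s.n} E={s.e} density={s.density:.3f} "
                f"negative={s.negative_edges} ({s.negative_fraction:.1%}) "
                f"Q={s.modularity:.3f} isolated={s.isolated}"
            )
        if self.contrast is not None:
            lines.append(
                f"  contrast: ddensity={self.contrast['delta_density']:+.3f} "
                f"dQ={self.contrast['delta_modularity']:+.3f} "
                f"dneg={self.contrast['delta_negative_edges']:+d}"
            )
        return "\n".join(lines)


class CorrelationNetwork:
    """Model: frequency table + groups -> per-group signed networks."""

    def __init__(
        self,
        freq_table: pd.DataFrame,
        groups: pd.Series,
        threshold: float = 0.6,
        alpha_edge: float = 0.05,
        method: str = "pearson",
    ):
        self.freq = freq_table
        self.groups = groups
        self.threshold = threshold
        self.alpha_edge = alpha_edge
        self.method = method

    def fit(self, which=(HEALTHY, SEPSIS), lineages: dict | None = None) -> NetworkResults:
        networks, summaries = {}, {}
        for group in which:
            corr, p = group_correlations(
                self.freq, self.groups, group, method=self.method
            )
            net = build_network(
                corr, p, self.threshold, self.alpha_edge, group=group
            )
            networks[group] = net
            summaries[group] = summarize(net)
        contrast = None
        if HEALTHY in networks and SEPSIS in networks:
            contrast = compare_networks(
                networks[HEALTHY], networks[SEPSIS], lineages=lineages
            )
        return NetworkResults(networks=networks, summaries=summaries, contrast=contrast)


def export_network(network: ImmuneNetwork, summary: NetworkSummary, outdir, stem: str):
    """Write edge list TSV, summary JSON, and GraphML."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network.edges.to_csv(outdir / f"{stem}_edges.tsv", sep="\t", index=False)
    with open(outdir / f"{stem}_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1)
    nx.write_graphml(network.graph, outdir / f"{stem}.graphml")
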