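"""The physical miRNA-protein interaction network and its topology analyses.

The network is a directed graph with two edge types: ``miRNA_target`` edges
run miRNA -> protein (repression evidenced by CLIP binding) and
``promoter_binding`` edges run protein -> miRNA (transcription-factor
occupancy of the miRNA promoter).  Only direct, first-neighbor physical
interactions enter the graph.  Node attributes carry the molecular kind
(mirna/protein) and the cross-dataset activation state (up/down/ns).

Analyses: activated-subnetwork extraction, first neighbors, directed
shortest paths (any miRNA-to-miRNA influence necessarily alternates through
proteins), miRNA-binding degree ranking with top-1 % hub calling, and
densely-connected module decomposition by greedy modularity maximization on
the undirected projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice
from typing import Callable, Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd

from .target_calling import PromoterBinding, TargetCall

__all__ = [
    "build_network",
    "induced_subnetwork",
    "activated_predicate",
    "first_neighbors",
    "shortest_paths",
    "PathResult",
    "degree_rank",
    "decompose_modules",
]

InteractionNetwork = nx.DiGraph


@dataclass(frozen=True)
class PathResult:
    """All minimal-length directed paths between one source/target pair.

    ``length`` is the minimal edge count, or ``math.inf`` when the target is
    unreachable (then ``paths`` is empty).
    """

    source: str
    target: str
    length: float
    paths: tuple[tuple[str, ...], ...]

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.length)

    @property
    def direct(self) -> bool:
        return self.length == 1


def _merge_edge(net: nx.DiGraph, u: str, v: str, edge_type: str,
                evidence: str) -> None:
    if net.has_edge(u, v):
        attrs = net.edges[u, v]
        if attrs["edge_type"] != edge_type:
            raise ValueError(
                f"conflicting edge types for {u}->{v}: "
                f"{attrs['edge_type']} vs {edge_type}"
            )
        if evidence not in attrs["evidence"]:
            attrs["evidence"].append(evidence)
    else:
        net.add_edge(u, v, edge_type=edge_type, evidence=[evidence])


def build_network(
    target_edges: Iterable[TargetCall],
    binding_edges: Iterable[PromoterBinding] = (),
    states: Mapping[str, str] | pd.DataFrame | None = None,
) -> InteractionNetwork:
    """Assemble the interaction network from binding evidence.

    Duplicate calls for one (miRNA, gene) pair merge into a single
    ``miRNA_target`` edge whose evidence list records the distinct
    supporting cluster/site descriptors; likewise peaks for
    ``promoter_binding`` edges.  ``states`` maps entity -> up/down/ns
    (a DataFrame with a ``state`` column is also accepted); entities
    without a state get ns.
    """
    if isinstance(states, pd.DataFrame):
        states = states["state"].to_dict()
    states = dict(states or {})

    net = nx.DiGraph()
    for call in target_edges:
        if call.mirna_id == call.gene_id:
            raise ValueError(
                f"self-loop target call rejected: {call.mirna_id}"
            )
        net.add_node(call.mirna_id, kind="mirna")
        net.add_node(call.gene_id, kind="protein")
        evidence = f"{call.cluster_name}:k{call.seed_len}@{call.site_start}"
        _merge_edge(net, call.mirna_id, call.gene_id, "miRNA_target", evidence)
    for binding in binding_edges:
        if binding.protein_id == binding.mirna_id:
            raise ValueError(
                f"self-loop promoter binding rejected: {binding.protein_id}"
            )
        net.add_node(binding.protein_id, kind="protein")
        net.add_node(binding.mirna_id, kind="mirna")
        _merge_edge(
            net, binding.protein_id, binding.mirna_id, "promoter_binding",
            binding.peak_name,
        )
    for node in net.nodes:
        net.nodes[node]["state"] = states.get(node, "ns")
    return net


def induced_subnetwork(
    net: InteractionNetwork,
    keep: Callable[[str, Mapping], bool],
) -> InteractionNetwork:
    """Subnetwork induced by nodes satisfying ``keep(node, attrs)``.

    An edge survives iff both endpoints are kept.  Returns an independent
    copy; the input is never mutated.
    """
    nodes = [n for n in net.nodes if keep(n, net.nodes[n])]
    sub = net.subgraph(nodes).copy()
    # deep-copy evidence lists so the subnetwork is fully independent
    for u, v in sub.edges:
        sub.edges[u, v]["evidence"] = list(sub.edges[u, v]["evidence"])
    return sub


def activated_predicate(node: str, attrs: Mapping) -> bool:
    """Node filter for the subnetwork activated by overexpressed miRNAs:
    up-regulated miRNAs together with the down-regulated proteins they
    repress."""
    if attrs.get("kind") == "mirna":
        return attrs.get("state") == "up"
    return attrs.get("state") == "down"


def first_neighbors(
    net: InteractionNetwork,
    seeds: Iterable[str],
    direction: Literal["out", "in", "both"] = "out",
) -> set[str]:
    """Nodes exactly one directed edge away from any seed (seeds excluded)."""
    seeds = set(seeds)
    missing = seeds - set(net.nodes)
    if missing:
        raise KeyError(f"unknown seed node(s): {sorted(missing)}")
    neighbors: set[str] = set()
    for seed in seeds:
        if direction in ("out", "both"):
            neighbors.update(net.successors(seed))
        if direction in ("in", "both"):
            neighbors.update(net.predecessors(seed))
    return neighbors - seeds


def shortest_paths(
    net: InteractionNetwork,
    source: str,
    target: str,
    max_len: int = 10,
    max_paths: int = 1000,
) -> PathResult:
    """All minimal-length directed paths from source to target (BFS).

    Paths longer than ``max_len`` edges count as unreachable; at most
    ``max_paths`` distinct minimal paths are enumerated.
    """
    for node in (source, target):
        if node not in net:
            raise KeyError(f"unknown node {node!r}")
    try:
        length = nx.shortest_path_length(net, source, target)
    except nx.NetworkXNoPath:
        return PathResult(source, target, math.inf, ())
    if length > max_len:
        return PathResult(source, target, math.inf, ())
    paths = tuple(
        tuple(p)
        for p in islice(nx.all_shortest_paths(net, source, target), max_paths)
    )
    return PathResult(source, target, float(length), paths)


def degree_rank(
    net: InteractionNetwork,
    restrict_to_state: str | None = "up",
) -> pd.DataFrame:
    """Rank protein nodes by miRNA binding number.

    For each protein, ``mirna_in_degree`` counts distinct incoming
    ``miRNA_target`` edges from miRNAs whose state matches
    ``restrict_to_state`` (``None`` accepts any state).  Proteins get a
    dense descending rank (ties share a rank), a percentile
    100 * rank / n proteins, and a ``top1pct`` flag (percentile <= 1).
    """
    proteins = sorted(
        n for n in net.nodes if net.nodes[n].get("kind") == "protein"
    )
    degrees = {}
    for protein in proteins:
        count = 0
        for pred in net.predecessors(protein):
            edge = net.edges[pred, protein]
            if edge["edge_type"] != "miRNA_target":
                continue
            if net.nodes[pred].get("kind") != "mirna":
                continue
            if (
                restrict_to_state is not None
                and net.nodes[pred].get("state") != restrict_to_state
            ):
                continue
            count += 1
        degrees[protein] = count
    df = pd.DataFrame(
        {"mirna_in_degree": pd.Series(degrees, dtype=int)}
    ).rename_axis("protein")
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        df["percentile"] = pd.Series(dtype=float)
        df["top1pct"] = pd.Series(dtype=bool)
        return df
    df["rank"] = (
        df["mirna_in_degree"].rank(method="dense", ascending=False).astype(int)
    )
    df["percentile"] = 100.0 * df["rank"] / len(df)
    df["top1pct"] = df["percentile"] <= 1.0
    return df.sort_values(["rank", "protein"]).reset_index().set_index("protein")


def decompose_modules(
    net: InteractionNetwork,
    min_size: int = 2,
) -> list[set[str]]:
    """Densely connected modules of the undirected projection.

    Communities are found by greedy modularity maximization; modules smaller
    than ``min_size`` are discarded.  Node insertion order is normalized
    (sorted) so the decomposition is deterministic.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if net.number_of_nodes() == 0:
        return []
    undirected = nx.Graph()
    undirected.add_nodes_from(sorted(net.nodes))
    undirected.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in net.edges))
    if undirected.number_of_edges() == 0:
        return []
    communities = nx.community.greedy_modularity_communities(undirected)
    modules = [set(c) for c in communities if len(c) >= min_size]
    modules.sort(key=lambda m: (-len(m), min(m)))
    return modules
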