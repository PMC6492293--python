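"""Discourse-coalition detection and coalition-level statistics.

Coalitions are cohesive subgroups detected with Girvan-Newman edge-betweenness
clustering on the *unweighted* thresholded graph (after thresholding, ties are
present/absent; tie counts in the embeddedness table are integers).  The
dendrogram cut is chosen by modularity maximization, and the full removal
history is retained so alternative cuts can be inspected.

The *external ratio* of an actor is the fraction of its ties that leave its
assigned coalition: 0 means fully embedded, high values mark brokers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from discoursenet.errors import CoverageError, UndefinedRatioError
from discoursenet.network_builder import ActorNetwork

Edge = tuple[str, str]


def _as_graph(network: ActorNetwork | nx.Graph) -> nx.Graph:
    return network.graph if isinstance(network, ActorNetwork) else network


def _sorted_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class DendrogramStep:
    """One edge removal: the edge taken out and the component count after."""

    removed_edge: Edge
    n_components: int
    split: tuple[frozenset[str], frozenset[str]] | None  # set when the removal disconnects


@dataclass
class Partition:
    """Actor -> coalition assignment selected from the dendrogram, plus the
    removal history and the modularity of the selected level."""

    assignment: dict[str, int]
    dendrogram: tuple[DendrogramStep, ...]
    modularity: float
    levels: tuple[tuple[float, tuple[frozenset[str], ...]], ...] = field(default_factory=tuple)

    @property
    def coalitions(self) -> dict[int, tuple[str, ...]]:
        out: dict[int, list[str]] = {}
        for actor, cid in self.assignment.items():
            out.setdefault(cid, []).append(actor)
        return {cid: tuple(sorted(members)) for cid, members in sorted(out.items())}

    @property
    def n_coalitions(self) -> int:
        return len(set(self.assignment.values()))


def edge_betweenness(network: ActorNetwork | nx.Graph) -> dict[Edge, float]:
    """Shortest-path edge betweenness on the unweighted graph.

    Each unordered node pair contributes 1, split equally across its tied
    shortest paths.  Returns an empty map for an edgeless graph.
    """
    G = _as_graph(network)
    if G.number_of_edges() == 0:
        return {}
    raw = nx.edge_betweenness_centrality(G, normalized=False, weight=None)
    return {_sorted_edge(u, v): val for (u, v), val in raw.items()}


def modularity(network: ActorNetwork | nx.Graph, assignment: dict[str, int]) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2) on the unweighted graph,
    where e_ii is the fraction of edges inside coalition i and a_i the
    fraction of edge endpoints in i.  Q = 0 for an edgeless graph."""
    G = _as_graph(network)
    missing = set(G.nodes) - set(assignment)
    if missing:
        raise CoverageError(f"assignment misses nodes: {sorted(missing)[:5]}")
    m = G.number_of_edges()
    if m == 0:
        return 0.0
    communities = sorted(set(assignment[n] for n in G.nodes))
    q = 0.0
    for cid in communities:
        members = {n for n in G.nodes if assignment[n] == cid}
        e_ii = sum(1 for u, v in G.edges if u in members and v in members) / m
        a_i = sum(G.degree(n) for n in members) / (2 * m)
        q += e_ii - a_i * a_i
    return q


def _components(G: nx.Graph) -> tuple[frozenset[str], ...]:
    comps = [frozenset(c) for c in nx.connected_components(G)]
    return tuple(sorted(comps, key=lambda c: min(c)))


def _assignment_from(comps: tuple[frozenset[str], ...]) -> dict[str, int]:
    assignment: dict[str, int] = {}
    for cid, comp in enumerate(comps):
        for node in comp:
            assignment[node] = cid
    return assignment


def girvan_newman(network: ActorNetwork | nx.Graph) -> Partition:
    """Full Girvan-Newman dendrogram with a modularity-maximizing cut.

    Repeatedly removes a single maximum-betweenness edge (recomputing
    betweenness after every removal); ties are broken by removing the
    lexicographically smallest (actor_a, actor_b) pair, so the result is
    deterministic.  Every component structure encountered — including the
    initial one — is scored with :func:`modularity` on the original graph and
    the best-scoring level is selected (first reached wins ties).
    Components are never merged, so initial disconnection is only refined.
    """
    G0 = _as_graph(network)
    if G0.number_of_nodes() < 2:
        raise CoverageError("need at least 2 nodes to cluster")
    work = nx.Graph()
    work.add_nodes_from(G0.nodes)
    work.add_edges_from(G0.edges)

    comps = _components(work)
    levels = [(modularity(G0, _assignment_from(comps)), comps)]
    steps: list[DendrogramStep] = []

    while work.number_of_edges() > 0:
        eb = edge_betweenness(work)
        best_val = max(eb.values())
        candidates = [e for e, v in eb.items() if v >= best_val - 1e-9]
        edge = min(candidates)
        prev = set(comps)
        work.remove_edge(*edge)
        comps = _components(work)
        if len(comps) > len(prev):
            new = tuple(sorted((c for c in comps if c not in prev), key=min))
            split = (new[0], new[1]) if len(new) == 2 else None
            steps.append(DendrogramStep(edge, len(comps), split))
            levels.append((modularity(G0, _assignment_from(comps)), comps))
        else:
            steps.append(DendrogramStep(edge, len(comps), None))

    best_q, best_comps = max(enumerate(levels), key=lambda iv: (iv[1][0], -iv[0]))[1]
    return Partition(
        assignment=_assignment_from(best_comps),
        dendrogram=tuple(steps),
        modularity=best_q,
        levels=tuple(levels),
    )


@dataclass(frozen=True)
class ExternalRatioRow:
    """Tie counts and embeddedness for one actor: external_ratio =
    (total_ties - within_ties) / total_ties."""

    actor: str
    total_ties: int
    within_ties: int

    @property
    def external_ratio(self) -> float:
        return (self.total_ties - self.within_ties) / self.total_ties

    @property
    def external_ratio_display(self) -> float:
        """Rounded to 2 decimals, the precision used in reported tables."""
        return round(self.external_ratio, 2)


def external_ratio(
    network: ActorNetwork | nx.Graph, assignment: dict[str, int], actor: str
) -> ExternalRatioRow:
    """Embeddedness of one actor: unweighted degree, ties inside its assigned
    coalition, and the resulting external ratio.  Raises
    :class:`UndefinedRatioError` for isolates (degree 0)."""
    G = _as_graph(network)
    if actor not in G:
        raise CoverageError(f"actor {actor!r} not in network")
    if actor not in assignment:
        raise CoverageError(f"actor {actor!r} not in assignment")
    neighbors = list(G.neighbors(actor))
    total = len(neighbors)
    if total == 0:
        raise UndefinedRatioError(f"actor {actor!r} has no ties")
    within = sum(1 for n in neighbors if assignment.get(n) == assignment[actor])
    return ExternalRatioRow(actor, total, within)


def external_ratio_table(
    network: ActorNetwork | nx.Graph,
    assignment: dict[str, int],
    actors: list[str] | None = None,
) -> list[ExternalRatioRow]:
    """External-ratio rows for the requested actors (default: every
    non-isolated node), sorted by actor key."""
    G = _as_graph(network)
    if actors is None:
        actors = [n for n in sorted(G.nodes) if G.degree(n) > 0]
    return [external_ratio(G, assignment, a) for a in sorted(actors)]


def write_partition_csv(partition: Partition, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor", "coalition_id"])
        for actor in sorted(partition.assignment):
            writer.writerow([actor, partition.assignment[actor]])


def write_external_ratio_csv(rows: list[ExternalRatioRow], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor", "total_ties", "within_ties", "external_ratio"])
        for row in rows:
            writer.writerow(
                [row.actor, row.total_ties, row.within_ties, f"{row.external_ratio_display:.2f}"]
            )


def annotate_with_coalitions(network: ActorNetwork, partition: Partition) -> ActorNetwork:
    """Attach ``coalition`` node attributes for downstream export."""
    for actor, cid in partition.assignment.items():
        if actor in network.graph:
            network.graph.nodes[actor]["coalition"] = int(cid)
    return network
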