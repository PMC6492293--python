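"""Project the stance matrix into weighted actor-actor networks.

For every unordered actor pair we count the concepts they jointly support
(``co_support``), jointly reject (``co_reject``), and take opposing net
stances on (``diverge``).  Tie weights are then:

* ``congruence``: co_support + co_reject
* ``conflict``:   diverge
* ``subtract``:   co_support + co_reject - diverge

optionally divided by the pair's average activity (mean statement count), so
that argumentative similarity rather than talkativeness drives the weight.
A threshold (default 0.4, inclusive) is applied after normalization; edges
below it are dropped entirely while isolated nodes are retained.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np

from discoursenet.errors import DegenerateActorError, SelfPairError, TooFewActorsError
from discoursenet.stance import StanceMatrix

Method = Literal["congruence", "conflict", "subtract"]
Normalization = Literal["none", "average_activity"]
ActivityMode = Literal["statements", "concepts"]


@dataclass(frozen=True)
class TieWeightConfig:
    """How pairwise stance components become an edge weight.

    ``threshold`` (when not ``None``) is applied only after normalization and
    keeps edges with weight >= threshold.  ``activity_mode`` selects what
    "activity" means under average-activity normalization: raw ``statements``
    (default, the literal reading) or distinct ``concepts`` addressed.
    """

    method: Method = "subtract"
    normalization: Normalization = "average_activity"
    threshold: float | None = 0.4
    activity_mode: ActivityMode = "statements"

    def __post_init__(self) -> None:
        if self.method not in ("congruence", "conflict", "subtract"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.normalization not in ("none", "average_activity"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class ActorNetwork:
    """Weighted undirected actor graph with tie-weight provenance.

    Nodes carry ``actor_type`` and ``statement_frequency``; edges carry
    ``weight`` plus the raw ``co_support``/``co_reject``/``diverge`` counts.
    """

    graph: nx.Graph
    config: TieWeightConfig
    window: tuple[dt.date, dt.date] | None = None

    @property
    def actors(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def weight(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["weight"]
        return None


def pair_concept_components(sm: StanceMatrix, a: str, b: str) -> tuple[int, int, int]:
    """(co_support, co_reject, diverge) for one actor pair under net-stance
    reduction; contested/absent cells contribute nothing."""
    if a == b:
        raise SelfPairError(f"cannot pair actor {a!r} with itself")
    ia, ib = sm.index_of(a), sm.index_of(b)
    net = sm.net
    sa, sb = net[ia], net[ib]
    co_support = int(np.sum((sa == 1) & (sb == 1)))
    co_reject = int(np.sum((sa == -1) & (sb == -1)))
    diverge = int(np.sum(((sa == 1) & (sb == -1)) | ((sa == -1) & (sb == 1))))
    return co_support, co_reject, diverge


def tie_weight(
    components: tuple[int, int, int],
    activity_a: int,
    activity_b: int,
    config: TieWeightConfig,
) -> float:
    """Weight for one pair from its stance components and activities."""
    co_support, co_reject, diverge = components
    if config.method == "congruence":
        raw = co_support + co_reject
    elif config.method == "conflict":
        raw = diverge
    else:
        raw = co_support + co_reject - diverge
    if config.normalization == "none":
        return float(raw)
    if activity_a < 1 or activity_b < 1:
        raise DegenerateActorError("average-activity normalization needs activity >= 1")
    return raw / ((activity_a + activity_b) / 2.0)


def _component_matrices(sm: StanceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    net = sm.net
    P = (net == 1).astype(np.int64)
    N = (net == -1).astype(np.int64)
    co_support = P @ P.T
    co_reject = N @ N.T
    diverge = P @ N.T + N @ P.T
    return co_support, co_reject, diverge


def build_network(
    sm: StanceMatrix,
    config: TieWeightConfig | None = None,
    window: tuple[dt.date, dt.date] | None = None,
) -> ActorNetwork:
    """Build the weighted actor network for a stance matrix.

    One edge per unordered pair whose pre-threshold weight is nonzero;
    thresholding then retains edges with weight >= threshold.  Every actor
    stays in the node set even if isolated.
    """
    config = config or TieWeightConfig()
    if len(sm.actors) < 2:
        raise TooFewActorsError("need at least 2 actors to build a network")
    CS, CR, DV = _component_matrices(sm)
    if config.method == "congruence":
        raw = CS + CR
    elif config.method == "conflict":
        raw = DV
    else:
        raw = CS + CR - DV
    activity = sm.activity
    if config.normalization == "average_activity":
        norm_act = activity if config.activity_mode == "statements" else sm.concepts_addressed
        if (norm_act < 1).any():
            raise DegenerateActorError("actor with zero activity under normalization")
        avg = (norm_act[:, None] + norm_act[None, :]) / 2.0
        weights = raw / avg
    else:
        weights = raw.astype(float)

    G = nx.Graph()
    for i, actor in enumerate(sm.actors):
        G.add_node(
            actor,
            actor_type=sm.actor_types.get(actor, ""),
            statement_frequency=int(activity[i]),
        )
    n = len(sm.actors)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(weights[i, j])
            if w == 0.0:
                continue  # sparse over non-interacting pairs
            if config.threshold is not None and w < config.threshold:
                continue
            G.add_edge(
                sm.actors[i],
                sm.actors[j],
                weight=w,
                co_support=int(CS[i, j]),
                co_reject=int(CR[i, j]),
                diverge=int(DV[i, j]),
            )
    return ActorNetwork(G, config, window)


def congruence_conflict_decomposition(
    sm: StanceMatrix,
) -> tuple[ActorNetwork, ActorNetwork]:
    """Unnormalized, unthresholded congruence and conflict networks; for
    every pair, subtract raw weight = congruence raw - conflict raw."""
    cfg = dict(normalization="none", threshold=None)
    return (
        build_network(sm, TieWeightConfig(method="congruence", **cfg)),
        build_network(sm, TieWeightConfig(method="conflict", **cfg)),
    )


def write_graphml(network: ActorNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))


def write_gexf(network: ActorNetwork, path: str | Path) -> None:
    nx.write_gexf(network.graph, str(path))


def write_edgelist_csv(network: ActorNetwork, path: str | Path) -> None:
    """Edge list with tie-weight provenance, sorted for diffable output."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor_a", "actor_b", "weight", "co_support", "co_reject", "diverge"])
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            d = network.graph.edges[a, b]
            writer.writerow(
                [a, b, repr(d["weight"]), d["co_support"], d["co_reject"], d["diverge"]]
            )
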