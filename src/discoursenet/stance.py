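"""Aggregate statements into a per-actor, per-concept stance matrix.

This is the two-mode (actor x concept) structure underlying every network:
for each actor and concept we count agreeing and disagreeing statements, and
reduce them to a *net stance* (+1 support, -1 reject, 0 contested, absent).
Contested and absent cells contribute neither congruence nor conflict.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from discoursenet.errors import EmptyCorpusError
from discoursenet.statement_store import AGREE, ActorLevel, Corpus


def net_stance(n_agree: int, n_disagree: int) -> int | None:
    """Sign of (agree - disagree); ``None`` when the actor never addressed
    the concept, 0 when counts tie (contested)."""
    if n_agree < 0 or n_disagree < 0:
        raise ValueError("counts must be non-negative")
    if n_agree == 0 and n_disagree == 0:
        return None
    return int(np.sign(n_agree - n_disagree))


@dataclass
class StanceMatrix:
    """Per actor x concept agreement/disagreement counts.

    ``actors`` and ``concepts`` are lexicographically ordered so that builds
    are deterministic; ``actor_types`` carries the modal actor-type label per
    actor for node annotation.
    """

    actors: tuple[str, ...]
    concepts: tuple[str, ...]
    n_agree: np.ndarray
    n_disagree: np.ndarray
    level: ActorLevel
    actor_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        na, nd = np.asarray(self.n_agree), np.asarray(self.n_disagree)
        if na.shape != (len(self.actors), len(self.concepts)) or na.shape != nd.shape:
            raise ValueError("count matrices inconsistent with actor/concept inventories")
        if (na < 0).any() or (nd < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def activity(self) -> np.ndarray:
        """Per-actor total statement count (raw statements, not distinct
        concepts)."""
        return (self.n_agree + self.n_disagree).sum(axis=1)

    @property
    def concepts_addressed(self) -> np.ndarray:
        """Per-actor number of distinct concepts addressed (alternative
        activity measure)."""
        return ((self.n_agree + self.n_disagree) > 0).sum(axis=1)

    @property
    def net(self) -> np.ndarray:
        """Net stance per cell: sign(agree - disagree); 0 for both contested
        and absent cells — disambiguate with :attr:`addressed`."""
        return np.sign(self.n_agree - self.n_disagree).astype(np.int8)

    @property
    def addressed(self) -> np.ndarray:
        return (self.n_agree + self.n_disagree) > 0

    def index_of(self, actor: str) -> int:
        return self.actors.index(actor)

    def stance_of(self, actor: str, concept: str) -> int | None:
        i, j = self.actors.index(actor), self.concepts.index(concept)
        return net_stance(int(self.n_agree[i, j]), int(self.n_disagree[i, j]))


def build_stance_matrix(corpus: Corpus, level: ActorLevel = "organization") -> StanceMatrix:
    """Tally the corpus into a stance matrix at the chosen actor level.

    Counts equal brute-force tallies over statements; actor and concept
    orderings are lexicographic.  Raises :class:`EmptyCorpusError` on an
    empty corpus.
    """
    if len(corpus) == 0:
        raise EmptyCorpusError("cannot build a stance matrix from an empty corpus")
    actors = corpus.actors(level)
    concepts = corpus.concepts
    a_idx = {a: i for i, a in enumerate(actors)}
    c_idx = {c: j for j, c in enumerate(concepts)}
    n_agree = np.zeros((len(actors), len(concepts)), dtype=np.int64)
    n_disagree = np.zeros_like(n_agree)
    type_votes: dict[str, Counter[str]] = {a: Counter() for a in actors}
    for s in corpus.statements:
        i, j = a_idx[s.actor(level)], c_idx[s.concept]
        if s.stance == AGREE:
            n_agree[i, j] += 1
        else:
            n_disagree[i, j] += 1
        type_votes[s.actor(level)][s.actor_type] += 1
    actor_types = {
        a: min(votes.most_common(), key=lambda kv: (-kv[1], kv[0]))[0]
        for a, votes in type_votes.items()
    }
    return StanceMatrix(actors, concepts, n_agree, n_disagree, level, actor_types)


def write_stance_csv(sm: StanceMatrix, path: str | Path) -> None:
    """Long-format export: actor,concept,n_agree,n_disagree,net_stance for
    every addressed cell."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor", "concept", "n_agree", "n_disagree", "net_stance"])
        for i, actor in enumerate(sm.actors):
            for j, concept in enumerate(sm.concepts):
                na, nd = int(sm.n_agree[i, j]), int(sm.n_disagree[i, j])
                if na == 0 and nd == 0:
                    continue
                writer.writerow([actor, concept, na, nd, net_stance(na, nd)])
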