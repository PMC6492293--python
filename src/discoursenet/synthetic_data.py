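"""Seeded statement-corpus generator with planted coalition structure.

Because no coded media corpus is publicly deposited for this kind of study,
every pipeline stage is exercised against synthetic corpora whose coalition
structure is known.  The generator plants ``n_coalitions`` polarized groups:
each concept is *owned* by one coalition, whose members net-support it while
everyone else net-rejects it.  Each statement samples an actor (heavy-tailed
activity, so a few dominant speakers emerge), a concept, and a stance that
follows the actor's planted position with probability ``p_aligned``.  Brokers
straddle the divide (alignment near 0.5), and one designated actor can drift
toward the other side across windows.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from discoursenet.community import Partition
from discoursenet.errors import ConfigError, CoverageError
from discoursenet.statement_store import AGREE, DISAGREE, Corpus, Statement

_ACTOR_TYPES = (
    "political party",
    "manufacturer",
    "charity",
    "think-tank",
    "academic",
    "public body",
)

_DEFAULT_SOURCES = (
    "Daily Chronicle",
    "Morning Post",
    "National Record",
    "Sunday Ledger",
    "The Examiner",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-coalition corpus.

    Defaults mirror the scale of the study being emulated: ~1,900 statements,
    ~90 organizations, 56 concepts, three half-year windows over an 18-month
    span.
    """

    n_coalitions: int = 2
    actors_per_coalition: tuple[int, ...] = (44, 44)
    n_brokers: int = 4
    n_concepts: int = 56
    n_statements: int = 1900
    p_aligned: float = 0.9
    broker_p_aligned: float = 0.5
    activity_exponent: float = 1.2  # truncated power law over actor ranks
    persons_per_actor: int = 2
    n_windows: int = 3
    start_date: dt.date = dt.date(2011, 6, 1)
    window_days: int = 183  # three half-year slices spanning ~18 months
    window_drift: float = 0.0
    drift_actor: str | None = None  # defaults to first coalition-0 actor when drift > 0
    sources: tuple[str, ...] = _DEFAULT_SOURCES
    concept_ownership: dict[str, int] | None = None
    concept_sampling: str = "balanced"  # balanced: per-actor shuffled cycle; uniform: iid
    seed: int = 0

    def validate(self) -> None:
        if self.n_coalitions < 1 or len(self.actors_per_coalition) != self.n_coalitions:
            raise ConfigError("actors_per_coalition must list one count per coalition")
        if any(c < 1 for c in self.actors_per_coalition):
            raise ConfigError("each coalition needs at least one actor")
        for name in ("p_aligned", "broker_p_aligned"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.n_concepts < 1 or self.n_statements < 1 or self.n_windows < 1:
            raise ConfigError("n_concepts, n_statements and n_windows must be >= 1")
        if self.window_drift < 0 or self.window_drift > 1:
            raise ConfigError("window_drift must be in [0, 1]")
        if self.persons_per_actor < 1 or self.window_days < 1 or self.n_brokers < 0:
            raise ConfigError("invalid count in config")
        if not self.sources:
            raise ConfigError("need at least one source")
        if self.concept_sampling not in ("balanced", "uniform"):
            raise ConfigError("concept_sampling must be 'balanced' or 'uniform'")
        if self.activity_exponent < 0:
            raise ConfigError("activity_exponent must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if "actors_per_coalition" in raw:
            raw["actors_per_coalition"] = tuple(raw["actors_per_coalition"])
        if "sources" in raw:
            raw["sources"] = tuple(raw["sources"])
        if "start_date" in raw and isinstance(raw["start_date"], str):
            raw["start_date"] = dt.date.fromisoformat(raw["start_date"])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Planted labels for scoring recovered coalitions."""

    coalition_of: dict[str, int]
    broker_set: frozenset[str]
    drift_alignment: dict[int, float] = field(default_factory=dict)  # window -> p for drift actor
    drift_actor: str | None = None

    @property
    def actors(self) -> tuple[str, ...]:
        return tuple(sorted(self.coalition_of))


def _actor_names(config: SimConfig) -> tuple[list[str], dict[str, int], set[str], dict[str, str]]:
    names: list[str] = []
    coalition_of: dict[str, int] = {}
    types: dict[str, str] = {}
    for cid, count in enumerate(config.actors_per_coalition):
        for i in range(count):
            name = f"C{cid}_Org{i:03d}"
            names.append(name)
            coalition_of[name] = cid
            types[name] = _ACTOR_TYPES[i % len(_ACTOR_TYPES)]
    brokers = set()
    for i in range(config.n_brokers):
        name = f"Broker_Org{i:03d}"
        names.append(name)
        brokers.add(name)
        # brokers are nominally attached to an alternating coalition but
        # behave near-independently of it
        coalition_of[name] = i % config.n_coalitions
        types[name] = "political party"
    return names, coalition_of, brokers, types


def generate_corpus(config: SimConfig) -> tuple[Corpus, GroundTruth]:
    """Draw a reproducible corpus (and its ground truth) from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    actors, coalition_of, brokers, actor_types = _actor_names(config)
    concepts = [f"concept_{j:03d}" for j in range(config.n_concepts)]
    ownership = config.concept_ownership or {
        c: j % config.n_coalitions for j, c in enumerate(concepts)
    }
    if set(ownership) != set(concepts):
        raise ConfigError("concept_ownership must cover exactly the generated concepts")

    # heavy-tailed activity: weight ~ rank^(-exponent), ranks shuffled so
    # dominant speakers land anywhere in the name list
    ranks = rng.permutation(len(actors)) + 1
    weights = ranks.astype(float) ** -config.activity_exponent
    weights /= weights.sum()

    drift_actor = config.drift_actor
    if drift_actor is None and config.window_drift > 0:
        drift_actor = next(a for a in actors if coalition_of[a] == 0 and a not in brokers)
    drift_alignment = {}
    if drift_actor is not None:
        drift_alignment = {
            w: float(np.clip(config.p_aligned - w * config.window_drift, 0.0, 1.0))
            for w in range(config.n_windows)
        }

    # balanced sampling walks a per-actor shuffled concept cycle so an actor's
    # statements cover distinct concepts before repeating; without this, iid
    # concept draws dilute tie weights below any useful threshold
    concept_cycle = {a: rng.permutation(config.n_concepts) for a in actors}
    cycle_pos = {a: 0 for a in actors}

    span_days = config.n_windows * config.window_days
    statements = []
    for k in range(config.n_statements):
        actor = actors[rng.choice(len(actors), p=weights)]
        if config.concept_sampling == "balanced":
            concept = concepts[concept_cycle[actor][cycle_pos[actor] % config.n_concepts]]
            cycle_pos[actor] += 1
        else:
            concept = concepts[rng.integers(config.n_concepts)]
        day = int(rng.integers(span_days))
        window = day // config.window_days
        date = config.start_date + dt.timedelta(days=day)

        planted = 1 if ownership[concept] == coalition_of[actor] else -1
        if actor in brokers:
            p = config.broker_p_aligned
        elif actor == drift_actor:
            p = drift_alignment.get(window, config.p_aligned)
        else:
            p = config.p_aligned
        sign = planted if rng.random() < p else -planted

        person_no = int(rng.integers(config.persons_per_actor))
        source = config.sources[int(rng.integers(len(config.sources)))]
        statements.append(
            Statement(
                statement_id=f"s{k + 1}",
                article_id=f"A{k // 3:05d}",
                source=source,
                date=date,
                person=f"{actor} Person{person_no}",
                organization=actor,
                actor_type=actor_types[actor],
                concept=concept,
                stance=AGREE if sign > 0 else DISAGREE,
            )
        )
    corpus = Corpus(tuple(statements))
    # ground truth covers exactly the corpus's actor inventory: actors that
    # drew no statements never enter any network and are not scored
    speakers = {s.organization for s in statements}
    truth = GroundTruth(
        coalition_of={a: c for a, c in coalition_of.items() if a in speakers},
        broker_set=frozenset(brokers & speakers),
        drift_alignment=drift_alignment,
        drift_actor=drift_actor if drift_actor in speakers else None,
    )
    return corpus, truth


def recovery_score(partition: Partition, truth: GroundTruth) -> float:
    """Adjusted Rand index between recovered coalitions and planted labels,
    with brokers excluded from scoring.

    The partition must cover exactly the non-broker actors of the ground
    truth (actors without statements never enter the network; compare on the
    emitted corpus)."""
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    scored_truth = set(truth.coalition_of) - set(truth.broker_set)
    scored_part = set(assignment) - set(truth.broker_set)
    if scored_part != scored_truth:
        missing = scored_truth ^ scored_part
        raise CoverageError(f"partition/truth actor mismatch: {sorted(missing)[:5]}")
    actors = sorted(scored_truth)
    return float(
        adjusted_rand_score(
            [truth.coalition_of[a] for a in actors], [assignment[a] for a in actors]
        )
    )


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["actor", "coalition_id", "is_broker"])
        for actor in truth.actors:
            writer.writerow(
                [actor, truth.coalition_of[actor], int(actor in truth.broker_set)]
            )
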