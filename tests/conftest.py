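import datetime as dt

import pytest

from discoursenet.statement_store import Corpus, Statement


def mk_statement(
    person="Alice Example",
    organization="Org A",
    concept="concept X",
    stance="agree",
    date=dt.date(2011, 6, 15),
    source="Daily Chronicle",
    actor_type="charity",
    statement_id="s1",
    article_id="A1",
    **extra,
):
    return Statement(
        statement_id=statement_id,
        article_id=article_id,
        source=source,
        date=date,
        person=person,
        organization=organization,
        actor_type=actor_type,
        concept=concept,
        stance=stance,
        extra=extra,
    )


def mk_corpus(*specs):
    """Build a corpus from (org, concept, stance) triples or keyword dicts."""
    statements = []
    for i, spec in enumerate(specs, start=1):
        if isinstance(spec, dict):
            spec = dict(spec)
            spec.setdefault("statement_id", f"s{i}")
            statements.append(mk_statement(**spec))
        else:
            org, concept, stance = spec
            statements.append(
                mk_statement(
                    person=f"{org} person",
                    organization=org,
                    concept=concept,
                    stance=stance,
                    statement_id=f"s{i}",
                )
            )
    return Corpus(tuple(statements))


@pytest.fixture
def small_corpus():
    """Two actors agreeing on two concepts, a third opposing one of them."""
    return mk_corpus(
        ("Org A", "concept X", "agree"),
        ("Org A", "concept Y", "agree"),
        ("Org B", "concept X", "agree"),
        ("Org B", "concept Y", "agree"),
        ("Org C", "concept X", "disagree"),
    )
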