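import numpy as np
import pytest
from conftest import mk_corpus
from oracles import brute_pair_components

from discoursenet.errors import (
    DegenerateActorError,
    SelfPairError,
    TooFewActorsError,
)
from discoursenet.network_builder import (
    TieWeightConfig,
    build_network,
    congruence_conflict_decomposition,
    pair_concept_components,
    tie_weight,
    write_edgelist_csv,
)
from discoursenet.stance import StanceMatrix, build_stance_matrix
from discoursenet.statement_store import Corpus
from discoursenet.synthetic_data import SimConfig, generate_corpus

RAW = TieWeightConfig(method="subtract", normalization="none", threshold=None)
NORM = TieWeightConfig(method="subtract", normalization="average_activity", threshold=None)


def sm_from(*specs):
    return build_stance_matrix(mk_corpus(*specs), "organization")


class TestPairConceptComponents:
    def test_identical_supporters(self):
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org A", "Y", "agree"),
            ("Org B", "X", "agree"), ("Org B", "Y", "agree"),
        )
        assert pair_concept_components(sm, "Org A", "Org B") == (2, 0, 0)

    def test_pure_divergence(self):
        sm = sm_from(("Org A", "X", "agree"), ("Org B", "X", "disagree"))
        assert pair_concept_components(sm, "Org A", "Org B") == (0, 0, 1)

    def test_three_concept_enumeration(self):
        # A: +X, -Y; B: -Y, +Z  ->  co_reject on Y only
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org A", "Y", "disagree"),
            ("Org B", "Y", "disagree"), ("Org B", "Z", "agree"),
        )
        assert pair_concept_components(sm, "Org A", "Org B") == (0, 1, 0)

    def test_contested_contributes_nothing(self):
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org A", "X", "disagree"),  # contested for A
            ("Org B", "X", "agree"),
        )
        assert pair_concept_components(sm, "Org A", "Org B") == (0, 0, 0)

    def test_self_pair_rejected(self, small_corpus):
        sm = build_stance_matrix(small_corpus, "organization")
        with pytest.raises(SelfPairError):
            pair_concept_components(sm, "Org A", "Org A")

    def test_matches_raw_row_oracle_on_synthetic(self):
        corpus, _ = generate_corpus(
            SimConfig(actors_per_coalition=(4, 4), n_concepts=6, n_statements=160, seed=9)
        )
        sm = build_stance_matrix(corpus, "organization")
        actors = sm.actors
        for a in actors[:4]:
            for b in actors[4:]:
                assert pair_concept_components(sm, a, b) == brute_pair_components(
                    list(corpus), "organization", a, b
                )


class TestTieWeight:
    def test_full_congruence_normalized(self):
        # (2 - 0) / ((2 + 2) / 2) = 1.0
        assert tie_weight((2, 0, 0), 2, 2, NORM) == pytest.approx(1.0)

    def test_pure_conflict_normalized(self):
        # (0 - 1) / ((1 + 1) / 2) = -1.0
        assert tie_weight((0, 0, 1), 1, 1, NORM) == pytest.approx(-1.0)

    def test_no_shared_concepts(self):
        assert tie_weight((0, 0, 0), 7, 3, NORM) == 0.0

    @pytest.mark.parametrize(
        "method,expected", [("congruence", 2.0), ("conflict", 1.0), ("subtract", 1.0)]
    )
    def test_methods_raw(self, method, expected):
        cfg = TieWeightConfig(method=method, normalization="none", threshold=None)
        assert tie_weight((1, 1, 1), 5, 5, cfg) == expected

    def test_zero_activity_rejected(self):
        with pytest.raises(DegenerateActorError):
            tie_weight((1, 0, 0), 0, 3, NORM)


class TestBuildNetwork:
    def test_two_actor_unit_weight(self):
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org A", "Y", "agree"),
            ("Org B", "X", "agree"), ("Org B", "Y", "agree"),
        )
        net = build_network(sm, NORM)
        assert net.weight("Org A", "Org B") == pytest.approx(1.0)
        assert net.graph.number_of_edges() == 1

    def test_threshold_boundary_inclusive(self):
        # A and B share 39 supported concepts out of 100 statements each -> 0.39
        # C and D share 40 out of 100 -> 0.40; threshold >= 0.4 keeps only CD
        def star(org, shared, n_shared, solo_prefix, n_solo):
            rows = [(org, f"{shared}{i}", "agree") for i in range(n_shared)]
            rows += [(org, f"{solo_prefix}{i}", "agree") for i in range(n_solo)]
            return rows

        rows = (
            star("Org A", "sh", 39, "soloA", 61)
            + star("Org B", "sh", 39, "soloB", 61)
            + star("Org C", "sc", 40, "soloC", 60)
            + star("Org D", "sc", 40, "soloD", 60)
        )
        sm = sm_from(*rows)
        unthresholded = build_network(sm, NORM)
        assert unthresholded.weight("Org A", "Org B") == pytest.approx(0.39)
        assert unthresholded.weight("Org C", "Org D") == pytest.approx(0.40)
        net = build_network(sm, TieWeightConfig(threshold=0.4))
        assert net.weight("Org A", "Org B") is None
        assert net.weight("Org C", "Org D") == pytest.approx(0.40)

    def test_isolates_retained_as_nodes(self):
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org B", "X", "agree"), ("Org C", "Z", "agree")
        )
        net = build_network(sm, TieWeightConfig(threshold=0.4))
        assert set(net.graph.nodes) == {"Org A", "Org B", "Org C"}
        assert net.graph.degree("Org C") == 0

    def test_node_attributes(self, small_corpus):
        sm = build_stance_matrix(small_corpus, "organization")
        net = build_network(sm, RAW)
        assert net.graph.nodes["Org A"]["statement_frequency"] == 2
        assert net.graph.nodes["Org A"]["actor_type"] == "charity"

    def test_too_few_actors(self):
        sm = sm_from(("Org A", "X", "agree"))
        with pytest.raises(TooFewActorsError):
            build_network(sm, RAW)

    def test_duplicating_all_statements_halves_normalized_weights(self):
        # net stances and concept counts are unchanged, average activity
        # doubles, so each normalized weight scales by exactly 1/2
        corpus, _ = generate_corpus(
            SimConfig(actors_per_coalition=(4, 4), n_concepts=8, n_statements=120, seed=2)
        )
        doubled = Corpus(tuple(list(corpus.statements) * 2))
        net1 = build_network(build_stance_matrix(corpus, "organization"), NORM)
        net2 = build_network(build_stance_matrix(doubled, "organization"), NORM)
        assert net1.graph.number_of_edges() == net2.graph.number_of_edges()
        for a, b in net1.graph.edges:
            assert net2.weight(a, b) == pytest.approx(net1.weight(a, b) / 2)

    def test_duplication_never_changes_raw_weights(self):
        # adding statements that change no net stance leaves the numerator alone
        corpus, _ = generate_corpus(
            SimConfig(actors_per_coalition=(4, 4), n_concepts=8, n_statements=120, seed=2)
        )
        doubled = Corpus(tuple(list(corpus.statements) * 2))
        raw1 = build_network(build_stance_matrix(corpus, "organization"), RAW)
        raw2 = build_network(build_stance_matrix(doubled, "organization"), RAW)
        for a, b in raw1.graph.edges:
            assert raw2.weight(a, b) == raw1.weight(a, b)

    def test_symmetry_and_boundedness_on_synthetic(self):
        corpus, _ = generate_corpus(
            SimConfig(actors_per_coalition=(5, 5), n_concepts=10, n_statements=250, seed=4)
        )
        sm = build_stance_matrix(corpus, "organization")
        net = build_network(sm, NORM)
        for a, b, data in net.graph.edges(data=True):
            assert abs(data["weight"]) <= 1.0 + 1e-12
            cs, cr, dv = pair_concept_components(sm, b, a)  # reversed order
            assert (data["co_support"], data["co_reject"], data["diverge"]) == (cs, cr, dv)

    def test_concepts_activity_mode(self):
        # two statements on one concept: statements-activity 2, concepts-activity 1
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org A", "X", "agree"),
            ("Org B", "X", "agree"), ("Org B", "X", "agree"),
        )
        by_stmt = build_network(sm, NORM)
        by_concept = build_network(
            sm,
            TieWeightConfig(normalization="average_activity", threshold=None,
                            activity_mode="concepts"),
        )
        assert by_stmt.weight("Org A", "Org B") == pytest.approx(0.5)
        assert by_concept.weight("Org A", "Org B") == pytest.approx(1.0)


class TestDecomposition:
    def test_definition(self):
        assert tie_weight((1, 1, 1), 9, 9, TieWeightConfig(method="congruence", normalization="none", threshold=None)) == 2
        assert tie_weight((1, 1, 1), 9, 9, TieWeightConfig(method="conflict", normalization="none", threshold=None)) == 1
        assert tie_weight((1, 1, 1), 9, 9, TieWeightConfig(method="subtract", normalization="none", threshold=None)) == 1

    def test_conflict_empty_without_opposing_stances(self):
        sm = sm_from(
            ("Org A", "X", "agree"), ("Org B", "X", "agree"), ("Org C", "Y", "agree")
        )
        _, conflict = congruence_conflict_decomposition(sm)
        assert conflict.graph.number_of_edges() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_on_synthetic(self, seed):
        corpus, _ = generate_corpus(
            SimConfig(actors_per_coalition=(5, 5), n_concepts=9, n_statements=200, seed=seed)
        )
        sm = build_stance_matrix(corpus, "organization")
        subtract = build_network(sm, RAW)
        congruence, conflict = congruence_conflict_decomposition(sm)
        for i, a in enumerate(sm.actors):
            for b in sm.actors[i + 1 :]:
                sub = subtract.weight(a, b) or 0.0
                con = congruence.weight(a, b) or 0.0
                cfl = conflict.weight(a, b) or 0.0
                assert sub == pytest.approx(con - cfl)


def test_edgelist_export_sorted(tmp_path, small_corpus):
    net = build_network(build_stance_matrix(small_corpus, "organization"), RAW)
    out = tmp_path / "edges.csv"
    write_edgelist_csv(net, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("actor_a,actor_b,weight")
    pairs = [tuple(line.split(",")[:2]) for line in lines[1:]]
    assert pairs == sorted(pairs)
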