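"""Example builders, shortest dependency paths, feature naming."""

import itertools

import pytest

from eventex.features import (
    FeatureSpace,
    GoldLabels,
    build_edge_examples,
    build_entity_examples,
    build_modifier_examples,
    build_unmerging_examples,
    edge_candidates,
    shortest_undirected_path,
    stem,
    valid_argument_subsets,
)
from eventex.graph import Document, EntityNode, EventGroup, InteractionEdge
from eventex.scheme import is_valid_edge, learn_scheme, parse_scheme

from .conftest import make_sentence


class TestShortestPath:
    def test_same_token_gives_empty_path(self):
        s = make_sentence([("a", "NN"), ("b", "NN")], deps=[("dep", 0, 1)])
        p = shortest_undirected_path("s0.t0", "s0.t0", s)
        assert len(p) == 0 and p.tokens[0].text == "a"

    def test_chain_of_two_dependencies(self):
        s = make_sentence(
            [("a", "NN"), ("b", "VBZ"), ("c", "NN")],
            deps=[("nsubj", 1, 0), ("dobj", 1, 2)],
        )
        p = shortest_undirected_path("s0.t0", "s0.t2", s)
        assert len(p) == 2
        assert p.direction_signature == "RF"  # up via nsubj, down via dobj

    def test_disconnected_tokens_give_none(self):
        s = make_sentence([("a", "NN"), ("b", "NN")])
        assert shortest_undirected_path("s0.t0", "s0.t1", s) is None

    def test_diamond_tie_break_is_lexicographic(self):
        # two length-2 paths a-b-d (amod, xcomp) and a-c-d (nsubj, dobj):
        # brute force all shortest paths and apply the dependency-type
        # tie-break by hand
        s = make_sentence(
            [("a", "NN"), ("b", "NN"), ("c", "NN"), ("d", "NN")],
            deps=[("amod", 1, 0), ("xcomp", 1, 3), ("nsubj", 2, 0), ("dobj", 2, 3)],
        )
        p = shortest_undirected_path("s0.t0", "s0.t3", s)
        label_seq = tuple(d.type for d in p.dependencies)
        # brute-force oracle over both candidate paths
        candidates = [("amod", "xcomp"), ("nsubj", "dobj")]
        assert label_seq == min(candidates)

    def test_parallel_edges_resolved_by_smallest_label(self):
        s = make_sentence(
            [("a", "NN"), ("b", "NN")],
            deps=[("zz", 0, 1), ("aa", 0, 1)],
        )
        p = shortest_undirected_path("s0.t0", "s0.t1", s)
        assert p.dependencies[0].type == "aa"


def _tiny_scheme():
    return parse_scheme(
        "ENTITY\tProtein\n"
        "EVENT\tPhosphorylation [1,2]\tCause [0,1] Protein / Theme [1,1] Protein\n"
        "TARGET\tENTITY\tPhosphorylation\n"
        "TARGET\tINTERACTION\tCause, Theme\n"
    )


def _phospho_sentence(with_gold=True):
    s = make_sentence(
        [("A", "NNP"), ("phosphorylates", "VBZ"), ("B", "NNP"), (".", ".")],
        deps=[("nsubj", 1, 0), ("dobj", 1, 2), ("punct", 1, 3)],
        entities=[
            ("Protein", 0, 0, {"given": True}),
            ("Protein", 2, 2, {"given": True}),
        ]
        + ([("Phosphorylation", 1, 1, {"event": True})] if with_gold else []),
        interactions=(
            [
                dict(type="Theme", source="s0.e2", target="s0.e1", event=True),
                dict(type="Cause", source="s0.e2", target="s0.e0", event=True),
            ]
            if with_gold
            else []
        ),
    )
    return s


def _doc_of(sentence):
    return Document(
        id="d", text=sentence.text, sentences=[sentence], sentence_offsets=[0],
        events=(
            [EventGroup("g0", "s0.e2", ("s0.i0", "s0.i1"))]
            if any(e.event for e in sentence.entities)
            else []
        ),
    )


class TestEntityExamples:
    def test_one_example_per_non_given_token(self):
        # five tokens, one of them a given single-token Protein -> 4 examples
        s = make_sentence(
            [("A", "NNP"), ("binds", "VBZ"), ("B", "NNP"), ("strongly", "RB"), (".", ".")],
            entities=[("Protein", 0, 0, {"given": True})],
        )
        assert len(build_entity_examples(s, _tiny_scheme())) == 4

    def test_gold_class_and_merged_class(self):
        s = _phospho_sentence()
        s.entities.append(
            EntityNode("s0.e3", "Regulation", s.entities[2].start, s.entities[2].end,
                       s.entities[2].text, head=s.entities[2].head, event=True)
        )
        labels = GoldLabels(_doc_of(s))
        examples = build_entity_examples(s, _tiny_scheme(), gold=labels)
        by_anchor = {ex.anchor[1]: ex.gold_class for ex in examples}
        assert by_anchor["s0.t1"] == "Phosphorylation---Regulation"
        assert by_anchor["s0.t3"] == "neg"

    def test_feature_name_conventions(self):
        s = _phospho_sentence()
        (ex,) = [
            e for e in build_entity_examples(s, _tiny_scheme())
            if e.anchor[1] == "s0.t1"
        ]
        names = set(ex.features)
        assert "POS_VBZ" in names
        assert "txt_phosphorylates" in names
        assert f"stem_{stem('phosphorylates')}" in names
        assert "dt_ph" in names and "tt_pho" in names  # character 2/3-grams
        assert "linear_-1_txt_A" in names and "linear_1_txt_B" in names
        assert "dist_1_annType_Protein" in names
        assert "bow_phosphorylates" in names and "sentAnnType_Protein" in names

    def test_purity_identical_sentence_identical_features(self):
        a = build_entity_examples(_phospho_sentence(), _tiny_scheme())
        b = build_entity_examples(_phospho_sentence(), _tiny_scheme())
        assert [e.features for e in a] == [e.features for e in b]


class TestEdgeExamples:
    def test_candidates_are_scheme_filtered(self):
        s = _phospho_sentence()
        cands = {(a.id, b.id) for a, b, _ in edge_candidates(s, _tiny_scheme())}
        # brute force: all ordered pairs minus is_valid_edge failures
        scheme = _tiny_scheme()
        types = sorted(scheme.edge_types())
        brute = {
            (a.id, b.id)
            for a, b in itertools.permutations(s.entities, 2)
            if any(is_valid_edge(scheme, a.type, b.type, t) for t in types)
        }
        assert cands == brute
        # trigger->protein only, never protein->protein
        assert cands == {("s0.e2", "s0.e0"), ("s0.e2", "s0.e1")}

    def test_empty_node_set_gives_no_examples(self):
        s = make_sentence([("nothing", "NN")])
        assert build_edge_examples(s, _tiny_scheme()) == []

    def test_gold_classes_and_path_features(self):
        s = _phospho_sentence()
        labels = GoldLabels(_doc_of(s))
        examples = build_edge_examples(s, _tiny_scheme(), gold=labels)
        by_anchor = {(e.anchor[1], e.anchor[2]): e for e in examples}
        theme = by_anchor[("s0.e2", "s0.e1")]
        assert theme.gold_class == "Theme"
        names = set(theme.features)
        assert "dep_Forward_dobj" in names
        assert any(n.startswith("tok_") for n in names)
        assert any(n.startswith("tokenPath_") for n in names)
        cause = by_anchor[("s0.e2", "s0.e0")]
        assert cause.gold_class == "Cause"
        assert "dep_Forward_nsubj" in cause.features

    def test_disconnected_pair_gets_no_path_indicator(self):
        s = _phospho_sentence()
        s.dependencies = []  # no parse edges at all
        examples = build_edge_examples(s, _tiny_scheme())
        assert all("noDepPath" in e.features for e in examples)


class TestUnmergingExamples:
    def test_subset_enumeration_matches_brute_force(self):
        # Theme:A, Theme:B, Cause:C under Theme[1,1] Cause[0,1] overall[1,2]
        # -> exactly {A},{B},{A,C},{B,C}
        scheme = _tiny_scheme()
        s = make_sentence(
            [("P", "VBZ"), ("A", "NNP"), ("B", "NNP"), ("C", "NNP")],
            deps=[("dobj", 0, 1), ("dobj", 0, 2), ("nsubj", 0, 3)],
            entities=[
                ("Phosphorylation", 0, 0, {"event": True}),
                ("Protein", 1, 1, {"given": True}),
                ("Protein", 2, 2, {"given": True}),
                ("Protein", 3, 3, {"given": True}),
            ],
            interactions=[
                dict(type="Theme", source="s0.e0", target="s0.e1", event=True),
                dict(type="Theme", source="s0.e0", target="s0.e2", event=True),
                dict(type="Cause", source="s0.e0", target="s0.e3", event=True),
            ],
        )
        trig = s.entities[0]
        subsets = valid_argument_subsets(trig, list(s.interactions), s, scheme)
        got = {frozenset(e.id for e, _ in sub) for sub in subsets}
        assert got == {
            frozenset({"s0.i0"}),
            frozenset({"s0.i1"}),
            frozenset({"s0.i0", "s0.i2"}),
            frozenset({"s0.i1", "s0.i2"}),
        }

    def test_binding_two_themes(self):
        scheme = parse_scheme(
            "ENTITY\tProtein\n"
            "EVENT\tBinding [1,2]\tTheme [1,2] Protein\n"
            "TARGET\tENTITY\tBinding\nTARGET\tINTERACTION\tTheme\n"
        )
        s = make_sentence(
            [("binds", "VBZ"), ("A", "NNP"), ("B", "NNP")],
            deps=[("dobj", 0, 1), ("dobj", 0, 2)],
            entities=[
                ("Binding", 0, 0, {"event": True}),
                ("Protein", 1, 1, {"given": True}),
                ("Protein", 2, 2, {"given": True}),
            ],
            interactions=[
                dict(type="Theme", source="s0.e0", target="s0.e1", event=True),
                dict(type="Theme", source="s0.e0", target="s0.e2", event=True),
            ],
        )
        subsets = valid_argument_subsets(s.entities[0], list(s.interactions), s, scheme)
        got = {frozenset(e.id for e, _ in sub) for sub in subsets}
        assert got == {
            frozenset({"s0.i0"}),
            frozenset({"s0.i1"}),
            frozenset({"s0.i0", "s0.i1"}),
        }

    def test_feature_prefixes(self):
        s = _phospho_sentence()
        labels = GoldLabels(_doc_of(s))
        examples = build_unmerging_examples(s, _tiny_scheme(), gold=labels, doc=_doc_of(s))
        positive = [e for e in examples if e.gold_class == "event"]
        assert len(positive) == 1
        names = set(positive[0].features)
        assert any(n.startswith("argTheme_") for n in names)
        assert any(n.startswith("argCause_") for n in names)
        assert any(n.startswith("trg_dt_") for n in names)
        assert any(n.startswith("bow_") for n in names)

    def test_subset_cap_limits_enumeration(self, caplog):
        import logging

        scheme = parse_scheme(
            "ENTITY\tProtein\n"
            "EVENT\tBinding [1,12]\tTheme [1,12] Protein\n"
            "TARGET\tENTITY\tBinding\nTARGET\tINTERACTION\tTheme\n"
        )
        n = 12
        words = [("binds", "VBZ")] + [(f"P{i}", "NNP") for i in range(n)]
        entities = [("Binding", 0, 0, {"event": True})] + [
            ("Protein", i + 1, i + 1, {"given": True}) for i in range(n)
        ]
        interactions = [
            dict(type="Theme", source="s0.e0", target=f"s0.e{i + 1}", event=True)
            for i in range(n)
        ]
        s = make_sentence(words, entities=entities, interactions=interactions)
        with caplog.at_level(logging.WARNING, logger="eventex.features"):
            subsets = valid_argument_subsets(
                s.entities[0], list(s.interactions), s, scheme, max_subsets=100
            )
        assert len(subsets) <= 100
        assert any("capped" in r.message for r in caplog.records)


class TestModifierExamples:
    def _scheme(self):
        return parse_scheme(
            "ENTITY\tProtein\n"
            "EVENT\tPhosphorylation [1,1]\tTheme [1,1] Protein\n"
            "EVENT\tExpression [1,1]\tTheme [1,1] Protein\n"
            "MODIFIER\tnegation\tPhosphorylation\n"
            "TARGET\tENTITY\tExpression, Phosphorylation\n"
            "TARGET\tINTERACTION\tTheme\n"
        )

    def test_non_capable_trigger_type_gets_no_example(self):
        s = _phospho_sentence()
        trig = s.entities[2]
        expr = EntityNode("s0.e9", "Expression", trig.start, trig.end, trig.text,
                          head=trig.head, event=True)
        examples = build_modifier_examples(s, self._scheme(), [(expr, [])])
        assert examples == []

    def test_negation_fixture_carries_neg_dependency_feature(self):
        # "B was not phosphorylated": the neg dependency on the trigger is
        # exactly what modifier detection keys on
        s = make_sentence(
            [("B", "NNP"), ("was", "VBD"), ("not", "RB"), ("phosphorylated", "VBN")],
            deps=[("nsubjpass", 3, 0), ("auxpass", 3, 1), ("neg", 3, 2)],
            entities=[
                ("Protein", 0, 0, {"given": True}),
                ("Phosphorylation", 3, 3, {"event": True,
                                           "modifiers": frozenset({"negation"})}),
            ],
            interactions=[
                dict(type="Theme", source="s0.e1", target="s0.e0", event=True)
            ],
        )
        doc = Document(id="d", text=s.text, sentences=[s], sentence_offsets=[0],
                       events=[EventGroup("g0", "s0.e1", ("s0.i0",),
                                          frozenset({"negation"}))])
        labels = GoldLabels(doc)
        trig = s.entities[1]
        subset = [(s.interactions[0], s.entities[0])]
        (ex,) = build_modifier_examples(s, self._scheme(), [(trig, subset)], gold=labels)
        assert ex.gold_class == "negation"
        assert "t1HOut_neg" in ex.features
        assert "t1HOut_neg_RB" in ex.features

    def test_speculation_word_list_features(self):
        s = make_sentence(
            [("X", "NNP"), ("may", "MD"), ("phosphorylate", "VB"), ("B", "NNP")],
            deps=[("nsubj", 2, 0), ("aux", 2, 1), ("dobj", 2, 3)],
            entities=[
                ("Protein", 3, 3, {"given": True}),
                ("Phosphorylation", 2, 2, {"event": True}),
            ],
        )
        (ex,) = build_modifier_examples(s, self._scheme(), [(s.entities[1], [])])
        assert "specWord_may" in ex.features


class TestFeatureSpace:
    def test_unseen_names_ignored_after_freeze(self):
        from eventex.features import Example

        fs = FeatureSpace()
        fs.transform([Example("a", None, {"x": 1.0, "y": 1.0}, ())])
        fs.freeze()
        m = fs.transform([Example("b", None, {"x": 1.0, "new": 1.0}, ())])
        assert m.shape[1] == 2 and m.nnz == 1

    def test_round_trip_through_dict(self):
        from eventex.features import Example

        fs = FeatureSpace()
        fs.transform([Example("a", None, {"x": 1.0, "y": 2.0}, ())])
        again = FeatureSpace.from_dict(fs.to_dict())
        assert again.names == fs.names and again.frozen


class TestGoldCoverage:
    def test_every_reachable_gold_element_has_one_positive_example(
        self, gen_default, scheme_default
    ):
        for doc in gen_default.corpus.documents:
            labels = GoldLabels(doc)
            n_gold_events = len(labels.reachable_events)
            positives = 0
            for sent in doc.sentences:
                for ex in build_unmerging_examples(
                    sent, scheme_default, gold=labels, doc=doc
                ):
                    if ex.gold_class == "event":
                        positives += 1
            # merged gold argument-set signatures can coincide for distinct
            # shared-trigger copies; each distinct signature appears once
            distinct = {
                (sig, frozenset(a))
                for sig, argsets in labels.event_arg_sets.items()
                for a in argsets
            }
            assert positives == len(distinct)
            assert positives <= n_gold_events
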