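"""Annotation-scheme induction and structural-validity queries."""

import random

import pytest

from eventex.graph import Corpus, Document, EventGroup
from eventex.scheme import (
    AnnotationScheme,
    is_valid_edge,
    is_valid_event_structure,
    learn_scheme,
    parse_scheme,
    serialize_scheme,
)
from eventex.synthetic import GeneratorSpec, generate_corpus, sample_scheme

from .conftest import make_sentence

# a GENIA-2013-style scheme fragment, in the serialized table layout
_GENIA_STYLE = """\
ENTITY\tEntity
ENTITY\tProtein
EVENT\tBinding [1,4]\tSite {Theme} [0,2] Entity / Theme [1,2] Protein
EVENT\tGene_expression [1,1]\tTheme [1,1] Protein
EVENT\tPhosphorylation [1,3]\tCause [0,1] Protein / Site {Theme} [0,1] Entity / Theme [1,1] Protein
RELATION\tCoreference, directed\tSubject(Anaphora) / Object(Anaphora, Entity, Protein)
RELATION\tSiteParent, directed\tArg1(Entity) / Arg2(Protein)
MODIFIER\tnegation\tBinding, Gene_expression, Phosphorylation
TARGET\tENTITY\tBinding, Entity, Gene_expression, Phosphorylation
TARGET\tINTERACTION\tCause, Site, SiteParent, Theme
"""


@pytest.fixture(scope="module")
def genia_style():
    return parse_scheme(_GENIA_STYLE)


def _doc_with_events(instances, doc_id="d0"):
    """One sentence per instance list entry: (trigger type, [(role, target type)])."""
    words, entities, interactions, groups = [], [], [], []
    # flat layout: trigger token then one token per argument
    sent_entities = []
    idx = 0
    edge_n = 0
    for gi, (etype, args) in enumerate(instances):
        words.append((f"trig{gi}", "VBZ"))
        trig_idx = idx
        idx += 1
        sent_entities.append((etype, trig_idx, trig_idx, {"event": True}))
        trig_id = f"s0.e{len(sent_entities) - 1}"
        arg_edges = []
        for role, ttype in args:
            words.append((f"m{idx}", "NNP"))
            sent_entities.append((ttype, idx, idx, {"given": ttype == "Protein"}))
            target_id = f"s0.e{len(sent_entities) - 1}"
            interactions.append(
                dict(type=role, source=trig_id, target=target_id, event=True)
            )
            arg_edges.append(f"s0.i{edge_n}")
            edge_n += 1
            idx += 1
        groups.append(EventGroup(f"g{gi}", trig_id, tuple(arg_edges)))
    sent = make_sentence(words, entities=sent_entities, interactions=interactions)
    return Document(
        id=doc_id, text=sent.text, sentences=[sent], sentence_offsets=[0],
        events=groups,
    )


class TestLearnScheme:
    def test_observed_extremes_become_constraints(self):
        doc = _doc_with_events(
            [("X", [("Theme", "Protein")]),
             ("X", [("Theme", "Protein"), ("Cause", "Protein")])]
        )
        s = learn_scheme([doc])
        d = s.events["X"]
        assert (d.overall_min, d.overall_max) == (1, 2)
        assert (d.arguments["Theme"].min, d.arguments["Theme"].max) == (1, 1)
        assert (d.arguments["Cause"].min, d.arguments["Cause"].max) == (0, 1)

    def test_event_attribute_wins_for_zero_argument_events(self):
        # a node flagged as an event but never with outgoing edges must be
        # learned as an event type with overall [0,0], not as an entity
        doc = _doc_with_events([("Glycolysis", [])])
        s = learn_scheme([doc])
        assert "Glycolysis" in s.events
        d = s.events["Glycolysis"]
        assert (d.overall_min, d.overall_max) == (0, 0)

    def test_empty_corpus_yields_empty_scheme(self):
        s = learn_scheme(Corpus("empty", []))
        assert not s.events and not s.entity_types and not s.relations

    def test_document_order_invariance(self, gen_default):
        docs = list(gen_default.corpus.documents)
        a = serialize_scheme(learn_scheme(docs))
        b = serialize_scheme(learn_scheme(list(reversed(docs))))
        assert a == b

    def test_soundness_every_gold_event_is_valid(self, gen_default, scheme_default):
        for doc in gen_default.corpus.documents:
            nodes = {e.id: e for e in doc.all_entities()}
            edges = {e.id: e for e in doc.all_edges()}
            for g in doc.events:
                args = []
                for aid in g.args:
                    e = edges[aid]
                    primary = (
                        edges[e.site_of].type if e.site_of is not None else None
                    )
                    args.append((e.type, nodes[e.target].type, primary))
                assert is_valid_event_structure(
                    scheme_default, nodes[g.trigger].type, args
                )

    def test_monotone_growth_with_more_documents(self, gen_default):
        docs = sorted(gen_default.corpus.documents, key=lambda d: d.id)
        prev = learn_scheme(docs[:5])
        grown = learn_scheme(docs)
        for t, d in prev.events.items():
            g = grown.events[t]
            assert g.overall_min <= d.overall_min and g.overall_max >= d.overall_max
            for role, c in d.arguments.items():
                gc = g.arguments[role]
                assert gc.min <= c.min and gc.max >= c.max
                assert gc.target_types >= c.target_types


class TestValidityQueries:
    def test_licensed_event_argument(self, genia_style):
        assert is_valid_edge(genia_style, "Gene_expression", "Protein", "Theme")

    def test_unlicensed_pair(self, genia_style):
        assert not is_valid_edge(genia_style, "Protein", "Protein", "Theme")

    def test_relation_direction_respected(self, genia_style):
        assert is_valid_edge(genia_style, "Entity", "Protein", "SiteParent")
        assert not is_valid_edge(genia_style, "Protein", "Entity", "SiteParent")

    def test_empty_scheme_licenses_nothing(self):
        empty = AnnotationScheme()
        assert not is_valid_edge(empty, "A", "B", "Theme")

    @pytest.mark.parametrize(
        "trigger,args,valid",
        [
            ("Binding", [("Theme", "Protein", None)] * 3, False),  # Theme max 2
            ("Phosphorylation", [("Theme", "Protein", None)], True),
            ("Binding", [("Theme", "Protein", None)] * 2, True),
            # Site whose primary is Cause when only {Theme} is licensed
            (
                "Phosphorylation",
                [
                    ("Theme", "Protein", None),
                    ("Cause", "Protein", None),
                    ("Site", "Entity", "Cause"),
                ],
                False,
            ),
            (
                "Phosphorylation",
                [("Theme", "Protein", None), ("Site", "Entity", "Theme")],
                True,
            ),
            ("Gene_expression", [], False),  # misses required Theme
            ("Unknown", [("Theme", "Protein", None)], False),
        ],
    )
    def test_event_structure_validation(self, genia_style, trigger, args, valid):
        assert is_valid_event_structure(genia_style, trigger, args) is valid


class TestSerialization:
    def test_round_trip_of_genia_style_scheme(self, genia_style):
        assert parse_scheme(serialize_scheme(genia_style)) == genia_style

    def test_round_trip_of_learned_scheme(self, scheme_default):
        assert parse_scheme(serialize_scheme(scheme_default)) == scheme_default

    def test_empty_scheme_serializes_to_header_and_targets(self):
        text = serialize_scheme(AnnotationScheme())
        lines = [l for l in text.splitlines() if l]
        assert lines[0].startswith("#")
        assert all(l.startswith(("#", "TARGET")) for l in lines)
        assert parse_scheme(text) == AnnotationScheme()

    def test_site_primary_roles_survive(self, genia_style):
        again = parse_scheme(serialize_scheme(genia_style))
        c = again.events["Phosphorylation"].arguments["Site"]
        assert c.site_primary_roles == frozenset({"Theme"})

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_of_sampled_schemes(self, seed):
        sch = sample_scheme(random.Random(seed))
        assert parse_scheme(serialize_scheme(sch)) == sch


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_saturated_corpus_recovers_generating_scheme(self, seed):
        sch = sample_scheme(random.Random(seed))
        gen = generate_corpus(GeneratorSpec(scheme=sch, saturate=True, seed=1))
        assert serialize_scheme(learn_scheme(gen.corpus)) == serialize_scheme(sch)
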