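"""Standoff parsing/writing, graph conversion, repair, Interaction XML."""

import io
import logging

import pytest

from eventex.graph import validate_graph
from eventex.ixml import read_interaction_xml, write_interaction_xml
from eventex.scheme import learn_scheme, parse_scheme
from eventex.st_io import (
    IntegrityError,
    STDocument,
    StandoffParseError,
    graph_to_st,
    read_st_document,
    site_primary_role,
    split_role,
    st_to_graph,
    validate_and_repair,
    validate_st_document,
    write_st_document,
)

from .test_scheme import _GENIA_STYLE


@pytest.fixture(scope="module")
def genia_style():
    return parse_scheme(_GENIA_STYLE)


class TestStandoffReading:
    def test_entity_line_fields(self):
        d = read_st_document("d", "BMP-6 binds X .", "T1\tProtein 0 5\tBMP-6\n", "")
        e = d.entities["T1"]
        assert (e.type, e.start, e.end, e.text, e.given) == ("Protein", 0, 5, "BMP-6", True)

    def test_nested_event_argument(self):
        txt = "A inhibits repression of B ."
        a2 = (
            "T1\tNegative_regulation 2 10\tinhibits\n"
            "T2\tNegative_regulation 11 21\trepression\n"
            "T3\tProtein 25 26\tB\n"
            "E1\tNegative_regulation:T2 Theme:T3\n"
            "E2\tNegative_regulation:T1 Theme:E1\n"
        )
        d = read_st_document("d", txt, "", a2)
        assert d.events["E2"].args == [("Theme", "E1")]

    def test_equiv_line(self):
        d = read_st_document(
            "d", "A B", "T1\tProtein 0 1\tA\nT2\tProtein 2 3\tB\n*\tEquiv T1 T2\n", ""
        )
        assert d.equivs[0].members == frozenset({"T1", "T2"})

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(StandoffParseError, match="line 1"):
            read_st_document("d", "x", "T1 Protein 0 1 x", "")

    def test_offset_text_mismatch_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            read_st_document("d", "ABCDE", "T1\tProtein 0 3\tXYZ\n", "")

    def test_dangling_reference_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="unknown target"):
            read_st_document(
                "d", "p x", "", "T1\tTrig 0 1\tp\nE1\tTrig:T1 Theme:T9\n"
            )


class TestStandoffWriting:
    def test_read_write_is_identity_up_to_renumbering(self, gen_default):
        for doc, (txt, a1, a2) in zip(gen_default.corpus.documents, gen_default.standoff):
            again = read_st_document(doc.id, txt, a1, a2)
            assert write_st_document(again) == (a1, a2)

    def test_event_with_theme_and_site_on_one_line(self):
        txt = "K phosphorylates P at S ."
        a2 = (
            "T2\tPhosphorylation 2 16\tphosphorylates\n"
            "T3\tEntity 22 23\tS\n"
            "E1\tPhosphorylation:T2 Theme:T1 Site:T3\n"
        )
        d = read_st_document("d", txt, "T1\tProtein 17 18\tP\n", a2)
        _, out_a2 = write_st_document(d)
        (eline,) = [l for l in out_a2.splitlines() if l.startswith("E")]
        assert "Theme:" in eline and "Site:" in eline

    def test_modifier_line_format(self):
        txt = "p binds q ."
        a2 = (
            "T1\tBinding 2 7\tbinds\nE1\tBinding:T1\nM1\tNegation E1\n"
        )
        d = read_st_document("d", txt, "", a2)
        _, out = write_st_document(d)
        assert "M1\tNegation E1" in out

    def test_dangling_reference_refuses_to_write(self):
        from eventex.st_io import STEntity, STEvent

        d = STDocument(id="d", text="x y")
        d.entities["T1"] = STEntity("T1", "Trig", 0, 1, "x")
        d.events["E1"] = STEvent("E1", "Trig", "T1", [("Theme", "E9")])
        with pytest.raises(IntegrityError):
            write_st_document(d)


class TestRoleHelpers:
    @pytest.mark.parametrize(
        "role,base,num", [("Theme", "Theme", 1), ("Theme2", "Theme", 2), ("Site3", "Site", 3)]
    )
    def test_split_role(self, role, base, num):
        assert split_role(role) == (base, num)

    def test_site_pairs_with_matching_theme(self):
        from eventex.st_io import STEvent

        ev = STEvent("E1", "X", "T1", [("Theme", "T2"), ("Theme2", "T3"), ("Site2", "T4")])
        assert site_primary_role(ev, "Site2") == ("Theme2", "T3")

    def test_csite_pairs_with_cause(self):
        from eventex.st_io import STEvent

        ev = STEvent("E1", "X", "T1", [("Theme", "T2"), ("Cause", "T3"), ("CSite", "T4")])
        assert site_primary_role(ev, "CSite") == ("Cause", "T3")


class TestSiteUnification:
    def _phospho_doc(self):
        txt = "K phosphorylates P at S ."
        a1 = "T1\tProtein 17 18\tP\n"
        a2 = (
            "T2\tPhosphorylation 2 16\tphosphorylates\n"
            "T3\tEntity 22 23\tS\n"
            "E1\tPhosphorylation:T2 Theme:T1 Site:T3\n"
        )
        return read_st_document("d", txt, a1, a2)

    def _parses(self, txt, sent_id="d.s0"):
        from eventex.graph import Dependency, Token
        from eventex.st_io import SentenceParse

        tokens, pos_ = [], 0
        for i, w in enumerate(txt.split(" ")):
            tokens.append(Token(f"{sent_id}.t{i}", w, "NN", pos_, pos_ + len(w)))
            pos_ += len(w) + 1
        deps = [
            Dependency("dep", tokens[0].id, t.id) for t in tokens[1:]
        ]
        return [SentenceParse(sent_id, 0, txt, tokens, deps)]

    def test_site_becomes_trigger_edge_plus_siteparent(self):
        d = self._phospho_doc()
        g = st_to_graph(d, self._parses(d.text))
        edges = list(g.all_edges())
        sites = [e for e in edges if e.type == "Site"]
        sps = [e for e in edges if e.type == "SiteParent"]
        assert len(sites) == 1 and len(sps) == 1
        # the Site edge leaves the trigger and names the Theme edge as primary
        theme = next(e for e in edges if e.type == "Theme")
        assert sites[0].source == theme.source
        assert sites[0].site_of == theme.id
        # SiteParent connects the site entity to the Theme's protein
        assert sps[0].source == sites[0].target and sps[0].target == theme.target

    def test_second_site_on_same_primary_is_discarded(self, genia_style):
        # two Site edges through distinct site entities whose SiteParent both
        # reach the primary argument's protein: only one survives on write
        d = self._phospho_doc()
        g = st_to_graph(d, self._parses(d.text))
        sent = g.sentences[0]
        trig = next(e for e in sent.entities if e.type == "Phosphorylation")
        theme = next(e for e in sent.interactions if e.type == "Theme")
        protein = next(e for e in sent.entities if e.type == "Protein")
        site2 = next(e for e in sent.entities if e.type == "Entity")
        from eventex.graph import EntityNode, InteractionEdge

        extra_site = EntityNode(
            id="x.site", type="Entity", start=site2.start, end=site2.end,
            text=site2.text, head=site2.head,
        )
        sent.entities.append(extra_site)
        e1 = InteractionEdge(id="x.i1", type="Site", source=trig.id,
                             target=extra_site.id, event=True)
        e2 = InteractionEdge(id="x.i2", type="SiteParent", source=extra_site.id,
                             target=protein.id)
        sent.interactions += [e1, e2]
        g.events[0].args = g.events[0].args + (e1.id,)
        st = graph_to_st(g)
        (ev,) = st.events.values()
        assert sum(1 for r, _ in ev.args if r.startswith("Site")) == 1

    def test_multi_parent_site_maps_to_one_primary_only(self):
        # predicted SiteParent links one site to two proteins; the site must
        # attach to exactly one primary argument (first target in doc order)
        txt = "binds A B at S ."
        from eventex.graph import Document, EntityNode, EventGroup, InteractionEdge

        parses = self._parses(txt)
        sent_tokens = parses[0].tokens
        from eventex.graph import SentenceGraph

        sent = SentenceGraph(id="d.s0", text=txt, tokens=sent_tokens,
                             dependencies=parses[0].dependencies)
        trig = EntityNode("n0", "Binding", 0, 5, "binds", sent_tokens[0].id, event=True)
        pa = EntityNode("n1", "Protein", 6, 7, "A", sent_tokens[1].id, given=True)
        pb = EntityNode("n2", "Protein", 8, 9, "B", sent_tokens[2].id, given=True)
        site = EntityNode("n3", "Entity", 13, 14, "S", sent_tokens[4].id)
        sent.entities = [trig, pa, pb, site]
        t1 = InteractionEdge("i0", "Theme", "n0", "n1", event=True)
        t2 = InteractionEdge("i1", "Theme", "n0", "n2", event=True)
        se = InteractionEdge("i2", "Site", "n0", "n3", event=True)
        sp1 = InteractionEdge("i3", "SiteParent", "n3", "n1")
        sp2 = InteractionEdge("i4", "SiteParent", "n3", "n2")
        sent.interactions = [t1, t2, se, sp1, sp2]
        doc = Document(id="d", text=txt, sentences=[sent], sentence_offsets=[0],
                       events=[EventGroup("g0", "n0", ("i0", "i1", "i2"))])
        st = graph_to_st(doc)
        (ev,) = st.events.values()
        site_roles = [r for r, _ in ev.args if "Site" in r]
        assert site_roles == ["Site"]  # bound to Theme (protein A, first in doc)


class TestDuplicateRemoval:
    def test_duplicates_collapse_to_fixpoint(self):
        # three events: two identical Binding events plus a Regulation
        # pointing at one of the duplicates; after collapse one Binding
        # survives and the Regulation re-points at it
        txt = "binds P regulates ."
        from eventex.graph import (
            Document, EntityNode, EventGroup, InteractionEdge, SentenceGraph, Token,
        )

        toks = []
        pos_ = 0
        for i, w in enumerate(txt.split(" ")):
            toks.append(Token(f"d.s0.t{i}", w, "NN", pos_, pos_ + len(w)))
            pos_ += len(w) + 1
        sent = SentenceGraph(id="d.s0", text=txt, tokens=toks)
        b1 = EntityNode("n0", "Binding", 0, 5, "binds", toks[0].id, event=True)
        b2 = EntityNode("n1", "Binding", 0, 5, "binds", toks[0].id, event=True)
        p = EntityNode("n2", "Protein", 6, 7, "P", toks[1].id, given=True)
        r = EntityNode("n3", "Regulation", 8, 17, "regulates", toks[2].id, event=True)
        sent.entities = [b1, b2, p, r]
        e1 = InteractionEdge("i0", "Theme", "n0", "n2", event=True)
        e2 = InteractionEdge("i1", "Theme", "n1", "n2", event=True)
        e3 = InteractionEdge("i2", "Theme", "n3", "n1", event=True)
        sent.interactions = [e1, e2, e3]
        doc = Document(
            id="d", text=txt, sentences=[sent], sentence_offsets=[0],
            events=[
                EventGroup("g0", "n0", ("i0",)),
                EventGroup("g1", "n1", ("i1",)),
                EventGroup("g2", "n3", ("i2",)),
            ],
        )
        st = graph_to_st(doc)
        bindings = [e for e in st.events.values() if e.type == "Binding"]
        regs = [e for e in st.events.values() if e.type == "Regulation"]
        assert len(bindings) == 1 and len(regs) == 1
        assert regs[0].args[0][1] == bindings[0].id

    def test_empty_document_gives_empty_a2(self):
        from eventex.graph import Document

        st = graph_to_st(Document(id="d", text=""))
        a1, a2 = write_st_document(st)
        assert a1 == "" and a2 == ""


class TestEquivalenceExpansion:
    def test_equiv_argument_expands_to_one_event_per_member(self):
        txt = "expresses A B ."
        a1 = "T1\tProtein 10 11\tA\nT2\tProtein 12 13\tB\n*\tEquiv T1 T2\n"
        a2 = "T3\tExpression 0 9\texpresses\nE1\tExpression:T3 Theme:T1\n"
        d = read_st_document("d", txt, a1, a2)
        g = st_to_graph(d, TestSiteUnification()._parses(txt))
        assert len(g.events) == 2
        targets = {
            next(e for e in g.all_edges() if e.id == ev.args[0]).target
            for ev in g.events
        }
        assert len(targets) == 2

    def test_expansion_then_write_recovers_original(self):
        txt = "expresses A B ."
        a1 = "T1\tProtein 10 11\tA\nT2\tProtein 12 13\tB\n*\tEquiv T1 T2\n"
        a2 = "T3\tExpression 0 9\texpresses\nE1\tExpression:T3 Theme:T1\n"
        d = read_st_document("d", txt, a1, a2)
        g = st_to_graph(d, TestSiteUnification()._parses(txt))
        assert write_st_document(graph_to_st(g)) == (a1, a2)


class TestCoreferenceSkipping:
    def test_relation_with_trigger_endpoint_is_skipped_with_warning(self, caplog):
        txt = "it binds P ."
        a1 = "T1\tProtein 9 10\tP\n"
        a2 = (
            "T2\tAnaphora 0 2\tit\n"
            "T3\tBinding 3 8\tbinds\n"
            "E1\tBinding:T3 Theme:T1\n"
            "R1\tCoreference Subject:T2 Object:T3\n"
        )
        d = read_st_document("d", txt, a1, a2)
        with caplog.at_level(logging.WARNING, logger="eventex.st_io"):
            g = st_to_graph(d, TestSiteUnification()._parses(txt))
        assert not [e for e in g.all_edges() if e.type == "Coreference"]
        assert any("skipped" in r.message for r in caplog.records)


class TestValidateAndRepair:
    def test_invalid_argument_renamed_to_missing_required_role(self, genia_style):
        txt = "expr P ."
        d = read_st_document(
            "d", txt, "T1\tProtein 5 6\tP\n",
            "T2\tGene_expression 0 4\texpr\nE1\tGene_expression:T2 Cause:T1\n",
        )
        fixed, log = validate_and_repair(d, genia_style)
        assert fixed.events["E1"].args == [("Theme", "T1")]
        assert any("renamed" in l for l in log)

    def test_extra_argument_beyond_maximum_removed(self, genia_style):
        txt = "expr A B ."
        d = read_st_document(
            "d", txt, "T1\tProtein 5 6\tA\nT2\tProtein 7 8\tB\n",
            "T3\tGene_expression 0 4\texpr\nE1\tGene_expression:T3 Theme:T1 Theme2:T2\n",
        )
        fixed, log = validate_and_repair(d, genia_style)
        assert len(fixed.events["E1"].args) == 1
        assert any("removed" in l for l in log)

    def test_unrepairable_event_removed_with_referencers(self, genia_style):
        # Phosphorylation without a Theme cannot be repaired; the Binding
        # event pointing at it must be removed recursively.  Reference via
        # an event-typed target is invalid anyway under this scheme, so use
        # a second Phosphorylation that loses its only Theme.
        txt = "phos q ."
        d = read_st_document(
            "d", txt, "",
            "T1\tPhosphorylation 0 4\tphos\nE1\tPhosphorylation:T1\n",
        )
        fixed, log = validate_and_repair(d, genia_style)
        assert not fixed.events
        assert any("removed" in l for l in log)

    def test_recursive_removal_of_referencing_events(self):
        scheme = parse_scheme(
            "ENTITY\tProtein\n"
            "EVENT\tExpression [1,1]\tTheme [1,1] Protein\n"
            "EVENT\tRegulation [1,1]\tTheme [1,1] Expression\n"
            "TARGET\tENTITY\tExpression, Regulation\n"
            "TARGET\tINTERACTION\tTheme\n"
        )
        txt = "expr reg Q ."
        d = read_st_document(
            "d", txt, "",
            "T1\tExpression 0 4\texpr\n"
            "T2\tRegulation 5 8\treg\n"
            "E1\tExpression:T1\n"  # invalid: Theme missing, unrepairable
            "E2\tRegulation:T2 Theme:E1\n",
        )
        fixed, log = validate_and_repair(d, scheme)
        assert not fixed.events
        assert any("recursively" in l for l in log)

    def test_output_always_validates(self, gen_default, scheme_default):
        from eventex.synthetic import ErrorSpec, perturb_predictions

        pert = perturb_predictions(
            gen_default.corpus,
            ErrorSpec(invalid_role=3, extra_argument=3, drop_argument=3, seed=5),
        )
        for doc in pert.documents:
            st = graph_to_st(doc)  # no scheme: defects pass through
            fixed, _ = validate_and_repair(st, scheme_default)
            assert validate_st_document(fixed, scheme_default) == []


class TestStGraphCycle:
    def test_full_cycle_identity_on_generated_corpora(self, gen_default):
        for doc, (txt, a1, a2) in zip(gen_default.corpus.documents, gen_default.standoff):
            st = read_st_document(doc.id, txt, a1, a2)
            g = st_to_graph(st, gen_default.parses[doc.id])
            assert validate_graph(g) == []
            assert write_st_document(graph_to_st(g)) == (a1, a2)

    def test_gold_output_has_empty_repair_log(self, gen_default, scheme_default):
        for doc in gen_default.corpus.documents:
            st = graph_to_st(doc, scheme_default)
            _, log = validate_and_repair(st, scheme_default)
            assert log == []


class TestInteractionXml:
    def _roundtrip(self, corpus):
        buf = io.StringIO()
        write_interaction_xml(corpus, buf)
        again = read_interaction_xml(io.StringIO(buf.getvalue()))
        buf2 = io.StringIO()
        write_interaction_xml(again, buf2)
        return buf.getvalue(), buf2.getvalue(), again

    def test_round_trip_is_byte_identical(self, gen_default):
        first, second, _ = self._roundtrip(gen_default.corpus)
        assert first == second

    def test_siteof_and_modifiers_survive(self, gen_default):
        _, _, again = self._roundtrip(gen_default.corpus)
        site_edges = [
            e for d in again.documents for e in d.all_edges() if e.site_of is not None
        ]
        assert site_edges, "generated corpus should contain siteOf edges"
        mods = {
            m for d in again.documents for e in d.all_entities() for m in e.modifiers
        }
        assert mods >= {"negation"}

    def test_unknown_attributes_preserved(self, gen_default):
        from eventex.graph import copy_document, Corpus

        doc = copy_document(gen_default.corpus.documents[0])
        doc.sentences[0].entities[0].extra["customFlag"] = "yes"
        first, second, again = self._roundtrip(Corpus("c", [doc]))
        assert 'customFlag="yes"' in first
        assert again.documents[0].sentences[0].entities[0].extra["customFlag"] == "yes"

    def test_scheme_learned_from_xml_round_trip_matches(self, gen_default, scheme_default):
        from eventex.scheme import serialize_scheme

        _, _, again = self._roundtrip(gen_default.corpus)
        assert serialize_scheme(learn_scheme(again)) == serialize_scheme(scheme_default)
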