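"""Interaction XML: the native on-disk form of the interaction graph.

A corpus element holds documents; a document holds sentences; a sentence
holds entity and interaction elements plus its tokenisation and dependency
parse.  Entities carry ``given``/``event`` attributes and modifier flags,
interactions carry ``directed``/``event``/``given``/``siteOf``.  Event
instances and equivalence groups are document-level elements, as are
sentence-boundary-crossing interactions.  Unknown attributes are preserved
verbatim so files written by other tools survive a round trip.
"""

from __future__ import annotations

from lxml import etree

from .graph import (
    Corpus,
    Dependency,
    Document,
    EntityNode,
    EventGroup,
    InteractionEdge,
    SentenceGraph,
    Token,
)

_BOOL = {"True": True, "False": False}


def _span(start: int, end: int) -> str:
    return f"{start}-{end}"


def _parse_span(text: str) -> tuple[int, int]:
    a, b = text.rsplit("-", 1)
    return int(a), int(b)


def _set_known(el, pairs, extra):
    for k, v in pairs:
        if v is not None:
            el.set(k, v)
    for k in sorted(extra):
        el.set(k, extra[k])


def _entity_el(parent, e: EntityNode):
    el = etree.SubElement(parent, "entity")
    _set_known(
        el,
        [
            ("id", e.id),
            ("type", e.type),
            ("charOffset", _span(e.start, e.end)),
            ("text", e.text),
            ("head", e.head),
            ("given", str(e.given)),
            ("event", str(e.event)),
            ("negation", "True" if "negation" in e.modifiers else None),
            ("speculation", "True" if "speculation" in e.modifiers else None),
        ],
        e.extra,
    )


_ENTITY_KEYS = {
    "id", "type", "charOffset", "text", "head", "given", "event",
    "negation", "speculation",
}


def _parse_entity(el) -> EntityNode:
    start, end = _parse_span(el.get("charOffset"))
    mods = set()
    if el.get("negation") == "True":
        mods.add("negation")
    if el.get("speculation") == "True":
        mods.add("speculation")
    return EntityNode(
        id=el.get("id"),
        type=el.get("type"),
        start=start,
        end=end,
        text=el.get("text", ""),
        head=el.get("head"),
        given=_BOOL.get(el.get("given", "False"), False),
        event=_BOOL.get(el.get("event", "False"), False),
        modifiers=frozenset(mods),
        extra={k: v for k, v in el.attrib.items() if k not in _ENTITY_KEYS},
    )


def _interaction_el(parent, i: InteractionEdge):
    el = etree.SubElement(parent, "interaction")
    _set_known(
        el,
        [
            ("id", i.id),
            ("type", i.type),
            ("e1", i.source),
            ("e2", i.target),
            ("directed", str(i.directed)),
            ("event", str(i.event)),
            ("given", str(i.given)),
            ("siteOf", i.site_of),
        ],
        i.extra,
    )


_INTERACTION_KEYS = {"id", "type", "e1", "e2", "directed", "event", "given", "siteOf"}


def _parse_interaction(el) -> InteractionEdge:
    return InteractionEdge(
        id=el.get("id"),
        type=el.get("type"),
        source=el.get("e1"),
        target=el.get("e2"),
        directed=_BOOL.get(el.get("directed", "True"), True),
        event=_BOOL.get(el.get("event", "False"), False),
        given=_BOOL.get(el.get("given", "False"), False),
        site_of=el.get("siteOf"),
        extra={k: v for k, v in el.attrib.items() if k not in _INTERACTION_KEYS},
    )


def write_interaction_xml(corpus: Corpus, stream) -> None:
    """Serialize a corpus; attribute order is fixed, so output is canonical."""
    root = etree.Element("corpus")
    root.set("source", corpus.name)
    for doc in corpus.documents:
        del_ = etree.SubElement(root, "document")
        _set_known(
            del_,
            [
                ("id", doc.id),
                ("set", doc.set_label),
                ("text", doc.text),
            ],
            doc.extra,
        )
        for sent, off in zip(doc.sentences, doc.sentence_offsets):
            sel = etree.SubElement(del_, "sentence")
            _set_known(
                sel,
                [
                    ("id", sent.id),
                    ("text", sent.text),
                    ("charOffset", _span(off, off + len(sent.text))),
                ],
                sent.extra,
            )
            for e in sent.entities:
                _entity_el(sel, e)
            for i in sent.interactions:
                _interaction_el(sel, i)
            analyses = etree.SubElement(sel, "analyses")
            tok = etree.SubElement(analyses, "tokenization")
            for t in sent.tokens:
                tel = etree.SubElement(tok, "token")
                _set_known(
                    tel,
                    [
                        ("id", t.id),
                        ("text", t.text),
                        ("POS", t.pos),
                        ("charOffset", _span(t.start, t.end)),
                    ],
                    {},
                )
            parse = etree.SubElement(analyses, "parse")
            for d in sent.dependencies:
                dep = etree.SubElement(parse, "dependency")
                _set_known(
                    dep, [("type", d.type), ("t1", d.governor), ("t2", d.dependent)], {}
                )
        for i in doc.cross_edges:
            _interaction_el(del_, i)
        for g in doc.events:
            ev = etree.SubElement(del_, "event")
            _set_known(
                ev,
                [
                    ("id", g.id),
                    ("trigger", g.trigger),
                    ("args", " ".join(g.args)),
                    ("negation", "True" if "negation" in g.modifiers else None),
                    ("speculation", "True" if "speculation" in g.modifiers else None),
                ],
                {},
            )
        for group in sorted(doc.equivs, key=sorted):
            eq = etree.SubElement(del_, "equiv")
            eq.set("members", " ".join(sorted(group)))
    data = etree.tostring(root, pretty_print=True, encoding="unicode")
    stream.write(data)


def read_interaction_xml(stream) -> Corpus:
    root = etree.parse(stream).getroot()
    corpus = Corpus(name=root.get("source", "corpus"))
    for del_ in root.findall("document"):
        extra = {
            k: v for k, v in del_.attrib.items() if k not in {"id", "set", "text"}
        }
        doc = Document(
            id=del_.get("id"),
            text=del_.get("text", ""),
            set_label=del_.get("set"),
            extra=extra,
        )
        for sel in del_.findall("sentence"):
            off, _end = _parse_span(sel.get("charOffset"))
            sent = SentenceGraph(
                id=sel.get("id"),
                text=sel.get("text", ""),
                extra={
                    k: v
                    for k, v in sel.attrib.items()
                    if k not in {"id", "text", "charOffset"}
                },
            )
            for el in sel.findall("entity"):
                sent.entities.append(_parse_entity(el))
            for el in sel.findall("interaction"):
                sent.interactions.append(_parse_interaction(el))
            analyses = sel.find("analyses")
            if analyses is not None:
                tok = analyses.find("tokenization")
                if tok is not None:
                    for tel in tok.findall("token"):
                        ts, te = _parse_span(tel.get("charOffset"))
                        sent.tokens.append(
                            Token(tel.get("id"), tel.get("text"), tel.get("POS"), ts, te)
                        )
                parse = analyses.find("parse")
                if parse is not None:
                    for dep in parse.findall("dependency"):
                        sent.dependencies.append(
                            Dependency(dep.get("type"), dep.get("t1"), dep.get("t2"))
                        )
            doc.sentences.append(sent)
            doc.sentence_offsets.append(off)
        for el in del_.findall("interaction"):
            doc.cross_edges.append(_parse_interaction(el))
        for el in del_.findall("event"):
            mods = set()
            if el.get("negation") == "True":
                mods.add("negation")
            if el.get("speculation") == "True":
                mods.add("speculation")
            doc.events.append(
                EventGroup(
                    id=el.get("id"),
                    trigger=el.get("trigger"),
                    args=tuple(el.get("args", "").split()) if el.get("args") else (),
                    modifiers=frozenset(mods),
                )
            )
        for el in del_.findall("equiv"):
            doc.equivs.append(frozenset(el.get("members", "").split()))
        corpus.documents.append(doc)
    return corpus
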