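"""In-memory interaction-graph model for event-annotated, dependency-parsed text.

Event extraction is modelled as graph generation: named entities and event
trigger words are nodes bound to single syntactic head tokens, while event
arguments and binary relations are typed, (optionally) directed edges between
nodes.  An event is a trigger node together with a set of outgoing argument
edges; nesting arises when an argument edge points at another event's trigger
node.  This module holds the data types and the structural validation that the
rest of the pipeline builds on.  Serialization (standoff files, Interaction
XML) lives in :mod:`eventex.st_io`.

Offsets are 0-based half-open and sentence-scoped; documents keep an explicit
sentence-to-document offset map so the document-scoped standoff format can be
converted without ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MODIFIER_KINDS = ("negation", "speculation")


class OffsetError(ValueError):
    """A character span does not line up with the tokens or text it refers to."""


@dataclass
class Token:
    id: str
    text: str
    pos: str
    start: int
    end: int


@dataclass
class Dependency:
    type: str
    governor: str  # token id
    dependent: str  # token id


@dataclass
class EntityNode:
    """A graph node: a named entity or an event trigger.

    ``given`` marks annotation provided as input (never a prediction target);
    ``event`` marks event-trigger nodes, including triggers of zero-argument
    events which would otherwise be indistinguishable from plain entities.
    """

    id: str
    type: str
    start: int
    end: int
    text: str
    head: str | None = None  # token id
    given: bool = False
    event: bool = False
    modifiers: frozenset[str] = frozenset()
    extra: dict[str, str] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def signature(self) -> tuple:
        """Id-free identity used for deduplication and alignment."""
        return (self.start, self.end, self.type, self.given)


@dataclass
class InteractionEdge:
    """A typed edge: an event argument (``event=True``) or a binary relation.

    ``site_of`` names the sibling edge that is the primary argument of a
    Site-style secondary argument, removing the ambiguity that arises when a
    site's parent protein is the target of several primary arguments.
    """

    id: str
    type: str
    source: str  # entity node id
    target: str  # entity node id
    directed: bool = True
    event: bool = False
    given: bool = False
    site_of: str | None = None
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class EventGroup:
    """One event instance: a trigger node plus the ids of its argument edges."""

    id: str
    trigger: str  # entity node id
    args: tuple[str, ...] = ()  # interaction edge ids
    modifiers: frozenset[str] = frozenset()


@dataclass
class SentenceGraph:
    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    dependencies: list[Dependency] = field(default_factory=list)
    entities: list[EntityNode] = field(default_factory=list)
    interactions: list[InteractionEdge] = field(default_factory=list)
    extra: dict[str, str] = field(default_factory=dict)

    def token_by_id(self, tid: str) -> Token:
        for t in self.tokens:
            if t.id == tid:
                return t
        raise KeyError(f"no token {tid!r} in sentence {self.id!r}")

    def entity_by_id(self, eid: str) -> EntityNode:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(f"no entity {eid!r} in sentence {self.id!r}")

    def edge_by_id(self, iid: str) -> InteractionEdge:
        for e in self.interactions:
            if e.id == iid:
                return e
        raise KeyError(f"no interaction {iid!r} in sentence {self.id!r}")


@dataclass
class Document:
    """A document: sentences plus document-level annotation.

    ``cross_edges`` holds interactions whose endpoints lie in different
    sentences; they are preserved but excluded from example generation, which
    is what makes the intra-sentence performance ceiling observable.
    ``events`` enumerates event instances (the unmerged view); ``equivs``
    groups entity nodes declared interchangeable by equivalence annotation.
    """

    id: str
    text: str
    sentences: list[SentenceGraph] = field(default_factory=list)
    sentence_offsets: list[int] = field(default_factory=list)
    cross_edges: list[InteractionEdge] = field(default_factory=list)
    events: list[EventGroup] = field(default_factory=list)
    equivs: list[frozenset[str]] = field(default_factory=list)
    set_label: str | None = None
    extra: dict[str, str] = field(default_factory=dict)

    # -- lookup helpers -------------------------------------------------
    def sentence_of_entity(self, eid: str) -> SentenceGraph | None:
        for s in self.sentences:
            for e in s.entities:
                if e.id == eid:
                    return s
        return None

    def entity_by_id(self, eid: str) -> EntityNode:
        for s in self.sentences:
            for e in s.entities:
                if e.id == eid:
                    return e
        raise KeyError(f"no entity {eid!r} in document {self.id!r}")

    def all_entities(self):
        for s in self.sentences:
            yield from s.entities

    def all_edges(self):
        for s in self.sentences:
            yield from s.interactions
        yield from self.cross_edges

    def edge_by_id(self, iid: str) -> InteractionEdge:
        for e in self.all_edges():
            if e.id == iid:
                return e
        raise KeyError(f"no interaction {iid!r} in document {self.id!r}")

    def sentence_offset(self, sentence_id: str) -> int:
        for s, off in zip(self.sentences, self.sentence_offsets):
            if s.id == sentence_id:
                return off
        raise KeyError(sentence_id)

    def doc_span(self, node: EntityNode) -> tuple[int, int]:
        """Entity span shifted from sentence scope to document scope."""
        sent = self.sentence_of_entity(node.id)
        if sent is None:
            raise KeyError(node.id)
        off = self.sentence_offset(sent.id)
        return (node.start + off, node.end + off)

    def events_of_trigger(self, node_id: str) -> list[EventGroup]:
        return [g for g in self.events if g.trigger == node_id]


@dataclass
class Corpus:
    name: str
    documents: list[Document] = field(default_factory=list)

    def partition(self, label: str) -> "Corpus":
        return Corpus(self.name, [d for d in self.documents if d.set_label == label])


# ---------------------------------------------------------------------------
# head resolution
# ---------------------------------------------------------------------------

def resolve_head_token(start: int, end: int, sentence: SentenceGraph) -> Token:
    """Pick the syntactic head token of the character span ``[start, end)``.

    Among tokens overlapping the span, the head is the token none of whose
    governors is itself inside the span (i.e. it is governed from outside, or
    is a parse root).  If several qualify the rightmost is taken; if none do
    (a dependency cycle confined to the span), the rightmost overlapping token
    is taken.  Deterministic by construction.
    """
    overlapping = [t for t in sentence.tokens if t.start < end and t.end > start]
    if not overlapping:
        raise OffsetError(
            f"span {start}..{end} overlaps no token in sentence {sentence.id!r}"
        )
    inside = {t.id for t in overlapping}
    governors: dict[str, set[str]] = {}
    for d in sentence.dependencies:
        governors.setdefault(d.dependent, set()).add(d.governor)
    candidates = [
        t for t in overlapping if not (governors.get(t.id, set()) & inside)
    ]
    pool = candidates if candidates else overlapping
    return max(pool, key=lambda t: (t.start, t.end))


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    kind: str
    where: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.where}: {self.message}"


def _validate_sentence(s: SentenceGraph, findings: list[Finding]) -> None:
    seen_tok: set[str] = set()
    n = len(s.text)
    for t in s.tokens:
        if t.id in seen_tok:
            findings.append(Finding("duplicate-id", s.id, f"token id {t.id!r}"))
        seen_tok.add(t.id)
        if not (0 <= t.start < t.end <= n):
            findings.append(
                Finding("offset", s.id, f"token {t.id!r} span {t.start}..{t.end}")
            )
        elif s.text[t.start : t.end] != t.text:
            findings.append(
                Finding("offset", s.id, f"token {t.id!r} text mismatch")
            )
    for d in s.dependencies:
        if d.governor == d.dependent:
            findings.append(Finding("dependency", s.id, f"self-loop on {d.governor!r}"))
        for tid in (d.governor, d.dependent):
            if tid not in seen_tok:
                findings.append(
                    Finding("dependency", s.id, f"unknown token {tid!r} in {d.type}")
                )
    seen_ent: set[str] = set()
    for e in s.entities:
        if e.id in seen_ent:
            findings.append(Finding("duplicate-id", s.id, f"entity id {e.id!r}"))
        seen_ent.add(e.id)
        if not (0 <= e.start < e.end <= n):
            findings.append(
                Finding("offset", s.id, f"entity {e.id!r} span {e.start}..{e.end}")
            )
        if e.head is not None and e.head not in seen_tok:
            findings.append(Finding("head", s.id, f"entity {e.id!r} head {e.head!r}"))
        if not set(e.modifiers) <= set(MODIFIER_KINDS):
            findings.append(
                Finding("modifier", s.id, f"entity {e.id!r} modifiers {sorted(e.modifiers)}")
            )


def _validate_edges(
    edges: list[InteractionEdge],
    entity_ids: set[str],
    edge_ids: dict[str, InteractionEdge],
    where: str,
    findings: list[Finding],
) -> None:
    for e in edges:
        for endpoint in (e.source, e.target):
            if endpoint not in entity_ids:
                findings.append(
                    Finding("dangling-endpoint", where, f"edge {e.id!r} -> {endpoint!r}")
                )
        if e.site_of is not None:
            primary = edge_ids.get(e.site_of)
            if primary is None:
                findings.append(
                    Finding("siteOf", where, f"edge {e.id!r} siteOf unknown edge {e.site_of!r}")
                )
            elif primary.source != e.source:
                findings.append(
                    Finding(
                        "siteOf",
                        where,
                        f"edge {e.id!r} siteOf {e.site_of!r} has a different source node",
                    )
                )


def _validate_document(doc: Document, findings: list[Finding]) -> None:
    if len(doc.sentences) != len(doc.sentence_offsets):
        findings.append(Finding("offset-map", doc.id, "sentence/offset count mismatch"))
        return
    prev_end = 0
    for s, off in zip(doc.sentences, doc.sentence_offsets):
        if off < prev_end:
            findings.append(Finding("offset-map", doc.id, f"sentence {s.id!r} overlaps"))
        if doc.text[off : off + len(s.text)] != s.text:
            findings.append(Finding("offset-map", doc.id, f"sentence {s.id!r} text mismatch"))
        prev_end = off + len(s.text)
        _validate_sentence(s, findings)

    entity_ids = {e.id for e in doc.all_entities()}
    all_edge_ids: dict[str, InteractionEdge] = {}
    for e in doc.all_edges():
        if e.id in all_edge_ids:
            findings.append(Finding("duplicate-id", doc.id, f"interaction id {e.id!r}"))
        all_edge_ids[e.id] = e
    for s in doc.sentences:
        sent_entity_ids = {e.id for e in s.entities}
        _validate_edges(s.interactions, sent_entity_ids, all_edge_ids, s.id, findings)
    _validate_edges(doc.cross_edges, entity_ids, all_edge_ids, doc.id, findings)

    for g in doc.events:
        if g.trigger not in entity_ids:
            findings.append(Finding("event", doc.id, f"event {g.id!r} trigger {g.trigger!r}"))
            continue
        for aid in g.args:
            edge = all_edge_ids.get(aid)
            if edge is None:
                findings.append(Finding("event", doc.id, f"event {g.id!r} arg edge {aid!r}"))
            elif edge.source != g.trigger:
                findings.append(
                    Finding("event", doc.id, f"event {g.id!r} arg {aid!r} leaves a foreign node")
                )
    for group in doc.equivs:
        for eid in group:
            if eid not in entity_ids:
                findings.append(Finding("equiv", doc.id, f"unknown entity {eid!r}"))


def validate_graph(obj: SentenceGraph | Document | Corpus) -> list[Finding]:
    """Structural validation report; empty iff all graph invariants hold.

    Reporting only: never raises on a malformed graph.
    """
    findings: list[Finding] = []
    if isinstance(obj, SentenceGraph):
        _validate_sentence(obj, findings)
        ids = {e.id for e in obj.entities}
        _validate_edges(
            obj.interactions, ids, {e.id: e for e in obj.interactions}, obj.id, findings
        )
    elif isinstance(obj, Document):
        _validate_document(obj, findings)
    elif isinstance(obj, Corpus):
        seen_docs: set[str] = set()
        for d in obj.documents:
            if d.id in seen_docs:
                findings.append(Finding("duplicate-id", obj.name, f"document id {d.id!r}"))
            seen_docs.add(d.id)
            _validate_document(d, findings)
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot validate {type(obj).__name__}")
    return findings


def copy_document(doc: Document) -> Document:
    """Deep-enough copy: new containers and records, shared immutable strings."""
    sentences = []
    for s in doc.sentences:
        sentences.append(
            SentenceGraph(
                id=s.id,
                text=s.text,
                tokens=[replace(t) for t in s.tokens],
                dependencies=[replace(d) for d in s.dependencies],
                entities=[replace(e, extra=dict(e.extra)) for e in s.entities],
                interactions=[replace(i, extra=dict(i.extra)) for i in s.interactions],
                extra=dict(s.extra),
            )
        )
    return Document(
        id=doc.id,
        text=doc.text,
        sentences=sentences,
        sentence_offsets=list(doc.sentence_offsets),
        cross_edges=[replace(i, extra=dict(i.extra)) for i in doc.cross_edges],
        events=[replace(g) for g in doc.events],
        equivs=[frozenset(g) for g in doc.equivs],
        set_label=doc.set_label,
        extra=dict(doc.extra),
    )
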