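"""Standoff and Interaction XML I/O, and conversion to/from the graph model.

The shared-task standoff format is a triplet of files per document: ``.txt``
(raw text), ``.a1`` (given entities) and ``.a2`` (predicted triggers, events,
relations, modifiers and equivalence lines), all with document-scoped
character offsets.  The graph side represents the same annotation as entity
nodes and interaction edges bound to dependency-parsed sentences.

Conversion in the standoff→graph direction expands equivalence groups into
individual events, creates one trigger node per event instance (so shared
triggers duplicate nodes and the gold graph is already "unmerged"), and maps
Site arguments to the unified representation: a Site edge from the trigger to
the site entity carrying a ``siteOf`` reference to its primary argument edge,
plus a SiteParent edge from the site entity to the primary argument's target.

The graph→standoff direction re-attaches Site arguments to primaries (via
``siteOf`` on known data, via SiteParent linkage on predictions), discards a
Site if its primary already has one, never maps one Site to several
primaries, collapses events made identical by these removals (recursively,
until none remain), and drops events that reference removed events.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field, replace

from .graph import (
    Dependency,
    Document,
    EntityNode,
    EventGroup,
    InteractionEdge,
    SentenceGraph,
    Token,
    resolve_head_token,
)
from .scheme import SITEPARENT_TYPE, AnnotationScheme, is_valid_event_structure

logger = logging.getLogger(__name__)


class StandoffParseError(ValueError):
    """A standoff line could not be parsed."""


class IntegrityError(ValueError):
    """Record contents contradict the document text or each other."""


# ---------------------------------------------------------------------------
# standoff records
# ---------------------------------------------------------------------------

@dataclass
class STEntity:
    id: str
    type: str
    start: int
    end: int
    text: str
    given: bool = False

    def signature(self) -> tuple:
        return (self.start, self.end, self.type, self.given)


@dataclass
class STEvent:
    id: str
    type: str
    trigger: str  # T id
    args: list[tuple[str, str]] = field(default_factory=list)  # (role, T/E id)


@dataclass
class STRelation:
    id: str
    type: str
    args: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class STModifier:
    id: str
    kind: str  # Negation / Speculation
    target: str  # E id


@dataclass
class STEquiv:
    members: frozenset[str]  # T ids
    given: bool = True


@dataclass
class STDocument:
    id: str
    text: str
    entities: dict[str, STEntity] = field(default_factory=dict)
    events: dict[str, STEvent] = field(default_factory=dict)
    relations: dict[str, STRelation] = field(default_factory=dict)
    modifiers: list[STModifier] = field(default_factory=list)
    equivs: list[STEquiv] = field(default_factory=list)


# -- role helpers -----------------------------------------------------------

_ROLE_RE = re.compile(r"^(?P<base>.*?)(?P<num>\d*)$")


def split_role(role: str) -> tuple[str, int]:
    """Split a role as written into (base, occurrence number); "Theme2"→("Theme", 2)."""
    m = _ROLE_RE.match(role)
    base, num = m.group("base"), m.group("num")
    return base, int(num) if num else 1


def _role_with_suffix(base: str, num: int) -> str:
    return base if num == 1 else f"{base}{num}"


def site_primary_role(event: STEvent, role: str) -> tuple[str, str] | None:
    """Resolve a Site-style role to its primary argument in the same event.

    Pairing is by occurrence number: ``SiteK`` pairs with ``ThemeK`` (falling
    back to ``CauseK``), ``CSiteK`` with ``CauseK`` (falling back to
    ``ThemeK``); if neither exists, the unique non-site argument with the same
    number.  Returns (primary role as written, primary target id) or None.
    """
    base, num = split_role(role)
    if base not in ("Site", "CSite"):
        return None
    order = ("Cause", "Theme") if base == "CSite" else ("Theme", "Cause")
    present = dict()
    for r, t in event.args:
        present.setdefault(r, t)
    for primary_base in order:
        r = _role_with_suffix(primary_base, num)
        if r in present:
            return r, present[r]
    same_num = [
        (r, t)
        for r, t in event.args
        if split_role(r)[1] == num and split_role(r)[0] not in ("Site", "CSite")
    ]
    if len(same_num) == 1:
        return same_num[0]
    return None


def edge_type_of_role(role: str) -> str:
    base, _ = split_role(role)
    return "Site" if base == "CSite" else base


# ---------------------------------------------------------------------------
# standoff reading
# ---------------------------------------------------------------------------

def _parse_entity_line(line: str, lineno: int, given: bool, text: str) -> STEntity:
    fields = line.split("\t")
    if len(fields) < 3:
        raise StandoffParseError(f"line {lineno}: entity line needs 3 fields: {line!r}")
    eid, header, literal = fields[0], fields[1], fields[2]
    parts = header.split(" ")
    if ";" in header:
        # discontinuous span: keep the covering interval, preserve the literal
        spans = header.split(" ", 1)[1].split(";")
        etype = parts[0]
        try:
            starts = [int(s.split(" ")[0]) for s in spans]
            ends = [int(s.split(" ")[1]) for s in spans]
        except (ValueError, IndexError):
            raise StandoffParseError(f"line {lineno}: bad offsets: {line!r}") from None
        return STEntity(eid, etype, min(starts), max(ends), literal, given)
    if len(parts) < 3:
        raise StandoffParseError(f"line {lineno}: bad entity header: {line!r}")
    etype, start, end = " ".join(parts[:-2]), parts[-2], parts[-1]
    try:
        start, end = int(start), int(end)
    except ValueError:
        raise StandoffParseError(f"line {lineno}: bad offsets: {line!r}") from None
    if text[start:end] != literal:
        raise IntegrityError(
            f"line {lineno}: entity {eid} text {literal!r} != document slice "
            f"{text[start:end]!r} at {start}..{end}"
        )
    return STEntity(eid, etype, start, end, literal, given)


def _parse_args(spec: str, lineno: int) -> list[tuple[str, str]]:
    args = []
    for chunk in spec.split(" "):
        if not chunk:
            continue
        if ":" not in chunk:
            raise StandoffParseError(f"line {lineno}: bad argument {chunk!r}")
        role, target = chunk.split(":", 1)
        args.append((role, target))
    return args


def read_st_document(doc_id: str, txt: str, a1: str, a2: str) -> STDocument:
    """Parse a standoff triplet into an :class:`STDocument`.

    Every ``T``/``E``/``R``/``M``/``*`` line becomes exactly one record;
    entity offsets are verified against the text.  Malformed lines raise
    :class:`StandoffParseError` with the line number, offset/text mismatches
    raise :class:`IntegrityError`.
    """
    doc = STDocument(id=doc_id, text=txt)
    for given, content in ((True, a1), (False, a2)):
        for lineno, line in enumerate(content.splitlines(), 1):
            if not line.strip():
                continue
            tag = line.split("\t", 1)[0]
            if tag.startswith("T"):
                ent = _parse_entity_line(line, lineno, given, txt)
                if ent.id in doc.entities:
                    raise IntegrityError(f"line {lineno}: duplicate id {ent.id}")
                doc.entities[ent.id] = ent
            elif tag.startswith("E"):
                fields = line.split("\t")
                if len(fields) < 2:
                    raise StandoffParseError(f"line {lineno}: bad event line {line!r}")
                parts = fields[1].split(" ", 1)
                if ":" not in parts[0]:
                    raise StandoffParseError(
                        f"line {lineno}: event head needs Type:Trigger: {line!r}"
                    )
                etype, trigger = parts[0].split(":", 1)
                args = _parse_args(parts[1], lineno) if len(parts) > 1 else []
                doc.events[tag] = STEvent(tag, etype, trigger, args)
            elif tag.startswith("R"):
                fields = line.split("\t")
                parts = fields[1].split(" ")
                doc.relations[tag] = STRelation(
                    tag, parts[0], _parse_args(" ".join(parts[1:]), lineno)
                )
            elif tag.startswith("M"):
                fields = line.split("\t")
                parts = fields[1].split(" ")
                if len(parts) != 2:
                    raise StandoffParseError(f"line {lineno}: bad modifier {line!r}")
                doc.modifiers.append(STModifier(tag, parts[0], parts[1]))
            elif tag == "*":
                fields = line.split("\t")
                parts = fields[1].split(" ")
                if parts[0] != "Equiv":
                    raise StandoffParseError(f"line {lineno}: unknown star line {line!r}")
                doc.equivs.append(STEquiv(frozenset(parts[1:]), given=given))
            else:
                raise StandoffParseError(f"line {lineno}: unknown record {line!r}")
    _check_references(doc)
    return doc


def _check_references(doc: STDocument) -> None:
    known = set(doc.entities) | set(doc.events)
    for ev in doc.events.values():
        if ev.trigger not in doc.entities:
            raise IntegrityError(f"event {ev.id}: unknown trigger {ev.trigger}")
        for role, target in ev.args:
            if target not in known:
                raise IntegrityError(f"event {ev.id}: unknown target {target}")
    for rel in doc.relations.values():
        for role, target in rel.args:
            if target not in known:
                raise IntegrityError(f"relation {rel.id}: unknown target {target}")
    for mod in doc.modifiers:
        if mod.target not in doc.events:
            raise IntegrityError(f"modifier {mod.id}: unknown event {mod.target}")
    for eq in doc.equivs:
        for tid in eq.members:
            if tid not in doc.entities:
                raise IntegrityError(f"Equiv: unknown entity {tid}")


# ---------------------------------------------------------------------------
# standoff writing (deterministic renumbering)
# ---------------------------------------------------------------------------

def write_st_document(doc: STDocument) -> tuple[str, str]:
    """Serialize to (a1, a2) text with deterministic id numbering.

    T records are ordered by (start, end, type) — a1 first, numbering
    continuing into a2 — E records topologically (arguments before the events
    that reference them, ties broken deterministically), then M and R records.
    ``read_st_document ∘ write_st_document`` is the identity up to id
    renumbering.  Dangling references refuse to serialize.
    """
    _check_references(doc)

    a1_entities = sorted(
        (e for e in doc.entities.values() if e.given),
        key=lambda e: (e.start, e.end, e.type),
    )
    a2_entities = sorted(
        (e for e in doc.entities.values() if not e.given),
        key=lambda e: (e.start, e.end, e.type),
    )
    t_number: dict[str, int] = {}
    for i, e in enumerate(a1_entities + a2_entities, 1):
        t_number[e.id] = i

    # topological ordering of events (arguments first)
    def _event_key(ev: STEvent):
        return (
            t_number[ev.trigger],
            ev.type,
            sorted((r, t_number.get(t, 10**6)) for r, t in ev.args),
        )

    remaining = dict(doc.events)
    e_number: dict[str, int] = {}
    ordered_events: list[STEvent] = []
    while remaining:
        ready = [
            ev
            for ev in remaining.values()
            if all(t not in remaining for _, t in ev.args if t.startswith("E"))
        ]
        if not ready:
            raise IntegrityError("event reference cycle detected")
        ev = min(ready, key=_event_key)
        e_number[ev.id] = len(e_number) + 1
        ordered_events.append(ev)
        del remaining[ev.id]

    def _ref(target: str) -> str:
        if target in t_number:
            return f"T{t_number[target]}"
        return f"E{e_number[target]}"

    def _entity_line(e: STEntity) -> str:
        return f"T{t_number[e.id]}\t{e.type} {e.start} {e.end}\t{e.text}"

    a1_lines = [_entity_line(e) for e in a1_entities]
    for eq in sorted(
        (eq for eq in doc.equivs if eq.given),
        key=lambda eq: sorted(t_number[m] for m in eq.members),
    ):
        members = " ".join(f"T{n}" for n in sorted(t_number[m] for m in eq.members))
        a1_lines.append(f"*\tEquiv {members}")

    a2_lines = [_entity_line(e) for e in a2_entities]
    for ev in ordered_events:
        head = f"{ev.type}:{_ref(ev.trigger)}"
        rendered = " ".join(f"{role}:{_ref(t)}" for role, t in ev.args)
        a2_lines.append(f"E{e_number[ev.id]}\t{head}{' ' + rendered if rendered else ''}")
    for i, mod in enumerate(
        sorted(doc.modifiers, key=lambda m: (e_number[m.target], m.kind)), 1
    ):
        a2_lines.append(f"M{i}\t{mod.kind} E{e_number[mod.target]}")
    for i, rel in enumerate(
        sorted(
            doc.relations.values(),
            key=lambda r: (r.type, [(role, _ref(t)) for role, t in r.args]),
        ),
        1,
    ):
        rendered = " ".join(f"{role}:{_ref(t)}" for role, t in rel.args)
        a2_lines.append(f"R{i}\t{rel.type} {rendered}")
    for eq in sorted(
        (eq for eq in doc.equivs if not eq.given),
        key=lambda eq: sorted(t_number[m] for m in eq.members),
    ):
        members = " ".join(f"T{n}" for n in sorted(t_number[m] for m in eq.members))
        a2_lines.append(f"*\tEquiv {members}")

    def _join(lines):
        return "\n".join(lines) + ("\n" if lines else "")

    return _join(a1_lines), _join(a2_lines)


# ---------------------------------------------------------------------------
# equivalence expansion
# ---------------------------------------------------------------------------

@dataclass
class _ExpandedEvent:
    id: str
    type: str
    trigger: str
    args: list[tuple[str, str]]  # (role as written, T id or expanded-event id)
    modifiers: frozenset[str]
    origin: str  # original E id


def _equiv_classes(doc: STDocument) -> dict[str, list[str]]:
    classes: dict[str, list[str]] = {}
    merged: list[set[str]] = []
    for eq in doc.equivs:
        hit = [g for g in merged if g & eq.members]
        group = set(eq.members)
        for g in hit:
            group |= g
            merged.remove(g)
        merged.append(group)
    for g in merged:
        members = sorted(g, key=lambda t: (doc.entities[t].start, doc.entities[t].end, t))
        for t in g:
            classes[t] = members
    return classes


def expand_events(doc: STDocument) -> list[_ExpandedEvent]:
    """Expand equivalence annotation into individual event instances.

    For every argument pointing into an equivalence group, one event copy is
    produced per group member; copies of events referenced by other events
    propagate upward (children are expanded first).  Modifiers are duplicated
    onto every copy.
    """
    classes = _equiv_classes(doc)
    mods: dict[str, set[str]] = {}
    for m in doc.modifiers:
        mods.setdefault(m.target, set()).add(m.kind.lower())

    copies: dict[str, list[_ExpandedEvent]] = {}
    remaining = dict(doc.events)
    result: list[_ExpandedEvent] = []
    counter = itertools.count()
    while remaining:
        ready = [
            ev
            for ev in remaining.values()
            if all(t not in remaining for _, t in ev.args if t in doc.events)
        ]
        if not ready:
            raise IntegrityError("event reference cycle detected")
        for ev in sorted(ready, key=lambda e: e.id):
            alternatives: list[list[str]] = []
            for role, target in ev.args:
                if target in doc.events:
                    alternatives.append([c.id for c in copies[target]])
                elif target in classes:
                    alternatives.append(classes[target])
                else:
                    alternatives.append([target])
            out = []
            for combo in itertools.product(*alternatives) if ev.args else [()]:
                out.append(
                    _ExpandedEvent(
                        id=f"x{next(counter)}",
                        type=ev.type,
                        trigger=ev.trigger,
                        args=[(r, t) for (r, _), t in zip(ev.args, combo)],
                        modifiers=frozenset(mods.get(ev.id, set())),
                        origin=ev.id,
                    )
                )
            copies[ev.id] = out
            result.extend(out)
            del remaining[ev.id]
    return result


# ---------------------------------------------------------------------------
# standoff -> graph
# ---------------------------------------------------------------------------

@dataclass
class SentenceParse:
    """Tokenisation and dependency parse of one sentence, with its document offset."""

    id: str
    offset: int
    text: str
    tokens: list[Token] = field(default_factory=list)
    dependencies: list[Dependency] = field(default_factory=list)


def st_to_graph(
    doc: STDocument, parses: list[SentenceParse], set_label: str | None = None
) -> Document:
    """Convert a standoff document to the interaction-graph representation.

    One trigger node is created per event instance (after equivalence
    expansion), with the ``event`` attribute set; arguments become directed
    edges from the trigger.  Site arguments yield a Site edge with ``siteOf``
    naming the primary argument's edge plus a SiteParent edge from the site
    entity to the primary argument's target.  Relations with an event-trigger
    endpoint are skipped with a warning; arguments crossing sentence
    boundaries are kept as document-level edges.
    """
    sentences = []
    offsets = []
    for p in parses:
        sentences.append(
            SentenceGraph(
                id=p.id,
                text=p.text,
                tokens=list(p.tokens),
                dependencies=list(p.dependencies),
            )
        )
        offsets.append(p.offset)
    out = Document(
        id=doc.id,
        text=doc.text,
        sentences=sentences,
        sentence_offsets=offsets,
        set_label=set_label,
    )

    def _sentence_for(start: int, end: int) -> int:
        for i, (s, off) in enumerate(zip(sentences, offsets)):
            if off <= start and end <= off + len(s.text):
                return i
        raise IntegrityError(
            f"{doc.id}: span {start}..{end} is not contained in any sentence"
        )

    node_counter = itertools.count()
    edge_counter = itertools.count()

    def _make_node(ent: STEntity, *, event: bool, modifiers=frozenset()) -> EntityNode:
        si = _sentence_for(ent.start, ent.end)
        sent, off = sentences[si], offsets[si]
        start, end = ent.start - off, ent.end - off
        node = EntityNode(
            id=f"{doc.id}.e{next(node_counter)}",
            type=ent.type,
            start=start,
            end=end,
            text=ent.text,
            head=resolve_head_token(start, end, sent).id,
            given=ent.given,
            event=event,
            modifiers=frozenset(modifiers),
        )
        sent.entities.append(node)
        return node

    def _add_edge(edge: InteractionEdge, src_node: EntityNode, tgt_node: EntityNode):
        s1 = out.sentence_of_entity(src_node.id)
        s2 = out.sentence_of_entity(tgt_node.id)
        if s1 is s2:
            s1.interactions.append(edge)
        else:
            out.cross_edges.append(edge)

    expanded = expand_events(doc)
    trigger_tids = {doc.events[x.origin].trigger for x in expanded}

    # shared nodes for every T that is not an event trigger
    t_nodes: dict[str, EntityNode] = {}
    for tid, ent in doc.entities.items():
        if tid not in trigger_tids:
            t_nodes[tid] = _make_node(ent, event=False)

    # one trigger node per expanded event instance
    ev_nodes: dict[str, EntityNode] = {}
    for x in expanded:
        ev_nodes[x.id] = _make_node(
            doc.entities[x.trigger], event=True, modifiers=x.modifiers
        )

    def _target_node(target: str) -> EntityNode:
        if target in ev_nodes:
            return ev_nodes[target]
        if target in t_nodes:
            return t_nodes[target]
        # an argument referencing an event trigger T directly: bind to the
        # first event instance on that trigger
        cands = [ev_nodes[x.id] for x in expanded if x.trigger == target]
        if cands:
            logger.warning(
                "%s: argument references trigger %s directly; using its first event",
                doc.id,
                target,
            )
            return cands[0]
        raise IntegrityError(f"{doc.id}: unresolvable argument target {target}")

    for x in expanded:
        trig = ev_nodes[x.id]
        pseudo = STEvent(x.id, x.type, x.trigger, x.args)
        edge_of_role: dict[str, InteractionEdge] = {}
        site_args = []
        for role, target in x.args:
            base, _ = split_role(role)
            if base in ("Site", "CSite"):
                site_args.append((role, target))
                continue
            edge = InteractionEdge(
                id=f"{doc.id}.i{next(edge_counter)}",
                type=edge_type_of_role(role),
                source=trig.id,
                target=_target_node(target).id,
                directed=True,
                event=True,
            )
            edge_of_role[role] = edge
            _add_edge(edge, trig, out.entity_by_id(edge.target))
        group_args = [e.id for e in edge_of_role.values()]
        for role, target in site_args:
            primary = site_primary_role(pseudo, role)
            site_node = _target_node(target)
            edge = InteractionEdge(
                id=f"{doc.id}.i{next(edge_counter)}",
                type="Site",
                source=trig.id,
                target=site_node.id,
                directed=True,
                event=True,
                site_of=edge_of_role[primary[0]].id if primary else None,
            )
            _add_edge(edge, trig, site_node)
            group_args.append(edge.id)
            if primary is not None:
                primary_target = out.entity_by_id(edge_of_role[primary[0]].target)
                sp = InteractionEdge(
                    id=f"{doc.id}.i{next(edge_counter)}",
                    type=SITEPARENT_TYPE,
                    source=site_node.id,
                    target=primary_target.id,
                    directed=True,
                    event=False,
                    extra={"e1Role": "Arg1", "e2Role": "Arg2"},
                )
                _add_edge(sp, site_node, primary_target)
        out.events.append(
            EventGroup(
                id=x.id, trigger=trig.id, args=tuple(group_args), modifiers=x.modifiers
            )
        )

    for rel in doc.relations.values():
        endpoint_nodes = []
        skip = False
        for role, target in rel.args:
            if target in trigger_tids or target in doc.events:
                logger.warning(
                    "%s: relation %s has an event-trigger endpoint (%s); skipped",
                    doc.id,
                    rel.id,
                    target,
                )
                skip = True
                break
            endpoint_nodes.append((role, t_nodes[target]))
        if skip or len(endpoint_nodes) != 2:
            continue
        (r1, n1), (r2, n2) = endpoint_nodes
        edge = InteractionEdge(
            id=f"{doc.id}.i{next(edge_counter)}",
            type=rel.type,
            source=n1.id,
            target=n2.id,
            directed=True,
            event=False,
            extra={"e1Role": r1, "e2Role": r2},
        )
        _add_edge(edge, n1, n2)

    classes = _equiv_classes(doc)
    seen_classes = set()
    for members in classes.values():
        key = tuple(members)
        if key in seen_classes:
            continue
        seen_classes.add(key)
        node_ids = frozenset(t_nodes[t].id for t in members if t in t_nodes)
        if len(node_ids) >= 2:
            out.equivs.append(node_ids)
    return out


# ---------------------------------------------------------------------------
# graph -> standoff
# ---------------------------------------------------------------------------

class StructuralValidityError(ValueError):
    """A predicted event violates the annotation scheme (strict mode only)."""


def graph_to_st(
    doc: Document, scheme: AnnotationScheme | None = None, strict: bool = False
) -> STDocument:
    """Convert an (unmerged) graph document back to a standoff document.

    Requires event memberships to be enumerated (``doc.events``).  Site edges
    are re-attached to their primary argument — via ``siteOf`` when present,
    otherwise via SiteParent linkage, attaching each site to at most one
    primary (the one whose target occurs first in document order) and
    discarding a Site if the primary already has one.  Events that become
    identical through these removals are deduplicated recursively until none
    remain; events referencing removed events are removed recursively.  With a
    scheme, structurally invalid events are removed (or raise if ``strict``).
    """
    nodes = {e.id: e for e in doc.all_entities()}
    edges = {e.id: e for e in doc.all_edges()}
    node_doc_span = {e.id: doc.doc_span(e) for e in nodes.values()}

    def _is_site_edge(edge: InteractionEdge) -> bool:
        return edge.type == "Site" or edge.site_of is not None

    # --- per-group Site resolution -------------------------------------
    resolved: dict[str, list[tuple[InteractionEdge, InteractionEdge | None]]] = {}
    for g in doc.events:
        plain = [edges[a] for a in g.args if not _is_site_edge(edges[a])]
        sites = [edges[a] for a in g.args if _is_site_edge(edges[a])]
        out_args: list[tuple[InteractionEdge, InteractionEdge | None]] = [
            (e, None) for e in plain
        ]
        taken_primaries: set[str] = set()
        for se in sorted(sites, key=lambda e: node_doc_span[e.target]):
            primary = None
            if se.site_of is not None and se.site_of in {e.id for e in plain}:
                primary = edges[se.site_of]
            else:
                parents = {
                    sp.target
                    for sp in doc.all_edges()
                    if sp.type == SITEPARENT_TYPE and sp.source == se.target
                }
                allowed_roles = None
                if scheme is not None:
                    d = scheme.events.get(nodes[g.trigger].type)
                    if d is not None and se.type in d.arguments:
                        allowed_roles = d.arguments[se.type].site_primary_roles
                cands = [
                    e
                    for e in plain
                    if e.target in parents
                    and (allowed_roles is None or e.type in allowed_roles)
                ]
                if cands:
                    # map to at most one primary: first target in document order
                    primary = min(cands, key=lambda e: (node_doc_span[e.target], e.id))
            if primary is None:
                logger.info("%s: site edge %s has no primary argument; dropped", doc.id, se.id)
                continue
            if primary.id in taken_primaries:
                logger.info(
                    "%s: primary %s already has a Site; dropping %s", doc.id, primary.id, se.id
                )
                continue
            taken_primaries.add(primary.id)
            out_args.append((se, primary))
        resolved[g.id] = out_args

    # --- drop groups whose event-valued args have no live target event --
    groups = {g.id: g for g in doc.events}
    groups_of_node: dict[str, list[str]] = {}
    for g in doc.events:
        groups_of_node.setdefault(g.trigger, []).append(g.id)

    def _is_event_node(n: EntityNode) -> bool:
        if scheme is not None and n.type in scheme.events:
            return True
        return n.event or bool(groups_of_node.get(n.id))

    removal_log: list[str] = []
    changed = True
    while changed:
        changed = False
        for gid in list(groups):
            g = groups[gid]
            for edge, _ in resolved[gid]:
                tgt = nodes[edge.target]
                if _is_event_node(tgt) and not any(
                    t in groups for t in groups_of_node.get(tgt.id, [])
                ):
                    removal_log.append(
                        f"{gid}: argument {edge.type} references a removed event node {tgt.id}"
                    )
                    del groups[gid]
                    changed = True
                    break

    # --- structural validation under the scheme ------------------------
    if scheme is not None:
        for gid in list(groups):
            g = groups[gid]
            trig = nodes[g.trigger]
            args = [
                (
                    edge.type,
                    nodes[edge.target].type,
                    primary.type if primary is not None else None,
                )
                for edge, primary in resolved[gid]
            ]
            if not is_valid_event_structure(scheme, trig.type, args):
                msg = f"{gid}: {trig.type} with args {sorted(a[:2] for a in args)} violates the scheme"
                if strict:
                    raise StructuralValidityError(msg)
                removal_log.append(msg)
                del groups[gid]
        # recursive removal of referencers
        changed = True
        while changed:
            changed = False
            for gid in list(groups):
                for edge, _ in resolved[gid]:
                    tgt = nodes[edge.target]
                    if _is_event_node(tgt) and not any(
                        t in groups for t in groups_of_node.get(tgt.id, [])
                    ):
                        removal_log.append(f"{gid}: references removed event; removed")
                        del groups[gid]
                        changed = True
                        break

    # --- build ST records ------------------------------------------------
    st = STDocument(id=doc.id, text=doc.text)

    t_of_sig: dict[tuple, str] = {}
    t_of_node: dict[str, str] = {}
    t_counter = itertools.count(1)

    def _t_for(node: EntityNode) -> str:
        start, end = node_doc_span[node.id]
        sig = (start, end, node.type, node.given)
        if sig not in t_of_sig:
            tid = f"Tp{next(t_counter)}"
            t_of_sig[sig] = tid
            st.entities[tid] = STEntity(
                tid, node.type, start, end, doc.text[start:end], node.given
            )
        t_of_node[node.id] = t_of_sig[sig]
        return t_of_sig[sig]

    for node in nodes.values():
        if node.given:
            _t_for(node)

    # cartesian expansion over event-valued arguments
    e_counter = itertools.count(1)
    st_events: dict[str, STEvent] = {}
    ev_mods: dict[str, frozenset[str]] = {}
    copies_of_group: dict[str, list[str]] = {}
    ordered = []
    pending = dict(groups)
    while pending:
        ready = []
        for gid, g in pending.items():
            ok = True
            for edge, _ in resolved[gid]:
                tgt = nodes[edge.target]
                if _is_event_node(tgt):
                    if any(t in pending for t in groups_of_node.get(tgt.id, [])):
                        ok = False
                        break
            if ok:
                ready.append(gid)
        if not ready:
            raise IntegrityError(f"{doc.id}: event nesting cycle")
        for gid in sorted(ready):
            ordered.append(gid)
            del pending[gid]

    for gid in ordered:
        g = groups[gid]
        trig_t = _t_for(nodes[g.trigger])
        plain = [(e, p) for e, p in resolved[gid] if p is None and not _is_site_edge(e)]
        sites = [(e, p) for e, p in resolved[gid] if p is not None]
        alternatives: list[list[str]] = []
        for edge, _ in plain:
            tgt = nodes[edge.target]
            if _is_event_node(tgt):
                alternatives.append(
                    [
                        c
                        for t in groups_of_node.get(tgt.id, [])
                        if t in groups
                        for c in copies_of_group[t]
                    ]
                )
            else:
                alternatives.append([_t_for(tgt)])
        out_ids = []
        for combo in itertools.product(*alternatives) if plain else [()]:
            # deterministic role numbering: repeats ordered by target position
            def _pos(ref: str, edge: InteractionEdge):
                if ref in st.entities:
                    e = st.entities[ref]
                    return (e.start, e.end, ref)
                child = st_events[ref]
                t = st.entities[child.trigger]
                return (t.start, t.end, ref)

            items = sorted(
                zip((e for e, _ in plain), combo),
                key=lambda it: (it[0].type, _pos(it[1], it[0])),
            )
            suffix_of_edge: dict[str, str] = {}
            counts: dict[str, int] = {}
            args: list[tuple[str, str]] = []
            for edge, ref in items:
                counts[edge.type] = counts.get(edge.type, 0) + 1
                role = _role_with_suffix(edge.type, counts[edge.type])
                suffix_of_edge[edge.id] = str(counts[edge.type])
                args.append((role, ref))
            for se, primary in sorted(
                sites, key=lambda it: (node_doc_span[it[0].target], it[0].id)
            ):
                num = int(suffix_of_edge.get(primary.id, "1"))
                base = "CSite" if primary.type == "Cause" else "Site"
                args.append((_role_with_suffix(base, num), _t_for(nodes[se.target])))
            eid = f"Ep{next(e_counter)}"
            st_events[eid] = STEvent(eid, nodes[g.trigger].type, trig_t, args)
            ev_mods[eid] = g.modifiers
            out_ids.append(eid)
        copies_of_group[gid] = out_ids

    # --- equivalence collapse + duplicate removal to fixpoint ------------
    repr_of_t: dict[str, str] = {}
    for group in doc.equivs:
        members = sorted(
            (t_of_node[n] for n in group if n in t_of_node),
            key=lambda t: (st.entities[t].start, st.entities[t].end, t),
        )
        for m in members:
            repr_of_t[m] = members[0]

    def _sig(eid: str, memo: dict[str, tuple]) -> tuple:
        if eid in memo:
            return memo[eid]
        ev = st_events[eid]
        parts = []
        for role, target in ev.args:
            if target in st_events:
                parts.append((split_role(role)[0], _sig(target, memo)))
            else:
                t = repr_of_t.get(target, target)
                e = st.entities[t]
                parts.append((split_role(role)[0], ("T", e.start, e.end, e.type)))
        trig = st.entities[ev.trigger]
        sig = (ev.type, trig.start, trig.end, tuple(sorted(parts)))
        memo[eid] = sig
        return sig

    def _raw_key(eid: str, memo: dict[str, tuple]) -> tuple:
        # id-free ordering of duplicate copies: earliest actual targets win
        parts = []
        for role, target in st_events[eid].args:
            if target in st.entities:
                e = st.entities[target]
                parts.append((split_role(role)[0], (0, e.start, e.end, e.type)))
            else:
                parts.append((split_role(role)[0], (1,) + _sig(target, memo)))
        return tuple(sorted(parts))

    while True:
        memo: dict[str, tuple] = {}
        by_sig: dict[tuple, list[str]] = {}
        for eid in st_events:
            by_sig.setdefault(_sig(eid, memo), []).append(eid)
        remap: dict[str, str] = {}
        for sig, ids in by_sig.items():
            if len(ids) > 1:
                survivor = min(
                    ids, key=lambda i: (_raw_key(i, memo), i)
                )
                for other in ids:
                    if other != survivor:
                        remap[other] = survivor
        if not remap:
            break
        for eid in remap:
            ev_mods[remap[eid]] = ev_mods[remap[eid]] | ev_mods[eid]
            del st_events[eid]
        for ev in st_events.values():
            ev.args = [(r, remap.get(t, t)) for r, t in ev.args]

    # --- relations, modifiers, final entity selection --------------------
    rel_counter = itertools.count(1)
    event_edge_ids = {a for g in doc.events for a in g.args}
    for edge in doc.all_edges():
        if edge.event or edge.type == SITEPARENT_TYPE or edge.id in event_edge_ids:
            continue
        src, tgt = nodes[edge.source], nodes[edge.target]
        if _is_event_node(src) or _is_event_node(tgt):
            logger.warning(
                "%s: relation edge %s touches an event trigger; skipped on write",
                doc.id,
                edge.id,
            )
            continue
        rid = f"Rp{next(rel_counter)}"
        st.relations[rid] = STRelation(
            rid,
            edge.type,
            [
                (edge.extra.get("e1Role", "Arg1"), _t_for(src)),
                (edge.extra.get("e2Role", "Arg2"), _t_for(tgt)),
            ],
        )

    for i, (eid, kinds) in enumerate(sorted(ev_mods.items())):
        if eid not in st_events:
            continue
        for kind in sorted(kinds):
            st.modifiers.append(STModifier(f"Mp{len(st.modifiers) + 1}", kind.capitalize(), eid))

    referenced: set[str] = set()
    for ev in st_events.values():
        referenced.add(ev.trigger)
        referenced.update(t for _, t in ev.args if t in st.entities)
    for rel in st.relations.values():
        referenced.update(t for _, t in rel.args if t in st.entities)
    equiv_members: set[str] = set()
    equiv_out = []
    for group in doc.equivs:
        members = {t_of_node[n] for n in group if n in t_of_node}
        given = all(st.entities[m].given for m in members)
        if given and len(members) >= 2:
            equiv_out.append(STEquiv(frozenset(members), given=True))
            equiv_members.update(members)
    st.equivs = equiv_out

    st.entities = {
        tid: e
        for tid, e in st.entities.items()
        if e.given or tid in referenced
    }
    st.events = st_events
    if removal_log:
        doc.extra.setdefault("conversion_removals", str(len(removal_log)))
    return st


# ---------------------------------------------------------------------------
# validation and repair of standoff documents
# ---------------------------------------------------------------------------

def _event_arg_views(
    doc: STDocument, ev: STEvent
) -> list[tuple[str, str, str | None]]:
    """(role base mapped to edge type, target type, site primary role) per arg."""
    views = []
    for role, target in ev.args:
        if target in doc.entities:
            ttype = doc.entities[target].type
        else:
            ttype = doc.events[target].type
        primary = site_primary_role(ev, role)
        views.append(
            (
                edge_type_of_role(role),
                ttype,
                edge_type_of_role(primary[0]) if primary else None,
            )
        )
    return views


def validate_and_repair(
    doc: STDocument, scheme: AnnotationScheme
) -> tuple[STDocument, list[str]]:
    """Deterministically repair a standoff document until it validates.

    Per invalid event, in order: (1) if one argument is invalid and one
    required argument is missing, rename the invalid argument's role to the
    missing role; (2) otherwise remove the invalid argument; (3) if the event
    still cannot be made valid, remove it.  Finally all events pointing to
    removed events are removed, recursively.  Always returns a document that
    validates cleanly; the log records every applied repair.
    """
    out = STDocument(
        id=doc.id,
        text=doc.text,
        entities={k: replace(v) for k, v in doc.entities.items()},
        events={k: replace(v, args=list(v.args)) for k, v in doc.events.items()},
        relations={k: replace(v, args=list(v.args)) for k, v in doc.relations.items()},
        modifiers=[replace(m) for m in doc.modifiers],
        equivs=[replace(e) for e in doc.equivs],
    )
    log: list[str] = []
    removed: set[str] = set()

    def _target_type(target: str) -> str:
        return (
            out.entities[target].type
            if target in out.entities
            else out.events[target].type
        )

    def _constraint_roles(d):
        return set(d.arguments)

    for eid in sorted(out.events, key=lambda e: (len(e), e)):
        ev = out.events[eid]
        d = scheme.events.get(ev.type)
        if d is None:
            log.append(f"{eid}: unknown event type {ev.type}; event removed")
            removed.add(eid)
            continue
        for _ in range(len(ev.args) + 2):  # bounded repair loop
            views = _event_arg_views(out, ev)
            if is_valid_event_structure(scheme, ev.type, views):
                break
            # classify arguments
            invalid_idx: list[int] = []
            counts: dict[str, int] = {}
            for i, (etype, ttype, primary) in enumerate(views):
                c = d.arguments.get(etype)
                if c is None or ttype not in c.target_types:
                    invalid_idx.append(i)
                    continue
                if c.site_primary_roles is not None and primary not in c.site_primary_roles:
                    invalid_idx.append(i)
                    continue
                counts[etype] = counts.get(etype, 0) + 1
            for role, c in d.arguments.items():
                n = counts.get(role, 0)
                while n > c.max:  # over-max repeats are invalid arguments too
                    # last occurrence of that role, not already marked
                    for i in reversed(range(len(views))):
                        if views[i][0] == role and i not in invalid_idx:
                            invalid_idx.append(i)
                            break
                    n -= 1
            missing = sorted(
                role
                for role, c in d.arguments.items()
                if counts.get(role, 0) < c.min
            )
            if invalid_idx and missing:
                i = min(invalid_idx)
                old_role = ev.args[i][0]
                _, num = split_role(old_role)
                new_role = _role_with_suffix(missing[0], 1 if counts.get(missing[0], 0) == 0 else counts[missing[0]] + 1)
                ev.args[i] = (new_role, ev.args[i][1])
                log.append(f"{eid}: argument {old_role} renamed to {new_role}")
            elif invalid_idx:
                i = min(invalid_idx)
                role, target = ev.args.pop(i)
                log.append(f"{eid}: invalid argument {role}:{target} removed")
            else:
                log.append(f"{eid}: structurally invalid; event removed")
                removed.add(eid)
                break
        else:
            log.append(f"{eid}: could not be repaired; event removed")
            removed.add(eid)
        if eid not in removed:
            views = _event_arg_views(out, ev)
            if not is_valid_event_structure(scheme, ev.type, views):
                log.append(f"{eid}: still invalid after repair; event removed")
                removed.add(eid)

    # recursive removal of events referencing removed events
    changed = True
    while changed:
        changed = False
        for eid, ev in list(out.events.items()):
            if eid in removed:
                continue
            if any(t in removed for _, t in ev.args):
                removed.add(eid)
                log.append(f"{eid}: referenced a removed event; removed recursively")
                changed = True

    for eid in removed:
        out.events.pop(eid, None)
    out.modifiers = [m for m in out.modifiers if m.target in out.events]
    out.relations = {
        rid: r
        for rid, r in out.relations.items()
        if all(t in out.entities or t in out.events for _, t in r.args)
    }
    # drop now-unreferenced predicted entities
    referenced = {ev.trigger for ev in out.events.values()}
    for ev in out.events.values():
        referenced.update(t for _, t in ev.args)
    for r in out.relations.values():
        referenced.update(t for _, t in r.args)
    out.entities = {
        tid: e for tid, e in out.entities.items() if e.given or tid in referenced
    }
    out.equivs = [
        e for e in out.equivs if all(m in out.entities for m in e.members)
    ]
    return out, log


def validate_st_document(doc: STDocument, scheme: AnnotationScheme) -> list[str]:
    """Scheme-validity findings for a standoff document (empty iff valid)."""
    findings = []
    for eid, ev in doc.events.items():
        d = scheme.events.get(ev.type)
        if d is None:
            findings.append(f"{eid}: unknown event type {ev.type}")
            continue
        if doc.entities[ev.trigger].type != ev.type:
            findings.append(f"{eid}: trigger type mismatch")
        if not is_valid_event_structure(scheme, ev.type, _event_arg_views(doc, ev)):
            findings.append(f"{eid}: invalid event structure")
    return findings


# Interaction XML lives in its own module; re-exported here as part of the
# serialization surface.
from .ixml import read_interaction_xml, write_interaction_xml  # noqa: E402,F401
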