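"""Deterministic induction of an annotation scheme from an annotated corpus.

Every event corpus comes with implicit annotation rules: which node types are
plain entities, which are events, which argument roles an event type may take
and how many, which node types can carry negation/speculation modifiers, and
which types must be predicted at all (versus being given as input).  This
module learns those rules by a single rule-based pass over a fully annotated
corpus and answers the structural-validity queries (is this edge licensed? is
this candidate argument set a valid event?) that drive candidate filtering in
edge detection and unmerging.

The learned constraints are observed extremes: per-role and overall argument
counts are the [min, max] seen over all event instances, so every gold event
in the learning corpus is valid under the learned scheme by construction.  A
scheme learned this way can be stricter than a corpus's official guidelines
(it only knows what the data realizes), which is accepted behaviour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .graph import Corpus, Document

#: edge types carrying structural plumbing rather than event arguments
SITEPARENT_TYPE = "SiteParent"


@dataclass(frozen=True)
class ArgumentConstraint:
    role: str
    min: int
    max: int
    target_types: frozenset[str]
    #: for Site-like roles: roles observed as the primary argument; None for
    #: ordinary roles
    site_primary_roles: frozenset[str] | None = None


@dataclass(frozen=True)
class EventDefinition:
    type: str
    overall_min: int
    overall_max: int
    arguments: dict[str, ArgumentConstraint] = field(default_factory=dict)

    def __hash__(self):  # dict field; identity by content via serialization
        return hash((self.type, self.overall_min, self.overall_max,
                     tuple(sorted(self.arguments))))


@dataclass(frozen=True)
class RelationDefinition:
    type: str
    directed: bool
    end1_role: str
    end2_role: str
    end1_types: frozenset[str]
    end2_types: frozenset[str]


@dataclass
class AnnotationScheme:
    entity_types: frozenset[str] = frozenset()
    events: dict[str, EventDefinition] = field(default_factory=dict)
    relations: dict[str, RelationDefinition] = field(default_factory=dict)
    modifier_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    target_entity_types: frozenset[str] = frozenset()
    target_edge_types: frozenset[str] = frozenset()

    def node_types(self) -> frozenset[str]:
        return self.entity_types | frozenset(self.events)

    def edge_types(self) -> frozenset[str]:
        roles = {r for d in self.events.values() for r in d.arguments}
        return frozenset(roles) | frozenset(self.relations)

    def is_event_type(self, t: str) -> bool:
        return t in self.events

    def __eq__(self, other):
        if not isinstance(other, AnnotationScheme):
            return NotImplemented
        return serialize_scheme(self) == serialize_scheme(other)


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def learn_scheme(corpus: Corpus | list[Document]) -> AnnotationScheme:
    """Induce the annotation scheme from a fully annotated corpus.

    Deterministic and invariant to document order.  Node types with the
    ``event`` attribute or with outgoing edges are event types (the attribute
    wins, so zero-argument event types are not mistaken for entities); the
    rest are entities.  Per event type, per-role and overall argument-count
    intervals are the observed extremes over all event instances.  Edges never
    grouped into an event define binary relations.  An unannotated corpus
    yields an empty scheme.
    """
    docs = corpus.documents if isinstance(corpus, Corpus) else list(corpus)
    docs = sorted(docs, key=lambda d: d.id)

    has_event_attr: set[str] = set()
    has_outgoing: set[str] = set()
    node_types: set[str] = set()
    target_node_types: set[str] = set()
    target_edge_types: set[str] = set()
    modifier_targets: dict[str, set[str]] = {}

    # accumulated per event type: list of per-instance role->count maps
    instances: dict[str, list[dict[str, int]]] = {}
    role_targets: dict[tuple[str, str], set[str]] = {}
    site_primaries: dict[tuple[str, str], set[str]] = {}
    # relation observations: type -> (directed, roles, end1 types, end2 types)
    rel_obs: dict[str, dict] = {}

    for doc in docs:
        nodes = {e.id: e for e in doc.all_entities()}
        edges = {e.id: e for e in doc.all_edges()}
        event_edge_ids = {aid for g in doc.events for aid in g.args}

        for e in nodes.values():
            node_types.add(e.type)
            if e.event:
                has_event_attr.add(e.type)
            if not e.given:
                target_node_types.add(e.type)
            for kind in e.modifiers:
                modifier_targets.setdefault(kind, set()).add(e.type)
        for edge in edges.values():
            # only event-argument edges make their source an event trigger;
            # outgoing relations (SiteParent from a site entity, coreference
            # from an anaphora) leave the source an entity
            if edge.event:
                has_outgoing.add(nodes[edge.source].type)
            if not edge.given:
                target_edge_types.add(edge.type)

        for g in doc.events:
            trig = nodes[g.trigger]
            counts: dict[str, int] = {}
            for aid in g.args:
                edge = edges[aid]
                role = edge.type
                counts[role] = counts.get(role, 0) + 1
                role_targets.setdefault((trig.type, role), set()).add(
                    nodes[edge.target].type
                )
                if edge.site_of is not None:
                    primary = edges.get(edge.site_of)
                    if primary is not None:
                        site_primaries.setdefault((trig.type, role), set()).add(
                            primary.type
                        )
            instances.setdefault(trig.type, []).append(counts)
            for kind in g.modifiers:
                modifier_targets.setdefault(kind, set()).add(trig.type)

        for edge in edges.values():
            if edge.id in event_edge_ids:
                continue
            src_t = nodes[edge.source].type
            tgt_t = nodes[edge.target].type
            obs = rel_obs.setdefault(
                edge.type,
                {
                    "directed": edge.directed,
                    "e1_role": edge.extra.get("e1Role", "Arg1"),
                    "e2_role": edge.extra.get("e2Role", "Arg2"),
                    "end1": set(),
                    "end2": set(),
                },
            )
            obs["directed"] = obs["directed"] and edge.directed
            obs["end1"].add(src_t)
            obs["end2"].add(tgt_t)

    event_types = (has_event_attr | has_outgoing) & node_types
    entity_types = node_types - event_types

    events: dict[str, EventDefinition] = {}
    for etype in sorted(event_types):
        insts = instances.get(etype, [])
        roles = sorted({r for c in insts for r in c})
        if not insts:
            # seen only as a node type with the event attribute, never with an
            # instance: a zero-argument event type at best
            events[etype] = EventDefinition(etype, 0, 0, {})
            continue
        args: dict[str, ArgumentConstraint] = {}
        for role in roles:
            counts = [c.get(role, 0) for c in insts]
            args[role] = ArgumentConstraint(
                role=role,
                min=min(counts),
                max=max(counts),
                target_types=frozenset(role_targets.get((etype, role), set())),
                site_primary_roles=(
                    frozenset(site_primaries[(etype, role)])
                    if (etype, role) in site_primaries
                    else None
                ),
            )
        totals = [sum(c.values()) for c in insts]
        events[etype] = EventDefinition(etype, min(totals), max(totals), args)

    relations: dict[str, RelationDefinition] = {}
    for rtype in sorted(rel_obs):
        obs = rel_obs[rtype]
        end1, end2 = set(obs["end1"]), set(obs["end2"])
        if not obs["directed"]:
            end1 = end2 = end1 | end2
        relations[rtype] = RelationDefinition(
            type=rtype,
            directed=obs["directed"],
            end1_role=obs["e1_role"],
            end2_role=obs["e2_role"],
            end1_types=frozenset(end1),
            end2_types=frozenset(end2),
        )

    return AnnotationScheme(
        entity_types=frozenset(entity_types),
        events=events,
        relations=relations,
        modifier_targets={k: frozenset(v) for k, v in sorted(modifier_targets.items())},
        target_entity_types=frozenset(target_node_types & node_types),
        target_edge_types=frozenset(target_edge_types),
    )


# ---------------------------------------------------------------------------
# validity queries
# ---------------------------------------------------------------------------

def is_valid_edge(
    scheme: AnnotationScheme, source_type: str, target_type: str, edge_type: str
) -> bool:
    """True iff some event or relation definition licenses this edge.

    Direction is respected: for event arguments the source must be the event
    type; for directed relations end1/end2 order is enforced, for undirected
    ones either orientation passes.
    """
    d = scheme.events.get(source_type)
    if d is not None:
        c = d.arguments.get(edge_type)
        if c is not None and c.max > 0 and target_type in c.target_types:
            return True
    r = scheme.relations.get(edge_type)
    if r is not None:
        if source_type in r.end1_types and target_type in r.end2_types:
            return True
        if not r.directed and source_type in r.end2_types and target_type in r.end1_types:
            return True
    return False


def is_valid_event_structure(
    scheme: AnnotationScheme,
    trigger_type: str,
    args: list[tuple[str, str, str | None]],
) -> bool:
    """Validate a candidate event against the learned constraints.

    ``args`` lists (role, target node type, primary-argument role or None for
    non-Site roles).  Valid iff the trigger type is an event type, every role
    is known with a licensed target type, per-role counts lie in the role's
    [min, max], the total count lies in the overall [min, max], and every
    Site-like argument has a licensed primary role.
    """
    d = scheme.events.get(trigger_type)
    if d is None:
        return False
    counts: dict[str, int] = {}
    for role, target_type, primary_role in args:
        c = d.arguments.get(role)
        if c is None or target_type not in c.target_types:
            return False
        if c.site_primary_roles is not None and primary_role not in c.site_primary_roles:
            return False
        counts[role] = counts.get(role, 0) + 1
    for role, c in d.arguments.items():
        n = counts.get(role, 0)
        if not (c.min <= n <= c.max):
            return False
    total = sum(counts.values())
    return d.overall_min <= total <= d.overall_max


# ---------------------------------------------------------------------------
# serialization (the "model file" scheme component)
# ---------------------------------------------------------------------------

_HEADER = "# eventex annotation scheme v1"


def _fmt_types(types: frozenset[str]) -> str:
    return ", ".join(sorted(types))


def _fmt_constraint(c: ArgumentConstraint) -> str:
    parts = [c.role]
    if c.site_primary_roles is not None:
        parts.append("{" + ",".join(sorted(c.site_primary_roles)) + "}")
    parts.append(f"[{c.min},{c.max}]")
    if c.target_types:
        parts.append(_fmt_types(c.target_types))
    return " ".join(parts)


_CONSTRAINT_RE = re.compile(
    r"^(?P<role>\S+?)"
    r"(?: \{(?P<prim>[^}]*)\})?"
    r" \[(?P<min>\d+),(?P<max>\d+)\]"
    r"(?: (?P<targets>.+))?$"
)


def serialize_scheme(scheme: AnnotationScheme) -> str:
    """Human-readable, diffable, lossless text form: one row per definition."""
    lines = [_HEADER]
    for t in sorted(scheme.entity_types):
        lines.append(f"ENTITY\t{t}")
    for t in sorted(scheme.events):
        d = scheme.events[t]
        args = " / ".join(_fmt_constraint(d.arguments[r]) for r in sorted(d.arguments))
        lines.append(f"EVENT\t{t} [{d.overall_min},{d.overall_max}]\t{args}")
    for t in sorted(scheme.relations):
        r = scheme.relations[t]
        kind = "directed" if r.directed else "undirected"
        lines.append(
            f"RELATION\t{t}, {kind}\t{r.end1_role}({_fmt_types(r.end1_types)})"
            f" / {r.end2_role}({_fmt_types(r.end2_types)})"
        )
    for kind in sorted(scheme.modifier_targets):
        lines.append(f"MODIFIER\t{kind}\t{_fmt_types(scheme.modifier_targets[kind])}")
    lines.append(f"TARGET\tENTITY\t{_fmt_types(scheme.target_entity_types)}")
    lines.append(f"TARGET\tINTERACTION\t{_fmt_types(scheme.target_edge_types)}")
    return "\n".join(lines) + "\n"


def _split_types(text: str) -> frozenset[str]:
    return frozenset(t for t in (s.strip() for s in text.split(",")) if t)


def parse_scheme(text: str) -> AnnotationScheme:
    """Inverse of :func:`serialize_scheme` (lossless round-trip)."""
    entity_types: set[str] = set()
    events: dict[str, EventDefinition] = {}
    relations: dict[str, RelationDefinition] = {}
    modifier_targets: dict[str, frozenset[str]] = {}
    target_entity: frozenset[str] = frozenset()
    target_edge: frozenset[str] = frozenset()

    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind == "ENTITY":
            entity_types.add(fields[1])
        elif kind == "EVENT":
            m = re.match(r"^(?P<type>.+) \[(?P<min>\d+),(?P<max>\d+)\]$", fields[1])
            if m is None:
                raise ValueError(f"scheme line {lineno}: bad event header {fields[1]!r}")
            args: dict[str, ArgumentConstraint] = {}
            body = fields[2] if len(fields) > 2 else ""
            for chunk in filter(None, (c.strip() for c in body.split(" / "))):
                cm = _CONSTRAINT_RE.match(chunk)
                if cm is None:
                    raise ValueError(f"scheme line {lineno}: bad constraint {chunk!r}")
                prim = cm.group("prim")
                args[cm.group("role")] = ArgumentConstraint(
                    role=cm.group("role"),
                    min=int(cm.group("min")),
                    max=int(cm.group("max")),
                    target_types=_split_types(cm.group("targets") or ""),
                    site_primary_roles=(
                        frozenset(p for p in prim.split(",") if p)
                        if prim is not None
                        else None
                    ),
                )
            events[m.group("type")] = EventDefinition(
                m.group("type"), int(m.group("min")), int(m.group("max")), args
            )
        elif kind == "RELATION":
            name, _, direction = fields[1].rpartition(", ")
            rm = re.match(r"^(\S+)\(([^)]*)\) / (\S+)\(([^)]*)\)$", fields[2])
            if rm is None:
                raise ValueError(f"scheme line {lineno}: bad relation body {fields[2]!r}")
            relations[name] = RelationDefinition(
                type=name,
                directed=direction == "directed",
                end1_role=rm.group(1),
                end2_role=rm.group(3),
                end1_types=_split_types(rm.group(2)),
                end2_types=_split_types(rm.group(4)),
            )
        elif kind == "MODIFIER":
            modifier_targets[fields[1]] = _split_types(fields[2])
        elif kind == "TARGET":
            which = fields[1]
            types = _split_types(fields[2] if len(fields) > 2 else "")
            if which == "ENTITY":
                target_entity = types
            else:
                target_edge = types
        else:
            raise ValueError(f"scheme line {lineno}: unknown record kind {kind!r}")

    return AnnotationScheme(
        entity_types=frozenset(entity_types),
        events=events,
        relations=relations,
        modifier_targets=modifier_targets,
        target_entity_types=target_entity,
        target_edge_types=target_edge,
    )
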