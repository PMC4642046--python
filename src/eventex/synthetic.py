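"""Synthetic gold-annotated corpora with controllable structure.

Real event corpora are large, license-encumbered and parsed by external
tools; this generator produces small, fully self-contained corpora — text,
standoff files, interaction graphs and dependency parses — whose structural
phenomena (nested events, shared triggers, Site/SiteParent structures,
equivalence groups, negation/speculation modifiers, cross-sentence
arguments) appear at configurable rates.  Sentences are template-based
subject–verb–object strings with simple projective parses, not natural text:
the goal is exercising annotation structure, not linguistic realism.

Two modes exist.  Random mode draws event instances from the feasible
argument-count vectors of a generating scheme.  Saturated mode emits every
feasible vector and systematically covers every target type, site primary
role and modifier target, so that scheme induction from the corpus recovers
the generating scheme exactly — the parameter-recovery contract.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace

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
from .scheme import (
    SITEPARENT_TYPE,
    AnnotationScheme,
    ArgumentConstraint,
    EventDefinition,
    RelationDefinition,
)
from .st_io import SentenceParse, STDocument, graph_to_st, write_st_document

_TRIGGER_WORDS = {
    "Phosphorylation": "phosphorylates",
    "Binding": "binds",
    "Expression": "expresses",
    "Regulation": "regulates",
    "Localization": "localizes",
    "Activation": "activates",
    "Conversion": "converts",
    "Degradation": "degrades",
    "Glycolysis": "glycolysis",
}

_ROLE_DEPS = {"Theme": "dobj", "Cause": "nsubj", "Site": "prep_at"}


def default_scheme() -> AnnotationScheme:
    """The default generating scheme: a compact GENIA-flavoured rule set.

    Given Protein mentions, predicted Entity (site) mentions, five event
    types including a nesting regulation type and a zero-argument event
    type, one binary relation, and modifier targets for both kinds.
    """
    evt = {
        "Expression": EventDefinition(
            "Expression", 1, 1,
            {"Theme": ArgumentConstraint("Theme", 1, 1, frozenset({"Protein"}))},
        ),
        "Phosphorylation": EventDefinition(
            "Phosphorylation", 1, 3,
            {
                "Theme": ArgumentConstraint("Theme", 1, 1, frozenset({"Protein"})),
                "Cause": ArgumentConstraint("Cause", 0, 1, frozenset({"Protein"})),
                "Site": ArgumentConstraint(
                    "Site", 0, 1, frozenset({"Entity"}), frozenset({"Theme"})
                ),
            },
        ),
        "Binding": EventDefinition(
            "Binding", 1, 2,
            {"Theme": ArgumentConstraint("Theme", 1, 2, frozenset({"Protein"}))},
        ),
        "Regulation": EventDefinition(
            "Regulation", 1, 2,
            {
                "Theme": ArgumentConstraint(
                    "Theme", 1, 1,
                    frozenset({"Protein", "Expression", "Phosphorylation", "Binding"}),
                ),
                "Cause": ArgumentConstraint("Cause", 0, 1, frozenset({"Protein"})),
            },
        ),
        "Glycolysis": EventDefinition("Glycolysis", 0, 0, {}),
    }
    relations = {
        SITEPARENT_TYPE: RelationDefinition(
            SITEPARENT_TYPE, True, "Arg1", "Arg2",
            frozenset({"Entity"}), frozenset({"Protein"}),
        ),
        "PartOf": RelationDefinition(
            "PartOf", True, "Arg1", "Arg2",
            frozenset({"Protein"}), frozenset({"Protein"}),
        ),
    }
    return AnnotationScheme(
        entity_types=frozenset({"Protein", "Entity"}),
        events=evt,
        relations=relations,
        modifier_targets={
            "negation": frozenset({"Binding", "Expression", "Phosphorylation", "Regulation"}),
            "speculation": frozenset({"Phosphorylation", "Regulation"}),
        },
        target_entity_types=frozenset(
            {"Entity", "Expression", "Phosphorylation", "Binding", "Regulation", "Glycolysis"}
        ),
        target_edge_types=frozenset({"Theme", "Cause", "Site", SITEPARENT_TYPE, "PartOf"}),
    )


@dataclass
class GeneratorSpec:
    """Study conditions for corpus generation; all rates in [0, 1]."""

    scheme: AnnotationScheme = field(default_factory=default_scheme)
    documents: int = 20
    sentences_per_doc: int = 3
    max_events_per_sentence: int = 2
    nesting_rate: float = 0.3
    max_nesting_depth: int = 2
    shared_trigger_rate: float = 0.15
    equiv_rate: float = 0.1
    cross_sentence_rate: float = 0.0
    modifier_rates: dict[str, float] = field(
        default_factory=lambda: {"negation": 0.15, "speculation": 0.1}
    )
    relation_rate: float = 0.2
    distractor_rate: float = 0.3
    two_token_entity_rate: float = 0.15
    seed: int = 1
    saturate: bool = False

    def __post_init__(self):
        rates = [
            self.nesting_rate, self.shared_trigger_rate, self.equiv_rate,
            self.cross_sentence_rate, self.relation_rate, self.distractor_rate,
            self.two_token_entity_rate, *self.modifier_rates.values(),
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")


class SpecificationError(ValueError):
    """The generator spec cannot be realized (e.g. ungroundable nesting)."""


@dataclass
class GeneratedCorpus:
    corpus: Corpus
    st_documents: list[STDocument]
    standoff: list[tuple[str, str, str]]  # (txt, a1, a2) per document
    parses: dict[str, list[SentenceParse]]
    manifest: dict[str, int]
    scheme: AnnotationScheme


# ---------------------------------------------------------------------------
# feasible argument-count vectors
# ---------------------------------------------------------------------------

def _sites_bindable(d: EventDefinition, v: dict[str, int]) -> bool:
    """Can every Site-like occurrence bind a distinct primary occurrence?"""
    used: dict[str, int] = {}
    for r in sorted(v):
        c = d.arguments[r]
        if c.site_primary_roles is None:
            continue
        for _ in range(v[r]):
            for p in sorted(c.site_primary_roles):
                if used.get(p, 0) < v.get(p, 0):
                    used[p] = used.get(p, 0) + 1
                    break
            else:
                return False
    return True


def feasible_vectors(d: EventDefinition) -> list[dict[str, int]]:
    """Role-count vectors consistent with per-role, overall and Site limits.

    A vector whose Site-like occurrences cannot each bind a distinct primary
    argument is infeasible (gold annotation always carries the primary, and
    a primary argument takes at most one Site).
    """
    roles = sorted(d.arguments)
    ranges = [range(d.arguments[r].min, d.arguments[r].max + 1) for r in roles]
    out = []
    for combo in itertools.product(*ranges):
        v = dict(zip(roles, combo))
        total = sum(v.values())
        if not (d.overall_min <= total <= d.overall_max):
            continue
        if _sites_bindable(d, v):
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# random scheme sampling (for parameter-recovery experiments)
# ---------------------------------------------------------------------------

_EVENT_NAME_POOL = (
    "Phosphorylation", "Binding", "Expression", "Regulation", "Localization",
    "Activation", "Conversion", "Degradation", "Methylation", "Transport",
)
_ROLE_POOL = ("Theme", "Cause", "Participant", "ToLoc")


def sample_scheme(rng: random.Random) -> AnnotationScheme:
    """Draw a random but always-realizable annotation scheme.

    Event types are ordered; roles requiring an argument may target only
    given entity types or strictly earlier event types, which guarantees
    that every event type has a finite grounded instance.  Constraints are
    the extremes over the feasible vector set, so a saturated corpus realizes
    every boundary.
    """
    given_types = ["Protein"] + (["Gene"] if rng.random() < 0.4 else [])
    has_entity = rng.random() < 0.7
    entity_types = set(given_types)
    if has_entity:
        entity_types.add("Entity")

    n_events = rng.randint(2, 4)
    names = list(rng.sample(_EVENT_NAME_POOL, n_events))
    if rng.random() < 0.5:
        names.append("Glycolysis")

    events: dict[str, EventDefinition] = {}
    ordered: list[str] = []
    for name in names:
        if name == "Glycolysis":
            events[name] = EventDefinition(name, 0, 0, {})
            ordered.append(name)
            continue
        roles: dict[str, ArgumentConstraint] = {}
        n_roles = rng.randint(1, 3)
        chosen = ["Theme"] + list(rng.sample([r for r in _ROLE_POOL if r != "Theme"], n_roles - 1))
        for role in chosen:
            lo = rng.choice([0, 1]) if role != "Theme" else 1
            hi = rng.randint(max(lo, 1), 2)
            # targets: given entities and, for nesting flavour, earlier events
            pool = list(given_types)
            if ordered and rng.random() < 0.4:
                pool += list(rng.sample(ordered, min(len(ordered), 2)))
            targets = frozenset(rng.sample(pool, rng.randint(1, len(pool))))
            if lo > 0 and not (targets & set(given_types)) and not (
                targets & set(o for o in ordered if o != "Glycolysis")
            ):
                targets = targets | {given_types[0]}
            roles[role] = ArgumentConstraint(role, lo, hi, targets)
        # optional Site-like role: primaries among entity-targeting roles
        if has_entity and rng.random() < 0.5:
            # standoff role numbering can only re-pair sites with Theme/Cause
            # primaries (SiteK↔ThemeK, CSiteK↔CauseK), as in the real corpora
            prim_cands = [
                r for r, c in roles.items()
                if r in ("Theme", "Cause") and c.target_types <= set(given_types)
            ]
            if prim_cands:
                prim = frozenset(rng.sample(prim_cands, rng.randint(1, len(prim_cands))))
                roles["Site"] = ArgumentConstraint(
                    "Site", 0, rng.randint(1, 2), frozenset({"Entity"}), prim
                )
        draft = EventDefinition(name, 0, sum(c.max for c in roles.values()), roles)
        vectors = feasible_vectors(draft)
        totals = sorted({sum(v.values()) for v in vectors})
        lo_t = rng.choice(totals[: max(1, len(totals) // 2)])
        hi_t = rng.choice([t for t in totals if t >= lo_t])
        draft = EventDefinition(name, lo_t, hi_t, roles)
        vectors = feasible_vectors(draft)
        if not vectors:
            events[name] = EventDefinition(name, 0, 0, {})
            ordered.append(name)
            continue
        # effective constraints: extremes over the realizable vector set
        eff_args = {}
        for role, c in roles.items():
            counts = [v[role] for v in vectors]
            prim = c.site_primary_roles
            if prim is not None:
                prim = frozenset(p for p in prim if any(
                    v[role] > 0 and v.get(p, 0) > 0 for v in vectors
                ))
                if not prim or max(counts) == 0:
                    continue
            if max(counts) == 0 and min(counts) == 0:
                continue
            eff_args[role] = ArgumentConstraint(
                role, min(counts), max(counts), c.target_types, prim
            )
        vectors = [{r: v.get(r, 0) for r in eff_args} for v in vectors]
        totals = [sum(v.values()) for v in vectors]
        events[name] = EventDefinition(name, min(totals), max(totals), eff_args)
        ordered.append(name)

    relations: dict[str, RelationDefinition] = {}
    # SiteParent appears whenever some event has a Site-like role
    sp_end1: set[str] = set()
    sp_end2: set[str] = set()
    for d in events.values():
        for c in d.arguments.values():
            if c.site_primary_roles is not None:
                sp_end1 |= c.target_types
                for p in c.site_primary_roles:
                    sp_end2 |= d.arguments[p].target_types & entity_types
    if sp_end1:
        relations[SITEPARENT_TYPE] = RelationDefinition(
            SITEPARENT_TYPE, True, "Arg1", "Arg2", frozenset(sp_end1), frozenset(sp_end2)
        )
    if rng.random() < 0.6:
        e1 = frozenset(rng.sample(given_types, rng.randint(1, len(given_types))))
        e2 = frozenset(rng.sample(given_types, rng.randint(1, len(given_types))))
        relations["PartOf"] = RelationDefinition("PartOf", True, "Arg1", "Arg2", e1, e2)

    modifier_targets: dict[str, frozenset[str]] = {}
    real_events = [n for n in ordered if n in events]
    for kind in ("negation", "speculation"):
        if rng.random() < 0.7 and real_events:
            modifier_targets[kind] = frozenset(
                rng.sample(real_events, rng.randint(1, len(real_events)))
            )

    role_types = {r for d in events.values() for r in d.arguments}
    return AnnotationScheme(
        entity_types=frozenset(entity_types),
        events=events,
        relations=relations,
        modifier_targets=modifier_targets,
        target_entity_types=frozenset(
            (entity_types - set(given_types)) | set(events)
        ),
        target_edge_types=frozenset(role_types | set(relations)),
    )


# ---------------------------------------------------------------------------
# instance planning
# ---------------------------------------------------------------------------

@dataclass
class _Inst:
    type: str
    # each arg: (role, target) where target is an entity type name or a child _Inst
    args: list[tuple[str, object]] = field(default_factory=list)
    # site argument index -> primary argument index
    site_primary: dict[int, int] = field(default_factory=dict)
    modifiers: frozenset[str] = frozenset()


def _given_types(scheme: AnnotationScheme) -> set[str]:
    return set(scheme.entity_types - scheme.target_entity_types)


def _event_order(scheme: AnnotationScheme) -> dict[str, int]:
    return {t: i for i, t in enumerate(sorted(scheme.events))}


def _minimal_instance(scheme: AnnotationScheme, etype: str, _depth: int = 0) -> _Inst:
    """Smallest grounded instance of an event type (required roles only)."""
    if _depth > 10:
        raise SpecificationError(f"cannot ground event type {etype!r}")
    d = scheme.events[etype]
    vectors = feasible_vectors(d)
    if not vectors:
        raise SpecificationError(f"event type {etype!r} has no feasible instances")
    v = min(vectors, key=lambda w: (sum(w.values()), sorted(w.items())))
    return _instance_from_vector(scheme, etype, v, chooser=None, _depth=_depth)


def _instance_from_vector(
    scheme: AnnotationScheme,
    etype: str,
    vector: dict[str, int],
    chooser=None,
    _depth: int = 0,
) -> _Inst:
    """Realize a role-count vector into a typed instance.

    ``chooser(role, occurrence, constraint)`` may return a target type to
    cover specific boundaries; by default the first entity-type target is
    used and event-type targets are grounded minimally.
    """
    d = scheme.events[etype]
    inst = _Inst(type=etype)
    for role in sorted(vector):
        c = d.arguments[role]
        for k in range(vector[role]):
            target_type = chooser(role, k, c) if chooser else None
            if target_type is None:
                ent = sorted(c.target_types & scheme.entity_types)
                if ent:
                    target_type = ent[0]
                else:
                    target_type = sorted(c.target_types)[0]
            if target_type in scheme.events:
                inst.args.append((role, _minimal_instance(scheme, target_type, _depth + 1)))
            else:
                inst.args.append((role, target_type))
    # bind each Site-like argument to a primary occurrence
    for i, (role, _) in enumerate(inst.args):
        c = d.arguments[role]
        if c.site_primary_roles is None:
            continue
        prim_idx = [
            j for j, (r2, _) in enumerate(inst.args) if r2 in c.site_primary_roles
        ]
        free = [j for j in prim_idx if j not in inst.site_primary.values()]
        if not free:
            raise SpecificationError(
                f"{etype}: Site argument without an available primary"
            )
        inst.site_primary[i] = free[0]
    return inst


def _saturation_plan(scheme: AnnotationScheme) -> list[_Inst]:
    """Instances realizing every constraint boundary of the scheme.

    Emits every feasible vector once, then adds instances until every
    target type of every role, every site primary role, and every modifier
    target has been realized at least once.
    """
    plan: list[_Inst] = []
    for etype in sorted(scheme.events):
        d = scheme.events[etype]
        vectors = feasible_vectors(d)
        if not vectors and d.arguments:
            raise SpecificationError(f"event type {etype!r} is unsatisfiable")
        for v in sorted(vectors, key=lambda w: sorted(w.items())):
            plan.append(_instance_from_vector(scheme, etype, v))
        # coverage: every (role, target type)
        for role in sorted(d.arguments):
            c = d.arguments[role]
            base = max(vectors, key=lambda w: (w[role], -sum(w.values())))
            if base[role] == 0:
                continue
            for tt in sorted(c.target_types):
                chooser = (
                    lambda r, k, cc, _tt=tt, _role=role: _tt if r == _role and k == 0 else None
                )
                plan.append(_instance_from_vector(scheme, etype, base, chooser))
        # coverage: every site primary role, with every primary target type
        for role in sorted(d.arguments):
            c = d.arguments[role]
            if c.site_primary_roles is None:
                continue
            for p in sorted(c.site_primary_roles):
                cands = [
                    v for v in vectors if v[role] > 0 and v.get(p, 0) > 0
                ]
                if not cands:
                    raise SpecificationError(
                        f"{etype}: primary role {p} for {role} is not realizable"
                    )
                base = min(cands, key=lambda w: (sum(w.values()), sorted(w.items())))
                for ptt in sorted(
                    d.arguments[p].target_types & scheme.entity_types
                ) or [None]:
                    chooser = (
                        lambda r, k, cc, _p=p, _ptt=ptt: _ptt
                        if (_ptt is not None and r == _p and k == 0)
                        else None
                    )
                    inst = _instance_from_vector(scheme, etype, base, chooser)
                    # rebind all sites to primary role p where possible
                    prim_idx = [j for j, (r2, _) in enumerate(inst.args) if r2 == p]
                    site_idx = [j for j, (r2, _) in enumerate(inst.args) if r2 == role]
                    inst.site_primary = {}
                    used: set[int] = set()
                    for si in site_idx:
                        free = [j for j in prim_idx if j not in used]
                        if not free:
                            free = [
                                j
                                for j, (r2, _) in enumerate(inst.args)
                                if r2 in c.site_primary_roles and j not in used
                            ]
                        inst.site_primary[si] = free[0]
                        used.add(free[0])
                    plan.append(inst)
    # modifiers: one instance per (kind, target event type)
    for kind in sorted(scheme.modifier_targets):
        for etype in sorted(scheme.modifier_targets[kind]):
            if etype not in scheme.events:
                continue
            inst = _minimal_instance(scheme, etype)
            inst.modifiers = frozenset({kind})
            plan.append(inst)
    return plan


# ---------------------------------------------------------------------------
# sentence realization
# ---------------------------------------------------------------------------

class _SentenceBuilder:
    def __init__(self, sent_id: str, doc_id: str, counters: dict):
        self.sent_id = sent_id
        self.doc_id = doc_id
        self.counters = counters
        self.tokens: list[tuple[str, str]] = []  # (text, pos)
        self.deps: list[tuple[str, int, int]] = []  # (type, governor, dependent)
        self.nodes: list[dict] = []
        self.edges: list[InteractionEdge] = []
        self.groups: list[EventGroup] = []
        self.root: int | None = None

    def add_token(self, text: str, pos: str) -> int:
        self.tokens.append((text, pos))
        return len(self.tokens) - 1

    def add_dep(self, dtype: str, governor: int, dependent: int) -> None:
        if governor != dependent:
            self.deps.append((dtype, governor, dependent))

    def new_node_id(self) -> str:
        self.counters["node"] += 1
        return f"{self.doc_id}.e{self.counters['node']}"

    def new_edge_id(self) -> str:
        self.counters["edge"] += 1
        return f"{self.doc_id}.i{self.counters['edge']}"

    def add_node(self, lo: int, hi: int, etype: str, given: bool, event: bool,
                 modifiers=frozenset()) -> str:
        nid = self.new_node_id()
        self.nodes.append(
            {"id": nid, "lo": lo, "hi": hi, "type": etype, "given": given,
             "event": event, "modifiers": frozenset(modifiers)}
        )
        return nid

    def finish(self) -> tuple[SentenceGraph, dict[str, str]]:
        texts = [t for t, _ in self.tokens]
        starts, pos_ = [], 0
        for t in texts:
            starts.append(pos_)
            pos_ += len(t) + 1
        text = " ".join(texts)
        toks = [
            Token(f"{self.sent_id}.t{i}", txt, pos, starts[i], starts[i] + len(txt))
            for i, (txt, pos) in enumerate(self.tokens)
        ]
        deps = [
            Dependency(d, f"{self.sent_id}.t{g}", f"{self.sent_id}.t{dp}")
            for d, g, dp in self.deps
        ]
        entities = []
        head_of = {}
        for n in self.nodes:
            start = starts[n["lo"]]
            end = starts[n["hi"]] + len(texts[n["hi"]])
            entities.append(
                EntityNode(
                    id=n["id"], type=n["type"], start=start, end=end,
                    text=text[start:end], head=f"{self.sent_id}.t{n['hi']}",
                    given=n["given"], event=n["event"], modifiers=n["modifiers"],
                )
            )
            head_of[n["id"]] = entities[-1].head
        sent = SentenceGraph(
            id=self.sent_id, text=text, tokens=toks, dependencies=deps,
            entities=entities, interactions=self.edges,
        )
        return sent, head_of


def _protein_name(counters: dict) -> str:
    counters["prot"] += 1
    return f"PROT{counters['prot']}"


def _site_name(counters: dict) -> str:
    counters["site"] += 1
    return f"Ser{counters['site']}"


def _realize_mention(
    b: _SentenceBuilder, etype: str, given: bool, rng: random.Random, spec: GeneratorSpec,
    attach_to: int,
) -> tuple[str, int]:
    """Emit tokens for one entity mention; returns (node id, head token index)."""
    counters = b.counters
    if etype == "Entity":
        text, pos = _site_name(counters), "NN"
    elif etype == "Gene":
        counters["prot"] += 1
        text, pos = f"geneG{counters['prot']}", "NN"
    else:
        text, pos = _protein_name(counters), "NNP"
    lo = hi = None
    if given and rng.random() < spec.two_token_entity_rate:
        first = b.add_token("human", "JJ")
        hi = b.add_token(text, pos)
        b.add_dep("nn", hi, first)
        lo = first
    else:
        lo = hi = b.add_token(text, pos)
    nid = b.add_node(lo, hi, etype, given=given, event=False)
    return nid, hi


def _realize_event(
    inst: _Inst,
    b: _SentenceBuilder,
    scheme: AnnotationScheme,
    rng: random.Random,
    spec: GeneratorSpec,
    manifest: dict[str, int],
    parent_tok: int | None = None,
    trigger_at: int | None = None,
) -> tuple[str, int]:
    """Emit one event instance; returns (trigger node id, trigger token index)."""
    given = _given_types(scheme)
    if trigger_at is None:
        word = _TRIGGER_WORDS.get(inst.type, inst.type.lower())
        pos = "NN" if not inst.args else "VBZ"
        t_idx = b.add_token(word, pos)
        if b.root is None:
            b.root = t_idx
        elif parent_tok is not None:
            b.add_dep("ccomp", parent_tok, t_idx)
        else:
            b.add_dep("conj_and", b.root, t_idx)
    else:
        t_idx = trigger_at
    trig_id = b.add_node(t_idx, t_idx, inst.type, given=False, event=True,
                         modifiers=inst.modifiers)

    edge_of_arg: dict[int, InteractionEdge] = {}
    node_of_arg: dict[int, str] = {}
    for i, (role, target) in enumerate(inst.args):
        if i in inst.site_primary:
            continue  # sites wired after their primaries
        if isinstance(target, _Inst):
            child_id, child_tok = _realize_event(
                target, b, scheme, rng, spec, manifest, parent_tok=t_idx
            )
            tgt_id = child_id
            manifest["nested_events"] += 1
        else:
            tgt_id, m_tok = _realize_mention(b, target, target in given, rng, spec, t_idx)
            b.add_dep(_ROLE_DEPS.get(role, "prep_of"), t_idx, m_tok)
        edge = InteractionEdge(
            id=b.new_edge_id(), type=role, source=trig_id, target=tgt_id,
            directed=True, event=True,
        )
        b.edges.append(edge)
        edge_of_arg[i] = edge
        node_of_arg[i] = tgt_id
    for i, (role, target) in enumerate(inst.args):
        if i not in inst.site_primary:
            continue
        tgt_id, m_tok = _realize_mention(b, target, target in given, rng, spec, t_idx)
        b.add_dep(_ROLE_DEPS.get(role, "prep_at"), t_idx, m_tok)
        primary = edge_of_arg[inst.site_primary[i]]
        edge = InteractionEdge(
            id=b.new_edge_id(), type=role, source=trig_id, target=tgt_id,
            directed=True, event=True, site_of=primary.id,
        )
        b.edges.append(edge)
        edge_of_arg[i] = edge
        sp = InteractionEdge(
            id=b.new_edge_id(), type=SITEPARENT_TYPE, source=tgt_id,
            target=primary.target, directed=True, event=False,
            extra={"e1Role": "Arg1", "e2Role": "Arg2"},
        )
        b.edges.append(sp)
        manifest["site_args"] += 1
    b.groups.append(
        EventGroup(
            id=f"{b.doc_id}.g{len(b.groups)}.{b.sent_id}",
            trigger=trig_id,
            args=tuple(edge_of_arg[i].id for i in sorted(edge_of_arg)),
            modifiers=inst.modifiers,
        )
    )
    manifest["events"] += 1
    for kind in inst.modifiers:
        manifest[f"{kind}_events"] += 1
    return trig_id, t_idx


def _random_instance(
    scheme: AnnotationScheme, etype: str, rng: random.Random, spec: GeneratorSpec,
    depth: int = 0,
) -> _Inst:
    d = scheme.events[etype]
    vectors = feasible_vectors(d)
    if not vectors:
        raise SpecificationError(f"event type {etype!r} is unsatisfiable")
    v = rng.choice(vectors)

    def chooser(role, k, c):
        ent = sorted(c.target_types & scheme.entity_types)
        evt = sorted(c.target_types & set(scheme.events))
        if evt and depth < spec.max_nesting_depth and rng.random() < spec.nesting_rate:
            return rng.choice(evt)
        if ent:
            return rng.choice(ent)
        return rng.choice(evt)

    inst = _Inst(type=etype)
    for role in sorted(v):
        c = d.arguments[role]
        for k in range(v[role]):
            tt = chooser(role, k, c)
            if tt in scheme.events:
                inst.args.append(
                    (role, _random_instance(scheme, tt, rng, spec, depth + 1)
                     if depth + 1 < spec.max_nesting_depth
                     else _minimal_instance(scheme, tt))
                )
            else:
                inst.args.append((role, tt))
    for i, (role, _) in enumerate(inst.args):
        c = d.arguments[role]
        if c.site_primary_roles is None:
            continue
        prim_idx = [
            j for j, (r2, _) in enumerate(inst.args)
            if r2 in c.site_primary_roles and j not in inst.site_primary.values()
        ]
        if not prim_idx:
            raise SpecificationError(f"{etype}: site without primary")
        inst.site_primary[i] = prim_idx[0]
    for kind, types in scheme.modifier_targets.items():
        if etype in types and rng.random() < spec.modifier_rates.get(kind, 0.0):
            inst.modifiers = inst.modifiers | {kind}
    return inst


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(spec: GeneratorSpec) -> GeneratedCorpus:
    """Generate a gold-annotated corpus; deterministic given the seed.

    Emits matched graphs, standoff triplets, Interaction-XML-ready documents
    and simple projective dependency parses.  Realized counts of every
    structural phenomenon are recorded in the manifest.
    """
    rng = random.Random(spec.seed)
    scheme = spec.scheme
    given = _given_types(scheme)
    manifest: dict[str, int] = {
        k: 0
        for k in (
            "documents", "sentences", "events", "nested_events", "site_args",
            "shared_trigger_sites", "equiv_groups", "cross_sentence_events",
            "negation_events", "speculation_events", "relations", "distractors",
        )
    }

    event_types = sorted(t for t in scheme.events)
    if not event_types:
        raise SpecificationError("scheme defines no event types")

    if spec.saturate:
        plan = _saturation_plan(scheme)
        per_sentence = 2
        n_sentences = (len(plan) + per_sentence - 1) // per_sentence
        n_docs = max(1, (n_sentences + spec.sentences_per_doc - 1) // spec.sentences_per_doc)
    else:
        plan = None
        n_docs = spec.documents

    docs: list[Document] = []
    plan_pos = 0
    for di in range(n_docs):
        doc_id = f"d{di}"
        counters = {"node": 0, "edge": 0, "prot": 0, "site": 0}
        sentences: list[SentenceGraph] = []
        head_maps: list[dict[str, str]] = []
        doc_groups: list[EventGroup] = []
        doc_equivs: list[frozenset[str]] = []

        for si in range(spec.sentences_per_doc):
            sent_id = f"{doc_id}.s{si}"
            b = _SentenceBuilder(sent_id, doc_id, counters)
            if spec.saturate:
                insts = plan[plan_pos : plan_pos + 2]
                plan_pos += 2
            else:
                n_ev = rng.randint(1, spec.max_events_per_sentence)
                insts = [
                    _random_instance(scheme, rng.choice(event_types), rng, spec)
                    for _ in range(n_ev)
                ]
            realized: list[tuple[str, int, _Inst]] = []
            for inst in insts:
                trig_id, t_idx = _realize_event(inst, b, scheme, rng, spec, manifest)
                realized.append((trig_id, t_idx, inst))

            # shared trigger: a second event of the same type on one trigger
            if not spec.saturate and realized and rng.random() < spec.shared_trigger_rate:
                trig_id, t_idx, inst = realized[0]
                d = scheme.events[inst.type]
                groundable = [
                    r for r, c in d.arguments.items()
                    if c.max >= 1 and c.site_primary_roles is None
                    and (c.target_types & scheme.entity_types)
                ]
                if groundable and d.overall_max >= 1:
                    alt = _minimal_instance(scheme, inst.type)
                    if alt.args:
                        _realize_event(
                            alt, b, scheme, rng, spec, manifest, trigger_at=t_idx
                        )
                        manifest["shared_trigger_sites"] += 1

            # binary relations between fresh given mentions
            relation_types = [t for t in scheme.relations if t != SITEPARENT_TYPE]
            if relation_types and rng.random() < spec.relation_rate:
                rtype = rng.choice(sorted(relation_types))
                rdef = scheme.relations[rtype]
                t1 = sorted(rdef.end1_types & given) or sorted(rdef.end1_types)
                t2 = sorted(rdef.end2_types & given) or sorted(rdef.end2_types)
                if t1 and t2 and not (set(t1) | set(t2)) & set(scheme.events):
                    anchor = b.root if b.root is not None else 0
                    c1, c2 = rng.choice(t1), rng.choice(t2)
                    n1, k1 = _realize_mention(b, c1, c1 in given, rng, spec, anchor)
                    n2, k2 = _realize_mention(b, c2, c2 in given, rng, spec, anchor)
                    if b.root is not None:
                        b.add_dep("dep", b.root, k1)
                    b.add_dep("appos", k1, k2)
                    b.edges.append(
                        InteractionEdge(
                            id=b.new_edge_id(), type=rtype, source=n1, target=n2,
                            directed=rdef.directed, event=False,
                            extra={"e1Role": rdef.end1_role, "e2Role": rdef.end2_role},
                        )
                    )
                    manifest["relations"] += 1

            # distractor mention (a given entity taking part in nothing)
            if not spec.saturate and given and rng.random() < spec.distractor_rate:
                anchor = b.root if b.root is not None else 0
                _, k = _realize_mention(b, sorted(given)[0], True, rng, spec, anchor)
                if b.root is not None:
                    b.add_dep("dep", b.root, k)
                manifest["distractors"] += 1

            if not b.tokens:
                b.add_token("nothing", "NN")
                b.root = 0
            dot = b.add_token(".", ".")
            b.add_dep("punct", b.root if b.root is not None else 0, dot)

            # equivalence: duplicate a given mention used by a top-level event
            if not spec.saturate and rng.random() < spec.equiv_rate:
                referenced = {e.target for g in b.groups for e in b.edges if e.id in g.args}
                child_triggers = {
                    e.target for e in b.edges if e.event and any(
                        n["id"] == e.target and n["event"] for n in b.nodes
                    )
                }
                cand_edges = [
                    e
                    for g in b.groups
                    for e in b.edges
                    if e.id in g.args
                    and e.site_of is None
                    and e.target not in child_triggers
                    and any(
                        n["id"] == e.target and n["given"] for n in b.nodes
                    )
                    and g.trigger not in child_triggers
                ]
                # only expand events that are not referenced by other events
                cand = [
                    (g, e)
                    for g in b.groups
                    for e in cand_edges
                    if e.id in g.args and g.trigger not in referenced
                    and not any(e2.site_of for e2 in b.edges if e2.id in g.args)
                ]
                if cand:
                    g, e = cand[0]
                    dup_id, dk = _realize_mention(
                        b, next(n["type"] for n in b.nodes if n["id"] == e.target),
                        True, rng, spec, b.root or 0,
                    )
                    orig_head = next(n for n in b.nodes if n["id"] == e.target)
                    b.add_dep("appos", orig_head["hi"], dk)
                    doc_equivs.append(frozenset({e.target, dup_id}))
                    manifest["equiv_groups"] += 1
                    # expanded copy: duplicate trigger node and all edges
                    trig_node = next(n for n in b.nodes if n["id"] == g.trigger)
                    copy_trig = b.add_node(
                        trig_node["lo"], trig_node["hi"], trig_node["type"],
                        given=False, event=True, modifiers=g.modifiers,
                    )
                    new_args = []
                    for aid in g.args:
                        old = next(x for x in b.edges if x.id == aid)
                        new = InteractionEdge(
                            id=b.new_edge_id(), type=old.type, source=copy_trig,
                            target=dup_id if old.id == e.id else old.target,
                            directed=True, event=True,
                        )
                        b.edges.append(new)
                        new_args.append(new.id)
                    b.groups.append(
                        EventGroup(
                            id=f"{doc_id}.g{len(b.groups)}.{sent_id}x",
                            trigger=copy_trig, args=tuple(new_args),
                            modifiers=g.modifiers,
                        )
                    )
                    manifest["events"] += 1
                    for kind in g.modifiers:
                        manifest[f"{kind}_events"] += 1

            sent, head_of = b.finish()
            sentences.append(sent)
            head_maps.append(head_of)
            doc_groups.extend(b.groups)
            manifest["sentences"] += 1

        text = " ".join(s.text for s in sentences)
        offsets = []
        pos_ = 0
        for s in sentences:
            offsets.append(pos_)
            pos_ += len(s.text) + 1
        doc = Document(
            id=doc_id, text=text, sentences=sentences, sentence_offsets=offsets,
            events=doc_groups, equivs=doc_equivs, set_label="train",
        )

        # cross-sentence arguments: retarget an argument into another sentence
        if not spec.saturate and len(sentences) > 1 and rng.random() < spec.cross_sentence_rate:
            _inject_cross_sentence(doc, given, manifest)

        docs.append(doc)
        manifest["documents"] += 1

    if spec.saturate:
        docs.append(_coverage_document(scheme, given, manifest))
        manifest["documents"] += 1

    corpus = Corpus(name="synthetic", documents=docs)
    st_documents = [graph_to_st(d) for d in docs]
    standoff = []
    for d, st in zip(docs, st_documents):
        a1, a2 = write_st_document(st)
        standoff.append((d.text, a1, a2))
    parses = {
        d.id: [
            SentenceParse(s.id, off, s.text, s.tokens, s.dependencies)
            for s, off in zip(d.sentences, d.sentence_offsets)
        ]
        for d in docs
    }
    return GeneratedCorpus(
        corpus=corpus,
        st_documents=st_documents,
        standoff=standoff,
        parses=parses,
        manifest=manifest,
        scheme=scheme,
    )


def _coverage_document(
    scheme: AnnotationScheme, given: set[str], manifest: dict
) -> Document:
    """One document realizing every entity type and relation definition.

    Saturated corpora must make every definition of the generating scheme
    observable; event instances are covered by the saturation plan, while
    standalone entity mentions and binary-relation instances live here.
    """
    rng = random.Random(0)
    spec = GeneratorSpec(two_token_entity_rate=0.0)
    counters = {"node": 0, "edge": 0, "prot": 0, "site": 0}
    b = _SentenceBuilder("dcov.s0", "dcov", counters)
    b.root = b.add_token("mentions", "VBZ")
    mention_of: dict[str, str] = {}

    def _mention(etype: str) -> str:
        nid, k = _realize_mention(b, etype, etype in given, rng, spec, b.root)
        b.add_dep("dep", b.root, k)
        return nid

    for etype in sorted(scheme.entity_types):
        mention_of[etype] = _mention(etype)
    for rtype in sorted(scheme.relations):
        if rtype == SITEPARENT_TYPE:
            continue  # realized by Site-argument instances
        rdef = scheme.relations[rtype]
        end1, end2 = sorted(rdef.end1_types), sorted(rdef.end2_types)
        pairs = [(t1, end2[0]) for t1 in end1] + [(end1[0], t2) for t2 in end2[1:]]
        for t1, t2 in pairs:
            n1, n2 = _mention(t1), _mention(t2)
            b.edges.append(
                InteractionEdge(
                    id=b.new_edge_id(), type=rtype, source=n1, target=n2,
                    directed=rdef.directed, event=False,
                    extra={"e1Role": rdef.end1_role, "e2Role": rdef.end2_role},
                )
            )
            manifest["relations"] += 1
    dot = b.add_token(".", ".")
    b.add_dep("punct", b.root, dot)
    sent, _ = b.finish()
    manifest["sentences"] += 1
    return Document(
        id="dcov", text=sent.text, sentences=[sent], sentence_offsets=[0],
        set_label="train",
    )


def _inject_cross_sentence(doc: Document, given: set[str], manifest: dict) -> None:
    """Move one event argument's target to a given mention in another sentence."""
    referenced = {
        e.target for g in doc.events for e in doc.all_edges() if e.id in g.args
    }
    equiv_members = {m for group in doc.equivs for m in group}
    for g in doc.events:
        if g.trigger in referenced:
            continue
        edges0 = {e.id: e for e in doc.all_edges()}
        if any(edges0[a].target in equiv_members for a in g.args):
            continue  # retargeting would break equivalence-expansion symmetry
        sent = doc.sentence_of_entity(g.trigger)
        edges = {e.id: e for e in doc.all_edges()}
        for aid in g.args:
            edge = edges[aid]
            if edge.site_of is not None:
                continue
            if any(e.site_of == edge.id for e in doc.all_edges()):
                continue
            tgt = doc.entity_by_id(edge.target)
            if not tgt.given:
                continue
            for other in doc.sentences:
                if other.id == sent.id:
                    continue
                cands = [e for e in other.entities if e.given and e.type == tgt.type]
                if cands:
                    edge.target = cands[0].id
                    sent.interactions.remove(edge)
                    doc.cross_edges.append(edge)
                    manifest["cross_sentence_events"] += 1
                    return
    return


# ---------------------------------------------------------------------------
# controlled error injection
# ---------------------------------------------------------------------------

@dataclass
class ErrorSpec:
    """Counts of structural errors to inject into a gold corpus."""

    invalid_role: int = 0  # required argument renamed to an unknown role
    extra_argument: int = 0  # one argument duplicated beyond its maximum
    drop_argument: int = 0  # one required argument removed
    duplicate_event: int = 0  # one event copied verbatim
    multi_parent_site: int = 0  # one site entity gains a second SiteParent
    seed: int = 1


def perturb_predictions(corpus: Corpus, error_spec: ErrorSpec) -> Corpus:
    """Inject controlled structural errors into copies of gold documents.

    A zero-error spec returns an identical (deep) copy.  Errors are applied
    to the first eligible sites in deterministic order, so the realized
    counts equal the requested ones whenever the corpus offers enough
    eligible structures.
    """
    from .graph import copy_document

    rng = random.Random(error_spec.seed)
    out = Corpus(corpus.name + "-perturbed", [copy_document(d) for d in corpus.documents])
    budgets = {
        "invalid_role": error_spec.invalid_role,
        "extra_argument": error_spec.extra_argument,
        "drop_argument": error_spec.drop_argument,
        "duplicate_event": error_spec.duplicate_event,
        "multi_parent_site": error_spec.multi_parent_site,
    }
    for doc in out.documents:
        edges = {e.id: e for e in doc.all_edges()}
        for g in list(doc.events):
            plain = [
                edges[a] for a in g.args
                if edges[a].site_of is None
                and not any(e.site_of == edges[a].id for e in doc.all_edges())
            ]
            if budgets["invalid_role"] > 0 and plain:
                plain[0].type = "Bogus"
                budgets["invalid_role"] -= 1
                continue
            if budgets["drop_argument"] > 0 and plain:
                edge = plain[0]
                sent = next(
                    (s for s in doc.sentences if edge in s.interactions), None
                )
                if sent is not None:
                    sent.interactions.remove(edge)
                elif edge in doc.cross_edges:
                    doc.cross_edges.remove(edge)
                g.args = tuple(a for a in g.args if a != edge.id)
                budgets["drop_argument"] -= 1
                continue
            if budgets["extra_argument"] > 0 and plain:
                edge = plain[0]
                dup = replace(edge, id=edge.id + ".dup", extra=dict(edge.extra))
                sent = doc.sentence_of_entity(edge.source)
                if sent is not None:
                    sent.interactions.append(dup)
                    g.args = g.args + (dup.id,)
                    budgets["extra_argument"] -= 1
                continue
            if budgets["duplicate_event"] > 0:
                sent = doc.sentence_of_entity(g.trigger)
                if sent is not None:
                    trig = doc.entity_by_id(g.trigger)
                    copy_trig = replace(
                        trig, id=trig.id + ".dup", extra=dict(trig.extra)
                    )
                    sent.entities.append(copy_trig)
                    new_args = []
                    for aid in g.args:
                        old = edges[aid]
                        new = replace(
                            old, id=old.id + ".dup", source=copy_trig.id,
                            extra=dict(old.extra),
                        )
                        sent.interactions.append(new)
                        new_args.append(new.id)
                    doc.events.append(
                        EventGroup(
                            id=g.id + ".dup", trigger=copy_trig.id,
                            args=tuple(new_args), modifiers=g.modifiers,
                        )
                    )
                    budgets["duplicate_event"] -= 1
                continue
        if budgets["multi_parent_site"] > 0:
            sites = [e for e in doc.all_edges() if e.type == SITEPARENT_TYPE]
            for sp in sites:
                sent = doc.sentence_of_entity(sp.source)
                others = [
                    e for e in sent.entities
                    if e.given and e.id != sp.target
                ]
                if others:
                    sent.interactions.append(
                        InteractionEdge(
                            id=sp.id + ".extra", type=SITEPARENT_TYPE,
                            source=sp.source, target=others[0].id,
                            directed=True, event=False,
                            extra=dict(sp.extra),
                        )
                    )
                    budgets["multi_parent_site"] -= 1
                    break
    return out
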