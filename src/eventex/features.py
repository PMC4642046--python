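"""Classifiable examples with sparse named-feature vectors for the four steps.

Each pipeline step — entity (trigger) detection, edge detection, unmerging
and modifier detection — classifies a different graph element: a token, a
node pair, a candidate argument subset, an event.  All steps share the same
example shape: an identifier, a gold class (when annotation is known), and a
sparse mapping from feature names to values (binary presence, 1.0, except
explicit distance buckets).  The dependency parse is the main source of
features; the central construct for pairwise steps is the shortest path of
dependencies connecting the two head tokens in the undirected dependency
graph.

Candidate generation is scheme-filtered: edge examples are built only for
node pairs between which some valid edge can exist, and unmerging examples
only for argument subsets that form structurally valid events.  This removes
most examples that could only ever be negative and is what keeps unmerging
computationally feasible.
"""

from __future__ import annotations

import itertools
import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .graph import Dependency, Document, EntityNode, SentenceGraph, Token
from .scheme import SITEPARENT_TYPE, AnnotationScheme, is_valid_edge, is_valid_event_structure

logger = logging.getLogger(__name__)

NEGATIVE_CLASS = "neg"
MERGE_SEPARATOR = "---"

#: small default list of speculation-related words; replaceable via the
#: ``spec_words`` argument of :func:`build_modifier_examples`
SPECULATION_WORDS = (
    "may", "might", "could", "can", "appear", "appears", "suggest", "suggests",
    "suggesting", "possible", "possibly", "potential", "potentially", "likely",
    "unlikely", "whether", "putative", "hypothesize", "hypothesized", "unclear",
    "unknown", "probably", "perhaps", "speculate", "significantly",
)

_STEM_SUFFIXES = (
    "ations", "ation", "ingly", "ings", "tion", "sion", "ing", "ed",
    "ion", "es", "ly", "s",
)


def stem(word: str) -> str:
    """Crude suffix-stripping stem; enough to conflate inflected trigger words."""
    w = word.lower()
    for suf in _STEM_SUFFIXES:
        if w.endswith(suf) and len(w) - len(suf) >= 3:
            return w[: -len(suf)]
    return w


@dataclass
class Example:
    id: str
    gold_class: str | None
    features: dict[str, float]
    anchor: tuple  # step-specific reference to the element(s) represented


class FeatureSpace:
    """Bidirectional feature-name ↔ column-index map, frozen after training.

    Names first seen at prediction time map to no column (they are ignored),
    never to a new one, so train- and test-time matrices stay conformable.
    """

    def __init__(self) -> None:
        self._index: dict[str, int] = {}
        self.frozen = False

    def __len__(self) -> int:
        return len(self._index)

    def index_of(self, name: str) -> int | None:
        idx = self._index.get(name)
        if idx is None and not self.frozen:
            idx = self._index[name] = len(self._index)
        return idx

    def name_of(self, idx: int) -> str:
        for name, i in self._index.items():
            if i == idx:
                return name
        raise KeyError(idx)

    @property
    def names(self) -> list[str]:
        return sorted(self._index, key=self._index.__getitem__)

    def freeze(self) -> "FeatureSpace":
        self.frozen = True
        return self

    def transform(self, examples: list[Example]) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for r, ex in enumerate(examples):
            for name, value in ex.features.items():
                c = self.index_of(name)
                if c is not None:
                    rows.append(r)
                    cols.append(c)
                    vals.append(value)
        n_cols = max(len(self._index), 1)
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(examples), n_cols), dtype=np.float64
        )

    def to_dict(self) -> dict[str, int]:
        return dict(self._index)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "FeatureSpace":
        fs = cls()
        fs._index = dict(sorted(d.items(), key=lambda kv: kv[1]))
        fs.frozen = True
        return fs


def export_sparse(examples: list[Example], space: FeatureSpace) -> str:
    """Sparse ``label index:value`` text lines for external trainers."""
    lines = []
    for ex in examples:
        items = sorted(
            (space.index_of(n), v)
            for n, v in ex.features.items()
            if space.index_of(n) is not None
        )
        body = " ".join(f"{i + 1}:{v:g}" for i, v in items)
        lines.append(f"{ex.gold_class or '?'} {body} # {ex.id}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# shortest dependency path
# ---------------------------------------------------------------------------

@dataclass
class ShortestPath:
    tokens: list[Token]
    dependencies: list[Dependency]
    forward: list[bool]  # per step: traversed governor→dependent?

    def __len__(self) -> int:
        return len(self.dependencies)

    @property
    def direction_signature(self) -> str:
        return "".join("F" if f else "R" for f in self.forward)


def shortest_undirected_path(
    t1: str, t2: str, sentence: SentenceGraph
) -> ShortestPath | None:
    """Minimal-length path between two tokens in the undirected dependency graph.

    Among equally short paths the one with the lexicographically smallest
    dependency-type sequence is returned (parallel edges between the same
    token pair are resolved the same way).  Returns None when the tokens are
    disconnected; t1 == t2 yields the empty path.
    """
    tok = {t.id: t for t in sentence.tokens}
    if t1 not in tok or t2 not in tok:
        raise KeyError(f"unknown token in ({t1!r}, {t2!r})")
    if t1 == t2:
        return ShortestPath([tok[t1]], [], [])

    adj: dict[str, dict[str, list[tuple[Dependency, bool]]]] = {}
    for d in sentence.dependencies:
        adj.setdefault(d.governor, {}).setdefault(d.dependent, []).append((d, True))
        adj.setdefault(d.dependent, {}).setdefault(d.governor, []).append((d, False))

    dist = {t1: 0}
    q = deque([t1])
    while q:
        u = q.popleft()
        for v in adj.get(u, {}):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if t2 not in dist:
        return None

    # walk backwards from t2, at each layer choosing the continuation with the
    # smallest (dependency-type, direction) sequence; enumerate all shortest
    # token paths (sentences are small) and pick the lexicographic minimum
    paths: list[list[str]] = []

    def _extend(path: list[str]) -> None:
        u = path[-1]
        if u == t2:
            paths.append(path)
            return
        for v in adj.get(u, {}):
            if dist.get(v) == dist[u] + 1:
                _extend(path + [v])

    _extend([t1])

    def _labels(path: list[str]) -> tuple:
        out = []
        for u, v in zip(path, path[1:]):
            d, fwd = min(adj[u][v], key=lambda df: (df[0].type, not df[1]))
            out.append((d.type, not fwd))
        return tuple(out)

    best = min(paths, key=_labels)
    deps, fwds = [], []
    for u, v in zip(best, best[1:]):
        d, fwd = min(adj[u][v], key=lambda df: (df[0].type, not df[1]))
        deps.append(d)
        fwds.append(fwd)
    return ShortestPath([tok[t] for t in best], deps, fwds)


# ---------------------------------------------------------------------------
# feature builders (token / entity level)
# ---------------------------------------------------------------------------

def _dep_index(sentence: SentenceGraph):
    by_token: dict[str, list[tuple[Dependency, bool]]] = {}
    for d in sentence.dependencies:
        by_token.setdefault(d.governor, []).append((d, True))
        by_token.setdefault(d.dependent, []).append((d, False))
    return by_token


def _given_types_at(sentence: SentenceGraph) -> dict[str, set[str]]:
    at: dict[str, set[str]] = {}
    for e in sentence.entities:
        if e.given and e.head:
            at.setdefault(e.head, set()).add(e.type)
    return at


def token_features(tok: Token, feats: dict[str, float], prefix: str = "") -> None:
    feats[f"{prefix}txt_{tok.text}"] = 1.0
    feats[f"{prefix}POS_{tok.pos}"] = 1.0
    w = tok.text.lower()
    feats[f"{prefix}stem_{stem(w)}"] = 1.0
    for i in range(len(w) - 1):
        feats[f"{prefix}dt_{w[i:i + 2]}"] = 1.0
    for i in range(len(w) - 2):
        feats[f"{prefix}tt_{w[i:i + 3]}"] = 1.0


def linear_context_features(
    tok: Token, sentence: SentenceGraph, feats: dict[str, float],
    window: int = 3, prefix: str = "",
) -> None:
    idx = next(i for i, t in enumerate(sentence.tokens) if t.id == tok.id)
    for off in range(-window, window + 1):
        if off == 0:
            continue
        j = idx + off
        if 0 <= j < len(sentence.tokens):
            other = sentence.tokens[j]
            feats[f"{prefix}linear_{off}_txt_{other.text}"] = 1.0
            feats[f"{prefix}linear_{off}_POS_{other.pos}"] = 1.0


def dependency_context_features(
    tok: Token, sentence: SentenceGraph, feats: dict[str, float],
    depth: int = 3, prefix: str = "",
) -> None:
    """Features from the dependency neighbourhood of a token up to ``depth``.

    Emits per-distance token text/POS and attached given-entity types
    (``dist_d_*``), head-out features for the token's own dependencies
    (``t1HOut_*``), per-distance dependency labels (``dep_dist_*``) and
    direction-labelled dependency chains (``chain_dist_*``).
    """
    by_token = _dep_index(sentence)
    given_at = _given_types_at(sentence)
    tokmap = {t.id: t for t in sentence.tokens}

    for d, fwd in by_token.get(tok.id, []):
        other = tokmap[d.dependent if fwd else d.governor]
        feats[f"{prefix}t1HOut_{d.type}"] = 1.0
        feats[f"{prefix}t1HOut_{d.type}_{other.pos}"] = 1.0
        feats[f"{prefix}t1HOut_{other.text.lower()}"] = 1.0

    # breadth-first over the undirected dependency graph with chain tracking
    frontier = [(tok.id, ())]
    visited = {tok.id}
    for d_level in range(1, depth + 1):
        nxt = []
        for tid, chain in frontier:
            for d, fwd in by_token.get(tid, []):
                other_id = d.dependent if fwd else d.governor
                if other_id in visited:
                    continue
                visited.add(other_id)
                other = tokmap[other_id]
                step = f"{'frw' if fwd else 'rev'}_{d.type}"
                new_chain = chain + (step,)
                feats[f"{prefix}dist_{d_level}_txt_{other.text}"] = 1.0
                feats[f"{prefix}dist_{d_level}_POS_{other.pos}"] = 1.0
                for etype in given_at.get(other_id, ()):
                    feats[f"{prefix}dist_{d_level}_annType_{etype}"] = 1.0
                feats[f"{prefix}dep_dist_dist_{d_level}{d.type}"] = 1.0
                feats[f"{prefix}chain_dist_dist_{d_level}-" + "-".join(new_chain)] = 1.0
                nxt.append((other_id, new_chain))
        frontier = nxt


def sentence_features(sentence: SentenceGraph, feats: dict[str, float], prefix: str = "") -> None:
    for t in sentence.tokens:
        feats[f"{prefix}bow_{t.text}"] = 1.0
    for e in sentence.entities:
        if e.given:
            feats[f"{prefix}sentAnnType_{e.type}"] = 1.0


def entity_features(
    node: EntityNode, sentence: SentenceGraph, feats: dict[str, float], prefix: str = ""
) -> None:
    feats[f"{prefix}nodeType_{node.type}"] = 1.0
    if node.given:
        feats[f"{prefix}given"] = 1.0
    if node.head is not None:
        head = sentence.token_by_id(node.head)
        token_features(head, feats, prefix)
        linear_context_features(head, sentence, feats, prefix=prefix)
        dependency_context_features(head, sentence, feats, prefix=prefix)


# ---------------------------------------------------------------------------
# gold labels
# ---------------------------------------------------------------------------

class GoldLabels:
    """Gold-class lookup for examples built over a (possibly predicted) graph.

    Alignment is by id-free signatures — token heads for entities,
    (source span/type, target span/type, edge type) for edges, trigger plus
    argument-set signatures for events — so that labels can be attached to
    examples generated from predicted upstream output as well as from gold
    annotation itself.  Edges crossing sentence boundaries (and the events
    containing them, transitively) are excluded: they are outside the reach
    of intra-sentence example generation.
    """

    def __init__(self, gold_doc: Document):
        self.doc = gold_doc
        nodes = {e.id: e for e in gold_doc.all_entities()}
        edges = {e.id: e for e in gold_doc.all_edges()}
        sent_of = {}
        for s in gold_doc.sentences:
            for e in s.entities:
                sent_of[e.id] = s.id

        # entity classes per (sentence, head token)
        self.entity_classes: dict[tuple[str, str], set[str]] = {}
        for s in gold_doc.sentences:
            for e in s.entities:
                if not e.given and e.head:
                    self.entity_classes.setdefault((s.id, e.head), set()).add(e.type)

        def _nsig(nid: str) -> tuple:
            n = nodes[nid]
            return (sent_of.get(nid), n.start, n.end, n.type)

        self._nsig = _nsig

        # edge classes between node signatures (intra-sentence edges only)
        self.edge_classes: dict[tuple, set[str]] = {}
        cross_ids = {e.id for e in gold_doc.cross_edges}
        for s in gold_doc.sentences:
            for e in s.interactions:  # every intra-sentence edge is a label
                self.edge_classes.setdefault(
                    (_nsig(e.source), _nsig(e.target)), set()
                ).add(e.type)

        # reachable gold events: all argument edges intra-sentence and all
        # event-valued targets reachable themselves
        groups_of_node: dict[str, list] = {}
        for g in gold_doc.events:
            groups_of_node.setdefault(g.trigger, []).append(g)
        reachable: dict[str, bool] = {}

        def _reachable(g) -> bool:
            if g.id in reachable:
                return reachable[g.id]
            reachable[g.id] = False  # break cycles defensively
            ok = True
            for aid in g.args:
                e = edges[aid]
                if e.id in cross_ids:
                    ok = False
                    break
                tgt = nodes[e.target]
                if tgt.event or groups_of_node.get(tgt.id):
                    if not any(_reachable(c) for c in groups_of_node.get(tgt.id, [])):
                        ok = False
                        break
            reachable[g.id] = ok
            return ok

        self.reachable_events = [g for g in gold_doc.events if _reachable(g)]

        # unmerging: per (sentence, trigger sig): set of gold argument-set
        # signatures; an argument is (edge type, target sig)
        self.event_arg_sets: dict[tuple, set[frozenset]] = {}
        self.event_modifiers: dict[tuple, frozenset] = {}
        for g in self.reachable_events:
            trig_sig = _nsig(g.trigger)
            argsig = frozenset(
                (edges[a].type, _nsig(edges[a].target), i)
                for i, a in enumerate(sorted(g.args, key=lambda x: (edges[x].type, _nsig(edges[x].target))))
            )
            # frozenset of (type, target, occurrence index) to keep repeated
            # same-role-same-target arguments distinct
            self.event_arg_sets.setdefault(trig_sig, set()).add(argsig)
            self.event_modifiers[(trig_sig, argsig)] = g.modifiers

    # -- queries -----------------------------------------------------------
    def entity_class(self, sentence_id: str, token_id: str) -> str:
        types = self.entity_classes.get((sentence_id, token_id))
        if not types:
            return NEGATIVE_CLASS
        return MERGE_SEPARATOR.join(sorted(types))

    def node_signature(self, sentence: SentenceGraph, node: EntityNode) -> tuple:
        return (sentence.id, node.start, node.end, node.type)

    def edge_class(
        self, sentence: SentenceGraph, a: EntityNode, b: EntityNode, directed: bool = True
    ) -> str:
        sa, sb = self.node_signature(sentence, a), self.node_signature(sentence, b)
        types = set(self.edge_classes.get((sa, sb), set()))
        if not directed:
            types |= self.edge_classes.get((sb, sa), set())
        if not types:
            return NEGATIVE_CLASS
        return MERGE_SEPARATOR.join(sorted(types))

    def subset_signature(self, sentence: SentenceGraph, doc_or_sent, subset) -> frozenset:
        items = sorted(
            ((e.type, self.node_signature(sentence, n)) for e, n in subset),
            key=lambda x: (x[0], x[1]),
        )
        return frozenset((t, s, i) for i, (t, s) in enumerate(items))

    def unmerging_class(
        self, sentence: SentenceGraph, trigger: EntityNode, subset
    ) -> str:
        trig_sig = self.node_signature(sentence, trigger)
        argsig = self.subset_signature(sentence, None, subset)
        if argsig in self.event_arg_sets.get(trig_sig, set()):
            return "event"
        return NEGATIVE_CLASS

    def modifier_class(self, sentence: SentenceGraph, trigger: EntityNode, subset) -> str:
        trig_sig = self.node_signature(sentence, trigger)
        argsig = self.subset_signature(sentence, None, subset)
        mods = self.event_modifiers.get((trig_sig, argsig))
        if not mods:
            return NEGATIVE_CLASS
        return MERGE_SEPARATOR.join(sorted(mods))


# ---------------------------------------------------------------------------
# example builders
# ---------------------------------------------------------------------------

def build_entity_examples(
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    gold: GoldLabels | None = None,
) -> list[Example]:
    """One classifiable example per token not already inside a given entity.

    The gold class is the node type headed at the token — several overlapping
    non-given nodes merge into one class joined by ``---`` — or ``neg``.
    """
    given_spans = [(e.start, e.end) for e in sentence.entities if e.given]
    examples = []
    sent_feats: dict[str, float] = {}
    sentence_features(sentence, sent_feats)
    for i, tok in enumerate(sentence.tokens):
        if any(tok.start < e and tok.end > s for s, e in given_spans):
            continue
        feats: dict[str, float] = dict(sent_feats)
        token_features(tok, feats)
        linear_context_features(tok, sentence, feats)
        dependency_context_features(tok, sentence, feats)
        gold_class = gold.entity_class(sentence.id, tok.id) if gold else None
        examples.append(
            Example(
                id=f"ent.{sentence.id}.{i}",
                gold_class=gold_class,
                features=feats,
                anchor=(sentence.id, tok.id),
            )
        )
    return examples


def _path_features(
    a: EntityNode, b: EntityNode, sentence: SentenceGraph, feats: dict[str, float]
) -> None:
    entity_at_head: dict[str, str] = {}
    for e in sentence.entities:
        if e.head:
            entity_at_head.setdefault(e.head, e.type)
    sp = shortest_undirected_path(a.head, b.head, sentence) if a.head and b.head else None
    if sp is None:
        feats["noDepPath"] = 1.0
        return
    sig = sp.direction_signature
    feats[f"path_sig_{sig}"] = 1.0
    feats[f"path_len_{len(sp)}"] = 1.0
    steps = []
    for d, fwd in zip(sp.dependencies, sp.forward):
        label = f"{'Forward' if fwd else 'Reverse'}_{d.type}"
        feats[f"dep_{label}"] = 1.0
        steps.append(label)
    for k, tok in enumerate(sp.tokens):
        feats[f"tok_{sig[:k]}txt_{tok.text}"] = 1.0
        feats[f"POS_{tok.pos}"] = 1.0
        feats[f"txt_{tok.text.lower()}"] = 1.0
    # whole token path with entity types substituted at annotated heads
    walk = [entity_at_head.get(t.id, t.text) for t in sp.tokens]
    feats["tokenPath_" + "_".join(walk)] = 1.0
    for n in (2, 3, 4):
        for k in range(len(steps) - n + 1):
            feats[f"ngram_{'-'.join(steps[k:k + n])}"] = 1.0


def edge_candidates(
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    nodes: list[EntityNode] | None = None,
) -> list[tuple[EntityNode, EntityNode, bool]]:
    """Scheme-filtered candidate node pairs for edge detection.

    Exactly the ordered pairs licensed for some directed edge type, plus one
    unordered pair (first-by-position source) for types licensed only
    undirected between the two node types.
    """
    if nodes is None:
        nodes = sentence.entities
    edge_types = sorted(scheme.edge_types())
    directed_types = [
        t for t in edge_types
        if t in scheme.relations and not scheme.relations[t].directed
    ]
    undirected_set = set(directed_types)
    out = []
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            fwd = any(
                is_valid_edge(scheme, a.type, b.type, t)
                for t in edge_types
                if t not in undirected_set
            )
            und = i < j and any(
                is_valid_edge(scheme, a.type, b.type, t) for t in undirected_set
            )
            if fwd:
                out.append((a, b, True))
            elif und:
                out.append((a, b, False))
    return out


def build_edge_examples(
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    nodes: list[EntityNode] | None = None,
    gold: GoldLabels | None = None,
) -> list[Example]:
    """One example per scheme-licensed node pair; class = edge type(s) or neg."""
    examples = []
    sent_feats: dict[str, float] = {}
    sentence_features(sentence, sent_feats)
    for k, (a, b, directed) in enumerate(edge_candidates(sentence, scheme, nodes)):
        feats: dict[str, float] = dict(sent_feats)
        entity_features(a, sentence, feats, prefix="e1_")
        entity_features(b, sentence, feats, prefix="e2_")
        _path_features(a, b, sentence, feats)
        gold_class = gold.edge_class(sentence, a, b, directed) if gold else None
        examples.append(
            Example(
                id=f"edge.{sentence.id}.{k}",
                gold_class=gold_class,
                features=feats,
                anchor=(sentence.id, a.id, b.id, directed),
            )
        )
    return examples


def _resolve_site_primary(
    edge, subset, sentence: SentenceGraph, doc: Document | None, allowed_roles=None
):
    """Primary role of a Site edge within a candidate argument subset.

    ``siteOf`` resolves directly (known data); otherwise SiteParent linkage
    is followed, preferring primaries whose role the scheme licenses for
    Site attachment (this disambiguates e.g. self-phosphorylation, where
    Theme and Cause target the same protein but only Theme takes a Site).
    """
    if edge.site_of is not None:
        for e, _ in subset:
            if e.id == edge.site_of:
                return e.type
        return None
    parents = set()
    pool = doc.all_edges() if doc is not None else sentence.interactions
    for sp in pool:
        if sp.type == SITEPARENT_TYPE and sp.source == edge.target:
            parents.add(sp.target)
    cands = [e for e, n in subset if e.target in parents and e is not edge]
    if allowed_roles is not None:
        licensed = [e for e in cands if e.type in allowed_roles]
        cands = licensed or cands
    if not cands:
        return None
    return min(cands, key=lambda e: e.id).type


def valid_argument_subsets(
    trigger: EntityNode,
    out_edges: list,
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    doc: Document | None = None,
    max_subsets: int = 4096,
) -> list[list]:
    """All subsets of a trigger's outgoing edges that form valid events.

    Enumerates the power set (smallest subsets first) and keeps subsets that
    pass structural validation; enumeration stops with a warning once
    ``max_subsets`` candidates have been examined.
    """
    node_of = {}
    for e in out_edges:
        if doc is not None:
            node_of[e.target] = doc.entity_by_id(e.target)
        else:
            node_of[e.target] = sentence.entity_by_id(e.target)
    valid = []
    examined = 0
    capped = False
    for size in range(0, len(out_edges) + 1):
        for combo in itertools.combinations(out_edges, size):
            examined += 1
            if examined > max_subsets:
                capped = True
                break
            subset = [(e, node_of[e.target]) for e in combo]
            d = scheme.events.get(trigger.type)
            args = []
            for e, n in subset:
                primary = None
                c = d.arguments.get(e.type) if d else None
                if c is not None and c.site_primary_roles is not None:
                    primary = _resolve_site_primary(
                        e, subset, sentence, doc, c.site_primary_roles
                    )
                elif e.site_of is not None:
                    primary = _resolve_site_primary(e, subset, sentence, doc)
                args.append((e.type, n.type, primary))
            if is_valid_event_structure(scheme, trigger.type, args):
                valid.append(subset)
        if capped:
            logger.warning(
                "trigger %s: subset enumeration capped at %d candidates",
                trigger.id,
                max_subsets,
            )
            break
    return valid


def build_unmerging_examples(
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    gold: GoldLabels | None = None,
    doc: Document | None = None,
    max_subsets: int = 4096,
) -> list[Example]:
    """One example per (trigger node, structurally valid outgoing-edge subset).

    The positive class marks subsets equal to a gold event's argument set.
    Argument features are the path features of each included edge prefixed by
    its role; trigger features carry the ``trg_`` prefix; a bag of words over
    the event's linear span and dependency labels outside it complete the set.
    """
    examples = []
    out_by_node: dict[str, list] = {}
    for e in sentence.interactions:
        if e.event or (e.type != SITEPARENT_TYPE and e.type not in scheme.relations):
            out_by_node.setdefault(e.source, []).append(e)
    k = 0
    for node in sentence.entities:
        if node.type not in scheme.events:
            continue
        out_edges = sorted(out_by_node.get(node.id, []), key=lambda e: e.id)
        for subset in valid_argument_subsets(
            node, out_edges, sentence, scheme, doc, max_subsets
        ):
            feats: dict[str, float] = {}
            entity_features(node, sentence, feats, prefix="trg_")
            feats[f"nArgs_{len(subset)}"] = 1.0
            span_tokens = {node.head}
            for e, n in subset:
                prefix = f"arg{e.type}_"
                entity_features(n, sentence, feats, prefix=prefix)
                pf: dict[str, float] = {}
                _path_features(node, n, sentence, pf)
                for name, v in pf.items():
                    feats[prefix + name] = v
                span_tokens.add(n.head)
            positions = [
                i for i, t in enumerate(sentence.tokens) if t.id in span_tokens
            ]
            if positions:
                lo, hi = min(positions), max(positions)
                for t in sentence.tokens[lo : hi + 1]:
                    feats[f"bow_{t.text}"] = 1.0
                inside = {t.id for t in sentence.tokens[lo : hi + 1]}
                for d in sentence.dependencies:
                    if d.governor not in inside or d.dependent not in inside:
                        feats[f"ctx_dep_{d.type}"] = 1.0
            gold_class = (
                gold.unmerging_class(sentence, node, subset) if gold else None
            )
            examples.append(
                Example(
                    id=f"unm.{sentence.id}.{k}",
                    gold_class=gold_class,
                    features=feats,
                    anchor=(sentence.id, node.id, tuple(e.id for e, _ in subset)),
                )
            )
            k += 1
    return examples


def build_modifier_examples(
    sentence: SentenceGraph,
    scheme: AnnotationScheme,
    events: list[tuple[EntityNode, list]],
    gold: GoldLabels | None = None,
    spec_words: tuple[str, ...] = SPECULATION_WORDS,
) -> list[Example]:
    """One example per event whose trigger type can carry a modifier.

    ``events`` lists (trigger node, argument subset) pairs — the unmerged
    events of the sentence.  Classes combine negation and speculation; the
    ``spec`` feature group flags matches against a curated speculation word
    list.
    """
    capable = set()
    for types in scheme.modifier_targets.values():
        capable |= types
    examples = []
    words = {w.lower() for w in spec_words}
    for k, (node, subset) in enumerate(events):
        if node.type not in capable:
            continue
        feats: dict[str, float] = {}
        entity_features(node, sentence, feats, prefix="")
        sentence_features(sentence, feats)
        for t in sentence.tokens:
            if t.text.lower() in words:
                feats[f"specWord_{t.text.lower()}"] = 1.0
        gold_class = gold.modifier_class(sentence, node, subset) if gold else None
        examples.append(
            Example(
                id=f"mod.{sentence.id}.{k}",
                gold_class=gold_class,
                features=feats,
                anchor=(sentence.id, node.id, tuple(e.id for e, _ in subset)),
            )
        )
    return examples
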