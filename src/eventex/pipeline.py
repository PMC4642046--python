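"""Train/predict orchestration over the step sequence, evaluation, ablation.

Event extraction proceeds through four consecutive, independent
classification steps: entity (trigger) detection over tokens, recall
adjustment of the trigger predictions, edge detection over scheme-licensed
node pairs, unmerging of each trigger's pooled argument edges into
individual structurally valid events, and modifier detection over the
resulting events.  Each downstream step is trained on gold upstream
annotation; at prediction time each consumes the previous step's output.

Evaluation is micro-averaged F-score, either over classification examples or
over whole events, where events match on type, trigger span and recursively
matched arguments with roles.  Replacing any subset of the steps with the
always-correct oracle classifier isolates the error contributed by each
component; with every step oracle and no sentence-boundary-crossing gold
interactions, event-level F is exactly 100.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import st_io
from .classify import (
    NEGATIVE_CLASS,
    OracleClassifier,
    PredictionRecord,
    adjust_recall,
)
from .features import (
    MERGE_SEPARATOR,
    GoldLabels,
    build_edge_examples,
    build_entity_examples,
    build_modifier_examples,
    build_unmerging_examples,
)
from .graph import Corpus, Document, EntityNode, EventGroup, InteractionEdge, copy_document
from .scheme import AnnotationScheme, learn_scheme, parse_scheme, serialize_scheme
from .st_io import STDocument, graph_to_st, split_role

logger = logging.getLogger(__name__)

STEPS = ("entity", "edge", "unmerging", "modifier")


@dataclass
class PipelineConfig:
    """Configuration of the extraction pipeline.

    ``adapters`` maps step name to an adapter factory spec; ``beta`` is the
    recall-adjustment multiplier applied to entity-step predictions;
    ``unmerging_cap`` bounds argument-subset enumeration per trigger.
    """

    steps: tuple[str, ...] = STEPS
    beta: float = 1.0
    beta_grid: tuple[float, ...] = ()
    unmerging_cap: int = 4096
    seed: int = 1
    learn_on: tuple[str, ...] = ("train", "devel")

    def __post_init__(self):
        unknown = set(self.steps) - set(STEPS)
        if unknown:
            raise ValueError(f"unknown pipeline steps: {sorted(unknown)}")
        if tuple(s for s in STEPS if s in self.steps) != tuple(self.steps):
            raise ValueError("steps must respect the order entity→edge→unmerging→modifier")


@dataclass
class ModelBundle:
    scheme: AnnotationScheme
    adapters: dict[str, object]
    beta: float = 1.0
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def save(self, directory: str | Path) -> None:
        import joblib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "scheme.txt").write_text(serialize_scheme(self.scheme))
        (directory / "settings.json").write_text(
            json.dumps({"beta": self.beta, "unmerging_cap": self.config.unmerging_cap,
                        "seed": self.config.seed}, indent=2)
        )
        joblib.dump(self.adapters, directory / "adapters.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        import joblib

        directory = Path(directory)
        scheme = parse_scheme((directory / "scheme.txt").read_text())
        settings = json.loads((directory / "settings.json").read_text())
        adapters = joblib.load(directory / "adapters.joblib")
        cfg = PipelineConfig(
            beta=settings["beta"],
            unmerging_cap=settings["unmerging_cap"],
            seed=settings["seed"],
        )
        return cls(scheme=scheme, adapters=adapters, beta=settings["beta"], config=cfg)


# ---------------------------------------------------------------------------
# example generation over a corpus
# ---------------------------------------------------------------------------

def _gold_events_by_sentence(doc: Document):
    by_sent: dict[str, list] = {}
    for g in doc.events:
        sent = doc.sentence_of_entity(g.trigger)
        if sent is not None:
            by_sent.setdefault(sent.id, []).append(g)
    return by_sent


def build_step_examples(step: str, doc: Document, scheme: AnnotationScheme,
                        labels: GoldLabels | None, cap: int = 4096):
    """Gold-state examples for one step of one (annotated) document."""
    out = []
    for sent in doc.sentences:
        if not sent.tokens:
            logger.warning("%s: sentence %s has no parse; skipped", doc.id, sent.id)
            continue
        if step == "entity":
            out.extend(build_entity_examples(sent, scheme, gold=labels))
        elif step == "edge":
            out.extend(build_edge_examples(sent, scheme, gold=labels))
        elif step == "unmerging":
            out.extend(
                build_unmerging_examples(sent, scheme, gold=labels, doc=doc, max_subsets=cap)
            )
        elif step == "modifier":
            events = []
            for g in _gold_events_by_sentence(doc).get(sent.id, []):
                edges = {e.id: e for e in doc.all_edges()}
                subset = [
                    (edges[a], doc.entity_by_id(edges[a].target)) for a in g.args
                ]
                trig = doc.entity_by_id(g.trigger)
                events.append((trig, subset))
            out.extend(build_modifier_examples(sent, scheme, events, gold=labels))
        else:  # pragma: no cover - guarded by PipelineConfig
            raise ValueError(step)
    return out


def train_pipeline(
    train: Corpus,
    devel: Corpus | None,
    adapters: dict[str, object],
    cfg: PipelineConfig | None = None,
) -> ModelBundle:
    """Learn the scheme, build gold examples per step, and train each adapter.

    Downstream steps are trained on gold upstream annotation.  When a beta
    grid is configured, the recall-adjustment multiplier is tuned against
    end-to-end event F on the development set (ties favour the largest beta);
    tuning without a development corpus is a configuration error.
    """
    cfg = cfg or PipelineConfig()
    learn_docs = list(train.documents)
    if devel is not None and "devel" in cfg.learn_on:
        learn_docs += devel.documents
    scheme = learn_scheme(learn_docs)

    for step in cfg.steps:
        examples = []
        for doc in train.documents:
            labels = GoldLabels(doc)
            examples.extend(build_step_examples(step, doc, scheme, labels, cfg.unmerging_cap))
        adapters[step].train(examples)

    bundle = ModelBundle(scheme=scheme, adapters=adapters, beta=cfg.beta, config=cfg)
    if cfg.beta_grid:
        if devel is None or not devel.documents:
            raise ValueError("beta tuning requires a development corpus")
        best = None
        gold_st = [graph_to_st(d, scheme) for d in devel.documents]
        for beta in cfg.beta_grid:
            bundle.beta = beta
            _, pred_st = predict_corpus(devel, bundle)
            f = evaluate_micro_f(pred_st, gold_st).micro_f
            if best is None or (f, beta) > best:
                best = (f, beta)
        bundle.beta = best[1]
    return bundle


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _strip_document(doc: Document) -> Document:
    """Remove everything that is a prediction target, keep given annotation."""
    out = copy_document(doc)
    for sent in out.sentences:
        sent.entities = [e for e in sent.entities if e.given]
        sent.interactions = [e for e in sent.interactions if e.given]
    out.cross_edges = [e for e in out.cross_edges if e.given]
    out.events = []
    kept = {e.id for e in out.all_entities()}
    out.equivs = [g for g in out.equivs if g <= kept]
    return out


def predict_document(
    gold_doc: Document, bundle: ModelBundle, use_gold_labels: bool = True
) -> tuple[Document, STDocument]:
    """Run the full step sequence on one document; returns graph + standoff.

    ``use_gold_labels`` attaches gold classes to generated examples (required
    by oracle adapters; harmless for trained ones).
    """
    scheme = bundle.scheme
    labels = GoldLabels(gold_doc) if use_gold_labels else None
    doc = _strip_document(gold_doc)
    counter = itertools.count()

    for sent in doc.sentences:
        if not sent.tokens:
            logger.warning("%s: sentence %s has no parse; skipped", doc.id, sent.id)
            continue

        # -- entity step + recall adjustment ------------------------------
        if "entity" in bundle.adapters:
            examples = build_entity_examples(sent, scheme, gold=labels)
            records = bundle.adapters["entity"].predict(examples)
            records = adjust_recall(records, bundle.beta)
            by_id = {ex.id: ex for ex in examples}
            for r in records:
                if r.predicted == NEGATIVE_CLASS:
                    continue
                _, tok_id = by_id[r.example_id].anchor
                tok = sent.token_by_id(tok_id)
                for etype in r.predicted.split(MERGE_SEPARATOR):
                    sent.entities.append(
                        EntityNode(
                            id=f"{doc.id}.p{next(counter)}",
                            type=etype,
                            start=tok.start,
                            end=tok.end,
                            text=tok.text,
                            head=tok.id,
                            given=False,
                            event=etype in scheme.events,
                        )
                    )

        # -- edge step ----------------------------------------------------
        if "edge" in bundle.adapters:
            examples = build_edge_examples(sent, scheme, gold=labels)
            records = bundle.adapters["edge"].predict(examples)
            by_id = {ex.id: ex for ex in examples}
            for r in records:
                if r.predicted == NEGATIVE_CLASS:
                    continue
                _, a_id, b_id, directed = by_id[r.example_id].anchor
                for etype in r.predicted.split(MERGE_SEPARATOR):
                    rel = scheme.relations.get(etype)
                    extra = {}
                    if rel is not None:
                        extra = {"e1Role": rel.end1_role, "e2Role": rel.end2_role}
                    sent.interactions.append(
                        InteractionEdge(
                            id=f"{doc.id}.p{next(counter)}",
                            type=etype,
                            source=a_id,
                            target=b_id,
                            directed=rel.directed if rel is not None else True,
                            event=rel is None,
                            given=False,
                            extra=extra,
                        )
                    )

        # -- unmerging step -------------------------------------------------
        if "unmerging" in bundle.adapters:
            examples = build_unmerging_examples(
                sent, scheme, gold=labels, doc=doc, max_subsets=bundle.config.unmerging_cap
            )
            records = bundle.adapters["unmerging"].predict(examples)
            by_id = {ex.id: ex for ex in examples}
            positive_triggers: set[str] = set()
            for r in records:
                if r.predicted == NEGATIVE_CLASS:
                    continue
                _, trig_id, edge_ids = by_id[r.example_id].anchor
                positive_triggers.add(trig_id)
                doc.events.append(
                    EventGroup(
                        id=f"{doc.id}.p{next(counter)}",
                        trigger=trig_id,
                        args=edge_ids,
                    )
                )
            # triggers with no positive subset are dropped with their edges
            dead = {
                e.id
                for e in sent.entities
                if e.type in scheme.events and not e.given and e.id not in positive_triggers
            }
            if dead:
                sent.entities = [e for e in sent.entities if e.id not in dead]
                sent.interactions = [
                    e
                    for e in sent.interactions
                    if e.source not in dead and e.target not in dead
                ]
                live_edges = {e.id for e in doc.all_edges()}
                doc.events = [
                    g
                    for g in doc.events
                    if g.trigger not in dead and all(a in live_edges for a in g.args)
                ]

        # -- modifier step --------------------------------------------------
        if "modifier" in bundle.adapters:
            edges = {e.id: e for e in doc.all_edges()}
            sent_nodes = {e.id for e in sent.entities}
            events = []
            group_refs = []
            for g in doc.events:
                if g.trigger in sent_nodes:
                    subset = [
                        (edges[a], doc.entity_by_id(edges[a].target)) for a in g.args
                    ]
                    events.append((doc.entity_by_id(g.trigger), subset))
                    group_refs.append(g)
            examples = build_modifier_examples(sent, scheme, events, gold=labels)
            if examples:
                records = bundle.adapters["modifier"].predict(examples)
                by_id = {ex.id: ex for ex in examples}
                anchor_to_group = {
                    (g.trigger, g.args): g for g in group_refs
                }
                for r in records:
                    if r.predicted == NEGATIVE_CLASS:
                        continue
                    _, trig_id, edge_ids = by_id[r.example_id].anchor
                    g = anchor_to_group.get((trig_id, edge_ids))
                    if g is not None:
                        g.modifiers = frozenset(r.predicted.split(MERGE_SEPARATOR))

    st = graph_to_st(doc, scheme)
    return doc, st


def predict_corpus(
    corpus: Corpus, bundle: ModelBundle, use_gold_labels: bool = True
) -> tuple[list[Document], list[STDocument]]:
    """Apply the pipeline to every document of a corpus."""
    docs, sts = [], []
    for gold_doc in corpus.documents:
        d, s = predict_document(gold_doc, bundle, use_gold_labels)
        docs.append(d)
        sts.append(s)
    return docs, sts


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassCounts:
    matched: int = 0
    spurious: int = 0
    missed: int = 0

    @property
    def precision(self) -> float:
        d = self.matched + self.spurious
        return 100.0 * self.matched / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.matched + self.missed
        return 100.0 * self.matched / d if d else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvaluationResult:
    per_class: dict[str, ClassCounts]
    matched: int
    spurious: int
    missed: int
    micro_precision: float
    micro_recall: float
    micro_f: float


def event_signatures(
    doc: STDocument, include_modifiers: bool = False
) -> list[tuple[str, tuple]]:
    """Recursive id-free signatures of all events and relations of a document.

    An event matches on (type, trigger span, multiset of (role, recursively
    matched argument)); a mismatch anywhere in a nested argument fails the
    whole chain up to the root.
    """
    mods: dict[str, frozenset] = {}
    if include_modifiers:
        by_ev: dict[str, set[str]] = {}
        for m in doc.modifiers:
            by_ev.setdefault(m.target, set()).add(m.kind.lower())
        mods = {k: frozenset(v) for k, v in by_ev.items()}

    memo: dict[str, tuple] = {}

    def _sig(eid: str) -> tuple:
        if eid in memo:
            return memo[eid]
        ev = doc.events[eid]
        parts = []
        for role, target in ev.args:
            base = split_role(role)[0]
            if target in doc.events:
                parts.append((base, _sig(target)))
            else:
                e = doc.entities[target]
                parts.append((base, ("T", e.start, e.end, e.type)))
        trig = doc.entities[ev.trigger]
        sig = (
            "E",
            ev.type,
            trig.start,
            trig.end,
            tuple(sorted(parts)),
            mods.get(eid, frozenset()) if include_modifiers else frozenset(),
        )
        memo[eid] = sig
        return sig

    out = [(doc.events[eid].type, _sig(eid)) for eid in doc.events]
    for rel in doc.relations.values():
        ends = []
        for role, target in rel.args:
            e = doc.entities[target]
            ends.append((split_role(role)[0], (e.start, e.end, e.type)))
        out.append((rel.type, ("R", rel.type, tuple(sorted(ends)))))
    return out


def evaluate_micro_f(
    pred: list[STDocument],
    gold: list[STDocument],
    include_modifiers: bool = False,
) -> EvaluationResult:
    """Event-level micro-averaged precision/recall/F over aligned documents.

    Matching is exact-span, per document, by multiset intersection of event
    signatures.  Percentages are reported to two decimals.
    """
    gold_by_id = {d.id: d for d in gold}
    per_class: dict[str, ClassCounts] = {}

    def _count(cls: str) -> ClassCounts:
        return per_class.setdefault(cls, ClassCounts())

    for pdoc in pred:
        gdoc = gold_by_id.get(pdoc.id, STDocument(pdoc.id, pdoc.text))
        psigs = event_signatures(pdoc, include_modifiers)
        gsigs = event_signatures(gdoc, include_modifiers)
        gpool: dict[tuple, int] = {}
        for cls, sig in gsigs:
            gpool[sig] = gpool.get(sig, 0) + 1
        for cls, sig in psigs:
            if gpool.get(sig, 0) > 0:
                gpool[sig] -= 1
                _count(cls).matched += 1
            else:
                _count(cls).spurious += 1
        ppool: dict[tuple, int] = {}
        for cls, sig in psigs:
            ppool[sig] = ppool.get(sig, 0) + 1
        for cls, sig in gsigs:
            if ppool.get(sig, 0) > 0:
                ppool[sig] -= 1
            else:
                _count(cls).missed += 1

    matched = sum(c.matched for c in per_class.values())
    spurious = sum(c.spurious for c in per_class.values())
    missed = sum(c.missed for c in per_class.values())
    micro = ClassCounts(matched, spurious, missed)
    return EvaluationResult(
        per_class=per_class,
        matched=matched,
        spurious=spurious,
        missed=missed,
        micro_precision=round(micro.precision, 2),
        micro_recall=round(micro.recall, 2),
        micro_f=round(micro.f, 2),
    )


# ---------------------------------------------------------------------------
# component ablation
# ---------------------------------------------------------------------------

ABLATION_ROWS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("None", ()),
    ("Entity", ("entity",)),
    ("Edge", ("edge",)),
    ("Unmerging", ("unmerging",)),
    ("Entity+Edge", ("entity", "edge")),
    ("All", STEPS),
)


def ablate_components(
    corpus: Corpus,
    bundle: ModelBundle,
    rows: tuple[tuple[str, tuple[str, ...]], ...] = ABLATION_ROWS,
    include_modifiers: bool = False,
) -> dict[str, EvaluationResult]:
    """Replace named steps with the always-correct oracle and re-evaluate.

    Returns one evaluation per row; the ``None`` row is the plain pipeline,
    the ``All`` row its theoretical ceiling (bounded only by annotation the
    pipeline cannot reach, such as sentence-boundary-crossing arguments).
    """
    gold_st = [graph_to_st(d, bundle.scheme) for d in corpus.documents]
    results = {}
    for name, oracle_steps in rows:
        unknown = set(oracle_steps) - set(STEPS)
        if unknown:
            raise ValueError(f"unknown steps {sorted(unknown)} in ablation row {name!r}")
        adapters = dict(bundle.adapters)
        for step in oracle_steps:
            adapters[step] = OracleClassifier()
        swapped = ModelBundle(
            scheme=bundle.scheme,
            adapters=adapters,
            beta=1.0 if set(oracle_steps) >= {"entity"} else bundle.beta,
            config=bundle.config,
        )
        _, pred_st = predict_corpus(corpus, swapped)
        results[name] = evaluate_micro_f(pred_st, gold_st, include_modifiers)
    return results


def oracle_bundle(scheme: AnnotationScheme, cfg: PipelineConfig | None = None) -> ModelBundle:
    """A bundle with the always-correct classifier at every step."""
    cfg = cfg or PipelineConfig()
    return ModelBundle(
        scheme=scheme,
        adapters={step: OracleClassifier() for step in cfg.steps},
        beta=1.0,
        config=cfg,
    )
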