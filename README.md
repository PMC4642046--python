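# eventex

Corpus-agnostic biomedical event extraction over interaction graphs.

Biomedical *events* are typed n-ary relations anchored to trigger words —
`Phosphorylation(Theme: STAT3, Site: Ser-727, Cause: PKCδ)` — whose arguments
may themselves be events, producing nested structures.  Shared-task corpora
distribute such annotation in the standoff format: per-document `.txt`
(text), `.a1` (given entities) and `.a2` (triggers, events, relations,
modifiers, equivalence lines), accompanied by tokenisations and
collapsed-CC Stanford dependency parses.

`eventex` is for text-mining researchers who want a single pipeline that
adapts itself to any such corpus.  It models extraction as **graph
generation**: named entities and triggers are nodes bound to syntactic head
tokens, relations and event arguments are typed directed edges, and an event
is a trigger node with its set of outgoing argument edges.  Extraction is
decomposed into four consecutive multiclass classification steps:

1. **entity** — one example per token; classes are node types, with
   overlapping nodes handled by merged classes (`Phosphorylation---Regulation`);
2. **recall adjustment** — the negative class confidence is scaled by
   β ∈ [0, 1], trading trigger precision for downstream event recall;
3. **edge** — one example per node pair licensed by the annotation scheme;
4. **unmerging** — one example per structurally valid subset of a trigger's
   pooled outgoing edges, "pulling apart" overlapping events that share a
   trigger; followed by an optional **modifier** step (negation/speculation).

The piece that makes this corpus-agnostic is the **annotation scheme
learner**: a deterministic rule-based pass over the annotated corpus that
induces, for every event type, per-role and overall argument-count intervals
`[min, max]` as the observed extremes, licensed target types, Site-argument
primary roles (via the `siteOf` edge attribute), relation endpoint types,
modifier targets and prediction targets.  The learned scheme drives candidate
filtering in edge detection and unmerging — without it the power-set
enumeration of unmerging would be infeasible — and a validator/repair pass
guarantees that every emitted `.a2` file is structurally valid.

Classifiers are pluggable: any scikit-learn estimator with per-class
confidences, plus an "always correct" oracle used to measure how much error
each pipeline component contributes.  Everything is testable offline via a
synthetic-corpus generator that realizes a generating scheme with
controllable rates of nesting, shared triggers, Site structures, equivalence
groups, modifiers and cross-sentence arguments.

## Worked example

Generate a small gold corpus, induce its scheme, and verify the oracle
ceiling:

```bash
$ eventex generate --n 5 --seed 1 --out corpus.xml --standoff-dir st
documents=5
events=25
nested_events=2
equiv_groups=2
shared_trigger_sites=1
site_args=1
...
```

The generator reports the realized structural phenomena.  Scheme induction
prints a table-style rule set — observed argument-count extremes per event
type, Site primary roles in braces, relation endpoints, modifier and
prediction targets:

```bash
$ eventex learn-scheme --corpus corpus.xml
ENTITY  Entity
ENTITY  Protein
EVENT   Binding [1,2]           Theme [1,2] Protein
EVENT   Glycolysis [0,0]
EVENT   Phosphorylation [2,3]   Cause [1,1] Protein / Site {Theme} [0,1] Entity / Theme [1,1] Protein
EVENT   Regulation [1,2]        Cause [0,1] Protein / Theme [1,1] Binding, Expression, Protein
RELATION SiteParent, directed   Arg1(Entity) / Arg2(Protein)
MODIFIER negation               Binding, Phosphorylation, Regulation
...
```

Note `Glycolysis [0,0]`: a zero-argument event type, learned as an event
(not an entity) because trigger nodes carry an explicit `event` attribute.
With the always-correct classifier at every step, event-level F on an
intra-sentence corpus is exactly 100 — the pipeline's structural ceiling:

```bash
$ eventex ablate --corpus corpus.xml
All     P=100.00        R=100.00        F=100.00
```

`eventex train` / `eventex classify` run the same pipeline with scikit-learn
classifiers; `eventex visualize --input corpus.xml --sentence d0.s0` emits a
GraphViz dot rendering of a sentence's parse and annotation.

The same flow from Python:

```python
from eventex import GeneratorSpec, generate_corpus, learn_scheme
from eventex.pipeline import oracle_bundle, predict_corpus, evaluate_micro_f
from eventex.st_io import graph_to_st

gen = generate_corpus(GeneratorSpec(documents=5, seed=1))
scheme = learn_scheme(gen.corpus)
_, predicted = predict_corpus(gen.corpus, oracle_bundle(scheme))
gold = [graph_to_st(d, scheme) for d in gen.corpus.documents]
print(evaluate_micro_f(predicted, gold).micro_f)   # 100.0
```

## Documentation

`docs/methods.md` describes the model, the learned-scheme semantics, the
synthetic-data generator and the numerical/design choices in detail.
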