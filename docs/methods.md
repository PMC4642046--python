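# Methods

## The graph model

All annotation — named entities, event triggers, binary relations, event
arguments — lives in one representation: entity nodes bound to single
syntactic head tokens, and typed, optionally directed interaction edges
between nodes.  An event is a trigger node plus its outgoing argument edges;
nesting is an edge whose target is another event's trigger node.  Offsets
are 0-based half-open and sentence-scoped; each document carries an explicit
sentence-to-document offset map, so conversion to the document-scoped
standoff format is a pure shift.

Two structural choices deserve spelling out:

**One trigger node per event instance.**  When standoff annotation is
converted to the graph, every event gets its own trigger node, even when
several events share one trigger word (the nodes then have identical spans).
This makes the gold graph the *unmerged* form and conversion lossless: an
event argument pointing at `E2` maps to the node of `E2` specifically, not
to an ambiguous shared node.  Merged nodes — one node per (token, type) with
the union of outgoing edges — arise only in the prediction path, and the
unmerging step is what recovers instance structure from them.  Event
instances are first-class (`EventGroup`: trigger node + argument edge ids +
modifiers) rather than implied by node connectivity.

**Unified Site representation.**  A Site argument adds sub-molecular detail
to a primary argument (which residue of the Theme protein is
phosphorylated).  Naively it is an edge attached to another edge, which a
node/edge graph cannot express.  Instead the Site is an ordinary argument
edge from the trigger to the site entity, a separate directed `SiteParent`
edge links the site entity to its protein, and on known data the Site edge
carries a `siteOf` attribute naming its primary argument's edge.  `siteOf`
is what lets scheme induction learn *which* roles may carry a Site (e.g.
only Theme, even when Cause targets the same protein — the
self-phosphorylation case), and what keeps conversion deterministic.

Head tokens are chosen among tokens overlapping the span: prefer tokens none
of whose governors lies inside the span (governed from outside, or a parse
root); among several, the rightmost; if none qualify, the rightmost
overlapping token.  The rule is a stand-in — no canonical definition exists
for this representation — chosen to be deterministic and close to common
head-percolation practice.

## Standoff conversion

Reading expands equivalence annotation into individual events: every
argument pointing into an `Equiv` group yields one event copy per member,
propagating upward through events that reference the copies; modifiers are
duplicated onto each copy.  Relations with an event-trigger endpoint are
skipped with a warning: the graph has no distinction between a trigger and
its event, so such relations cannot be attached faithfully.  Arguments
crossing sentence boundaries are kept as document-level edges but excluded
from example generation; they define the pipeline's intra-sentence ceiling.

Writing re-attaches Sites to primaries — by `siteOf` when present, otherwise
through SiteParent linkage restricted to scheme-licensed primary roles, and
taking the candidate whose target occurs first in document order.  A Site is
discarded if its primary already has one, and never maps to more than one
primary.  These removals can make two events identical; duplicates are
collapsed recursively until none remain (the event count strictly decreases,
so the recursion terminates), with the surviving copy chosen by canonical
target positions so the choice is independent of internal ids.  Events
referencing removed events are removed recursively.  Events identical up to
equivalent entities collapse to the copy using the class representative (the
member earliest in the document), and the `Equiv` line is re-emitted when it
was given annotation.

Standoff ids are renumbered deterministically on write: `T` records by
(start, end, type) with `.a1` numbering continuing into `.a2`, `E` records
topologically (arguments before referencing events), then `M` and `R`
records.  Reading followed by writing is therefore the identity, and the
full standoff→graph→standoff cycle is the identity on every corpus the
generator emits — including equivalence expansion/collapse, verified at the
byte level.

The Site role dialect on the standoff side pairs by occurrence number:
`SiteK` with `ThemeK` (falling back to `CauseK`), `CSiteK` with `CauseK`.
Primaries outside {Theme, Cause} are representable in Interaction XML
(through `siteOf`) but not in this standoff dialect; the generator
accordingly restricts site primaries to Theme/Cause, as the real corpora do.
Undirected relations are likewise an XML-side concept: `R` lines are
role-ordered and read back as directed.

## Scheme induction

A node type is an event type iff it carries the `event` attribute or has
outgoing *event-argument* edges; outgoing relation edges (a site entity's
SiteParent, an anaphora's coreference) do not make their source an event.
The explicit attribute is what keeps zero-argument event types (realized
only as bare triggers) from being misclassified as entities.  Everything
observed is extremes-of-data: per-role `[min, max]` over all instances of a
type (absent roles count 0), overall totals, target-type sets, site primary
roles via `siteOf`, relation endpoint sets (unioned over both orders for
undirected types), modifier targets, and prediction targets (types lacking
the `given` attribute).  Consequences worth knowing:

- every gold event in the learning corpus validates under the learned
  scheme, by construction;
- adding documents only widens intervals and grows sets (monotonicity);
- the scheme can be *stricter* than a corpus's official guidelines — if the
  data never shows three Binding Themes, three are never allowed.  No
  relaxation mechanism is provided.

The default learning corpus is the union of training and development
partitions.  Schemes serialize to a diffable tab-separated table (one row
per definition) that round-trips losslessly and is stored in the model
bundle next to the trained classifiers.

## Candidate filtering and examples

Edge examples are generated only for node pairs between which some edge type
is licensed; unmerging examples only for argument subsets that validate as
events (per-role counts, overall count, target types, site primaries all
checked, with the Site's primary resolved inside the candidate subset).
Both generators are verified equivalent to brute-force enumeration
(all-ordered-pairs minus invalid; power-set filtering) in the test suite and
the acceptance script.  On generated corpora the edge filter removes roughly
half of the negative pairs; on sparser real-world type systems the reduction
is larger.  Subset enumeration is capped (default 4096 candidates per
trigger, smallest subsets first) with a logged warning.

Features are binary-presence named features (value 1.0): token text/POS,
suffix-stripped stems and character 2-/3-grams (`dt_`/`tt_`), linear context
at signed offsets ±3, dependency context to depth 3 (per-distance
text/POS/given-entity types, direction-labelled chains, head-out
dependencies `t1HOut_*`), sentence bag-of-words and given-type presence, and
— for pairwise steps — the shortest undirected dependency path between head
tokens: per-step direction-labelled dependency labels, per-position tokens
with direction-prefix signatures, a whole-path token signature, and label
n-grams of length 2–4.  Shortest-path ties break lexicographically on the
dependency-label sequence; parallel edges resolve to the smallest label.
The modifier step adds matches against a small built-in speculation word
list (replaceable by the caller).  Window sizes, depth and n-gram lengths
are fixed defaults in the builders.  Feature extraction is pure: identical
sentences yield identical feature multisets, so swapping classifier adapters
cannot change example content.

The feature space freezes after training; names first seen at prediction
time map to no column.

## Classification, recall adjustment, tuning

Adapters wrap scikit-learn estimators (decision values when available,
probabilities otherwise; explicit seeds for anything randomized) next to an
always-correct oracle that returns each example's annotated class.  Recall
adjustment multiplies the negative class's confidence by β ∈ [0, 1] and
re-takes the argmax; records carrying signed decision values are first
shifted per record so the minimum is zero (argmax-preserving and independent
of β), which makes the positive-prediction count non-increasing in β for any
score scale.  β = 1 is the identity, β = 0 forces every example to its best
positive class.  Multiplicative scaling was chosen for scale-invariance
across classifiers and for its clean endpoints; the parameter is tuned by
exhaustive grid search, by default against end-to-end event F on the
development set, with deterministic tie-breaks (largest β, then smallest
regularization).  Tree-ensemble adapters expose impurity-decrease feature
importances, reported per feature group as quartile/outlier summaries and
top-k tables.

## Pipeline and evaluation

Downstream steps train on gold upstream annotation (independent
classification steps, not self-training).  At prediction time a document is
stripped to its given annotation and the steps run in order; predicted
trigger spans are the head token's span, predicted events are the positively
classified argument subsets, and triggers left without any positive subset
are dropped along with their edges — dropping preserves precision and
structural validity.  Conversion to standoff plus the scheme validator
guarantee that predicted `.a2` files always pass validation with an empty
repair log; the repair pass itself (rename an invalid argument to a missing
required role, else remove the argument, else remove the event, then remove
referencing events recursively) exists for foreign or perturbed input and
always terminates in a valid document.

Event-level evaluation is micro-averaged F over exact-span signatures:
(type, trigger span, multiset of (role, recursively matched argument)); a
nested mismatch fails the whole chain.  Modifier flags can be included in
the signature (off by default).  Component ablation replaces any subset of
steps with the oracle; with every step oracle and no cross-sentence gold
interactions, F is exactly 100.00, and with cross-sentence interactions it
equals the closed-form ceiling 2m/(n+m) computed from the counts of
reachable (m) and total (n) gold events — the quantitative statement of what
intra-sentence extraction cannot reach.

## The synthetic generator

Sentences are template-based subject–verb–object token sequences with simple
projective parses (role-typed attachments to the trigger verb), not natural
text.  From a generating scheme the generator draws feasible argument-count
vectors (respecting per-role, overall and site-binding limits) and realizes
them with typed mentions, at configurable rates of nesting, shared triggers,
equivalence groups (emitted in expanded form, with the matching `Equiv`
line), modifiers, binary relations, distractor mentions and cross-sentence
arguments (document-level edges, skipping equivalence-involved events so
expansion symmetry is preserved).  Every emitted corpus passes structural
validation, and the manifest's counts equal the realized counts — the
generation is self-audited.

Saturated mode emits every feasible vector of every event type plus
systematic coverage instances (every role target type, every site primary
role with every primary target type, every modifier target, every relation
endpoint, and one standalone mention per entity type), so scheme induction
recovers the generating scheme *exactly*.  The random-scheme sampler is
constrained to schemes the standoff dialect can round-trip: required roles
ground out in entity types or strictly earlier event types, and site
primaries are entity-targeting Theme/Cause roles.

What passing tests on this generator do **not** show: robustness to noisy
or non-projective parses, discontinuous trigger spans, natural lexical
variety, or the class imbalance of real corpora.  They do show that the
representation, conversions, induction, filtering and orchestration are
exact — the properties that are checkable at all are checked exactly.

Default study conditions (chosen once): 20 documents × 3 sentences, 1–2
events per sentence, nesting 0.3 (depth ≤ 2), shared triggers 0.15,
equivalences 0.1, relations 0.2, distractors 0.3, two-token given mentions
0.15, negation 0.15 / speculation 0.1, cross-sentence 0 (enabled explicitly
where the ceiling is under study).  The acceptance script scales the same
conditions to 1,000 documents for round-tripping, 20 random schemes for
recovery and ≥500 sentences for filter equivalence.

## Known limitations

- The standoff dialect cannot express undirected relations or Site
  primaries outside {Theme, Cause}; Interaction XML can.
- Discontinuous entity spans are kept as covering intervals with the
  literal text preserved; writing emits the covering interval.
- Equivalence collapse assumes expansion symmetry (every member has a
  copy); foreign documents violating it are re-expanded on the next read
  rather than preserved verbatim.
- Learned schemes never relax beyond the data (see above); applying a
  learned scheme to a differently annotated corpus will reject valid events.
- Cartesian expansion of equivalences and of event-valued arguments can in
  principle blow up on adversarial inputs; rates in realistic corpora keep
  it negligible, and unmerging enumeration is capped.
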