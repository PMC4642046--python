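import pytest
from hypothesis import settings

from eventex.graph import Dependency, EntityNode, InteractionEdge, SentenceGraph, Token
from eventex.scheme import learn_scheme
from eventex.synthetic import GeneratorSpec, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_sentence(words, deps=(), entities=(), interactions=(), sent_id="s0"):
    """Build a sentence from (text, pos) pairs; deps/entities by token index."""
    tokens, pos_ = [], 0
    for i, (text, pos) in enumerate(words):
        tokens.append(Token(f"{sent_id}.t{i}", text, pos, pos_, pos_ + len(text)))
        pos_ += len(text) + 1
    text = " ".join(w for w, _ in words)
    dep_objs = [
        Dependency(d, f"{sent_id}.t{g}", f"{sent_id}.t{dp}") for d, g, dp in deps
    ]
    ents = []
    for j, (etype, lo, hi, kw) in enumerate(entities):
        start, end = tokens[lo].start, tokens[hi].end
        ents.append(
            EntityNode(
                id=f"{sent_id}.e{j}", type=etype, start=start, end=end,
                text=text[start:end], head=tokens[hi].id, **kw,
            )
        )
    edges = [
        InteractionEdge(id=f"{sent_id}.i{k}", **kw) for k, kw in enumerate(interactions)
    ]
    return SentenceGraph(
        id=sent_id, text=text, tokens=tokens, dependencies=dep_objs,
        entities=ents, interactions=edges,
    )


@pytest.fixture(scope="session")
def gen_default():
    """A structurally rich generated corpus shared across the suite."""
    return generate_corpus(
        GeneratorSpec(documents=20, seed=3, equiv_rate=0.2, shared_trigger_rate=0.3)
    )


@pytest.fixture(scope="session")
def scheme_default(gen_default):
    return learn_scheme(gen_default.corpus)
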