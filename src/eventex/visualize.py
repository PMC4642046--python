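"""Render a sentence's annotation and parse as a GraphViz dot description.

Nested event structures are hard to read in either standoff lines or XML;
a picture of the dependency parse with entity boxes attached to head tokens
and labelled interaction arrows between them is the quickest way to debug a
prediction.  The contract ends at valid dot text: rendering to an image is
delegated to an external ``dot`` processor when one is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import SentenceGraph

_DEFAULT_COLORS = {
    "token": "lightgrey",
    "entity": "lightyellow",
    "event": "lightblue",
    "given": "palegreen",
}


@dataclass
class RenderOptions:
    show_parse: bool = True
    show_annotation: bool = True
    rankdir: str = "LR"
    colors: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_COLORS))

    def __post_init__(self):
        if not (self.show_parse or self.show_annotation):
            raise ValueError("at least one of the parse/annotation layers must be enabled")


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(sentence: SentenceGraph, opts: RenderOptions | None = None) -> str:
    """Deterministic dot text: one node per token, arcs for dependencies,
    boxes for entities attached to their head tokens, labelled arrows for
    interaction edges.  An empty sentence yields a minimal valid graph with
    a placeholder node."""
    opts = opts or RenderOptions()
    lines = [
        f"digraph {_quote(sentence.id or 'sentence')} {{",
        f"  rankdir={opts.rankdir};",
        "  node [fontname=Helvetica];",
    ]
    if not sentence.tokens:
        lines.append(f'  empty [label="(empty sentence)", shape=plaintext];')
        lines.append("}")
        return "\n".join(lines) + "\n"

    for t in sentence.tokens:
        label = f"{t.text}\\n{t.pos}"
        lines.append(
            f"  {_quote(t.id)} [label={_quote(label)}, shape=ellipse, "
            f"style=filled, fillcolor={_quote(opts.colors['token'])}];"
        )
    if opts.show_parse:
        for d in sentence.dependencies:
            lines.append(
                f"  {_quote(d.governor)} -> {_quote(d.dependent)} "
                f"[label={_quote(d.type)}, color=gray40, fontcolor=gray40];"
            )
    if opts.show_annotation:
        for e in sentence.entities:
            color = (
                opts.colors["given"]
                if e.given
                else opts.colors["event"] if e.event else opts.colors["entity"]
            )
            mods = "".join(f"\\n[{m}]" for m in sorted(e.modifiers))
            lines.append(
                f"  {_quote(e.id)} [label={_quote(e.type + chr(92) + 'n' + e.text + mods)}, "
                f"shape=box, style=filled, fillcolor={_quote(color)}];"
            )
            if e.head is not None:
                lines.append(
                    f"  {_quote(e.id)} -> {_quote(e.head)} [style=dotted, arrowhead=none];"
                )
        for i in sentence.interactions:
            style = "solid" if i.event else "dashed"
            label = i.type + (" (siteOf)" if i.site_of else "")
            arrow = "normal" if i.directed else "none"
            lines.append(
                f"  {_quote(i.source)} -> {_quote(i.target)} "
                f"[label={_quote(label)}, style={style}, arrowhead={arrow}, color=blue, fontcolor=blue];"
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
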