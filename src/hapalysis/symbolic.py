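"""Symbolic representations of a parse: grammar, production graph, pulsicons.

The pulse language is a context-free language over the five-character
alphabet {(, ), :, <, >}: "(" opens a pulse at its starting nadir, ")"
closes it at its ending nadir, ":" marks the peak separating the rising
from the falling side of a composite pulse, and ">"/"<" encode a
falling lead-in or rising tail at the series boundary.  A leaf pulse is
"()"; a composite pulse is "(RISING:FALLING)" whose sides hold the
embedded pulses of the level below; the whole core is wrapped in one
outer group.  One pulsicon is emitted per iteration level by rendering
only the nodes at that level or deeper, so the strings get strictly
shorter up the hierarchy and the deepest pulse-bearing level of a fully
nested parse reads "(())".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .parser import BoundaryFlank, HapResult
from .rates import RiseFallSegment, extract_segments

__all__ = [
    "Grammar",
    "GRAMMAR",
    "PulseNode",
    "ProductionGraph",
    "Pulsicon",
    "GroupNode",
    "PulsiconSyntaxError",
    "build_production_graph",
    "emit_pulsicon",
    "validate_pulsicon",
    "to_dot",
]


@dataclass(frozen=True)
class Grammar:
    """The quadruple defining the pulse language."""

    alphabet: frozenset[str]
    variables: frozenset[str]
    start: str
    rules: tuple[str, ...]


#: The pulse-language grammar: S derives flank-wrapped group sequences,
#: G derives hierarchically matched groups with ":"-separated sides.
GRAMMAR = Grammar(
    alphabet=frozenset("():<>"),
    variables=frozenset({"S", "B", "G", "H"}),
    start="S",
    rules=(
        "S -> B H B",
        "B -> > | < | ε",
        "H -> G H | ε",
        "G -> ( H ) | ( H : H )",
    ),
)


@dataclass
class PulseNode:
    """A pulse in the core tree: a leaf (simple pulse) or a composite
    whose peak splits rising-side from falling-side children."""

    segment: RiseFallSegment
    rising: list["PulseNode"] = field(default_factory=list)
    falling: list["PulseNode"] = field(default_factory=list)

    @property
    def level(self) -> int:
        return self.segment.level

    @property
    def is_leaf(self) -> bool:
        return not (self.rising or self.falling)


@dataclass
class ProductionGraph:
    """Ordered record of the productions generating a series: leading
    flank, core forest of embedded pulses, trailing flank."""

    leading: Optional[BoundaryFlank]
    roots: list[PulseNode]
    trailing: Optional[BoundaryFlank]
    terminal_level: int
    n_pulse_levels: int


@dataclass(frozen=True)
class Pulsicon:
    level: int
    text: str


def build_production_graph(hap: HapResult) -> ProductionGraph:
    """Assemble the core pulse tree from a parse.

    Each level-k segment (k >= 2) becomes a composite whose children are
    the level-(k-1) segments nested in its time span, split at the
    composite's peak; level-1 segments are leaves.  Segments not covered
    by any higher-level segment stay as additional forest roots.
    """
    depth = hap.n_pulse_levels
    per_level: dict[int, list[PulseNode]] = {}
    for k in range(1, depth + 1):
        per_level[k] = [PulseNode(s) for s in extract_segments(hap, k)]
    orphans: list[PulseNode] = []
    for k in range(1, depth):
        parents = per_level[k + 1]
        for node in per_level[k]:
            t = node.segment.peak.time
            home = next(
                (p for p in parents
                 if p.segment.nadir_start.time < t < p.segment.nadir_end.time),
                None,
            )
            if home is None:
                orphans.append(node)
            elif t < home.segment.peak.time:
                home.rising.append(node)
            else:
                home.falling.append(node)
    roots = sorted(
        per_level.get(depth, []) + orphans,
        key=lambda n: n.segment.nadir_start.time,
    )
    leading, trailing = hap.boundary
    return ProductionGraph(
        leading=leading,
        roots=roots,
        trailing=trailing,
        terminal_level=hap.terminal_level,
        n_pulse_levels=depth,
    )


def _render(node: PulseNode, level: int) -> str:
    if node.level < level:
        return ""
    if node.level == level:
        return "()"
    rise = "".join(_render(c, level) for c in node.rising)
    fall = "".join(_render(c, level) for c in node.falling)
    return f"({rise}:{fall})"


def emit_pulsicon(graph: ProductionGraph, level: int) -> Pulsicon:
    """Render the level-``level`` pulsicon from the production graph.

    Only nodes at that level or deeper contribute; the core, when
    non-empty, is wrapped in one outer group, flanked by one ">" or "<"
    per boundary run.  At the terminal (peakless) level only the flank
    symbols remain.
    """
    if not 1 <= level <= graph.terminal_level:
        raise ValueError(
            f"level {level} out of range 1..{graph.terminal_level}"
        )
    core = "".join(_render(r, level) for r in graph.roots)
    text = ""
    if graph.leading is not None:
        text += graph.leading.symbol
    if core:
        text += f"({core})"
    if graph.trailing is not None:
        text += graph.trailing.symbol
    return Pulsicon(level, text)


class PulsiconSyntaxError(ValueError):
    """Rejection of a candidate pulsicon; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass
class GroupNode:
    """A parsed "(...)" group; ``falling`` is None for a plain group
    (no ":"), so a leaf pulse is GroupNode([], None)."""

    rising: list["GroupNode"]
    falling: Optional[list["GroupNode"]]

    @property
    def depth(self) -> int:
        kids = self.rising + (self.falling or [])
        return 1 + max((k.depth for k in kids), default=0)


def validate_pulsicon(text: str) -> list[GroupNode]:
    """Accept iff ``text`` is in the pulse language; return the group forest.

    Balanced parentheses, ":" only directly inside a group, and flank
    symbols only at the two ends; rejection raises
    :class:`PulsiconSyntaxError` with the first offending position.
    """
    pos = 0
    n = len(text)
    for i, ch in enumerate(text):
        if ch not in GRAMMAR.alphabet:
            raise PulsiconSyntaxError(f"character {ch!r} not in alphabet", i)
    while pos < n and text[pos] in "<>":
        pos += 1

    def parse_seq(p: int) -> tuple[list[GroupNode], int]:
        groups = []
        while p < n and text[p] == "(":
            node, p = parse_group(p)
            groups.append(node)
        return groups, p

    def parse_group(p: int) -> tuple[GroupNode, int]:
        p += 1  # consume "("
        rising, p = parse_seq(p)
        falling = None
        if p < n and text[p] == ":":
            falling, p = parse_seq(p + 1)
        if p >= n:
            raise PulsiconSyntaxError("unmatched '('", n)
        if text[p] != ")":
            raise PulsiconSyntaxError(f"unexpected {text[p]!r} inside group", p)
        return GroupNode(rising, falling), p + 1

    forest, pos = parse_seq(pos)
    while pos < n and text[pos] in "<>":
        pos += 1
    if pos != n:
        raise PulsiconSyntaxError(f"unexpected {text[pos]!r}", pos)
    return forest


def to_dot(graph: ProductionGraph) -> str:
    """GraphViz DOT rendering of the production graph (core tree plus
    flank markers), for visual inspection."""
    lines = ["digraph production {", "  node [shape=box];"]
    counter = 0

    def add(node: PulseNode, parent: Optional[str]) -> None:
        nonlocal counter
        name = f"n{counter}"
        counter += 1
        seg = node.segment
        label = (
            f"L{node.level} [{seg.nadir_start.time:g},{seg.nadir_end.time:g}] "
            f"peak t={seg.peak.time:g}"
        )
        lines.append(f'  {name} [label="{label}"];')
        if parent is not None:
            lines.append(f"  {parent} -> {name};")
        for child in node.rising + node.falling:
            add(child, name)

    if graph.leading is not None:
        lines.append('  lead [label=">", shape=plaintext];')
    for root in graph.roots:
        add(root, None)
    if graph.trailing is not None:
        lines.append('  tail [label="<", shape=plaintext];')
    lines.append("}")
    return "\n".join(lines)
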