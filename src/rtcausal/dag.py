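"""Extended causal diagrams with response-type nodes, and d-separation.

The ordinary diagram has four observed nodes (C -> E, C -> D, E -> D,
E -> S, D -> S).  The extended diagram adds one response-type node per
caused variable (``ET``, ``DT``, ``ST``) whose only outgoing arrow points to
its observed variable, plus three mutually independent latent common causes
``U1``, ``U2``, ``U3`` of the response types (``U1`` also causes ``C``).
The observed variable is then a deterministic function of its response type
and its observed parents — e.g. ``E = C*E_1 + (1-C)*E_0``.

Intervention is graph surgery: marginal randomization of exposure deletes
both arrows into ``E``; stratified randomization deletes only ``ET -> E``.
Conditioning is always an explicit set argument, never graph mutation.

The d-separation engine is path-based (enumerate simple paths in the
skeleton, classify each by the collider rule); tests cross-check it against
an independent reachability-style oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

#: edge set of the extended base diagram
_BASE_EDGES = (
    ("U1", "C"), ("U1", "ET"), ("U1", "DT"), ("U1", "ST"),
    ("U2", "ET"), ("U2", "DT"), ("U2", "ST"),
    ("U3", "DT"), ("U3", "ST"),
    ("ET", "E"), ("C", "E"),
    ("DT", "D"), ("C", "D"), ("E", "D"),
    ("ST", "S"), ("E", "S"), ("D", "S"),
)

_OBSERVED_EDGES = (("C", "E"), ("C", "D"), ("E", "D"), ("E", "S"), ("D", "S"))

#: diagram variants: the plain observed diagram, the extended base diagram,
#: its marginal-randomization surgery, its stratified-randomization surgery,
#: and the observational stratification scenario (same graph as the base;
#: conditioning on C is an analysis choice, not a structural one)
GRAPH_VARIANTS = ("fig1", "fig5", "fig6", "fig7", "fig8")


def build_graph(variant: str) -> nx.DiGraph:
    """Build a diagram variant.

    ``fig1``: observed variables only.  ``fig5``: extended base diagram.
    ``fig6``: marginal randomization (both arrows into E removed).
    ``fig7``: stratified randomization (only ET -> E removed).
    ``fig8``: observational study analyzed within C strata — structurally
    identical to ``fig5``.
    """
    if variant not in GRAPH_VARIANTS:
        raise ValueError(f"unknown graph variant {variant!r}; expected one of {GRAPH_VARIANTS}")
    if variant == "fig1":
        g = nx.DiGraph(_OBSERVED_EDGES)
    else:
        g = nx.DiGraph(_BASE_EDGES)
        if variant == "fig6":
            g.remove_edges_from([("C", "E"), ("ET", "E")])
        elif variant == "fig7":
            g.remove_edge("ET", "E")
    assert nx.is_directed_acyclic_graph(g)
    g.graph["variant"] = variant
    return g


@dataclass(frozen=True)
class Path:
    """An undirected simple path with its edge orientations.

    ``nodes`` is the node sequence; ``forward[i]`` is True when the i-th
    edge is oriented ``nodes[i] -> nodes[i+1]`` in the DAG.
    """

    nodes: tuple[str, ...]
    forward: tuple[bool, ...]

    def __str__(self) -> str:
        parts = [self.nodes[0]]
        for node, fwd in zip(self.nodes[1:], self.forward):
            parts.append(" -> " if fwd else " <- ")
            parts.append(node)
        return "".join(parts)

    @classmethod
    def parse(cls, text: str) -> "Path":
        """Parse a path written as e.g. ``"E -> S <- D <- DT"``."""
        tokens = text.split()
        nodes = tuple(tokens[0::2])
        arrows = tokens[1::2]
        if any(a not in ("->", "<-") for a in arrows) or len(arrows) != len(nodes) - 1:
            raise ValueError(f"malformed path {text!r}")
        return cls(nodes, tuple(a == "->" for a in arrows))

    def colliders(self) -> tuple[str, ...]:
        """Interior nodes with both path edges pointing into them."""
        out = []
        for pos in range(1, len(self.nodes) - 1):
            if self.forward[pos - 1] and not self.forward[pos]:
                out.append(self.nodes[pos])
        return tuple(out)


def _orient(g: nx.DiGraph, a: str, b: str) -> bool:
    if g.has_edge(a, b):
        return True
    if g.has_edge(b, a):
        return False
    raise ValueError(f"no edge between {a} and {b} in graph")


def simple_paths(g: nx.DiGraph, x: str, y: str, max_edges: int = 8) -> list[Path]:
    """All undirected simple paths between two nodes, lexicographic order.

    Enumerates simple paths in the skeleton (ignoring direction) up to
    ``max_edges`` edges and records each edge's orientation.
    """
    for node in (x, y):
        if node not in g:
            raise ValueError(f"unknown node {node!r}")
    if x == y:
        raise ValueError("path endpoints must differ")
    if max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    skeleton = g.to_undirected(as_view=False)
    out = []
    for nodes in nx.all_simple_paths(skeleton, x, y, cutoff=max_edges):
        fwd = tuple(_orient(g, a, b) for a, b in zip(nodes, nodes[1:]))
        out.append(Path(tuple(nodes), fwd))
    out.sort(key=lambda p: p.nodes)
    return out


@dataclass(frozen=True)
class PathClassification:
    """Verdict of the collider rule for one path and conditioning set."""

    path: Path
    conditioning_set: frozenset[str]
    open: bool
    blocking_nodes: tuple[str, ...]  # nodes at which the path is blocked


def path_open(g: nx.DiGraph, path: Path | str, conditioning_set: Iterable[str] = ()) -> PathClassification:
    """Classify one path as open or blocked given a conditioning set.

    A non-collider blocks iff it is in the conditioning set; a collider
    blocks iff neither it nor any of its descendants is in the set.
    """
    if isinstance(path, str):
        path = Path.parse(path)
    z = frozenset(conditioning_set)
    for node in path.nodes:
        if node not in g:
            raise ValueError(f"unknown node {node!r}")
    for (a, b), fwd in zip(zip(path.nodes, path.nodes[1:]), path.forward):
        if _orient(g, a, b) != fwd:
            raise ValueError(f"path edge {a}-{b} orientation disagrees with graph")
    blocked_at = []
    colliders = set(path.colliders())
    for pos in range(1, len(path.nodes) - 1):
        node = path.nodes[pos]
        if node in colliders:
            opened = node in z or any(desc in z for desc in nx.descendants(g, node))
            if not opened:
                blocked_at.append(node)
        elif node in z:
            blocked_at.append(node)
    return PathClassification(path, z, open=not blocked_at, blocking_nodes=tuple(blocked_at))


def open_paths(
    g: nx.DiGraph, x: str, y: str, conditioning_set: Iterable[str] = (), max_edges: int = 8
) -> list[Path]:
    """The simple paths between two nodes left open by a conditioning set."""
    z = frozenset(conditioning_set)
    return [p for p in simple_paths(g, x, y, max_edges) if path_open(g, p, z).open]


def d_separated(
    g: nx.DiGraph,
    x: str | Iterable[str],
    y: str | Iterable[str],
    z: Iterable[str] = (),
) -> bool:
    """Whether every path between the node sets is blocked given ``z``."""
    xs = {x} if isinstance(x, str) else set(x)
    ys = {y} if isinstance(y, str) else set(y)
    zs = frozenset(z)
    if (xs | ys) & zs:
        raise ValueError("conditioning set must be disjoint from the endpoint sets")
    for a in sorted(xs):
        for b in sorted(ys):
            if a == b or open_paths(g, a, b, zs, max_edges=len(g)):
                return False
    return True


def to_dot(g: nx.DiGraph) -> str:
    """Graphviz DOT rendering (latent nodes dashed, response types boxed)."""
    lines = ["digraph {", "  rankdir=LR;"]
    for node in sorted(g.nodes):
        attrs = []
        if node.startswith("U"):
            attrs.append('style="dashed"')
        if node.endswith("T"):
            attrs.append('shape="box"')
        lines.append(f"  {node}" + (f" [{', '.join(attrs)}]" if attrs else "") + ";")
    for a, b in sorted(g.edges):
        lines.append(f"  {a} -> {b};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# The documented independence and path claims for the diagram variants
# ---------------------------------------------------------------------------

#: the seven E–DT paths in the marginal-randomization diagram that are
#: blocked marginally and opened by conditioning on the selection collider
SELECTION_BIAS_PATHS_FIG6 = tuple(
    Path.parse(p)
    for p in (
        "E -> S <- D <- DT",
        "E -> S <- ST <- U1 -> DT",
        "E -> S <- ST <- U2 -> DT",
        "E -> S <- ST <- U3 -> DT",
        "E -> D -> S <- ST <- U1 -> DT",
        "E -> D -> S <- ST <- U2 -> DT",
        "E -> D -> S <- ST <- U3 -> DT",
    )
)

#: the three marginal E–DT paths in the observational stratification diagram
OBS_E_DT_PATHS_FIG8 = tuple(
    Path.parse(p)
    for p in (
        "E <- ET <- U1 -> DT",
        "E <- ET <- U2 -> DT",
        "E <- C <- U1 -> DT",
    )
)

#: the two ET–DT paths that conditioning on C cannot block
ET_DT_PATHS_GIVEN_C = tuple(Path.parse(p) for p in ("ET <- U1 -> DT", "ET <- U2 -> DT"))


@dataclass(frozen=True)
class Claim:
    """One documented statement about a diagram variant."""

    graph: str
    kind: str  # "dsep" or "path"
    x: str
    y: str
    given: frozenset[str]
    expected: bool  # dsep: separated?; path: open?
    path: Path | None = None
    note: str = ""


def _dsep(graph, x, y, given, expected, note=""):
    return Claim(graph, "dsep", x, y, frozenset(given), expected, None, note)


def _path(graph, path, given, expected, note=""):
    p = Path.parse(path) if isinstance(path, str) else path
    return Claim(graph, "path", p.nodes[0], p.nodes[-1], frozenset(given), expected, p, note)


def claim_list() -> list[Claim]:
    """Every independence statement and path classification documented for
    the diagram variants."""
    claims: list[Claim] = []
    # marginal randomization: exposure independent of every response type
    claims += [
        _dsep("fig6", "E", "ET", (), True, "randomized E carries no type information"),
        _dsep("fig6", "E", "DT", (), True, "(full) exchangeability"),
        _dsep("fig6", "E", "ST", (), True),
        _dsep("fig6", "E", "DT", ("C",), True, "(full) conditional exchangeability"),
        _dsep("fig6", "E", "DT", ("S",), False, "selection on follow-up breaks exchangeability"),
        _dsep("fig6", "ET", "DT", ("C",), False, "type independence not granted by randomization"),
        _dsep("fig6", "ET", "DT", ("C", "U1", "U2"), True),
    ]
    for p in SELECTION_BIAS_PATHS_FIG6:
        claims.append(_path("fig6", p, (), False, "blocked at the selection collider"))
        claims.append(_path("fig6", p, ("S",), True, "opened by conditioning on S"))
    # stratified randomization: conditioning on C restores the independences
    claims += [
        _dsep("fig7", "E", "ET", ("C",), True),
        _dsep("fig7", "E", "DT", ("C",), True, "conditional exchangeability by design"),
        _dsep("fig7", "E", "ST", ("C",), True),
        _dsep("fig7", "E", "ET", (), False),
        _dsep("fig7", "E", "DT", (), False),
        _dsep("fig7", "E", "ST", (), False),
        _path("fig7", "E <- C <- U1 -> ET", (), True),
        _path("fig7", "E <- C <- U1 -> ET", ("C",), False),
        _path("fig7", "E <- C <- U1 -> DT", (), True),
        _path("fig7", "E <- C <- U1 -> DT", ("C",), False),
        _path("fig7", "E <- C <- U1 -> ST", (), True),
        _path("fig7", "E <- C <- U1 -> ST", ("C",), False),
    ]
    # observational stratification: adjustment for C is not enough
    for p in OBS_E_DT_PATHS_FIG8:
        claims.append(_path("fig8", p, (), True, "marginal E-DT connection"))
    claims += [
        _path("fig8", "E <- ET <- U1 -> DT", ("C",), True, "survives adjustment for C"),
        _path("fig8", "E <- ET <- U2 -> DT", ("C",), True, "survives adjustment for C"),
        _path("fig8", "E <- C <- U1 -> DT", ("C",), False, "blocked by adjusting for C"),
        _dsep("fig8", "E", "DT", ("C",), False),
        _dsep("fig8", "E", "DT", ("C", "U1", "U2"), True, "latent adjustment closes the rest"),
        _dsep("fig8", "ET", "DT", ("C",), False),
        _dsep("fig8", "ET", "DT", ("C", "U1", "U2"), True),
    ]
    for claim_path in ET_DT_PATHS_GIVEN_C:
        claims.append(_path("fig8", claim_path, ("C",), True))
    return claims


@dataclass(frozen=True)
class ClaimResult:
    claim: Claim
    verdict: bool
    agrees: bool


def claims_audit() -> list[ClaimResult]:
    """Evaluate every documented claim with the d-separation engine."""
    graphs = {v: build_graph(v) for v in ("fig6", "fig7", "fig8")}
    results = []
    for claim in claim_list():
        g = graphs[claim.graph]
        if claim.kind == "dsep":
            verdict = d_separated(g, claim.x, claim.y, claim.given)
        else:
            verdict = path_open(g, claim.path, claim.given).open
        results.append(ClaimResult(claim, verdict, verdict == claim.expected))
    return results


def selection_bias_path_census(
    g: nx.DiGraph | None = None, max_edges: int = 8
) -> list[Path]:
    """All E–DT paths in the marginal-randomization diagram that are blocked
    marginally and opened by conditioning on S — the full census, of which
    the documented seven are a subset."""
    g = g if g is not None else build_graph("fig6")
    out = []
    for p in simple_paths(g, "E", "DT", max_edges):
        if not path_open(g, p, ()).open and path_open(g, p, ("S",)).open:
            out.append(p)
    return out
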