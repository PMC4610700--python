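"""Delay-weighted directed graph model and file I/O.

The central data structure is :class:`DelayWeightedDigraph`, a directed graph
whose edges carry positive integer interaction delays (e.g. reconstructed
information-transfer delays in milliseconds, linearly scaled to integers).
Three on-disk formats are supported: a TSV edge list, a square adjacency
matrix in CSV (0 = no edge, legal because delays are >= 1), and GraphML with
an integer ``delay`` edge attribute.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Label = Hashable
Edge = tuple[Label, Label]

FORMATS = ("edgelist", "adjacency", "graphml")


class GraphError(Exception):
    """Base class for graph-related errors."""


class GraphParseError(GraphError):
    """A file could not be parsed under the named format."""


class GraphValidationError(GraphError):
    """An input violates a graph invariant (self-loop, bad weight, ...)."""


@dataclass(frozen=True)
class PathRecord:
    """A path <v_0, ..., v_l> with its graphical length and summed weight.

    ``graphical_length`` counts edges (number of vertices minus one);
    ``total_weight`` is the sum of the member edges' delays, which is a
    different quantity and the one the alternative-path search constrains.
    """

    vertices: tuple[Label, ...]
    total_weight: int

    @property
    def graphical_length(self) -> int:
        return len(self.vertices) - 1

    def validate_against(self, graph: "DelayWeightedDigraph") -> None:
        """Check membership of every hop and the weight sum; raise on failure."""
        weight = 0
        for u, v in zip(self.vertices, self.vertices[1:]):
            if (u, v) not in graph.weights:
                raise GraphValidationError(f"path uses non-edge {(u, v)!r}")
            weight += graph.weights[(u, v)]
        if weight != self.total_weight:
            raise GraphValidationError(
                f"recorded total_weight {self.total_weight} != actual {weight}"
            )


class DelayWeightedDigraph:
    """Directed graph with unique vertex labels and integer delay weights >= 1.

    Vertices keep their external labels; internal 1-based indices follow
    first-appearance order (index 1 is the first vertex added). No self-loops
    and no parallel edges; antiparallel pairs (u, v) and (v, u) may coexist.
    """

    def __init__(self) -> None:
        self._vertices: list[Label] = []
        self._index: dict[Label, int] = {}
        self.weights: dict[Edge, int] = {}

    # -- construction -------------------------------------------------

    def add_vertex(self, label: Label) -> int:
        """Add a vertex (idempotent); return its 1-based internal index."""
        if label not in self._index:
            self._vertices.append(label)
            self._index[label] = len(self._vertices)
        return self._index[label]

    def add_edge(self, u: Label, v: Label, weight: int) -> None:
        if u == v:
            raise GraphValidationError(f"self-loop on vertex {u!r}")
        if (u, v) in self.weights:
            raise GraphValidationError(f"duplicate edge {(u, v)!r}")
        if isinstance(weight, bool) or not isinstance(weight, (int,)):
            # numpy integers pass through the int() check below
            try:
                as_int = int(weight)
            except (TypeError, ValueError):
                raise GraphValidationError(
                    f"edge {(u, v)!r}: non-integer delay {weight!r}"
                ) from None
            if as_int != weight:
                raise GraphValidationError(
                    f"edge {(u, v)!r}: non-integer delay {weight!r}"
                )
            weight = as_int
        if weight < 1:
            raise GraphValidationError(
                f"edge {(u, v)!r}: delay must be a positive integer, got {weight}"
            )
        self.add_vertex(u)
        self.add_vertex(v)
        self.weights[(u, v)] = int(weight)

    def remove_edge(self, u: Label, v: Label) -> None:
        if (u, v) not in self.weights:
            raise GraphValidationError(f"edge {(u, v)!r} not in graph")
        del self.weights[(u, v)]

    def copy(self) -> "DelayWeightedDigraph":
        g = DelayWeightedDigraph()
        g._vertices = list(self._vertices)
        g._index = dict(self._index)
        g.weights = dict(self.weights)
        return g

    # -- inspection ---------------------------------------------------

    @property
    def vertices(self) -> list[Label]:
        return list(self._vertices)

    def index(self, label: Label) -> int:
        """1-based internal index of a vertex label."""
        return self._index[label]

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def edges(self) -> list[Edge]:
        """Edges in deterministic lexicographic (source index, target index) order."""
        return sorted(self.weights, key=lambda e: (self._index[e[0]], self._index[e[1]]))

    def successors(self, u: Label) -> list[tuple[Label, int]]:
        return [
            (v, w) for (a, v), w in self.weights.items() if a == u
        ]

    def predecessors(self, v: Label) -> list[tuple[Label, int]]:
        return [
            (u, w) for (u, b), w in self.weights.items() if b == v
        ]

    def __contains__(self, edge: Edge) -> bool:
        return edge in self.weights

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DelayWeightedDigraph):
            return NotImplemented
        # label set + edge set + weights; internal index order is not identity
        return set(self._vertices) == set(other._vertices) and self.weights == other.weights

    def __repr__(self) -> str:
        return (
            f"<DelayWeightedDigraph |V|={self.n_vertices} |E|={self.n_edges}>"
        )


def from_edges(
    edges: Iterable[tuple[Label, Label, int]],
    vertices: Iterable[Label] = (),
) -> DelayWeightedDigraph:
    """Build a graph from (source, target, delay) triples.

    ``vertices`` may pre-declare labels (e.g. isolated vertices, or to fix
    the internal index order independently of edge order).
    """
    g = DelayWeightedDigraph()
    for v in vertices:
        g.add_vertex(v)
    for u, v, w in edges:
        g.add_edge(u, v, w)
    return g


# ---------------------------------------------------------------------------
# file I/O


def load_graph(path: str | Path, format: str) -> DelayWeightedDigraph:
    """Load a delay-weighted digraph from ``path`` in the named format.

    Formats: ``edgelist`` (TSV with header source/target/delay), ``adjacency``
    (square CSV, 0 = absent, optional label header row + column), ``graphml``
    (directed, integer ``delay`` edge attribute).
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edgelist":
        return _load_edgelist(path)
    if format == "adjacency":
        return _load_adjacency(path)
    return _load_graphml(path)


def save_graph(graph: DelayWeightedDigraph, path: str | Path, format: str) -> None:
    """Write ``graph`` so that :func:`load_graph` reproduces it exactly."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "edgelist":
        _save_edgelist(graph, path)
    elif format == "adjacency":
        _save_adjacency(graph, path)
    else:
        _save_graphml(graph, path)


def _parse_delay(token: str, where: str) -> int:
    try:
        value = float(token)
    except ValueError:
        raise GraphParseError(f"{where}: cannot parse delay {token!r}") from None
    if value != int(value):
        raise GraphValidationError(f"{where}: non-integer delay {token!r}")
    return int(value)


def _load_edgelist(path: Path) -> DelayWeightedDigraph:
    g = DelayWeightedDigraph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GraphParseError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:3]] != ["source", "target", "delay"]:
            raise GraphParseError(
                f"{path}: line 1: expected header 'source\\ttarget\\tdelay', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise GraphParseError(f"{path}: line {lineno}: expected 3 columns")
            u, v = row[0], row[1]
            w = _parse_delay(row[2], f"{path}: line {lineno}")
            try:
                g.add_edge(u, v, w)
            except GraphValidationError as exc:
                raise GraphValidationError(f"{path}: line {lineno}: {exc}") from None
    return g


def _save_edgelist(graph: DelayWeightedDigraph, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "delay"])
        # NB an edge list cannot represent isolated vertices; use the
        # adjacency or GraphML format when those must survive a round trip
        for u, v in graph.edges():
            writer.writerow([u, v, graph.weights[(u, v)]])


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _load_adjacency(path: Path) -> DelayWeightedDigraph:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise GraphParseError(f"{path}: empty file")
    # labeled dialect: empty corner cell, or a non-numeric header row
    labeled = rows[0][0].strip() == "" or not all(
        _looks_numeric(c) for c in rows[0]
    )
    if labeled:
        labels = [c for c in rows[0][1:]]
        body = rows[1:]
        if len(body) != len(labels):
            raise GraphParseError(
                f"{path}: {len(labels)} column labels but {len(body)} data rows"
            )
        matrix: list[list[str]] = []
        for i, row in enumerate(body):
            if row[0] != labels[i]:
                raise GraphParseError(
                    f"{path}: row label {row[0]!r} != column label {labels[i]!r}"
                )
            matrix.append(row[1:])
    else:
        labels = [str(i + 1) for i in range(len(rows))]
        matrix = rows
    n = len(labels)
    g = DelayWeightedDigraph()
    for lab in labels:
        g.add_vertex(lab)
    for i, row in enumerate(matrix):
        if len(row) != n:
            raise GraphParseError(
                f"{path}: row {i + 1} has {len(row)} cells, expected {n}"
            )
        for j, token in enumerate(row):
            w = _parse_delay(token, f"{path}: cell ({i + 1},{j + 1})")
            if w == 0:
                continue
            try:
                g.add_edge(labels[i], labels[j], w)
            except GraphValidationError as exc:
                raise GraphValidationError(
                    f"{path}: cell ({i + 1},{j + 1}): {exc}"
                ) from None
    return g


def _save_adjacency(graph: DelayWeightedDigraph, path: Path) -> None:
    labels = graph.vertices
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([""] + [str(v) for v in labels])
        for u in labels:
            writer.writerow(
                [str(u)] + [graph.weights.get((u, v), 0) for v in labels]
            )


def _load_graphml(path: Path) -> DelayWeightedDigraph:
    try:
        nxg = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors vary
        raise GraphParseError(f"{path}: {exc}") from None
    if not nxg.is_directed():
        raise GraphParseError(f"{path}: GraphML graph is not directed")
    g = DelayWeightedDigraph()
    for node in nxg.nodes:
        g.add_vertex(node)
    for u, v, data in nxg.edges(data=True):
        if "delay" not in data:
            raise GraphParseError(f"{path}: edge {(u, v)!r} lacks 'delay' attribute")
        try:
            g.add_edge(u, v, data["delay"])
        except GraphValidationError as exc:
            raise GraphValidationError(f"{path}: {exc}") from None
    return g


def _save_graphml(graph: DelayWeightedDigraph, path: Path) -> None:
    nxg = nx.DiGraph()
    for v in graph.vertices:
        nxg.add_node(v)
    for (u, v), w in graph.weights.items():
        nxg.add_edge(u, v, delay=int(w))
    nx.write_graphml(nxg, path)


def to_networkx(graph: DelayWeightedDigraph) -> nx.DiGraph:
    """Export as a networkx DiGraph with a ``delay`` edge attribute."""
    nxg = nx.DiGraph()
    nxg.add_nodes_from(graph.vertices)
    for (u, v), w in graph.weights.items():
        nxg.add_edge(u, v, delay=w)
    return nxg


def quantize_weights(
    raw_graph: nx.DiGraph | Mapping[Edge, float],
    scale: float = 1.0,
    rel_tol: float = 0.10,
) -> DelayWeightedDigraph:
    """Convert real-valued delays to integer weights by linear scaling.

    Each delay d becomes round(d * scale). A delay that rounds to zero is an
    error (the scale is too small to resolve it); a relative rounding error
    above ``rel_tol`` (default 10%) is logged as a warning.

    ``raw_graph`` is either a networkx DiGraph with a ``delay`` edge
    attribute or a mapping {(source, target): delay}.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if isinstance(raw_graph, nx.DiGraph):
        items = [((u, v), d["delay"]) for u, v, d in raw_graph.edges(data=True)]
        vertices: Iterable[Label] = raw_graph.nodes
    else:
        items = list(raw_graph.items())
        vertices = ()
    g = DelayWeightedDigraph()
    for v in vertices:
        g.add_vertex(v)
    for (u, v), delay in items:
        if delay <= 0:
            raise GraphValidationError(
                f"edge {(u, v)!r}: raw delay must be positive, got {delay}"
            )
        w = round(delay * scale)
        if w == 0:
            raise GraphValidationError(
                f"edge {(u, v)!r}: delay {delay} * scale {scale} rounds to 0; "
                "use a larger scale factor"
            )
        rel_err = abs(w - delay * scale) / (delay * scale)
        if rel_err > rel_tol:
            logger.warning(
                "edge %r: rounding %g*%g -> %d loses %.1f%% (> %.0f%% tolerance)",
                (u, v), delay, scale, w, 100 * rel_err, 100 * rel_tol,
            )
        g.add_edge(u, v, w)
    return g
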