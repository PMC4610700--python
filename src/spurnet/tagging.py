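"""Network-wide tagging of potentially spurious edges and pruning.

Every edge is examined against the full original graph minus only itself
(never against a partially pruned graph): an alternative path found for one
edge persists even if edges inside it are tagged later, because each tagged
edge has, by construction, its own delay-matched detour. Tagging is therefore
order-independent.

Two tag kinds:

* **CE (cascade effect)** — the edge has at least one alternative path, or
  hit the reconstruction limit (in which case at least ``limit`` such paths
  exist and the edge is additionally flagged intractable).
* **CD (simple common drive)** — for every CE-tagged edge (v_s, v_t) and
  every one of its alternative paths of graphical length exactly two,
  <v_s, v_1, v_t>, the triangle's second edge (v_1, v_t) is tagged: the
  timing is equally consistent with v_s driving both v_1 and v_t with
  differential delays. At most one of the two tagged edges of a triangle can
  actually be spurious; the tool reports both and leaves the choice to the
  prune policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .altpath import (
    DEFAULT_PATH_LIMIT,
    AltPathResult,
    PathLimitError,
    find_alternative_paths,
)
from .graph import DelayWeightedDigraph, GraphError, Label

Edge = tuple[Label, Label]
Triangle = tuple[Label, Label, Label]  # (v_s, v_1, v_t)

PRUNE_POLICIES = ("all", "ce-only", "cd-only", "report-only")


@dataclass(frozen=True)
class EdgeTag:
    """A CE or CD verdict on one edge, with its supporting evidence."""

    edge: Edge
    kind: Literal["CE", "CD"]
    # CE: the alternative paths; CD: the (v_s, v_1, v_t) triangle
    paths: tuple = ()
    triangle: Triangle | None = None


@dataclass
class TaggingResult:
    """Aggregate outcome of running the search over every edge of a graph."""

    graph: DelayWeightedDigraph
    theta: int
    limit: int
    per_edge: dict[Edge, AltPathResult] = field(default_factory=dict)
    tags: list[EdgeTag] = field(default_factory=list)
    triangles: list[Triangle] = field(default_factory=list)
    intractable_edges: list[Edge] = field(default_factory=list)

    def tagged_edges(self, kind: str | None = None) -> set[Edge]:
        return {t.edge for t in self.tags if kind is None or t.kind == kind}

    def tag_kinds(self, edge: Edge) -> set[str]:
        return {t.kind for t in self.tags if t.edge == edge}

    @property
    def total_dp_steps(self) -> int:
        return sum(r.dp_steps for r in self.per_edge.values())

    @property
    def total_paths(self) -> int:
        return sum(r.n_paths for r in self.per_edge.values())


@dataclass
class PruneResult:
    """A pruned copy of the graph plus the removal log."""

    graph: DelayWeightedDigraph
    removed: list[tuple[Edge, tuple[str, ...]]]  # (edge, sorted tag kinds)
    # triangles in which policy=all removed both candidates, although at most
    # one of the two can actually be spurious
    conflicted_triangles: list[Triangle] = field(default_factory=list)


def tag_cascade_effects(
    graph: DelayWeightedDigraph,
    theta: int,
    limit: int = DEFAULT_PATH_LIMIT,
    on_limit: Literal["mark", "abort"] = "mark",
) -> TaggingResult:
    """Run the alternative-path search on every edge; tag CE candidates.

    Edges are examined in lexicographic (source index, target index) order.
    ``on_limit='mark'`` flags limit-hitting edges intractable and continues;
    ``'abort'`` raises :class:`PathLimitError` for the whole run.
    """
    result = TaggingResult(graph=graph, theta=theta, limit=limit)
    for edge in graph.edges():
        r = find_alternative_paths(graph, edge, theta, limit)
        result.per_edge[edge] = r
        if r.intractable:
            result.intractable_edges.append(edge)
            if on_limit == "abort":
                raise PathLimitError(
                    f"edge {edge!r}: {limit} alternative paths reconstructed; "
                    "instance is intractable"
                )
        if r.has_alternative:
            result.tags.append(
                EdgeTag(edge=edge, kind="CE", paths=tuple(r.paths))
            )
    return result


def tag_common_drive(result: TaggingResult) -> TaggingResult:
    """Add CD tags for every triangle behind a length-2 alternative path.

    Mutates and returns ``result``. One CD tag per distinct triangle; an
    edge may accumulate several CD tags (one per triangle) in addition to
    its own CE tag.
    """
    seen: set[Triangle] = set()
    for tag in [t for t in result.tags if t.kind == "CE"]:
        v_s, v_t = tag.edge
        for path in tag.paths:
            if path.graphical_length != 2:
                continue
            v_1 = path.vertices[1]
            triangle: Triangle = (v_s, v_1, v_t)
            if triangle in seen:
                continue
            seen.add(triangle)
            result.triangles.append(triangle)
            result.tags.append(
                EdgeTag(edge=(v_1, v_t), kind="CD", triangle=triangle)
            )
    return result


def tag_spurious_edges(
    graph: DelayWeightedDigraph,
    theta: int,
    limit: int = DEFAULT_PATH_LIMIT,
    on_limit: Literal["mark", "abort"] = "mark",
) -> TaggingResult:
    """CE pass followed by the triangle-motif CD pass."""
    return tag_common_drive(tag_cascade_effects(graph, theta, limit, on_limit))


def prune(
    graph: DelayWeightedDigraph,
    result: TaggingResult,
    policy: str = "report-only",
) -> PruneResult:
    """Remove tagged edges from a copy of the graph according to ``policy``.

    ``all`` removes every tagged edge (the survivors are then guaranteed
    free of the detectable timing signatures, at the price of possibly
    removing true edges); ``ce-only`` / ``cd-only`` remove one tag kind;
    ``report-only`` removes nothing.
    """
    if policy not in PRUNE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {PRUNE_POLICIES}")
    if result.graph is not graph and result.graph != graph:
        raise GraphError("tagging result was computed on a different graph")
    for tag in result.tags:
        if tag.edge not in graph.weights:
            raise GraphError(f"tagged edge {tag.edge!r} absent from graph")
    if policy == "all":
        to_remove = result.tagged_edges()
    elif policy == "ce-only":
        to_remove = result.tagged_edges("CE")
    elif policy == "cd-only":
        to_remove = result.tagged_edges("CD")
    else:
        to_remove = set()
    pruned = graph.copy()
    removed: list[tuple[Edge, tuple[str, ...]]] = []
    for edge in sorted(to_remove, key=lambda e: (graph.index(e[0]), graph.index(e[1]))):
        pruned.remove_edge(*edge)
        removed.append((edge, tuple(sorted(result.tag_kinds(edge)))))
    conflicted = []
    if policy == "all":
        for v_s, v_1, v_t in result.triangles:
            if (v_s, v_t) in to_remove and (v_1, v_t) in to_remove:
                conflicted.append((v_s, v_1, v_t))
    return PruneResult(graph=pruned, removed=removed, conflicted_triangles=conflicted)
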