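"""Alternative-path search by memoized dynamic programming plus backtracking.

Given an edge (v_a, v_b) with delay w in a delay-weighted digraph and a
tolerance theta, an *alternative path* is a simple path v_a -> ... -> v_b that
avoids the edge itself and whose summed delay lies in the closed interval
[w - theta, w + theta]. Existence of such a path is the timing signature of a
cascade effect: the apparent direct transfer could be relayed through the
intermediate nodes with the same total delay.

The search runs in two stages:

1.  A dynamic program fills a *solution array* L of shape
    (w_crit + 1) x |V|, with w_crit = w + theta. Cell L[w_i][j] collects
    tuples (edge weight, predecessor index) witnessing walks from the start
    vertex to vertex j of total weight exactly w_i in the reduced graph G'
    (the input minus the examined edge). Because every edge weight is >= 1,
    walk length is bounded by w_crit and the table is finite.

2.  A depth-first backtracking pass expands every witness chain found in the
    reconstruction interval rows [w - theta, w + theta] of the target column
    into explicit vertex sequences, discarding any sequence that revisits a
    vertex (walks with loops are represented at the DP level but are not
    valid alternative paths). Reconstruction stops once ``limit`` valid paths
    have been found; the edge is then flagged intractable.

The DP performs exactly indegree(v_j) *algorithmic steps* per cell, hence
w_crit * |E(G')| steps in total — linear in both the critical weight and the
edge count. All exponential cost lives in the backtracking stage, where it is
capped by ``limit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import DelayWeightedDigraph, GraphError, Label, PathRecord

DEFAULT_PATH_LIMIT = 20_000


class PathLimitError(GraphError):
    """Raised in strict mode when the path-reconstruction limit is reached."""


@dataclass
class ProblemInstance:
    """Preprocessed input for the alternative-path search on one edge.

    Vertices are relabeled so that the start vertex v_s has index 1 and the
    target v_t has index |V|; the reduced graph G' (examined edge removed) is
    stored as an inverted adjacency list ``preds``: for each internal index
    j, the list of (predecessor index, edge weight) pairs, sorted by
    predecessor index for deterministic expansion order.
    """

    graph: DelayWeightedDigraph
    edge: tuple[Label, Label]
    weight: int
    theta: int
    order: list[Label]              # order[i-1] is the label with internal index i
    preds: list[list[tuple[int, int]]]  # 1-based; preds[0] unused

    @property
    def w_crit(self) -> int:
        return self.weight + self.theta

    @property
    def n_vertices(self) -> int:
        return len(self.order)

    @property
    def n_reduced_edges(self) -> int:
        return sum(len(p) for p in self.preds)


@dataclass
class SolutionArray:
    """The (w_crit + 1) x |V| memoization table of the dynamic program.

    ``cells[w][j]`` (w in 0..w_crit, j in 1..|V|) is the set of
    (edge weight, predecessor index) tuples solving the subproblem "a walk
    of weight exactly w from v_s to v_j exists in G'". The base cell
    cells[0][1] holds the sentinel (0, 1) for the empty walk at v_s.
    """

    cells: list[list[set[tuple[int, int]]]]
    dp_steps: int

    def cell(self, w: int, j: int) -> set[tuple[int, int]]:
        return self.cells[w][j]


@dataclass
class AltPathResult:
    """Outcome of the alternative-path search for one examined edge."""

    edge: tuple[Label, Label]
    weight: int
    theta: int
    paths: list[PathRecord] = field(default_factory=list)
    intractable: bool = False
    dp_steps: int = 0
    n_paths: int = 0
    n_loops_discarded: int = 0

    @property
    def has_alternative(self) -> bool:
        return bool(self.paths) or self.intractable


def preprocess_edge(
    graph: DelayWeightedDigraph, edge: tuple[Label, Label], theta: int
) -> ProblemInstance:
    """Build the reduced, reordered problem instance for one examined edge.

    Removes the edge, puts its source first and its target last in the
    internal ordering, and inverts the adjacency (predecessor lists).
    """
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if edge not in graph.weights:
        raise GraphError(f"edge {edge!r} not in graph")
    v_s, v_t = edge
    others = [v for v in graph.vertices if v != v_s and v != v_t]
    order = [v_s] + others + [v_t]
    new_index = {lab: i for i, lab in enumerate(order, start=1)}
    n = len(order)
    preds: list[list[tuple[int, int]]] = [[] for _ in range(n + 1)]
    for (u, v), w in graph.weights.items():
        if (u, v) == edge:
            continue
        preds[new_index[v]].append((new_index[u], w))
    for lst in preds:
        lst.sort()
    return ProblemInstance(
        graph=graph,
        edge=edge,
        weight=graph.weights[edge],
        theta=theta,
        order=order,
        preds=preds,
    )


def solve_subproblems(instance: ProblemInstance) -> SolutionArray:
    """Fill the solution array bottom-up over weights, then vertex indices.

    A tuple (w_e, p) enters cell (w_i, j) iff edge (p, j) exists in G' with
    weight w_e and cell (w_i - w_e, p) is already non-empty. The start column
    stays empty for w_i > 0: a walk re-entering v_s can only ever extend to
    non-simple paths, which backtracking would discard anyway.
    """
    n = instance.n_vertices
    w_crit = instance.w_crit
    preds = instance.preds
    cells: list[list[set[tuple[int, int]]]] = [
        [set() for _ in range(n + 1)] for _ in range(w_crit + 1)
    ]
    cells[0][1].add((0, 1))  # empty walk at the start vertex
    steps = 0
    for w_i in range(1, w_crit + 1):
        row = cells[w_i]
        for j in range(1, n + 1):
            incoming = preds[j]
            steps += len(incoming)
            if j == 1:
                continue
            cell = row[j]
            for p, w_e in incoming:
                w_p = w_i - w_e
                if w_p >= 0 and cells[w_p][p]:
                    cell.add((w_e, p))
    return SolutionArray(cells=cells, dp_steps=steps)


def backtrack_paths(
    array: SolutionArray,
    instance: ProblemInstance,
    limit: int = DEFAULT_PATH_LIMIT,
) -> AltPathResult:
    """Reconstruct all loop-free alternative paths from the solution array.

    Depth-first expansion starts once per entry of the reconstruction
    interval — rows [w - theta, w + theta] (clamped at 0) of the target
    column — and follows witness tuples back towards the base cell.
    Sequences revisiting a vertex are discarded. Hitting ``limit`` valid
    paths flags the result intractable and stops reconstruction.
    """
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    n = instance.n_vertices
    order = instance.order
    result = AltPathResult(
        edge=instance.edge,
        weight=instance.weight,
        theta=instance.theta,
        dp_steps=array.dp_steps,
    )
    w_lo = max(0, instance.weight - instance.theta)
    w_hi = instance.w_crit

    def expand(w: int, j: int, suffix: list[int], on_path: set[int], row_weight: int) -> bool:
        """DFS backwards from cell (w, j); returns False once the limit is hit."""
        if w == 0 and j == 1:
            # suffix already starts at the start vertex (index 1)
            seq = tuple(order[k - 1] for k in suffix)
            result.paths.append(PathRecord(vertices=seq, total_weight=row_weight))
            result.n_paths += 1
            return result.n_paths < limit
        # predecessors expanded in ascending vertex index for deterministic output
        for w_e, p in sorted(array.cells[w][j], key=lambda t: (t[1], t[0])):
            if p in on_path:
                result.n_loops_discarded += 1
                continue
            on_path.add(p)
            ok = expand(w - w_e, p, [p] + suffix, on_path, row_weight)
            on_path.discard(p)
            if not ok:
                return False
        return True

    for w in range(w_lo, w_hi + 1):
        if not array.cells[w][n]:
            continue
        if not expand(w, n, [n], {n}, w):
            result.intractable = True
            break
    return result


def find_alternative_paths(
    graph: DelayWeightedDigraph,
    edge: tuple[Label, Label],
    theta: int,
    limit: int = DEFAULT_PATH_LIMIT,
) -> AltPathResult:
    """Full pipeline for one edge: preprocess, solve the DP, backtrack."""
    instance = preprocess_edge(graph, edge, theta)
    array = solve_subproblems(instance)
    return backtrack_paths(array, instance, limit)
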