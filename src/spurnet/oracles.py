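"""Independent brute-force oracles for small graphs.

These enumerators deliberately share no traversal code with the dynamic
program in :mod:`spurnet.altpath`: they walk the graph forward over successor
lists by plain recursion, so they remain meaningful as an independent check
of the DP + backtracking pipeline. They are exponential and guarded by a
vertex-count cap.
"""

from __future__ import annotations

from .graph import DelayWeightedDigraph, Label, PathRecord

ORACLE_VERTEX_CAP = 10


def _check_cap(graph: DelayWeightedDigraph, cap: int) -> None:
    if graph.n_vertices > cap:
        raise ValueError(
            f"oracle limited to |V| <= {cap} (got {graph.n_vertices}); "
            "exhaustive enumeration is factorial in |V|"
        )


def enumerate_simple_paths(
    graph: DelayWeightedDigraph,
    s: Label,
    t: Label,
    w_lo: int,
    w_hi: int,
    exclude_edge: tuple[Label, Label] | None = None,
    vertex_cap: int = ORACLE_VERTEX_CAP,
) -> list[PathRecord]:
    """All simple paths s -> t avoiding ``exclude_edge`` with weight in [w_lo, w_hi]."""
    if s == t:
        raise ValueError("start and target must differ")
    if not 0 <= w_lo <= w_hi:
        raise ValueError(f"need 0 <= w_lo <= w_hi, got [{w_lo}, {w_hi}]")
    _check_cap(graph, vertex_cap)
    succ: dict[Label, list[tuple[Label, int]]] = {v: [] for v in graph.vertices}
    for (u, v), w in graph.weights.items():
        if (u, v) != exclude_edge:
            succ[u].append((v, w))
    out: list[PathRecord] = []

    def walk(v: Label, acc: int, trail: list[Label]) -> None:
        if acc > w_hi:  # weights >= 1: no extension can come back down
            return
        if v == t:
            if w_lo <= acc <= w_hi:
                out.append(PathRecord(vertices=tuple(trail), total_weight=acc))
            return  # simple paths only: do not continue through t
        for nxt, w in succ[v]:
            if nxt in trail:
                continue
            walk(nxt, acc + w, trail + [nxt])

    walk(s, 0, [s])
    return out


def enumerate_walks(
    graph: DelayWeightedDigraph,
    s: Label,
    v: Label,
    exact_weight: int,
    exclude_edge: tuple[Label, Label] | None = None,
    vertex_cap: int = ORACLE_VERTEX_CAP,
    forbid_start_reentry: bool = False,
) -> bool:
    """True iff a walk (vertex repeats allowed) s -> v of exactly this weight exists.

    With ``forbid_start_reentry`` the walk may not pass through ``s`` again
    after leaving it — the walk population the solution array represents,
    since walks re-entering the start can only extend to non-simple paths.
    """
    if exact_weight < 0:
        raise ValueError("exact_weight must be >= 0")
    _check_cap(graph, vertex_cap)
    succ: dict[Label, list[tuple[Label, int]]] = {u: [] for u in graph.vertices}
    for (a, b), w in graph.weights.items():
        if (a, b) == exclude_edge:
            continue
        if forbid_start_reentry and b == s:
            continue
        succ[a].append((b, w))
    # memoized forward recursion; weights >= 1 bound the depth by exact_weight
    memo: dict[tuple[Label, int], bool] = {}

    def reach(u: Label, remaining: int) -> bool:
        if remaining == 0:
            return u == v
        key = (u, remaining)
        if key not in memo:  # remaining strictly decreases: no reentrancy
            memo[key] = any(
                w <= remaining and reach(b, remaining - w) for b, w in succ[u]
            )
        return memo[key]

    return reach(s, exact_weight)
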