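"""Directed, delay-weighted test-network generators and path-count analytics.

Three topology families commonly reported for brain networks are provided,
each extended to directed edges with integer delays drawn uniformly from
[1, w_max]:

* small-world: a directed ring lattice (each node points to its n nearest
  neighbors, n/2 on either side) with per-edge rewiring probability p —
  a directed, weighted variant of the Watts–Strogatz construction;
* random: every ordered vertex pair included independently with
  probability rho (the graph density);
* scale-free: preferential-attachment growth from a complete seed digraph
  on m+1 nodes, each new node attaching m edges (directed new -> old) to
  targets drawn proportionally to current total degree, so |E| = m * |V|.

``w_max`` defaults to 17 throughout: delay-weighted MEG interaction networks
of the kind this tool post-processes show reconstructed delays of up to
17 ms on a millisecond-integer scale. Weights are drawn after the topology,
in edge-lexicographic order, so the topology at a fixed seed is comparable
across w_max settings.

The module also evaluates the closed-form machinery used to reason about
path proliferation in random graphs: the number of compositions of an
integer (ordered positive summands), 2^(i-1), and the expected
alternative-path count

    sum_{w'=1}^{w_crit} sum_{j=1}^{w'} C(w'-1, j-1) * (rho / w_max)^j

which grows as Omega(2^w_crit) in dense random graphs — the reason a
reconstruction limit is needed at all.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .graph import DelayWeightedDigraph, from_edges

DEFAULT_W_MAX = 17


@dataclass(frozen=True)
class SmallWorldParams:
    n_vertices: int
    neighbors: int          # n: per-node neighbor count, even
    rewire_p: float         # p: per-edge rewiring probability
    w_max: int = DEFAULT_W_MAX
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertices < 3:
            raise ValueError("small-world graph needs |V| >= 3")
        if self.neighbors % 2 != 0 or not 0 < self.neighbors < self.n_vertices:
            raise ValueError("neighborhood coefficient n must be even and < |V|")
        if not 0 <= self.rewire_p <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")
        if self.w_max < 1:
            raise ValueError("w_max must be >= 1")


@dataclass(frozen=True)
class RandomGraphParams:
    n_vertices: int
    density: float          # rho: independent edge probability
    w_max: int = DEFAULT_W_MAX
    seed: int = 0

    def validate(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("random graph needs |V| >= 2")
        if not 0 <= self.density <= 1:
            raise ValueError("density must lie in [0, 1]")
        if self.w_max < 1:
            raise ValueError("w_max must be >= 1")


@dataclass(frozen=True)
class ScaleFreeParams:
    n_vertices: int
    attach_m: int           # m: edges attached per new node
    w_max: int = DEFAULT_W_MAX
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.attach_m < self.n_vertices:
            raise ValueError("attachment count m must satisfy 1 <= m < |V|")
        if self.w_max < 1:
            raise ValueError("w_max must be >= 1")


def _labels(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def _assign_weights(
    edges: set[tuple[int, int]], n: int, w_max: int, rng: random.Random
) -> DelayWeightedDigraph:
    """Weight edges uniformly on [1, w_max] in edge-lexicographic order."""
    labels = _labels(n)
    triples = [
        (labels[u], labels[v], rng.randint(1, w_max)) for u, v in sorted(edges)
    ]
    return from_edges(triples, vertices=labels)


def gen_small_world(params: SmallWorldParams) -> DelayWeightedDigraph:
    """Directed, weighted Watts–Strogatz-style small-world network.

    Step 1 builds the directed ring lattice (edges to the n/2 nearest
    neighbors on each side); step 2 rewires each edge's target independently
    with probability p to a uniform vertex, redrawing on self-loops and
    duplicates; step 3 draws the weights.
    """
    params.validate()
    rng = random.Random(params.seed)
    nv, half = params.n_vertices, params.neighbors // 2
    edges: set[tuple[int, int]] = set()
    for i in range(nv):
        for off in range(1, half + 1):
            edges.add((i, (i + off) % nv))
            edges.add((i, (i - off) % nv))
    if params.rewire_p > 0:
        for edge in sorted(edges):
            if rng.random() >= params.rewire_p:
                continue
            i, _ = edge
            edges.remove(edge)
            while True:
                k = rng.randrange(nv)
                if k != i and (i, k) not in edges:
                    break
            edges.add((i, k))
    return _assign_weights(edges, nv, params.w_max, rng)


def gen_random(params: RandomGraphParams) -> DelayWeightedDigraph:
    """Erdos–Renyi-style digraph: each ordered pair present with prob. rho."""
    params.validate()
    rng = random.Random(params.seed)
    nv = params.n_vertices
    edges = {
        (i, j)
        for i in range(nv)
        for j in range(nv)
        if i != j and rng.random() < params.density
    }
    return _assign_weights(edges, nv, params.w_max, rng)


def gen_scale_free(params: ScaleFreeParams) -> DelayWeightedDigraph:
    """Preferential-attachment digraph (Barabasi–Albert rationale).

    Seed graph: complete digraph on m+1 nodes. Each subsequent node draws m
    distinct attachment targets with probability proportional to current
    total (in + out) degree and adds directed edges new -> target. The edge
    count is therefore exactly m * |V|; the emergent degree distribution is
    heavy-tailed.
    """
    params.validate()
    rng = random.Random(params.seed)
    nv, m = params.n_vertices, params.attach_m
    edges: set[tuple[int, int]] = set()
    degree = [0] * nv
    for i in range(m + 1):
        for j in range(m + 1):
            if i != j:
                edges.add((i, j))
                degree[i] += 1
                degree[j] += 1
    for new in range(m + 1, nv):
        targets: set[int] = set()
        while len(targets) < m:
            total = sum(degree[v] for v in range(new))
            r = rng.random() * total
            acc = 0.0
            pick = new - 1
            for v in range(new):
                acc += degree[v]
                if r < acc:
                    pick = v
                    break
            if pick in targets:
                continue
            targets.add(pick)
        for t in sorted(targets):
            edges.add((new, t))
            degree[new] += 1
            degree[t] += 1
    return _assign_weights(edges, nv, params.w_max, rng)


def density(graph: DelayWeightedDigraph) -> float:
    """rho = |E| / (|V| * (|V| - 1)), the fraction of possible directed edges."""
    nv = graph.n_vertices
    if nv < 2:
        raise ValueError("density undefined for graphs with fewer than 2 vertices")
    return graph.n_edges / (nv * (nv - 1))


def compositions_count(i: int) -> int:
    """Number of ordered sequences of positive integers summing to i: 2^(i-1)."""
    if i < 1:
        raise ValueError(f"i must be >= 1, got {i}")
    return 2 ** (i - 1)


def expected_alt_path_count(rho: float, w_max: int, w_crit: int) -> float:
    """Expected number of alternative paths in a dense random graph.

    Evaluates sum_{w'=1}^{w_crit} sum_{j=1}^{w'} C(w'-1, j-1) * (rho/w_max)^j,
    i.e. every composition of every total weight w' <= w_crit, each edge of a
    j-edge candidate present with probability rho and carrying the required
    weight with probability 1/w_max. Valid as a growth model for dense graphs
    with w_crit large relative to individual weights; the uniform-weight cap
    w <= w_max is deliberately not enforced per composition part.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if w_max < 1 or w_crit < 1:
        raise ValueError("w_max and w_crit must be >= 1")
    q = rho / w_max
    total = 0.0
    for w_prime in range(1, w_crit + 1):
        total += sum(
            math.comb(w_prime - 1, j - 1) * q**j for j in range(1, w_prime + 1)
        )
    return total
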