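"""Estimation-cost model, network-overlap statistics, and the benchmark harness.

The cost model compares two strategies for upgrading a pairwise-estimated
interaction network to targeted three-node (trivariate) estimation:

* two-stage: |V|(|V|-1) bivariate estimations, then 6 trivariate
  estimations per triangle motif actually present (6 = m(m-1) ordered
  interaction motifs per node triple at m = 3);
* brute force: 6 * C(|V|, 3) trivariate estimations over all node triples.

With a fraction f of all C(|V|, 3) triples forming triangles, the two-stage
approach is strictly cheaper for all |V| above a crossover size that depends
only on f.

The benchmark harness replays the simulation-performance design (network
family x size x critical weight) with hardware-independent counters: DP
algorithmic steps, reconstructed path counts, and intractability flags at
the reconstruction limit. It never reports wall-clock time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .altpath import DEFAULT_PATH_LIMIT, find_alternative_paths
from .generators import (
    RandomGraphParams,
    ScaleFreeParams,
    SmallWorldParams,
    gen_random,
    gen_scale_free,
    gen_small_world,
)
from .graph import DelayWeightedDigraph, Label


@dataclass(frozen=True)
class CostModel:
    """Estimation counts for both strategies at one network size."""

    n_vertices: int
    motif_fraction: float

    @property
    def n_triples(self) -> int:
        return math.comb(self.n_vertices, 3)

    @property
    def two_stage_cost(self) -> float:
        nv = self.n_vertices
        return nv * (nv - 1) + 6 * self.motif_fraction * self.n_triples

    @property
    def brute_force_cost(self) -> float:
        return 6 * self.n_triples


def crossover_size(motif_fraction: float) -> int:
    """Largest |V| at which two-stage estimation is not yet cheaper.

    For every |V| above the returned size, the two-stage strategy (pairwise
    scan plus targeted trivariate follow-up on present triangles) needs
    strictly fewer estimations than brute-force trivariate estimation over
    all node triples.
    """
    if not 0 <= motif_fraction < 1:
        raise ValueError(
            "motif fraction must lie in [0, 1); at f = 1 every triple is a "
            "triangle and the two-stage approach is never cheaper"
        )
    # two_stage >= brute reduces to |V| <= 2 + 1/(1-f); scan the integer range
    upper = int(2 + 1 / (1 - motif_fraction)) + 2
    best = 3
    for nv in range(3, upper + 1):
        model = CostModel(nv, motif_fraction)
        if model.two_stage_cost >= model.brute_force_cost:
            best = nv
    return best


def overlap_stats(
    edges_a: Iterable[tuple[Label, Label]],
    edges_b: Iterable[tuple[Label, Label]],
    n_vertices: int,
) -> dict[str, float]:
    """Overlap between two edge sets over the same vertex set.

    Returns the shared edge count, the overlap as a percentage of the
    smaller set, and the percentage overlap expected purely by chance —
    the probability that any given directed edge slot is occupied in both
    networks if each were an independent uniform draw of its size:
    100 * (|A|/P) * (|B|/P) with P = |V|(|V|-1) possible edges.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    a, b = set(edges_a), set(edges_b)
    if not a or not b:
        raise ValueError("overlap percentage undefined for an empty edge set")
    possible = n_vertices * (n_vertices - 1)
    shared = len(a & b)
    return {
        "shared_count": shared,
        "pct_of_smaller": 100.0 * shared / min(len(a), len(b)),
        "chance_pct": 100.0 * len(a) * len(b) / (possible * possible),
    }


# ---------------------------------------------------------------------------
# benchmark harness


def _build(model: Mapping, n_vertices: int, w_max: int, seed: int) -> DelayWeightedDigraph:
    kind = model["model"]
    if kind == "random":
        return gen_random(
            RandomGraphParams(n_vertices, model["density"], w_max, seed)
        )
    if kind == "smallworld":
        return gen_small_world(
            SmallWorldParams(
                n_vertices, model["neighbors"], model["rewire_p"], w_max, seed
            )
        )
    if kind == "scalefree":
        return gen_scale_free(
            ScaleFreeParams(n_vertices, model["attach_m"], w_max, seed)
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _model_name(model: Mapping) -> str:
    parts = [model["model"]] + [
        f"{k}={v}" for k, v in sorted(model.items()) if k != "model"
    ]
    return ",".join(parts)


def bench(
    models: Sequence[Mapping],
    sizes: Sequence[int],
    w_crit_values: Sequence[int],
    seeds: Sequence[int],
    w_max: int,
    limit: int = DEFAULT_PATH_LIMIT,
    stop_on_intractable: bool = True,
) -> pd.DataFrame:
    """Run the per-edge search over a parameter grid; return counters.

    For a target critical weight w_crit, each edge of weight w is examined
    with theta = max(0, w_crit - w) so that the DP explores weights up to
    w_crit (requires w_max <= w_crit for the cap to be uniform across
    edges). ``stop_on_intractable`` aborts the edge scan of a cell at the
    first limit-hitting edge, mirroring an aborted-execution protocol; the
    cell is then recorded with partial counters and ``intractable=True``.
    """
    rows = []
    for model in models:
        for nv in sizes:
            for w_crit in w_crit_values:
                for seed in seeds:
                    graph = _build(model, nv, w_max, seed)
                    dp_steps = n_paths = n_edges_examined = 0
                    intractable = False
                    for edge in graph.edges():
                        theta = max(0, w_crit - graph.weights[edge])
                        r = find_alternative_paths(graph, edge, theta, limit)
                        dp_steps += r.dp_steps
                        n_paths += r.n_paths
                        n_edges_examined += 1
                        if r.intractable:
                            intractable = True
                            if stop_on_intractable:
                                break
                    rows.append(
                        {
                            "model": _model_name(model),
                            "n_vertices": nv,
                            "w_crit": w_crit,
                            "seed": seed,
                            "n_edges": graph.n_edges,
                            "n_edges_examined": n_edges_examined,
                            "dp_steps": dp_steps,
                            "n_paths": n_paths,
                            "intractable": intractable,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "model", "n_vertices", "w_crit", "seed", "n_edges",
            "n_edges_examined", "dp_steps", "n_paths", "intractable",
        ],
    )
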