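# spurnet

Post-processing for directed interaction networks whose edges carry
reconstructed interaction delays — typically effective-connectivity networks
obtained from pairwise (bivariate) transfer-entropy estimation on neural
time series. Pairwise estimation cannot distinguish a genuine direct
interaction from information that is merely *relayed* (a cascade effect, CE)
or *co-received* from a shared driver (a common drive effect, CD). Both
confounds leave a timing signature: spurnet finds it and tags the affected
edges so the user can inspect or remove them.

## The method

A network is a directed graph **G** = {**V**, **E**} with a positive integer
delay weight w₍ᵤ,ᵥ₎ on every edge. For each edge (v_s, v_t) with weight w and
a user tolerance θ, an **alternative path** is a simple path v_s ⇝ v_t that
avoids the edge itself and whose summed delay lies in [w − θ, w + θ]. If one
exists, the apparent direct transfer could be routed through the
intermediate nodes with the same total delay, and the edge is tagged as a
potential cascade effect.

Existence and enumeration are solved in two stages per edge:

1. **Dynamic programming.** After removing the examined edge, a solution
   array L of shape (w_crit + 1) × |V|, w_crit = w + θ, is filled bottom-up:
   cell L(w_i, v_j) collects tuples (w₍ᵥₚ,ᵥⱼ₎, v_p) witnessing a walk of
   weight exactly w_i from v_s to v_j, entered whenever an edge (v_p, v_j)
   extends a non-empty cell L(w_i − w₍ᵥₚ,ᵥⱼ₎, v_p). Because weights are ≥ 1
   the table is finite; the pass performs exactly w_crit · |E′| algorithmic
   steps — linear in both the critical weight and the edge count.
2. **Backtracking.** Every witness chain in the reconstruction interval rows
   [w − θ, w + θ] of the target column is expanded depth-first into explicit
   vertex sequences; sequences revisiting a vertex are discarded. The number
   of valid paths can grow as Ω(2^w_crit) in dense random graphs, so
   reconstruction stops at a limit (default 20 000) and flags the edge
   *intractable* (at least that many alternatives exist).

A second pass tags **simple common drive**: for every CE-tagged edge
(v_s, v_t) with a length-2 alternative path ⟨v_s, v_1, v_t⟩, the triangle's
second edge (v_1, v_t) is also suspicious — the timing is equally consistent
with v_s driving v_1 and v_t with differential delays. At most one of the two
tagged edges per triangle can actually be spurious; spurnet reports both and
leaves the verdict to the prune policy (`all`, `ce-only`, `cd-only`,
`report-only`).

The package also ships the surrounding toolkit: generators for directed,
delay-weighted small-world, scale-free and random test networks; brute-force
oracles for validation; analytic path-count formulas; an estimation-cost
model for targeted trivariate follow-up; network-overlap statistics; and a
hardware-independent benchmark harness (step counters, never wall-clock).

## Worked example

The minimal cascade motif: delays 1→2 of 3 ms, 2→3 of 4 ms, and a direct
edge 1→3 of 7 ms (exactly the detour's total).

```python
import spurnet as sp

g = sp.from_edges([("1", "2", 3), ("2", "3", 4), ("1", "3", 7)])
result = sp.tag_spurious_edges(g, theta=0)
print("CE:", result.tagged_edges("CE"))
print("CD:", result.tagged_edges("CD"))
print("triangles:", result.triangles)
```

prints

```
CE: {('1', '3')}
CD: {('2', '3')}
triangles: [('1', '2', '3')]
```

The direct edge (1, 3) has the alternative path ⟨1, 2, 3⟩ with summed delay
3 + 4 = 7 ms, matching its own delay at θ = 0, so it is a cascade-effect
candidate; the triangle's second edge (2, 3) gets the common-drive tag. The
same run from the shell:

```sh
$ spurnet tag --input triangle.tsv --theta 0 --output tags.tsv
$ cat tags.tsv
source	target	delay	tag	n_alt_paths	intractable
1	3	7	CE	1	False
2	3	4	CD	0	False
```

Pruning with `--policy all` leaves only edge (1, 2) and warns that the two
removed edges belong to one triangle of mutually exclusive candidates.

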