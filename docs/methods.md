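# Methods

## Problem setting and assumptions

spurnet operates on directed graphs whose edges carry positive integer
interaction delays. The intended source is pairwise effective-connectivity
estimation (e.g. transfer entropy with reconstructed transfer delays), but
nothing upstream is assumed beyond the graph itself: no time series, no
estimator statistics. Delay estimation and edge significance testing are
explicitly out of scope.

Weights must be integers ≥ 1 because the dynamic-programming table is
indexed by integer path weight. Real-valued delays are converted with
`quantize_weights(raw, scale)`, which maps each delay d to round(d · scale).
A delay that rounds to zero is an error (the scale cannot resolve it); a
relative rounding error above 10% (configurable) is logged as a warning.
The default scale is 1, i.e. delays already on an integer millisecond grid
pass through unchanged; no canonical scale factor exists, so it is left to
the user. The tolerance θ is expressed in the same scaled integer units.

## The alternative-path search

For an examined edge (v_s, v_t) of weight w and tolerance θ the search asks
for *simple* paths v_s ⇝ v_t in G′ = G minus the edge, with summed weight in
the closed interval [w − θ, w + θ]. θ = 0 therefore means exact delay
equality. The interval is closed by design: the reconstruction step reads
the solution-array rows w − θ … w + θ inclusive, and a tolerance of zero
should accept an exact match rather than nothing.

**Preprocessing** relabels vertices so v_s has internal index 1 and v_t
index |V|, and stores G′ as an inverted adjacency list (per-vertex
predecessor lists, sorted by predecessor index).

**Dynamic programming.** The solution array L has rows 0..w_crit
(w_crit = w + θ) and one column per vertex. The base cell L(0, v_s) holds a
sentinel; a tuple (w_e, v_p) enters L(w_i, v_j) iff G′ has an edge
(v_p, v_j) of weight w_e and L(w_i − w_e, v_p) is non-empty. Rows are filled
in increasing weight, columns in increasing index, so every referenced
subproblem is already solved. Two deliberate choices:

* The start column stays empty for w_i > 0. A walk re-entering v_s can only
  ever extend to a non-simple path, which backtracking discards anyway;
  pruning these cells saves work without changing the output (verified
  against the brute-force simple-path oracle across the seeded test
  population). Consequently the walk-level reading of a cell is: L(w, v) is
  non-empty iff a walk v_s → v of weight exactly w exists *that does not
  re-enter v_s*; the walk oracle exposes a `forbid_start_reentry` flag to
  test precisely this.
* Every incoming edge of every cell is counted as one *algorithmic step*
  even when the weight difference is negative, so the DP performs exactly
  w_crit · |E(G′)| steps on every instance. This counter is the
  hardware-independent stand-in for DP running time and is asserted as an
  exact law in the tests.

**Backtracking** starts one depth-first expansion per entry of the
reconstruction-interval rows of the target column (lower bound clamped at
0), following witness tuples backwards; predecessors are expanded in
ascending vertex index, making the output order deterministic. A branch
whose predecessor is already on the partial path is discarded (counted in
`n_loops_discarded`; the counter tallies pruned branches, each standing for
at least one looped walk). Distinct witness chains always yield distinct
vertex sequences — edge weights are unique per edge and rows encode total
weight — so no deduplication is needed. When `limit` valid paths (default
20 000) have been reconstructed the edge is flagged intractable: at least
that many alternatives exist, which is itself the answer for tagging
purposes.

## Tagging and pruning

Every edge is evaluated against the full original graph minus only itself,
never against a partially pruned graph. This makes tagging order-independent
and is justified by a persistence argument: if an edge inside a found
alternative path is itself tagged later, that edge has by definition its own
delay-matched detour, which closes the gap at equal summed delay.

CE tags: edges with ≥ 1 alternative path, or intractable edges (which are
additionally listed so downstream users can tell them apart). CD tags: for
each CE edge and each of its length-2 alternative paths ⟨v_s, v_1, v_t⟩, one
tag on (v_1, v_t) per distinct triangle. Only this "simple" triangle form of
common drive is detected; common drive through longer cascades would require
enumerating variable-delay motif families of factorial cost and is out of
scope. An edge may hold a CE tag and any number of CD tags simultaneously;
tags are never merged.

Pruning is policy-driven (`all`, `ce-only`, `cd-only`, `report-only`) and
returns both the pruned copy and a removal log. Under `all`, triangles whose
two candidate edges were both removed are flagged: at most one of the two
can actually be spurious, so removing both is deliberately conservative.

## Synthetic network generators

All generators draw weights uniformly on [1, w_max] *after* the topology,
in edge-lexicographic order, so a fixed seed gives the same topology at any
w_max. Identical parameter sets reproduce bit-identical graphs. The default
w_max = 17 mirrors the upper end of reconstructed MEG interaction delays
(5–17 ms on a millisecond grid), the setting these tools were designed
around; it is configurable everywhere.

* **Small-world**: a directed ring lattice — each node points to its n/2
  nearest neighbors on either side — then each edge's target is rewired
  with probability p to a uniform random vertex, redrawing on self-loops
  and duplicates (|E| = n · |V| is preserved). Only the underlying
  undirected, unweighted lattice is small-world in the classic sense; the
  directed weighted variant is an approximation, and no clustering
  coefficient or characteristic path length is asserted.
* **Random**: every ordered pair present independently with probability ρ
  (the density |E| / (|V|(|V|−1))).
* **Scale-free**: preferential attachment from a complete seed digraph on
  m + 1 nodes; each new node attaches m distinct edges (directed new → old)
  with probability proportional to current total degree, giving
  |E| = m · |V| exactly. Seed-graph convention and edge direction are fixed
  and documented rather than inherited from any particular reference
  implementation; the power-law exponent is emergent and not asserted.

What the generators do *not* emulate: estimation noise on delays, missing
edges, delay-dependent edge probability, or any correlation between weight
and topology. Passing tests on these graphs therefore demonstrates
algorithmic correctness and scaling behavior, not robustness to estimation
error in real recordings.

## Path-count analytics and cost model

`expected_alt_path_count(ρ, w_max, w_crit)` evaluates
Σ_{w′=1}^{w_crit} Σ_{j=1}^{w′} C(w′−1, j−1) (ρ/w_max)^j — every composition
of every total weight up to w_crit, each edge of a j-edge candidate present
with probability ρ and carrying the required weight with probability
1/w_max. The formula is a growth model for dense random graphs with w_crit
large relative to individual weights: it ignores the weight cap w ≤ w_max
within compositions and the simple-path constraint, so it is compared to
simulation only qualitatively outside that regime. Its Ω(2^w_crit) growth
(via the composition identity Σ_j C(i−1, j−1) = 2^{i−1}) is the reason the
reconstruction limit exists.

The estimation-cost model compares upgrading a network to targeted
three-node estimation (|V|(|V|−1) bivariate runs plus 6 trivariate runs per
triangle motif present) against brute force (6 · C(|V|, 3) trivariate runs
over all triples; 6 = m(m−1) ordered motifs at m = 3). `crossover_size(f)`
returns the largest |V| at which two-stage is not yet cheaper; at f = 0.9
this is 12. `overlap_stats` reads "overlap expected purely by chance" as the
per-edge joint occupancy probability (|A|/P)(|B|/P), P = |V|(|V|−1) — the
unique reading that is symmetric in the two networks and dimensionless.

## Benchmark harness

`bench` replays the simulation-performance design over a grid of network
family × size × critical weight × seed, recording only counters: DP steps,
reconstructed paths, intractability at the limit. Wall-clock time is never
recorded — it is hardware-bound and non-reproducible. For a target w_crit,
each edge of weight w is examined with θ = w_crit − w (clamped at 0), so
the DP cap is uniform across edges whenever w_max ≤ w_crit. By default a
cell's edge scan aborts at the first intractable edge, mirroring an
aborted-execution protocol, and the cell is recorded with partial counters.

The default acceptance grid is scaled down: |V| ∈ {20, 30}, w_max = 5,
w_crit ∈ {10, 12}, random ρ = 0.5 against small-world n = 4, p = 0.1. Path
proliferation is driven by the number of weight-compatible edge
compositions, which grows with w_crit/w_max and with |V|; shrinking |V| and
w_max together while keeping w_crit/w_max above the onset ratio preserves
the qualitative contrast — dense random graphs hit the 20 000-path limit,
size-matched small-world graphs do not — in seconds rather than hours. Only
this ordering is asserted; absolute onset sizes depend on weight draws and
are not reproduced.

## Numerical and degenerate-input choices

* Duplicate rows in an edge-list file are an error, never an overwrite:
  delays are measurements, and a collision signals an upstream problem.
* The adjacency CSV uses 0 for "no edge" (legal since weights are ≥ 1);
  label headers are optional on read, always written on save. An edge list
  cannot represent isolated vertices; adjacency or GraphML can.
* Graph equality is label-set + edge-set + weights; internal index order is
  an implementation detail and not part of identity.
* `crossover_size` scans the integer range against the exact cost
  expressions rather than trusting a floating-point closed form.
* Oracles (`enumerate_simple_paths`, `enumerate_walks`) share no traversal
  code with the DP — they walk forward over successor lists — and are
  capped at |V| ≤ 10 by default to guard their factorial cost.

## Known limitations

* Only triangle (length-2) common drive is detected; longer common-drive
  cascades are not.
* The tool reports *potentially* spurious edges; adjudicating which
  triangle edge is real requires external evidence (anatomy, multivariate
  estimation) and is deliberately left to the user.
* θ trades sensitivity against false removals; a sensible upper bound is
  the smallest plausible interaction delay, or a bootstrap estimate of the
  delay-reconstruction error if available. The tool does not choose θ.
* Intractable edges are tagged but their path lists are truncated at the
  limit; counts above the limit are lower bounds.
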