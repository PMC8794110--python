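# Methods

## Scope and model

`lcdago` predicts protein complexes on an undirected, unweighted PPI
network `G = (V, E)` by local community detection.  The output is a hard
partition: every processed protein belongs to exactly one community, and
each community is identified by its *source* protein, a high-degree member
from which hop distances are measured.  Per-node state is deliberately
minimal — community label `cl`, hop-level `hl` (source convention
`hl = 1`), GO term set `g`, cached degree `k` — and every update for a node
reads only that node's own state and the states of its first neighbours.
This locality is a contract, not an optimisation: the test suite verifies
with an access-tracking state map that a node's decision never touches
state outside its closed neighbourhood.

## The update rules

A run starts from one node (given, seed-chosen, or the lexicographically
smallest) and discovers the component breadth-first; a node entering the
visit list is lazily initialised to its own singleton community
(`cl = self`, `hl = HL`, default `HL = 4`; any value > 1 works, since the
level is revised as sources emerge).  Each sweep processes the visit list
in discovery order and applies, per node `v`:

1. **degree rule** — if `k_v` strictly exceeds every neighbour's degree,
   `hl_v` decreases by one (floored at 1).  Local degree maxima therefore
   drift toward `hl = 1` and become attractive anchors.
2. **candidate community** — the label with the most links to `v`, ties
   broken by the smaller minimum neighbour hop-level, then the
   lexicographically smallest label.
3. **expansion rules** — with candidate `u` and
   `μ(v, u) = (2·E_in − k_v)/k_v`:
   * `μ > 0`: `v` joins `u`; `hl_v ← min(hl over labelled neighbours) + 1`;
   * `μ ≤ 0` and `cl(v) = u`: the neighbourhood has elected `v`; it becomes
     a source (`hl = 1`);
   * otherwise `v` follows the labelled neighbour `p` maximising
     `ln(k_p / hl_p)·|g_v ∩ g_p|` (topology mode: `ln(k_p / hl_p)`),
     copying `p`'s label and hop-level — but only if that influence is
     strictly positive.  If no neighbour exerts positive influence, `v`
     starts a new community (`cl = v`, `hl = 1`).

The sweep repeats until a full pass over the complete component changes no
label, or a hard cap (`max_iter = 100`) is hit, in which case the result is
returned with a non-convergence flag rather than looping.

### Design choices on genuinely open ground

* **E_out counts the whole rest of the neighbourhood.**  `μ`'s
  out-links include still-unvisited neighbours, so `μ > 0` certifies a
  strict majority of `v`'s full neighbourhood.  The alternative — counting
  only labelled neighbours — makes every frontier node see `μ = 1` toward
  its discoverer, and the start label floods the entire component; the
  planted-partition experiments in the test suite distinguish the two
  readings decisively.
* **Following requires strictly positive influence.**  The GO term overlap
  enters the dynamics only through the influence score; if zero- or
  negative-influence neighbours could recruit, label flow would cross
  functional boundaries unchecked and the GO signal would never matter.
  The "start a new community" fallback is the natural complement: a node
  surrounded by functionally alien communities seeds its own.
* **Influence of a neighbour is computed from that neighbour's own state**
  (`ln(k_p/hl_p)` weighted by the functions shared with `v`).  Evaluating a
  neighbour's full community-influence score would require *its*
  neighbourhood and break the locality contract.
* **The followed neighbour's hop-level is copied verbatim.**  A
  `follow_hl_increment` switch adds one instead (the graph-distance
  consistent variant); the default reproduces the printed rule.  Either
  way hop-levels are heuristic distances, not exact shortest paths.
* **Tie-breaks are deterministic everywhere** (link count, then minimum
  neighbour hop-level, then lexicographic label; influence, then
  lexicographic node ID).  Identical inputs, seed and start node give
  byte-identical outputs.
* **Source normalisation.**  The raw updates can leave a converged source
  with `hl > 1` (its own `μ > 0` branch reassigns `min+1`).  When the
  partition is assembled, each community label — by convention a member of
  its own community — is set to `hl = 1`; in the rare case a label drifted
  into another community, the community is relabelled to its member with
  the smallest hop-level (ties lexicographic).

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `hl_init` (HL) | 4 | initial hop-level of a freshly visited node; any value > 1 |
| `mode` | `go` | `go` = LCDA-GO (topology + GO), `topology` = LCDA |
| `theta` (θ) | 0.1 | inclusive affinity-score threshold for complex matching |
| `max_iter` | 100 | outer sweep cap; 2–5 sweeps suffice in practice |
| `min_component_size` | 3 | components below this cannot form a community and are dropped |
| `intersection` | `union` | neighbour-term aggregation in λ: pooled union (default) or per-neighbour sum |

θ's comparison is inclusive (`AS ≥ θ`), so θ = 0 matches even
zero-overlap pairs — a documented footgun; keep θ > 0.

## Evaluation conventions

All metrics retain full precision internally; table rendering rounds
half-up to 2 decimals.  Predicted communities of size 1–2 are evaluated by
default (`min_complex_size` excludes them).  The benchmark is used in full
by default; `restrict_to_nodes` optionally intersects each benchmark
complex with the evaluated network's protein set, which raises Recall and
Sn when the network covers only part of the benchmark's universe.  PPV is
defined as 0 when the overlap matrix is all-zero.

## The synthetic benchmark

The generator emulates the coupled inputs of a real complex-prediction
study.  Edges follow a stochastic block model — communities of
configurable sizes with intra-/inter-community edge probabilities
`p_in`/`p_out` — with the draw retried until every planted community is
internally connected.  Each planted community owns a characteristic subset
of a small per-category term vocabulary (defaults 8 MF / 11 BP / 3 CC,
mirroring a coarse protein-class vocabulary), dealt round-robin so the
subsets are pairwise disjoint; a sparse category simply leaves some
communities without a term there, and only a community that would have no
term in *any* category wraps around and shares one.  Annotation noise
swaps each term, independently, for a foreign same-category term with the
given probability.  `perturb` rewires a fraction of edges uniformly while
preserving the simple graph and edge count, emulating screening error.

What the generator does **not** emulate: scale-free degree distributions,
overlapping complexes, hierarchical GO structure (terms are flat symbols,
no ancestor relations), correlated false positives of specific screening
technologies, or proteins with missing annotations inside an annotated
community.  Passing the recovery tests therefore shows the machinery is
correct under clean planted conditions, not that real-map accuracy matches
any published figure.

## Problem sizes used in checks

The recovery experiments use 4 communities × 10 nodes (`p_in = 0.9`,
`p_out = 0.02`, noise 0) over 20 seeds, with exact-recovery checks at
`p_out = 0`.  Convergence and scaling checks use planted networks of
250–2000 nodes (communities of 10, `p_out ≈ 3/n` to keep the planted
structure sparse between blocks at every size) and measure the sweep
counter and a neighbour-touch counter rather than wall-clock time; sweep
cost grows close to linearly in the edge count.

## Known limitations

* Hard partitions only: no overlapping complexes, no weighted or directed
  graphs, no GO semantic-similarity — term sets are compared by exact
  intersection.
* A single run handles one connected component; `run_multi` splits the
  network and drops components below the size threshold, so proteins in
  tiny components are never assigned.
* Hop-levels are heuristic and can disagree with true shortest-path
  distances after long label churn; they influence tie-breaks and
  influence scores, not the final partition's validity.
* The predicted community count is sensitive to the annotation sparsity:
  unannotated proteins (empty term sets) can only be recruited through the
  `μ > 0` majority rule, and in GO mode tend to end up as singletons when
  they sit on community boundaries.
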