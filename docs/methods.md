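# Methods

## Model

Edge confidences P(e) ∈ (0, 1] are read as independent probabilities that the
corresponding interactions are real, so the probability that an entire chain
of interactions is real is the product of its edge confidences. The strongest
path between source set A and target set B maximizes that product with a
per-edge penalty D:

    score(π) = ∏ₑ∈π P(e) · D^|π|,    D ∈ (0, 1].

Without the penalty, and with the product alone tying, the shorter path is
preferred; any D < 1 enforces that preference automatically and additionally
lets users trade confidence against path length. Maximizing score(π) equals
minimizing the additive dual length ∑ₑ W(e) with W(e) = −(ln D + ln P(e)) ≥ 0,
so Dijkstra on the reweighted ("dual") graph is exact. Multi-source/multi-sink
search is reduced to single-pair by a super-source σ → A and B → super-sink τ;
those artificial edges get dual weight exactly 0, not W(1, D) — charging the
length penalty for artificial hops would bias every path's score by D² and,
worse, bias comparisons between paths only when super-edge counts differed.

Independence of edge probabilities is of course an idealization: confidence
scores from a single database pipeline are correlated, and the product is a
ranking device rather than a calibrated path probability.

### ε-suboptimal node sets

For ε ≥ 0, a path is ε-strongest if its dual length is within ε of the
optimum w*. Listing such paths is exponential; the useful summary is the node
set V_ε of proteins on at least one of them. With a(v) the dual distance
σ → v and b(v) the dual distance v → τ (one forward and one backward Dijkstra
pass over the dual graph — the backward pass runs on the reversed adjacency),

    V_ε = { v : a(v) + b(v) ≤ w* + ε }.

One subtlety, documented rather than hidden: a(v) + b(v) is the length of the
best *walk* through v, which in principle may revisit a node that the forward
and backward halves share. Membership is therefore witnessed by a walk, not
always by a simple path. The acceptance oracle checks exactly the stated
criterion (via all-pairs Floyd–Warshall relaxation); nodes of every optimal
simple path are always included, and the node sets are monotone in ε.

Edge retention has two modes. Dense: the full induced subgraph on V_ε.
Sparse: only edges with a(u) + W(u,v) + b(v) ≤ w* + ε (either orientation for
undirected edges), i.e. edges themselves on some ε-strongest path; the sparse
set is always a subset of the dense set over the same nodes. BFS hop layers
from the source set inside the retained subnetwork are attached for
layout/reporting; every V_ε node is reachable there, because each node on a
witnessing walk satisfies the membership inequality itself.

ε is expressed in dual-length units. Natural logarithms are used throughout
(a base change only rescales ε), so ε is interpretable as −ln of a
probability-score ratio: ε = 0.1 admits paths whose penalized score is within
a factor e^−0.1 ≈ 0.905 of optimal.

### Determinism and ties

D < 1 already prefers fewer edges among equal products, but exact dual-length
ties still occur (identical confidences are common in curated databases). The
search therefore runs Dijkstra on the lexicographic pair (dual length, hop
count) — both components additive and nonnegative — and then reconstructs the
path through the tight-edge DAG, greedily choosing the smallest node label at
each step. On every optimal path each prefix is tight, so the walk yields the
lexicographically smallest label sequence among minimal-length, minimal-hop
optima; repeated runs are byte-identical. A 1e−9 additive slack absorbs
floating-point noise in all tightness and V_ε membership comparisons.

"No path" is a first-class result (`result.exists == False`), not an
exception: batch runs over several databases must continue past databases
that do not connect the query sets. The CLI exits 0 and writes a NO_PATH
marker line.

## Expansion

Candidates v ∉ S are scored by Σ P(e) over edges between v and the current
set S; candidate–candidate edges are deliberately excluded (the score
measures attachment to the *current* network, and including them would let
two well-connected outsiders bootstrap each other in). For directed networks
both orientations count. Batch mode ranks once and takes the top n — one
"expand" action; sequential mode re-ranks after each single addition, so a
node two steps away can enter once its neighbor has been added. Ties break by
label, keeping runs deterministic. If fewer than n candidates touch the set,
all are added and a shortfall flag is raised.

## Regulatory paths

Signed TF→target networks use BFS (hop-minimal, unweighted — confidences play
no role here) per source/target pair, then enumerate *all* minimal-length
paths from the BFS predecessor DAG: distinct minimal paths can carry
different sign products, so returning a single path would silently hide one
of the two regulation modes. A path is activating iff its ±1 sign product is
+1 (an even number of repressions; double repression activates). Parallel
edges with conflicting annotations are kept as two distinct edges and expand
into one path per sign choice. Enumeration is capped (default 100 paths per
pair, flagged when hit) because minimal-path counts can grow exponentially.
Edges annotated "Unknown" are dropped by default — the classification is
defined only for ±1 — with opt-in policies to map them to activation or to
both signs. A gene in both the source and target lists yields no length-0
path to itself.

## Evaluation statistics

For a search that returned a node set, the intermediate genes are that set
minus sources and targets. Against a curated pathway set, significance of the
overlap k between n found genes and K pathway genes in a background of N
network nodes is the inclusive upper tail P(X ≥ k) of the hypergeometric
distribution (scipy's log-gamma based survival function; equivalently
`phyper(k−1, K, N−K, n, lower.tail=FALSE)`). The background N is the node
count of the network actually searched, and pathway sets are intersected with
that background before K is counted — genes absent from the searched network
are unfindable and would deflate p-values. Across pathways, Benjamini–
Hochberg step-up adjustment controls the FDR. Precision = |found ∩ pathway| /
|found| (0 for an empty found set), recall = |found ∩ pathway| / |pathway|.

## Synthetic data

The fixture generators exist to make every algorithm verifiable against
exhaustive oracles, not to mimic PPI topology:

- `random_network(n, density, weight_range, directed, seed)` — Erdős–Rényi
  edge sampling with confidences uniform in (0.2, 0.95) by default, the range
  spanning typical database scores while keeping dual weights bounded away
  from 0.
- `planted_path_network` — a chain of `length` edges at confidence `p_hi`
  (default 0.95, a high-confidence curated interaction) between a designated
  source and target, embedded in background noise with confidences capped at
  `p_lo` (default 0.3, low-confidence predicted interactions) at density 0.2
  on 20 nodes. At these defaults any 2-edge noise detour scores at most
  0.3² · D² ≈ 0.081 against the chain's 0.95³ · D³ ≈ 0.735, so recovery is
  expected in every instance; recovery tests still confirm optimality
  per-instance through the all-pairs oracle instead of assuming it.
- `random_signed_network(n, density, inhibitory_fraction, seed)` — directed
  edges, each inhibitory with the stated probability.

One integer seed drives all randomness through a private numpy Generator;
identical spec + seed is bit-reproducible, and labels are "n000", "n001", …
so label-based tie-breaks are predictable. What these generators do *not*
emulate: scale-free degree distributions, edge-confidence correlation, hubs,
or database-specific score calibration. Passing tests therefore demonstrate
algorithmic correctness (agreement with exhaustive search on the stated
graph family), not biological performance on real networks.

## Problem sizes and numerical choices

Correctness checks run on graphs small enough for exhaustive enumeration:
300 instances of 4–10 nodes across densities {0.2, 0.5, 0.8}, both
orientations and D ∈ {1.0, 0.95, 0.8} for the path/ε checks; 100 instances
each for the unit-weight, planted-recovery, expansion and regulatory checks.
The brute-force simple-path oracle refuses graphs above 12 nodes by design.
Tolerances: 1e−9 additive on dual lengths and scores, 1e−12 on exact
rational statistics. Duplicate edges merge by maximum (idempotent and
order-independent across concatenated database dumps, and the only choice
consistent with "strongest" semantics); out-of-range scores are hard errors
rather than silently clamped.

## Known limitations

- V_ε membership can be witnessed by a non-simple walk (see above).
- The expansion score ignores candidate–candidate edges by design; protein
  complexes whose members attach weakly to the seed but strongly to each
  other will not be pulled in as a block.
- Regulatory path enumeration is capped per pair; on dense networks the cap
  (not completeness) bounds the output.
- Confidence independence across edges is assumed, as in any product-score
  path model.
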