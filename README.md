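# strongpaths

Maximum-confidence path analysis on weighted protein–protein interaction and
signaling networks.

Interaction databases attach a confidence score P(e) ∈ (0, 1] to each edge —
the probability that the interaction is real. Given a set of source proteins
*A* (say, a pathway's receptors) and a set of targets *B* (its transcription
factors), the **strongest path** is the chain of interactions from some a ∈ A
to some b ∈ B maximizing

    score(π) = ∏ₑ∈π P(e) · D^|π|

where D ∈ (0, 1] (default 0.95) is a constant per-edge penalty that favors
shorter chains among near-equal products. Unpenalized max-product path search
on general graphs is intractable, but because every weight lies in (0, 1],
reweighting each edge to the nonnegative **dual weight**

    W(e) = −(ln D + ln P(e))

turns the problem into an ordinary shortest-path search: one Dijkstra pass on
the dual graph (with a super-source wired to A and a super-sink wired from B
by zero-weight edges) finds the exact optimum. Two passes — forward from A and
backward from B — give, for every node v, the distances a(v) and b(v), and the
**ε-suboptimal node set**

    V_ε = { v : a(v) + b(v) ≤ w* + ε }

collects every protein lying on some path within ε (natural-log units) of the
optimal dual length w*, without enumerating the exponentially many paths.

The package also provides:

- **Expansion** — greedily grow a protein set by the n external proteins with
  the largest total interaction confidence into the current set (protein
  complex / regulatory circuitry completion);
- **Regulatory paths** — in a signed TF→target network (TRRUST-style
  Activation/Repression edge lists), enumerate all hop-minimal directed paths
  per source/target pair and classify each as *activating* (sign product +1)
  or *inhibitory* (−1);
- **Evaluation statistics** — overlap of recovered intermediate genes with a
  curated pathway set: upper-tail hypergeometric p-value, Benjamini–Hochberg
  FDR across pathways, precision and recall;
- **Synthetic fixtures** — seeded random and planted-path network generators
  plus brute-force oracles, so everything is testable without database
  downloads.

Intended users: computational biologists reconstructing signaling pathways
from confidence-weighted networks (STRING-, KEGG- or TRRUST-style exports),
and anyone needing an auditable, scriptable max-product path engine.

## File formats

- **Network**: tab-separated, no header, three columns — source label, target
  label, confidence in (0, 1]. Duplicate edges are merged keeping the maximum
  confidence; self-loops are dropped. `--score-divisor 1000` rescales raw
  0–1000 combined scores.
- **Annotation** (optional): tab-separated, no header; column 1 is the
  canonical node label, further columns are comma-separated alternative
  identifiers. Any alias may be used to name a node; matching is
  case-insensitive.
- **Signed network**: tab-separated; source, target, regulation mode
  (`Activation` / `Repression` / `Unknown`, case-insensitive).

## Worked example

```sh
$ strongpaths simulate --nodes 15 --density 0.2 --seed 7 \
      --planted 3 0.95 0.3 --out demo.tsv
planted chain: n000 -> n001 -> n002 -> n003
demo.tsv: 15 nodes, 24 edges

$ strongpaths path --network demo.tsv --sources n000 --targets n003 \
      --epsilon 0.1 --out demo
demo.tsv: strongest path n000 -> n001 -> n002 -> n003 (product 0.857375,
penalized 0.735092); |V_eps| = 4
```

The simulator embedded a 3-edge chain at confidence 0.95 in background noise
capped at 0.3; the search recovers exactly that chain. Its raw product is
0.95³ = 0.857375 and the reported penalized score is 0.95³ · 0.95³ = 0.735092
(three edges, D = 0.95 charged once per edge). `demo.nodes.tsv` lists each
V_ε member with its BFS layer, forward/backward dual distances and a flag
marking nodes on an optimal path; `demo.edges.tsv` flags edges lying on some
ε-strongest path.

Library equivalent:

```python
from strongpaths import planted_path_network, strongest_path

net, chain = planted_path_network(n_nodes=15, density=0.2, length=3,
                                  p_hi=0.95, p_lo=0.3, seed=7)
result = strongest_path(net, {chain[0]}, {chain[-1]})
print(result.labels, result.product, result.penalized_score)
# ('n000', 'n001', 'n002', 'n003') 0.8573749999999999 0.7350918906249998
```

Other subcommands: `strongpaths expand` (greedy growth), `strongpaths
regulatory` (signed path classification), `strongpaths enrich` (hypergeometric
/ FDR / precision-recall tables), `strongpaths simulate` (synthetic networks).
Run any of them with `--help`.

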