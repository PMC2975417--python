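# Methods

## Problem setting

A protein–protein interaction (PPI) network is an undirected simple graph
G(V, E) with proteins as vertices and reported interactions as edges.
Protein complexes appear in such networks as dense, small subgraphs, and a
protein can belong to several complexes at once, so complex detection is an
*overlapping* community detection problem. The clique percolation method
(CPM) finds overlapping communities as unions of k-cliques chained through
shared (k−1)-vertex faces, but its single global parameter k is a blunt
instrument on PPI data: at k = 3 percolation glues a large fraction of the
network into one giant community, while at k ≥ 4 most output degenerates to
isolated cliques. Biologically relevant complexes sit at the meso-scale —
roughly 5–25 proteins — and curated complex catalogs show that nearly all
such complexes have graph diameter at most 2.

## The detection model

Detection starts from the maximal cliques of G with at least
`min_clique_size` (default 3) members; each is a *basic cluster unit*. Two
units U, V merge when both conditions hold:

1. **Shared-vertex condition.** |U ∩ V| ≥ N with N = MIN(|U|, |V|) − 1: the
   smaller unit must share all but one of its members with the other. Unlike
   CPM's fixed k−1, the bar rises with unit size, so large units only merge
   with near-duplicates.
2. **Distance restriction.** The subgraph of G *induced* by U ∪ V has
   diameter at most d (default d = 2, the empirical bound on curated complex
   diameters). Only edges of G inside the union count; a disconnected union
   has infinite diameter and never merges.

The scan processes units in a canonical order (size descending, then
lexicographically by sorted member list), compares each unit against every
other unit in the pool — including unions appended earlier in the same scan
— appends each mergeable pair's union at the pool's tail, and retires a unit
once its comparisons are done iff it merged at least once. Scans repeat
until a full pass produces no merge. Exact duplicate member sets are never
created twice (a union is appended only if its member set has never been in
the pool), which, together with the finite number of diameter-d clique
unions, guarantees termination; a `max_passes` cap (default 1000) is a
safety net only and is asserted unreached in the test corpora.

Every emitted cluster is a union of maximal cliques, has at least 3 members
and induced diameter ≤ d, and clusters may overlap. A consequence of the
retirement rule worth stating explicitly: at the fixpoint no emitted
cluster is a proper subset of another, because a subset unit always
satisfies both merge conditions against its superset and is therefore
retired during some pass. The `absorb_subsets` option performs that
filtering as an explicit post-step; at the fixpoint it is a no-op, and it
exists so the containment behaviour is an inspectable choice rather than an
emergent one.

### CPM baseline

`kclique_communities` implements classic clique percolation at the level of
maximal cliques: enumerate maximal cliques of size ≥ k, build the
clique–clique overlap matrix, keep off-diagonal entries ≥ k−1, and read
communities off the connected components, each community being the union of
its component's cliques. A clique adjacent to nothing is a community by
itself. Tests verify this route is identical to direct percolation over
exact k-cliques (the textbook definition) on random-graph corpora, and to
networkx's independent implementation.

## Evaluation battery

* **Overlap score** OS(Pc, Kc) = i² / (|Pc|·|Kc|) with i = |Pc ∩ Kc|, the
  standard geometric match score; i counts *shared proteins* (gold-standard
  catalogs carry member lists, not edge lists). A prediction matches a
  known complex when OS ≥ 0.2, the conventional threshold.
* **Sensitivity** TP/(TP+FN) over known complexes, **specificity**
  TP/(TP+FP) over predictions, and the **f-measure** 2·Sn·Sp/(Sn+Sp). The
  harmonic-mean form is validated exactly, in rational arithmetic, against
  all four published reference rows it must reproduce. Because the
  known-complex denominator is a reporting choice (catalogs are sometimes
  filtered by size), `match_complexes` exposes `min_known_size` rather than
  hard-coding one denominator.
* **Overlapping rate** OR = Σᵢ|cluster_i| / |covered proteins| — the mean
  number of clusters a covered protein belongs to (1 exactly for disjoint
  predictions) — plus the fraction of covered proteins in more than one
  cluster. Proteins in no cluster are excluded from the denominator.
* **Function enrichment.** For a cluster of size C in an N-protein network,
  a category with F annotated proteins and k hits in the cluster gets the
  upper-tail hypergeometric probability P = Σ_{i=k}^{min(C,F)}
  C(F,i)·C(N−F,C−i)/C(N,C), inclusive of the observed k (the standard
  over-representation convention); k = 0 gives P = 1. The
  minimum-P-value category is the cluster's main function, ties broken by
  lexicographically smallest code. Dotted category codes are treated as
  independent categories — no propagation along the annotation tree, since
  no propagation rule is part of the model. Raw P-values are reported (the
  conventional 0.01 / 0.001 cutoffs in the CLI summary); multiple-testing
  correction is out of scope.
* **Complex–complex interactions**: the pairs of predicted clusters sharing
  at least one protein, the overlap structure's own network.

## Synthetic benchmarks

`synthetic.generate` plants `n_complexes` complexes with sizes drawn
uniformly from [size_min, size_max] (defaults 5–25, the meso-scale regime)
in a chain where consecutive complexes share `overlap_size` vertices
(default 2), so each adjacent pair's expected merge behaviour is
analytically derivable. Within a complex each pair is an edge with
probability `intra_density` (default 1, making each complex a diameter-1
clique); `noise_edges` (default 50) spurious edges connect proteins sharing
no complex. One integer seed drives all randomness through a local
`numpy` generator; identical parameters give byte-identical benchmarks.

What the generator does *not* emulate: scale-free degree structure, false
negatives in complex membership, confidence-weighted edges, and the
heavy-tailed complex-size distribution of curated catalogs. Passing tests
on these benchmarks demonstrate algorithmic correctness (recovery of
planted structure, invariant preservation, exact agreement with brute-force
oracles), not field performance on any particular curated network.

## Numerical and design choices

* Degree-0/1 vertices contribute 0 to the mean clustering coefficient;
  diameter and mean distance are over the largest connected component
  (real interaction networks are disconnected, and finite summary values
  require a convention).
* Proteins appearing only in self-interactions are dropped during graph
  construction; identifiers are case-sensitive opaque strings with no
  ORF-name normalisation.
* Clique enumeration uses pivoting Bron–Kerbosch recursion (networkx);
  correctness is pinned by a brute-force subset-enumeration oracle on
  random graphs, so the enumerator is replaceable.
* All orderings (clique lists, cluster output, overlap-matrix rows) follow
  one canonical key — size descending, then lexicographic — making every
  run reproducible and diffable.
* The hypergeometric tail is computed by `scipy.stats.hypergeom.sf`,
  clamped into [0, 1]; an exact `math.comb` sum serves as the test oracle.
* Merge scanning compares units pairwise and creates one union per
  mergeable pair (not one grand union per scan); chains of adjacency are
  realised across passes through the appended unions.

## Scale of the shipped analyses

The bundled tests and reproduction script run on synthetic corpora —
hundreds of random graphs of ≤ 12 vertices for oracle equivalence and 100
planted benchmarks of up to ~150 proteins for detection invariants — sizes
chosen so the full suite completes in a few minutes while still exercising
every code path and invariant. The algorithms themselves handle
thousands-of-protein networks; the merge scan is quadratic in the number of
maximal cliques with small per-pair BFS cost, and clique enumeration is the
usual worst-case-exponential but benign on sparse PPI topologies.

## Known limitations

* Cluster counts on a real network depend on the scan order only through
  which duplicate unions are created first; output member sets are
  order-independent in all tested corpora, but no formal proof of
  order-invariance is claimed.
* `k_cliques` materialises every k-subset of every maximal clique — fine
  for oracles and moderate graphs, combinatorial on large dense cliques.
* The refinement relationship with CPM is partial by design: a CPM k=3
  community of diameter ≤ 2 built from large cliques sharing only 2
  vertices is *not* reproduced by the per-pair shared-vertex rule, which
  demands min(|U|,|V|) − 1 shared members. Tests assert exact refinement
  on disjoint planted corpora and measure the violation rate on
  overlapping ones.
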