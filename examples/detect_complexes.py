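"""Detect overlapping complexes in a planted benchmark and check recovery.

Generates a clean benchmark (disjoint fully-connected complexes), runs the
distance-restricted merge algorithm, and prints the clusters next to the
ground truth.
"""

from cpdr import GeneratorParams, cpdr_clusters, generate

bench = generate(
    GeneratorParams(
        n_complexes=5, size_min=5, size_max=9, overlap_size=0,
        intra_density=1.0, noise_edges=0, seed=42,
    )
)
print(f"benchmark: {bench.graph.number_of_nodes()} proteins, "
      f"{bench.graph.number_of_edges()} interactions, "
      f"{len(bench.truth)} planted complexes")

clusters = cpdr_clusters(bench.graph)
print(f"detected {len(clusters)} clusters (diameter <= 2, size >= 3):")
for unit in clusters:
    planted = any(unit.members == c for c in bench.truth)
    print(f"  size {len(unit.members):2d}  planted={planted}  "
          + " ".join(sorted(unit.members)[:6])
          + (" ..." if len(unit.members) > 6 else ""))

# On a clean benchmark every planted complex is a maximal clique and nothing
# merges, so detection is exact.
assert {u.members for u in clusters} == set(bench.truth)
print("recovery: exact — every planted complex detected, nothing spurious")
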