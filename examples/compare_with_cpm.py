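"""Contrast the distance-restricted algorithm with the CPM baseline.

Two size-8 complexes sharing 2 proteins: CPM at k=3 percolates through the
shared pair and reports one merged community, while the per-pair
shared-vertex rule (needing min(|U|,|V|)-1 = 7 shared members) keeps the
two complexes apart.  Evaluation scores quantify the difference.
"""

from cpdr import (
    GeneratorParams, cpdr_clusters, f_measure, generate, induced_diameter,
    kclique_communities, match_complexes, sensitivity, specificity,
)

bench = generate(
    GeneratorParams(
        n_complexes=2, size_min=8, size_max=8, overlap_size=2,
        intra_density=1.0, noise_edges=0, seed=1,
    )
)
catalog = {f"complex{i}": c for i, c in enumerate(bench.truth)}
print("planted: two size-8 complexes sharing 2 proteins\n")

for label, predicted in [
    ("CPM k=3", [c.members for c in kclique_communities(bench.graph, 3)]),
    ("CP-DR  ", [u.members for u in cpdr_clusters(bench.graph)]),
]:
    sizes = sorted((len(p) for p in predicted), reverse=True)
    diams = [induced_diameter(bench.graph, p) for p in predicted]
    r = match_complexes(predicted, catalog, threshold=0.2)
    sn, sp = sensitivity(r.tp, r.fn), specificity(r.tp, r.fp)
    print(f"{label}: {len(predicted)} prediction(s), sizes {sizes}, "
          f"diameters {diams}")
    print(f"         Sn={sn:.3f} Sp={sp:.3f} F={f_measure(sn, sp):.3f}"
          f"  (TP={r.tp} FP={r.fp} FN={r.fn})\n")

print("CPM's single merged community still matches both planted complexes at\n"
      "the 0.2 overlap-score threshold; the difference shows in cluster sizes\n"
      "and becomes dramatic on chains of many overlapping complexes, where\n"
      "CPM returns one giant community.")
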