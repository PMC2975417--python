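"""Scoring predicted complexes against gold-standard catalogs and annotations.

The battery mirrors what the complex-prediction literature reports:

* overlap score ``OS(Pc, Kc) = i^2 / (|Pc| * |Kc|)`` with ``i`` the number
  of shared proteins, and a match threshold (conventionally 0.2);
* sensitivity ``TP / (TP + FN)``, specificity ``TP / (TP + FP)`` and their
  harmonic mean, the f-measure;
* the overlapping rate — the mean number of predicted complexes a covered
  protein belongs to — together with the fraction of proteins in more than
  one complex;
* hypergeometric function enrichment: the upper-tail probability that a
  complex of size C drawn from an N-protein network hits at least k of the
  F proteins carrying a functional category, with the minimum-P-value
  category assigned as the complex's main function.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, TextIO, Union

from scipy.stats import hypergeom

__all__ = [
    "MatchResult",
    "EnrichmentResult",
    "OverlapRate",
    "overlap_score",
    "match_complexes",
    "sensitivity",
    "specificity",
    "f_measure",
    "overlapping_rate",
    "hypergeom_pvalue",
    "assign_main_function",
    "complex_overlap_network",
    "load_catalog",
    "load_annotations",
]

Source = Union[str, Path, TextIO]

#: Conventional overlap-score threshold above which a prediction counts as a match.
DEFAULT_OS_THRESHOLD = 0.2


def overlap_score(pc: Iterable[str], kc: Iterable[str]) -> float:
    """Overlap score between a predicted cluster and a known complex.

    ``OS = i^2 / (|Pc| * |Kc|)`` with ``i = |Pc ∩ Kc|``: symmetric, 0 for
    disjoint sets, 1 exactly when the sets coincide.
    """
    pc, kc = set(pc), set(kc)
    if not pc or not kc:
        raise ValueError("overlap_score requires non-empty sets")
    i = len(pc & kc)
    return (i * i) / (len(pc) * len(kc))


@dataclass(frozen=True)
class MatchResult:
    """Match counts of predicted clusters against a known-complex catalog.

    ``tp + fp`` equals the number of predicted clusters and
    ``matched_known + fn`` the number of known complexes considered.
    ``best_scores[i]`` is predicted cluster i's best OS over the catalog.
    """

    tp: int
    fp: int
    matched_known: int
    fn: int
    threshold: float
    best_scores: tuple[float, ...] = ()


def match_complexes(
    predicted: Sequence[Iterable[str]],
    known: Mapping[str, Iterable[str]],
    threshold: float = DEFAULT_OS_THRESHOLD,
    min_known_size: int | None = None,
) -> MatchResult:
    """Count matches at an overlap-score threshold.

    A predicted cluster is a true positive iff its best OS over the catalog
    reaches ``threshold``; a known complex is matched iff some prediction
    reaches ``threshold`` against it.  ``min_known_size`` optionally
    restricts the catalog to complexes of at least that size — the
    sensitivity denominator is a reporting choice, so it is exposed rather
    than fixed.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    catalog = {name: frozenset(m) for name, m in known.items()}
    if min_known_size is not None:
        catalog = {n: m for n, m in catalog.items() if len(m) >= min_known_size}
    if not catalog:
        raise ValueError("known-complex catalog is empty")
    predicted_sets = [frozenset(p) for p in predicted]

    best_scores = []
    matched_known_names: set[str] = set()
    tp = 0
    for p in predicted_sets:
        best = 0.0
        for name, kcm in catalog.items():
            score = overlap_score(p, kcm) if p else 0.0
            if score > best:
                best = score
            if score >= threshold:
                matched_known_names.add(name)
        best_scores.append(best)
        if best >= threshold:
            tp += 1
    matched_known = len(matched_known_names)
    return MatchResult(
        tp=tp,
        fp=len(predicted_sets) - tp,
        matched_known=matched_known,
        fn=len(catalog) - matched_known,
        threshold=threshold,
        best_scores=tuple(best_scores),
    )


def sensitivity(tp: int, fn: int) -> float:
    """Fraction of known complexes recovered: ``TP / (TP + FN)``."""
    if tp + fn <= 0:
        raise ValueError("sensitivity undefined for tp + fn = 0")
    return tp / (tp + fn)


def specificity(tp: int, fp: int) -> float:
    """Fraction of predictions that match a known complex: ``TP / (TP + FP)``."""
    if tp + fp <= 0:
        raise ValueError("specificity undefined for tp + fp = 0")
    return tp / (tp + fp)


def f_measure(sn: float, sp: float) -> float:
    """Harmonic mean of sensitivity and specificity: ``2·Sn·Sp / (Sn + Sp)``."""
    if sn + sp <= 0:
        raise ValueError("f_measure undefined for sn + sp = 0")
    return 2.0 * sn * sp / (sn + sp)


class OverlapRate(NamedTuple):
    """Overlapping rate and the fraction of covered proteins in > 1 cluster."""

    rate: float
    fraction_multi: float


def overlapping_rate(predicted: Sequence[Iterable[str]]) -> OverlapRate:
    """Mean occurrence count of each covered protein across predicted clusters.

    ``OR = Σ_i |cluster_i| / |proteins covered by >= 1 cluster|`` — always
    >= 1, equal to 1 exactly when clusters are pairwise disjoint.  The
    second component is the share of covered proteins appearing in more
    than one cluster.
    """
    sets = [frozenset(p) for p in predicted]
    if not sets or any(not s for s in sets):
        raise ValueError("overlapping_rate requires non-empty clusters")
    occurrences: dict[str, int] = {}
    for s in sets:
        for v in s:
            occurrences[v] = occurrences.get(v, 0) + 1
    covered = len(occurrences)
    rate = sum(len(s) for s in sets) / covered
    multi = sum(1 for c in occurrences.values() if c > 1) / covered
    return OverlapRate(rate=rate, fraction_multi=multi)


def hypergeom_pvalue(n_total: int, c_size: int, f_size: int, k_hit: int) -> float:
    """Upper-tail hypergeometric probability of >= ``k_hit`` category members.

    ``P = Σ_{i=k}^{min(C,F)} C(F,i)·C(N−F,C−i) / C(N,C)`` — the chance that
    a random C-protein set from an N-protein network contains at least k of
    the F proteins annotated to the category.  ``k_hit = 0`` gives 1.
    """
    if not (0 <= k_hit <= min(c_size, f_size) <= n_total):
        raise ValueError("require 0 <= k_hit <= min(c_size, f_size) <= n_total")
    if c_size > n_total or f_size > n_total:
        raise ValueError("category and complex sizes cannot exceed n_total")
    if k_hit == 0:
        return 1.0
    p = float(hypergeom.sf(k_hit - 1, n_total, f_size, c_size))
    return min(1.0, max(p, 0.0))


@dataclass(frozen=True)
class EnrichmentResult:
    """Main-function assignment for one predicted cluster.

    ``best_category`` is None when no member carries an annotation
    ("unassigned"); otherwise it is the minimum-P-value category, ties
    broken by lexicographically smallest code.
    """

    best_category: str | None
    p_value: float
    k_in: int
    cluster_size: int

    @property
    def assigned(self) -> bool:
        return self.best_category is not None


def assign_main_function(
    cluster: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    n_total: int,
    category_sizes: Mapping[str, int] | None = None,
) -> EnrichmentResult:
    """Assign a cluster the functional category with minimum enrichment P-value.

    ``annotations`` maps protein -> category codes (dotted FunCat-style
    strings, each treated as an independent category).  ``category_sizes``
    may be precomputed once per analysis; otherwise it is derived from
    ``annotations``.
    """
    members = frozenset(cluster)
    if not members:
        raise ValueError("cluster must be non-empty")
    if category_sizes is None:
        category_sizes = {}
        for codes in annotations.values():
            for code in codes:
                category_sizes[code] = category_sizes.get(code, 0) + 1
    hits: dict[str, int] = {}
    for protein in members:
        for code in annotations.get(protein, ()):
            hits[code] = hits.get(code, 0) + 1
    if not hits:
        return EnrichmentResult(
            best_category=None, p_value=1.0, k_in=0, cluster_size=len(members)
        )
    best_code, best_p, best_k = None, None, 0
    for code in sorted(hits):  # lexicographic scan makes the tie-break explicit
        k = hits[code]
        f = category_sizes[code]
        p = hypergeom_pvalue(n_total, len(members), f, k)
        if best_p is None or p < best_p:
            best_code, best_p, best_k = code, p, k
    return EnrichmentResult(
        best_category=best_code, p_value=best_p, k_in=best_k, cluster_size=len(members)
    )


def complex_overlap_network(predicted: Sequence[Iterable[str]]) -> list[tuple[int, int]]:
    """Complex–complex interactions: index pairs (i < j) of clusters sharing >= 1 protein."""
    sets = [frozenset(p) for p in predicted]
    pairs = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                pairs.append((i, j))
    return pairs


def load_catalog(source: Source) -> dict[str, frozenset[str]]:
    """Load a known-complex catalog: per line, a name then tab-separated members.

    Complexes with fewer than two proteins are discarded on load.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    catalog: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t.strip() for t in line.split("\t") if t.strip()]
        name, members = tokens[0], frozenset(tokens[1:])
        if name in catalog:
            raise ValueError(f"line {lineno}: duplicate complex name {name!r}")
        if len(members) >= 2:
            catalog[name] = members
    return catalog


def load_annotations(source: Source) -> dict[str, frozenset[str]]:
    """Load protein -> category-code annotations (one TAB-separated pair per line)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    out: dict[str, set[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = [t.strip() for t in line.split("\t")]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"line {lineno}: expected 'protein<TAB>category'")
        out.setdefault(fields[0], set()).add(fields[1])
    return {p: frozenset(codes) for p, codes in out.items()}
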