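"""Term enrichment: exact hypergeometric Fisher tests and elim decorrelation.

``classic`` tests every term independently with the one-sided (upper tail)
hypergeometric probability, computed by exact integer summation. ``elim``
walks the DAG bottom-up (strictly decreasing longest-path depth, stable
lexicographic order within a depth) and removes the genes of significantly
enriched descendants before testing their ancestors, penalizing general
terms whose signal is owned by a more specific child.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .ontology import AnnotationMap, OntologyGraph

__all__ = [
    "hypergeom_sf",
    "expected_count",
    "classic_fisher",
    "elim_enrichment",
    "enrich",
    "report",
    "infer_universe_size",
    "EnrichmentRun",
]


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, K, n).

    Exact integer summation of C(K, x) * C(N-K, n-x) over x >= k, divided
    by C(N, n) with a single correctly-rounded float conversion.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataValidationError(f"invalid hypergeometric parameters N={N} K={K} n={n}")
    if k <= max(0, n - (N - K)):
        return 1.0
    hi = min(K, n)
    if k > hi:
        return 0.0
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, hi + 1))
    return float(Fraction(num, comb(N, n)))


def expected_count(n: int, K: int, N: int) -> float:
    """Hypergeometric mean n*K/N: study-set genes expected on the term by chance."""
    if N <= 0:
        raise DataValidationError("universe size must be positive")
    return n * K / N


def _study_in_universe(study, annotations: AnnotationMap) -> tuple[set[str], int]:
    study = set(study)
    universe = annotations.universe
    kept = study & universe
    return kept, len(study - universe)


def classic_fisher(
    term: str, study, annotations: AnnotationMap
) -> tuple[int, int, float, float]:
    """(k, K, expected, p) for one term; terms with K = 0 are undefined."""
    K = annotations.count(term)
    if K == 0:
        raise DataValidationError(f"term {term!r} annotates no genes in the universe")
    kept, _ = _study_in_universe(study, annotations)
    n = len(kept)
    k = len(annotations.genes_by_term[term] & kept)
    N = annotations.n_universe
    return k, K, expected_count(n, K, N), hypergeom_sf(k, N, K, n)


def elim_enrichment(
    graph: OntologyGraph,
    annotations: AnnotationMap,
    study,
    cutoff: float = 0.01,
) -> dict[str, float]:
    """Per-term decorrelated p-values via the elim procedure.

    Terms are processed children-before-parents (decreasing longest-path
    depth, ties in stable lexicographic id order). Each term's Fisher test
    drops genes already eliminated at that term; a term falling below
    ``cutoff`` marks its annotated genes eliminated for all its ancestors.
    The universe N and study size n stay fixed throughout.
    """
    if not (0 < cutoff < 1):
        raise DataValidationError("elim cutoff must lie in (0, 1)")
    kept, _ = _study_in_universe(study, annotations)
    n = len(kept)
    N = annotations.n_universe
    depth = graph.depths()
    order = sorted(
        (t for t in graph.terms if annotations.count(t) > 0),
        key=lambda t: (-depth[t], t),
    )
    eliminated: dict[str, set[str]] = {}
    out: dict[str, float] = {}
    for term in order:
        genes = annotations.genes_by_term[term]
        elim = eliminated.get(term)
        usable = genes - elim if elim else genes
        K = len(usable)
        k = len(usable & kept)
        p = 1.0 if K == 0 else hypergeom_sf(k, N, K, n)
        out[term] = p
        if p < cutoff:
            for ancestor in graph.ancestors(term):
                eliminated.setdefault(ancestor, set()).update(genes)
    return out


@dataclass
class EnrichmentRun:
    """Full per-term enrichment table plus run bookkeeping."""

    table: pd.DataFrame  # index term; name, K, k, expected, p_classic, p_elim
    study_size: int
    n_universe: int
    dropped_from_study: int
    cutoff: float

    def reported(self, min_significant_genes: int = 10) -> pd.DataFrame:
        return report(self.table, min_significant_genes)


def enrich(
    graph: OntologyGraph,
    annotations: AnnotationMap,
    study,
    cutoff: float = 0.01,
) -> EnrichmentRun:
    """Classic and elim enrichment over every annotated term."""
    kept, dropped = _study_in_universe(study, annotations)
    n = len(kept)
    N = annotations.n_universe
    p_elim = elim_enrichment(graph, annotations, kept, cutoff=cutoff)
    rows = []
    for term in graph.terms:
        K = annotations.count(term)
        if K == 0:
            continue
        k = len(annotations.genes_by_term[term] & kept)
        rows.append(
            {
                "term": term,
                "name": graph.name(term),
                "K": K,
                "k": k,
                "expected": expected_count(n, K, N),
                "p_classic": hypergeom_sf(k, N, K, n),
                "p_elim": p_elim[term],
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return EnrichmentRun(
        table=table,
        study_size=n,
        n_universe=N,
        dropped_from_study=dropped,
        cutoff=cutoff,
    )


def report(table: pd.DataFrame, min_significant_genes: int = 10) -> pd.DataFrame:
    """Reporting filter: keep terms with k strictly above the floor, sort by p_elim."""
    kept = table[table["k"] > min_significant_genes]
    return kept.sort_values(["p_elim", "p_classic"], kind="mergesort")


def infer_universe_size(n: int, background_counts, expecteds) -> int:
    """Integer universe size N minimizing sum((n*K/N - e)^2) over rows.

    Solves the continuous least-squares optimum 1/N = sum(e*nK)/sum((nK)^2)
    and refines over nearby integers.
    """
    nK = np.asarray([n * K for K in background_counts], dtype=float)
    e = np.asarray(expecteds, dtype=float)
    if nK.size == 0 or nK.size != e.size:
        raise DataValidationError("need matching non-empty K and Expected vectors")
    n_cont = (nK**2).sum() / (e * nK).sum()
    candidates = range(max(1, int(n_cont) - 5), int(n_cont) + 6)
    return min(candidates, key=lambda N: float(((nK / N - e) ** 2).sum()))
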