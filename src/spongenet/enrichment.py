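"""Over-representation analysis (ORA) of gene sets against annotation terms.

For a query of ``n`` genes drawn from a universe of ``N``, a term with ``K``
annotated members and ``k`` of them in the query is scored by the upper-tail
hypergeometric probability P(X >= k).  Benjamini-Hochberg adjustment is
applied within each namespace (BP/MF/CC/pathway separately), mirroring the
per-panel top-10 reporting convention.  The universe defaults to the union
of all annotation-set members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records import AnnotationSet, Namespace

__all__ = ["EnrichmentResult", "hypergeom_test", "bh_adjust", "run_ora"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: Namespace
    k_overlap: int
    n_query: int
    K_term: int
    N_universe: int
    p_value: float
    p_adjusted: float
    overlap_ids: frozenset[str]


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` query genes hit a term of size ``K``, with ``n`` query genes drawn
    from a universe of ``N``.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: Iterable[str],
    sets: Sequence[AnnotationSet],
    universe: Iterable[str] | None = None,
    top: int | None = 10,
    keep_zero_overlap: bool = False,
) -> list[EnrichmentResult]:
    """Rank annotation terms by over-representation in the query gene set.

    Query genes outside the universe are dropped with a warning.  BH
    adjustment runs across all tested terms within each namespace; results
    are sorted by p-value ascending and truncated to ``top`` per namespace
    (``top=None`` returns everything).
    """
    universe_set = set(universe) if universe is not None else set().union(
        *(s.members for s in sets)
    ) if sets else set()
    query_set = set(query)
    outside = query_set - universe_set
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe were dropped")
        query_set -= outside
    n, N = len(query_set), len(universe_set)

    by_namespace: dict[Namespace, list[tuple[AnnotationSet, frozenset[str], float]]] = {}
    for annotation in sets:
        members = annotation.members & universe_set
        overlap = frozenset(query_set & members)
        if not overlap and not keep_zero_overlap:
            continue
        p = hypergeom_test(len(overlap), n, len(members), N) if members else 1.0
        by_namespace.setdefault(annotation.namespace, []).append((annotation, overlap, p))

    results: list[EnrichmentResult] = []
    for namespace, tested in by_namespace.items():
        adjusted = bh_adjust([p for _, _, p in tested])
        ranked = sorted(
            (
                EnrichmentResult(
                    term_id=a.term_id,
                    term_name=a.term_name,
                    namespace=namespace,
                    k_overlap=len(overlap),
                    n_query=n,
                    K_term=len(a.members & universe_set),
                    N_universe=N,
                    p_value=p,
                    p_adjusted=float(q),
                    overlap_ids=overlap,
                )
                for (a, overlap, p), q in zip(tested, adjusted)
            ),
            key=lambda r: (r.p_value, r.term_id),
        )
        results.extend(ranked[:top] if top is not None else ranked)
    results.sort(key=lambda r: (r.namespace.value, r.p_value, r.term_id))
    return results
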