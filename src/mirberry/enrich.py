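"""GO-term enrichment of miRNA target genes.

Each GO term seen in the target set is tested with a hypergeometric upper
tail over term-assignment counts: N assignments in the background
namespace, m of them to the term, n assignments among target genes, k of
those to the term.  P-values are Benjamini-Hochberg adjusted per namespace
(biological process and molecular function are tested separately by
default) and a term is called enriched when its adjusted p falls below
alpha = 0.05.

A ``paper_literal`` mode is available that replaces the upper tail with
``1 - pmf(k)``; it exists purely so the two definitions can be compared
side by side and is not a valid tail probability.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_pmf",
    "enrichment_pvalue",
    "bh_adjust",
    "enrich",
]


def _check_bounds(k: int, n: int, m: int, N: int) -> None:
    if not (0 <= m <= N and 0 <= n <= N and 0 <= k <= min(m, n)):
        raise ValueError(
            f"hypergeometric bounds violated: k={k}, n={n}, m={m}, N={N}"
        )


def hypergeom_pmf(k: int, n: int, m: int, N: int) -> float:
    """P(X = k) drawing n from N with m marked: C(m,k) C(N-m,n-k) / C(N,n)."""
    _check_bounds(k, n, m, N)
    return float(stats.hypergeom.pmf(k, N, m, n))


def enrichment_pvalue(
    k: int, n: int, m: int, N: int, paper_literal: bool = False
) -> float:
    """Upper-tail P(X >= k) of the hypergeometric distribution.

    ``paper_literal=True`` instead returns 1 - pmf(k), for auditing only.
    """
    _check_bounds(k, n, m, N)
    if paper_literal:
        return 1.0 - hypergeom_pmf(k, n, m, N)
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adjusted_(r) = min_{j >= r} p_(j) * d / j, capped at 1, where d is the
    number of tests and r the ascending rank.
    """
    d = len(pvalues)
    if d == 0:
        return []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
    order = sorted(range(d), key=lambda i: pvalues[i])
    adjusted = [0.0] * d
    running = 1.0
    for rank in range(d, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * d / rank)
        adjusted[i] = running
    return adjusted


@dataclass(frozen=True)
class EnrichmentResult:
    go_id: str
    namespace: str
    k: int
    m: int
    n: int
    N: int
    pvalue: float
    adjusted_pvalue: float
    enriched: bool


def enrich(
    target_genes: Iterable[str],
    go_table: Sequence[tuple[str, str]],
    go_namespaces: Mapping[str, str],
    alpha: float = 0.05,
    joint_namespaces: bool = False,
    paper_literal: bool = False,
) -> list[EnrichmentResult]:
    """Test every GO term of the target set for enrichment.

    ``go_table`` holds (gene id, GO id) assignment rows for the whole
    background; ``go_namespaces`` maps each GO id to its namespace.  Target
    genes missing from the table are logged and skipped.  Results are
    sorted by adjusted p-value, then GO id.
    """
    targets = set(target_genes)
    annotated_genes = {gene for gene, _ in go_table}
    missing = targets - annotated_genes
    if missing:
        logger.warning(
            "%d target gene(s) missing from the GO table; skipped", len(missing)
        )
    by_ns: dict[str, dict[str, Counter]] = {}
    for gene, go_id in go_table:
        ns = go_namespaces.get(go_id)
        if ns is None:
            raise ValueError(f"GO id {go_id} has no namespace assignment")
        slot = by_ns.setdefault(ns, {"bg": Counter(), "tg": Counter()})
        slot["bg"][go_id] += 1
        if gene in targets:
            slot["tg"][go_id] += 1
    if joint_namespaces:
        merged = {"bg": Counter(), "tg": Counter()}
        for slot in by_ns.values():
            merged["bg"].update(slot["bg"])
            merged["tg"].update(slot["tg"])
        by_ns = {"all": merged}

    results: list[EnrichmentResult] = []
    for ns in sorted(by_ns):
        bg, tg = by_ns[ns]["bg"], by_ns[ns]["tg"]
        N = sum(bg.values())
        n = sum(tg.values())
        terms = sorted(tg)  # d = number of distinct terms in the target set
        if not terms:
            continue
        pvals = [
            enrichment_pvalue(tg[t], n, bg[t], N, paper_literal) for t in terms
        ]
        adjusted = bh_adjust(pvals)
        for t, p, ap in zip(terms, pvals, adjusted):
            results.append(
                EnrichmentResult(
                    go_id=t,
                    namespace=ns if not joint_namespaces else go_namespaces[t],
                    k=tg[t],
                    m=bg[t],
                    n=n,
                    N=N,
                    pvalue=p,
                    adjusted_pvalue=ap,
                    enriched=ap < alpha,
                )
            )
    results.sort(key=lambda r: (r.adjusted_pvalue, r.go_id))
    return results
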