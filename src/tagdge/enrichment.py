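"""Hypergeometric enrichment of GO terms and KEGG pathways among DEGs.

For a namespace the universe N is every gene carrying at least one
annotation in that namespace, n the DEGs among them, M the genes in one
term and m the DEGs in that term.  The enrichment p-value is the exact
upper tail

    P(X >= m) = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

with the observed m included.  Q-values are Benjamini-Hochberg across the
terms of one namespace.  Following the two different gates used in
practice, GO terms are flagged on raw p <= p_max and KEGG pathways on
q <= q_max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .diffexpr import bh_fdr
from .io import VALID_NAMESPACES, TermAssignment

log = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "hypergeom_upper_tail", "enrich_terms"]


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-term contingency, enrichment p-value, BH q-value and verdict."""

    term_id: str
    namespace: str
    term_name: str
    m: int  # DEGs in the term
    n: int  # DEGs with any annotation in the namespace
    M: int  # annotated genes in the term
    N: int  # genes with any annotation in the namespace
    p_value: float
    q_value: float
    enriched: bool


def hypergeom_upper_tail(m: int, n: int, M: int, N: int) -> float:
    """Exact P(X >= m) for X ~ Hypergeometric(N, M, n).

    Drawing n genes (the DEGs) without replacement from a universe of N
    annotated genes of which M belong to the term, the probability of
    seeing m or more term members.  P(X >= 0) is 1 by convention.
    """
    if not (0 <= M <= N):
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"need 0 <= m <= min(n, M), got m={m}, n={n}, M={M}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich_terms(
    deg_ids: Iterable[str],
    assignments: Sequence[TermAssignment],
    namespace: str,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every term of one namespace for DEG over-representation.

    The universe is built from the assignment table alone, so it may
    legitimately differ between GO and KEGG.  Terms with no DEG member are
    kept with p = 1, never dropped.  Output is ordered by ascending
    p-value, ties broken by term_id for determinism.
    """
    if namespace not in VALID_NAMESPACES:
        raise ValueError(f"namespace must be one of {VALID_NAMESPACES}, got {namespace!r}")
    ns_assignments = [a for a in assignments if a.namespace == namespace]
    if not ns_assignments:
        raise ValueError(f"no assignments in namespace {namespace}")

    universe: set[str] = {a.gene_id for a in ns_assignments}
    deg_set = set(deg_ids) & universe
    if not deg_set:
        log.warning("no DEG carries a %s annotation; all m = 0", namespace)

    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for a in ns_assignments:
        members.setdefault(a.term_id, set()).add(a.gene_id)
        names.setdefault(a.term_id, a.term_name)

    N = len(universe)
    n = len(deg_set)
    term_ids = sorted(members)
    p_values = [
        hypergeom_upper_tail(len(members[t] & deg_set), n, len(members[t]), N)
        for t in term_ids
    ]
    q_values = bh_fdr(p_values)

    records = []
    for t, p, q in zip(term_ids, p_values, q_values):
        m = len(members[t] & deg_set)
        enriched = p <= p_max if namespace == "GO" else q <= q_max
        records.append(
            EnrichmentRecord(t, namespace, names[t], m, n, len(members[t]), N,
                             float(p), float(q), bool(enriched))
        )
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records
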