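"""Hypergeometric pathway enrichment and the enriched-pathway network.

A query gene set (the genes of one or more diseases, or the union of target
genes of a disease's miRNAs) is tested against every pathway in a
:class:`~comorbnet.datatypes.GeneSetCollection`. For a background universe of
N genes containing a pathway of K genes, a query of n genes overlapping the
pathway in k genes is scored with the upper-tail hypergeometric probability
P(X >= k) — the chance of at least k hits when n genes are drawn without
replacement from the universe.

Default significance thresholds: 0.05 for gene-set queries and 0.001 for
miRNA-target queries (miRNA target lists are large, so a stricter cut is the
customary choice). Raw p-values are thresholded by default; an optional
Benjamini-Hochberg flag switches the flagging to FDR-adjusted q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats

from .datatypes import GeneSetCollection, MirnaTables
from .errors import DomainError, UnknownEntityError

logger = logging.getLogger("comorbnet")

DEFAULT_ALPHA_GENE = 0.05
DEFAULT_ALPHA_MIRNA = 0.001

__all__ = [
    "DEFAULT_ALPHA_GENE",
    "DEFAULT_ALPHA_MIRNA",
    "EnrichmentRow",
    "hypergeom_upper_tail",
    "enrich",
    "enrich_mirna",
    "build_pathway_network",
    "rows_to_dataframe",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested pathway: overlap k, pathway size K, query size n, universe
    size N (all within the universe), the upper-tail p-value, and the overlap."""

    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    overlap_genes: tuple[str, ...]
    enriched: bool
    q_value: float | None = None


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed with the survival function of :class:`scipy.stats.hypergeom`
    (numerically stable for large parameters); the parameter box is validated
    first and violations raise :class:`DomainError`.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise DomainError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K <= N and 0 <= n <= N, got K={K}, n={n}, N={N}")
    if not (max(0, n + K - N) <= k <= min(K, n)):
        raise DomainError(
            f"k={k} outside its support [{max(0, n + K - N)}, {min(K, n)}] for K={K}, n={n}, N={N}"
        )
    if k == max(0, n + K - N):
        return 1.0  # certain event; avoids sf round-off at the support edge
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes: Iterable[str],
    pathways: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA_GENE,
    fdr: bool = False,
) -> list[EnrichmentRow]:
    """Test ``query_genes`` against every pathway; rows (k >= 1) sorted by (p, set_id).

    Query genes outside the universe are dropped (count logged); enrichment
    results are therefore invariant to out-of-universe query genes. Rows are
    flagged enriched when p <= alpha (or q <= alpha with ``fdr=True``).
    """
    if not 0.0 < alpha <= 1.0:
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    universe_set = frozenset(universe) if universe is not None else pathways.universe
    if not universe_set:
        raise DomainError("enrichment universe is empty")
    query = frozenset(query_genes)
    effective = query & universe_set
    if len(effective) < len(query):
        logger.info("dropped %d query gene(s) outside the universe", len(query) - len(effective))
    if not effective:
        logger.warning("empty effective query: no query gene lies in the universe")
        return []
    n, N = len(effective), len(universe_set)
    rows = []
    for s in pathways:
        members = s.genes & universe_set
        overlap = effective & members
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(
            EnrichmentRow(
                set_id=s.set_id,
                description=s.description,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                overlap_genes=tuple(sorted(overlap)),
                enriched=p <= alpha,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    if fdr and rows:
        qvals = stats.false_discovery_control([r.p_value for r in rows], method="bh")
        rows = [replace(r, q_value=float(q), enriched=q <= alpha) for r, q in zip(rows, qvals)]
    return rows


def enrich_mirna(
    disease: str,
    mir: MirnaTables,
    pathways: GeneSetCollection,
    universe: Iterable[str] | None = None,
    alpha: float = DEFAULT_ALPHA_MIRNA,
    fdr: bool = False,
) -> list[EnrichmentRow]:
    """Enrichment of the union of target genes of the disease's miRNAs."""
    targets = mir.targets_of_disease(disease)  # raises for a disease with no miRNAs
    if not targets:
        raise UnknownEntityError(f"disease {disease!r}: no miRNA has known targets")
    return enrich(targets, pathways, universe=universe, alpha=alpha, fdr=fdr)


def build_pathway_network(rows: Sequence[EnrichmentRow], pathways: GeneSetCollection) -> nx.Graph:
    """Pathway-overlap network: one node per row, an edge wherever two pathways
    share members, weighted by the shared count (edge thickness in the
    original visualisation)."""
    g = nx.Graph()
    ids = [r.set_id for r in rows]
    for r in rows:
        g.add_node(r.set_id, member_count=len(pathways.genes_of(r.set_id)), p_value=r.p_value)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = pathways.genes_of(a) & pathways.genes_of(b)
            if shared:
                g.add_edge(a, b, weight=len(shared), shared=tuple(sorted(shared)))
    return g


def rows_to_dataframe(rows: Sequence[EnrichmentRow]):
    """Tabular view of enrichment results (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": "" if r.q_value is None else r.q_value,
                "enriched": r.enriched,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in rows
        ],
        columns=["set_id", "description", "k", "K", "n", "N", "p_value", "q_value", "enriched", "overlap_genes"],
    )
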