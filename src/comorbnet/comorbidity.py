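"""Pairwise disease-comorbidity scores.

Four scores, each predicting the risk that two diseases co-occur from the
molecular data alone:

``shared_genes``
    100 * |G_i ∩ G_j| / min(|G_i|, |G_j|), where G_i is the gene set of
    disease i. Higher = riskier.
``uniqueness``
    Sum over shared genes g of Uniqueness(g) = 1 - sqrt(D_g / D_T), where
    D_g is the number of diseases associated with g and D_T the total number
    of diseases in the dataset. Genes specific to few diseases weigh more.
    Higher = riskier. Reported unnormalised (no division by the number of
    shared genes), so the score grows with overlap size.
``ontology``
    100 * Jaccard index of the two diseases' distinct GO biological-process /
    molecular-function term sets (union of terms over each disease's genes).
    Higher = riskier.
``network_separation``
    s_ij = D_ij - (D_ii + D_jj) / 2 on the unweighted interactome, where
    D_ii is the mean over genes of disease i of the shortest distance to the
    nearest *other* gene of disease i (0 for a single-gene disease), and
    D_ij the mean over all genes of both diseases of the shortest distance
    to the nearest gene of the other disease (a shared gene contributes 0).
    Lower = riskier: overlapping network neighbourhoods give s <= 0.

Degenerate interactome cases (genes absent from the graph, unreachable
components) are handled by exclusion rather than infinity substitutes; a
disease with no usable network gene yields a missing (NaN) score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneDiseaseTable, GeneSetCollection, Interactome
from .errors import ConfigurationError, UndefinedScoreError

logger = logging.getLogger("comorbnet")

Method = Literal["shared_genes", "uniqueness", "ontology", "network_separation"]
METHODS: tuple[Method, ...] = ("shared_genes", "uniqueness", "ontology", "network_separation")

__all__ = [
    "METHODS",
    "score_shared_genes",
    "gene_uniqueness",
    "score_uniqueness",
    "score_ontology",
    "score_network_separation",
    "ComorbidityMatrix",
    "comorbidity_matrix",
]


def score_shared_genes(gd: GeneDiseaseTable, d_i: str, d_j: str) -> float:
    """Shared-gene score in [0, 100]; 100 when the smaller gene set is contained in the larger."""
    g_i, g_j = gd.genes_of(d_i), gd.genes_of(d_j)
    return 100.0 * len(g_i & g_j) / min(len(g_i), len(g_j))


def gene_uniqueness(gd: GeneDiseaseTable, gene: str) -> float:
    """1 - sqrt(D_g / D_T): 0 for a gene associated with every disease, -> 1 for a specific one."""
    return 1.0 - math.sqrt(gd.n_diseases_of_gene(gene) / gd.n_diseases)


def score_uniqueness(gd: GeneDiseaseTable, d_i: str, d_j: str) -> float:
    """Sum of gene uniqueness over the shared genes of the pair (>= 0)."""
    shared = gd.genes_of(d_i) & gd.genes_of(d_j)
    return sum(gene_uniqueness(gd, g) for g in shared)


def score_ontology(gd: GeneDiseaseTable, ann: GeneSetCollection, d_i: str, d_j: str) -> float:
    """100 * Jaccard index of the diseases' GO term sets (BP + MF).

    Raises :class:`UndefinedScoreError` when neither disease has any
    annotated gene — an empty union makes the Jaccard index undefined, and
    silently reporting 0 would fake evidence of non-comorbidity.
    """
    terms_i = ann.terms_for_genes(gd.genes_of(d_i))
    terms_j = ann.terms_for_genes(gd.genes_of(d_j))
    union = terms_i | terms_j
    if not union:
        raise UndefinedScoreError(
            f"ontology score undefined for ({d_i}, {d_j}): no annotated genes in either disease"
        )
    return 100.0 * len(terms_i & terms_j) / len(union)


# ---------------------------------------------------------------------------
# network separation

class _DistanceCache:
    """Per-source BFS shortest-path lengths over an unweighted graph, computed lazily."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._lengths: dict[str, dict[str, int]] = {}

    def lengths_from(self, gene: str) -> dict[str, int]:
        if gene not in self._lengths:
            self._lengths[gene] = nx.single_source_shortest_path_length(self.graph, gene)
        return self._lengths[gene]


def _network_genes(gd: GeneDiseaseTable, net: Interactome, disease: str) -> list[str]:
    genes = sorted(gd.genes_of(disease))
    present = [g for g in genes if g in net.graph]
    if len(present) < len(genes):
        logger.info(
            "disease %s: %d of %d genes absent from the interactome, dropped",
            disease, len(genes) - len(present), len(genes),
        )
    return present


def _mean_within(genes: Sequence[str], cache: _DistanceCache) -> float:
    """Mean over genes of the distance to the nearest *different* gene of the same set.

    A single-gene set has no internal spread: 0. Genes with no reachable
    counterpart are excluded from the mean; if none has one, the spread is 0.
    """
    if len(genes) <= 1:
        return 0.0
    vals = []
    for g in genes:
        lengths = cache.lengths_from(g)
        best = min((lengths[h] for h in genes if h != g and h in lengths), default=None)
        if best is not None:
            vals.append(best)
    return float(np.mean(vals)) if vals else 0.0


def _mean_cross(genes_i: Sequence[str], genes_j: Sequence[str], cache: _DistanceCache) -> float | None:
    """Mean over all genes of both diseases of the distance to the nearest gene
    of the other disease; a gene shared by both contributes 0. ``None`` when no
    gene has a reachable counterpart."""
    vals = []
    for src, dst in ((genes_i, genes_j), (genes_j, genes_i)):
        dst_set = set(dst)
        for g in src:
            if g in dst_set:
                vals.append(0)
                continue
            lengths = cache.lengths_from(g)
            best = min((lengths[h] for h in dst if h in lengths), default=None)
            if best is not None:
                vals.append(best)
    return float(np.mean(vals)) if vals else None


def score_network_separation(
    gd: GeneDiseaseTable,
    net: Interactome,
    d_i: str,
    d_j: str,
    _cache: _DistanceCache | None = None,
) -> float:
    """Network separation s_ij = D_ij - (D_ii + D_jj)/2; NaN when undefined.

    Lower scores mean the two diseases' genes occupy overlapping interactome
    neighbourhoods, hence a higher comorbidity risk. Self-comparison gives
    s <= 0 for any disease with at least one network gene.
    """
    genes_i = _network_genes(gd, net, d_i)
    genes_j = _network_genes(gd, net, d_j)
    if not genes_i or not genes_j:
        logger.info("separation (%s, %s): a disease has no interactome gene -> missing", d_i, d_j)
        return math.nan
    cache = _cache if _cache is not None else _DistanceCache(net.graph)
    d_cross = _mean_cross(genes_i, genes_j, cache)
    if d_cross is None:
        logger.info("separation (%s, %s): no finite cross-distance -> missing", d_i, d_j)
        return math.nan
    d_ii = _mean_within(genes_i, cache)
    d_jj = _mean_within(genes_j, cache)
    return d_cross - (d_ii + d_jj) / 2.0


# ---------------------------------------------------------------------------
# matrix assembly

@dataclass
class ComorbidityMatrix:
    """Symmetric pairwise score matrix for one method over an ordered disease list.

    ``scores[i, j]`` is the score of (diseases[i], diseases[j]); NaN marks a
    missing network-separation score. ``shared_genes`` holds the per-pair
    shared-gene lists (sorted).
    """

    method: Method
    diseases: tuple[str, ...]
    scores: np.ndarray
    shared_genes: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    @property
    def risk_direction(self) -> str:
        return "lower_is_risk" if self.method == "network_separation" else "higher_is_risk"

    def score(self, d_i: str, d_j: str) -> float:
        i, j = self.diseases.index(d_i), self.diseases.index(d_j)
        return float(self.scores[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=list(self.diseases), columns=list(self.diseases))

    def to_long_dataframe(self) -> pd.DataFrame:
        """One row per unordered pair: disease_a, disease_b, score, shared genes."""
        rows = []
        for i, a in enumerate(self.diseases):
            for j in range(i + 1, len(self.diseases)):
                b = self.diseases[j]
                key = (a, b) if a < b else (b, a)
                shared = self.shared_genes.get(key, ())
                rows.append(
                    {
                        "disease_a": a,
                        "disease_b": b,
                        "method": self.method,
                        "score": self.scores[i, j],
                        "n_shared_genes": len(shared),
                        "shared_genes": ";".join(shared),
                    }
                )
        return pd.DataFrame(rows, columns=["disease_a", "disease_b", "method", "score", "n_shared_genes", "shared_genes"])


def comorbidity_matrix(
    gd: GeneDiseaseTable,
    method: Method,
    diseases: Iterable[str],
    ann: GeneSetCollection | None = None,
    net: Interactome | None = None,
) -> ComorbidityMatrix:
    """Full symmetric score matrix over ``diseases`` (order preserved)."""
    diseases = tuple(diseases)
    if len(diseases) < 2:
        raise ConfigurationError("comorbidity matrix needs at least 2 diseases")
    if method not in METHODS:
        raise ConfigurationError(f"unknown comorbidity method: {method!r}")
    if method == "ontology" and ann is None:
        raise ConfigurationError("method 'ontology' requires GO annotations")
    if method == "network_separation" and net is None:
        raise ConfigurationError("method 'network_separation' requires an interactome")
    for d in diseases:
        gd.genes_of(d)  # raises UnknownEntityError early

    n = len(diseases)
    scores = np.zeros((n, n))
    shared: dict[tuple[str, str], tuple[str, ...]] = {}
    cache = _DistanceCache(net.graph) if net is not None else None
    for i in range(n):
        for j in range(i, n):
            d_i, d_j = diseases[i], diseases[j]
            if method == "shared_genes":
                s = score_shared_genes(gd, d_i, d_j)
            elif method == "uniqueness":
                s = score_uniqueness(gd, d_i, d_j)
            elif method == "ontology":
                s = score_ontology(gd, ann, d_i, d_j)
            else:
                s = score_network_separation(gd, net, d_i, d_j, _cache=cache)
            scores[i, j] = scores[j, i] = s
            if i != j:
                key = (d_i, d_j) if d_i < d_j else (d_j, d_i)
                shared[key] = tuple(sorted(gd.genes_of(d_i) & gd.genes_of(d_j)))
    return ComorbidityMatrix(method=method, diseases=diseases, scores=scores, shared_genes=shared)
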