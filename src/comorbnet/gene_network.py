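"""Gene-interaction subnetworks, centralities and hub/bottleneck prioritisation.

The subnetwork for a set of enriched pathways is the interactome induced on
the union of their member genes (members missing from the interactome stay as
isolated nodes). Three unweighted topological centralities are computed per
gene:

* degree — number of interaction partners;
* closeness — harmonic closeness, the sum of reciprocal shortest-path
  distances to every other node (an unreachable node contributes 0, so the
  measure is well defined on disconnected subnetworks);
* betweenness — Brandes node betweenness, unnormalised, endpoints excluded,
  equal-length shortest paths split evenly.

Classification (strict inequalities; means and population standard
deviations taken over the table itself):

* hub: degree > mean_deg + 2*sd_deg  OR  closeness > mean_clo + 2*sd_clo;
* bottleneck: degree < mean_deg  AND  betweenness > mean_bet.

A degree-hub can never be a bottleneck (mean + 2 sd >= mean); a
closeness-hub that bridges communities can legitimately carry both flags.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection, Interactome
from .enrichment import EnrichmentRow
from .errors import ConfigurationError, DomainError, UnknownEntityError

logger = logging.getLogger("comorbnet")

__all__ = ["pathway_subgraph", "compute_centralities", "classify", "tissue_view"]

CENTRALITY_COLUMNS = ["gene", "degree", "closeness", "betweenness", "is_hub", "is_bottleneck"]


def pathway_subgraph(
    rows: Sequence[EnrichmentRow] | Iterable[str],
    pathways: GeneSetCollection,
    net: Interactome,
) -> Interactome:
    """Interactome induced on the union of member genes of the selected pathways.

    ``rows`` may be enrichment rows or bare set ids. Pathway members absent
    from the interactome are retained as isolated nodes so the gene inventory
    of the selected pathways is preserved.
    """
    ids = [r.set_id if isinstance(r, EnrichmentRow) else r for r in rows]
    if not ids:
        raise ConfigurationError("no pathways selected for the gene subnetwork")
    members: set[str] = set()
    for sid in ids:
        members |= pathways.genes_of(sid)
    sub = net.induced(members)
    if sub.graph.number_of_edges() == 0:
        logger.warning("pathway subnetwork has no interactions (%d isolated genes)", len(members))
    return sub


def compute_centralities(net: Interactome, classify_rows: bool = True) -> pd.DataFrame:
    """Per-gene degree / harmonic closeness / betweenness table, optionally classified.

    Deterministic: rows sorted by gene symbol. Requires >= 2 nodes (centrality
    over a single node is meaningless).
    """
    g = net.graph
    if g.number_of_nodes() < 2:
        raise DomainError("centrality table needs a graph with >= 2 nodes")
    closeness = nx.harmonic_centrality(g)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    genes = sorted(g.nodes)
    df = pd.DataFrame(
        {
            "gene": genes,
            "degree": [g.degree[x] for x in genes],
            "closeness": [closeness[x] for x in genes],
            "betweenness": [betweenness[x] for x in genes],
        }
    )
    return classify(df) if classify_rows else df


def classify(table: pd.DataFrame) -> pd.DataFrame:
    """Add is_hub / is_bottleneck flags to a centrality table.

    Thresholds are computed over the table's own rows with the population
    standard deviation (ddof=0); ties at exact threshold equality are not
    flagged.
    """
    if len(table) == 0:
        raise DomainError("cannot classify an empty centrality table")
    deg = table["degree"].to_numpy(dtype=float)
    clo = table["closeness"].to_numpy(dtype=float)
    bet = table["betweenness"].to_numpy(dtype=float)
    hub = (deg > deg.mean() + 2 * deg.std()) | (clo > clo.mean() + 2 * clo.std())
    bottleneck = (deg < deg.mean()) & (bet > bet.mean())
    out = table.copy()
    out["is_hub"] = hub
    out["is_bottleneck"] = bottleneck
    return out


def tissue_view(net: Interactome, gene: str, tissue: str) -> Interactome:
    """Star subgraph of ``gene`` and its neighbours expressed in ``tissue``."""
    if net.node_tissues is None:
        raise ConfigurationError("tissue view requires gene->tissue annotations")
    if gene not in net.graph:
        raise UnknownEntityError(f"gene {gene!r} not in the network")
    keep = {gene} | {
        nb for nb in net.graph.neighbors(gene) if tissue in net.node_tissues.get(nb, frozenset())
    }
    star = nx.Graph()
    star.add_nodes_from(keep)
    for nb in keep - {gene}:
        star.add_edge(gene, nb, **net.graph.edges[gene, nb])
    tissues = {g: t for g, t in net.node_tissues.items() if g in keep}
    return Interactome(graph=star, node_tissues=tissues)
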