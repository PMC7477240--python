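"""Core in-memory containers.

The toolkit revolves around four containers:

* :class:`GeneDiseaseTable` — the bipartite disease <-> gene association set.
* :class:`Interactome` — an undirected simple graph over gene symbols
  (a :class:`networkx.Graph` plus optional tissue labels per node).
* :class:`GeneSetCollection` — named gene sets: pathways, or GO terms of the
  biological-process / molecular-function namespaces.
* :class:`MirnaTables` — disease -> miRNA and miRNA -> target-gene maps.

Gene, disease, term and miRNA identifiers are opaque case-sensitive strings;
no symbol aliasing or ID mapping is performed anywhere.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import FormatError, UnknownEntityError

logger = logging.getLogger("comorbnet")

__all__ = ["GeneDiseaseTable", "Interactome", "GeneSet", "GeneSetCollection", "MirnaTables"]


class GeneDiseaseTable:
    """A validated set of (disease_id, disease_name, gene) associations.

    Duplicate (disease, gene) pairs are collapsed on construction (the count
    is logged and kept in :attr:`n_duplicates_collapsed`). Row order never
    affects the stored value: two tables built from permutations of the same
    records compare equal.
    """

    def __init__(self, records: Iterable[tuple[str, str, str]]):
        genes_of: dict[str, set[str]] = defaultdict(set)
        diseases_of: dict[str, set[str]] = defaultdict(set)
        names: dict[str, str] = {}
        seen: set[tuple[str, str]] = set()
        n_dup = 0
        for disease_id, disease_name, gene in records:
            if not disease_id or not gene:
                raise FormatError("empty disease_id or gene in association record")
            key = (disease_id, gene)
            if key in seen:
                n_dup += 1
            seen.add(key)
            genes_of[disease_id].add(gene)
            diseases_of[gene].add(disease_id)
            # order-invariant tie-break for conflicting names
            if disease_id not in names or disease_name < names[disease_id]:
                names[disease_id] = disease_name
        if not seen:
            raise FormatError("gene-disease table contains no associations")
        if n_dup:
            logger.info("collapsed %d duplicate (disease, gene) pairs", n_dup)
        self._genes_of = {d: frozenset(g) for d, g in genes_of.items()}
        self._diseases_of = {g: frozenset(d) for g, d in diseases_of.items()}
        self._names = names
        self.n_duplicates_collapsed = n_dup

    # -- views -------------------------------------------------------------
    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self._genes_of))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self._diseases_of))

    @property
    def n_diseases(self) -> int:
        """Total number of diseases in the dataset (the D^T of the uniqueness score)."""
        return len(self._genes_of)

    def disease_name(self, disease_id: str) -> str:
        self._check_disease(disease_id)
        return self._names[disease_id]

    def genes_of(self, disease_id: str) -> frozenset[str]:
        self._check_disease(disease_id)
        return self._genes_of[disease_id]

    def diseases_of(self, gene: str) -> frozenset[str]:
        if gene not in self._diseases_of:
            raise UnknownEntityError(f"unknown gene: {gene!r}")
        return self._diseases_of[gene]

    def n_diseases_of_gene(self, gene: str) -> int:
        return len(self.diseases_of(gene))

    def _check_disease(self, disease_id: str) -> None:
        if disease_id not in self._genes_of:
            raise UnknownEntityError(f"unknown disease_id: {disease_id!r}")

    def records(self) -> Iterator[tuple[str, str, str]]:
        """All associations in canonical (disease_id, gene) sort order."""
        for d in self.diseases:
            for g in sorted(self._genes_of[d]):
                yield d, self._names[d], g

    def __len__(self) -> int:
        return sum(len(g) for g in self._genes_of.values())

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self._genes_of

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneDiseaseTable):
            return NotImplemented
        return self._genes_of == other._genes_of and self._names == other._names

    def __repr__(self) -> str:
        return (
            f"<GeneDiseaseTable: {self.n_diseases} diseases, "
            f"{len(self._diseases_of)} genes, {len(self)} associations>"
        )


@dataclass
class Interactome:
    """Undirected simple protein-protein interaction graph over gene symbols.

    Edges may carry a confidence ``score`` in [0, 1] (used only for filtering
    at load time; all distance and centrality computations are unweighted).
    ``node_tissues`` optionally maps genes to the tissues they are expressed in.
    """

    graph: nx.Graph
    node_tissues: dict[str, frozenset[str]] | None = None
    n_self_loops_dropped: int = 0

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float | None]],
        nodes: Iterable[str] = (),
        min_score: float = 0.0,
        node_tissues: Mapping[str, Iterable[str]] | None = None,
    ) -> "Interactome":
        """Build from (a, b, score) triples.

        Self-loops are dropped (counted), reciprocal duplicates merged keeping
        the maximum score, and edges scoring below ``min_score`` removed.
        """
        if not 0.0 <= min_score <= 1.0:
            raise FormatError(f"min_score must be in [0, 1], got {min_score}")
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        missing = object()  # sentinel: "edge not seen yet"
        best: dict[tuple[str, str], float | None] = {}
        for a, b, score in edges:
            if score is not None and not 0.0 <= score <= 1.0:
                raise FormatError(f"edge score outside [0, 1]: {a}-{b} = {score}")
            g.add_node(a)
            g.add_node(b)
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            prev = best.get(key, missing)
            if prev is missing:
                best[key] = score
            elif score is not None and (prev is None or score > prev):
                best[key] = score
        if n_loops:
            logger.info("dropped %d self-loop edge(s)", n_loops)
        for (a, b), score in best.items():
            eff = score if score is not None else 1.0
            if eff >= min_score:
                if score is None:
                    g.add_edge(a, b)
                else:
                    g.add_edge(a, b, score=score)
        tissues = None
        if node_tissues is not None:
            tissues = {g_: frozenset(t) for g_, t in node_tissues.items()}
        return cls(graph=g, node_tissues=tissues, n_self_loops_dropped=n_loops)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def induced(self, genes: Iterable[str]) -> "Interactome":
        """Induced subgraph on ``genes``; genes absent from the graph become isolated nodes."""
        genes = set(genes)
        sub = nx.Graph()
        sub.add_nodes_from(genes)
        present = genes & set(self.graph.nodes)
        sub.add_edges_from(self.graph.subgraph(present).edges(data=True))
        tissues = None
        if self.node_tissues is not None:
            tissues = {g: t for g, t in self.node_tissues.items() if g in genes}
        return Interactome(graph=sub, node_tissues=tissues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return (
            set(self.graph.nodes) == set(other.graph.nodes)
            and self.edges == other.edges
            and all(
                self.graph.edges[e].get("score") == other.graph.edges[e].get("score")
                for e in self.graph.edges
            )
            and (self.node_tissues or {}) == (other.node_tissues or {})
        )

    def __repr__(self) -> str:
        return f"<Interactome: {self.graph.number_of_nodes()} nodes, {self.graph.number_of_edges()} edges>"


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    genes: frozenset[str]


class GeneSetCollection:
    """Named, non-empty gene sets with a background universe.

    The universe defaults to the union of all member genes and may be
    overridden (the enrichment background is a modelling choice, not a
    property of the file).
    """

    def __init__(
        self,
        sets: Mapping[str, tuple[str, Iterable[str]]] | Iterable[GeneSet],
        universe: Iterable[str] | None = None,
    ):
        if isinstance(sets, Mapping):
            items = [GeneSet(sid, desc, frozenset(genes)) for sid, (desc, genes) in sets.items()]
        else:
            items = list(sets)
        self._sets: dict[str, GeneSet] = {}
        for s in items:
            if not s.genes:
                raise FormatError(f"gene set {s.set_id!r} is empty")
            if s.set_id in self._sets:
                raise FormatError(f"duplicate set id: {s.set_id!r}")
            self._sets[s.set_id] = s
        member_union = frozenset().union(*(s.genes for s in self._sets.values())) if self._sets else frozenset()
        if universe is None:
            self._universe = member_union
        else:
            self._universe = frozenset(universe)
            if not member_union <= self._universe:
                raise FormatError("explicit universe does not contain all member genes")
        self._inverted: dict[str, frozenset[str]] | None = None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._sets))

    @property
    def universe(self) -> frozenset[str]:
        return self._universe

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        for sid in self.ids:
            yield self._sets[sid]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        if set_id not in self._sets:
            raise UnknownEntityError(f"unknown set id: {set_id!r}")
        return self._sets[set_id]

    def genes_of(self, set_id: str) -> frozenset[str]:
        return self[set_id].genes

    def sets_of_gene(self, gene: str) -> frozenset[str]:
        """Ids of the sets containing ``gene`` (empty for an unknown gene)."""
        if self._inverted is None:
            inv: dict[str, set[str]] = defaultdict(set)
            for s in self._sets.values():
                for g in s.genes:
                    inv[g].add(s.set_id)
            self._inverted = {g: frozenset(v) for g, v in inv.items()}
        return self._inverted.get(gene, frozenset())

    def terms_for_genes(self, genes: Iterable[str]) -> frozenset[str]:
        """Union of set ids over ``genes`` — the distinct annotation terms of a gene list."""
        out: set[str] = set()
        for g in genes:
            out |= self.sets_of_gene(g)
        return frozenset(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets and self._universe == other._universe

    def __repr__(self) -> str:
        return f"<GeneSetCollection: {len(self)} sets, universe of {len(self._universe)} genes>"


@dataclass
class MirnaTables:
    """Disease -> miRNA associations and miRNA -> target-gene sets.

    miRNAs referenced by a disease but missing from the target table are kept
    (the association is real) but flagged in :attr:`missing_mirnas` and logged;
    they contribute no targets downstream.
    """

    disease_mirnas: dict[str, frozenset[str]]
    mirna_targets: dict[str, frozenset[str]]
    missing_mirnas: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        referenced = set().union(*self.disease_mirnas.values()) if self.disease_mirnas else set()
        missing = frozenset(referenced - set(self.mirna_targets))
        if missing:
            logger.warning(
                "%d miRNA(s) referenced by diseases have no target entry: %s",
                len(missing),
                ", ".join(sorted(missing)[:5]),
            )
        object.__setattr__(self, "missing_mirnas", missing)

    def mirnas_of(self, disease_id: str) -> frozenset[str]:
        if disease_id not in self.disease_mirnas:
            raise UnknownEntityError(f"disease {disease_id!r} has no associated miRNAs")
        return self.disease_mirnas[disease_id]

    def targets_of_disease(self, disease_id: str) -> frozenset[str]:
        """Union of target genes over the disease's miRNAs (missing miRNAs skipped)."""
        out: set[str] = set()
        for m in self.mirnas_of(disease_id):
            out |= self.mirna_targets.get(m, frozenset())
        return frozenset(out)
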