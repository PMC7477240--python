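"""Disease-disease networks and multi-way Venn partitions.

A disease network over a selected disease list has one node per disease
(sized by its number of associated genes, or miRNAs) and an edge wherever
two diseases share at least one entity, weighted by the shared count.

The Venn partition of 2-6 labelled item sets assigns every item of the union
to exactly one exclusive region — the subset of labels whose sets contain it.
All 2^n - 1 regions are materialised (possibly empty) so downstream joins see
a fixed schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .datatypes import GeneDiseaseTable, GeneSetCollection, MirnaTables
from .errors import DomainError

__all__ = [
    "build_disease_network",
    "venn",
    "VennPartition",
    "disease_pathways",
    "disease_ontology_terms",
]


def _entity_sets(assoc: GeneDiseaseTable | MirnaTables, diseases: tuple[str, ...]):
    if isinstance(assoc, GeneDiseaseTable):
        return {d: assoc.genes_of(d) for d in diseases}
    return {d: assoc.mirnas_of(d) for d in diseases}


def build_disease_network(
    assoc: GeneDiseaseTable | MirnaTables,
    diseases: Iterable[str],
) -> nx.Graph:
    """Disease network over ``diseases``; entities are genes (GeneDiseaseTable)
    or miRNAs (MirnaTables). Edge attributes: ``weight`` and the sorted
    ``shared`` entity tuple."""
    diseases = tuple(diseases)
    if len(diseases) < 2:
        raise DomainError("disease network needs at least 2 diseases")
    sets = _entity_sets(assoc, diseases)
    g = nx.Graph()
    for d in diseases:
        g.add_node(d, size=len(sets[d]))
    for a, b in combinations(diseases, 2):
        shared = sets[a] & sets[b]
        if shared:
            g.add_edge(a, b, weight=len(shared), shared=tuple(sorted(shared)))
    return g


@dataclass(frozen=True)
class VennPartition:
    """Exclusive-region partition of up to six labelled sets.

    ``regions`` maps every non-empty subset of labels (a lexicographically
    sorted tuple) to the sorted items belonging to exactly those sets; the
    2^n - 1 keys are always present.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[str, ...], tuple[str, ...]]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {key: len(items) for key, items in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(items) for items in self.regions.values())


def venn(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition 2-6 labelled item sets into exclusive Venn regions."""
    labels = tuple(sorted(sets))
    if not 2 <= len(labels) <= 6:
        raise DomainError(f"venn analysis supports 2-6 sets, got {len(labels)}")
    frozen = {lab: frozenset(sets[lab]) for lab in labels}
    regions: dict[tuple[str, ...], list[str]] = {}
    for r in range(1, len(labels) + 1):
        for key in combinations(labels, r):  # labels sorted -> keys sorted
            regions[key] = []
    for item in sorted(set().union(*frozen.values())):
        key = tuple(lab for lab in labels if item in frozen[lab])
        regions[key].append(item)
    return VennPartition(labels=labels, regions={k: tuple(v) for k, v in regions.items()})


def disease_pathways(gd: GeneDiseaseTable, pathways: GeneSetCollection, disease: str) -> frozenset[str]:
    """Pathways of a disease = pathways containing >= 1 of its genes."""
    return pathways.terms_for_genes(gd.genes_of(disease))


def disease_ontology_terms(gd: GeneDiseaseTable, ann: GeneSetCollection, disease: str) -> frozenset[str]:
    """Distinct GO terms over the disease's genes (the sets the ontology score compares)."""
    return ann.terms_for_genes(gd.genes_of(disease))
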