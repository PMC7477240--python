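"""Seeded generator of complete synthetic universes.

One :class:`SimulationConfig` + seed deterministically produces a coherent
bundle — gene-disease table, interactome, pathway GMT, GO annotations, miRNA
tables and a tissue table — with *planted* structure that the analysis
modules should recover:

* the interactome is built from communities (scale-free preferential-
  attachment subgraphs of ``attachment_m`` edges per new node) chained by a
  few inter-community edges, so the community quotient graph is a path and
  "distant" communities are provably many hops apart;
* planted disease pairs draw their genes either from a single community
  (``same_module=True`` — low network separation expected) or from two
  communities at quotient distance >= 3 (high separation expected), with a
  controllable shared-gene fraction;
* planted enrichments make a pathway absorb a chosen fraction of a disease's
  genes, and attach one dedicated miRNA to that disease whose targets cover
  the same overlap, so both the gene-mode and the miRNA-mode hypergeometric
  tests flag the pathway.

Everything else (background diseases, pathways, annotations, miRNA targets,
tissues) is drawn uniformly. A single :class:`numpy.random.Generator` is
threaded through all draws; identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml

from . import io_formats
from .datatypes import GeneDiseaseTable, GeneSet, GeneSetCollection, Interactome, MirnaTables
from .errors import ConfigurationError

logger = logging.getLogger("comorbnet")

TISSUES = ("ovary", "liver", "brain", "muscle", "kidney")

__all__ = [
    "PlantedPair",
    "PlantedEnrichment",
    "SimulationConfig",
    "SyntheticUniverse",
    "simulate",
    "write_universe",
    "load_config",
]


@dataclass(frozen=True)
class PlantedPair:
    disease_a: str
    disease_b: str
    overlap_fraction: float
    same_module: bool


@dataclass(frozen=True)
class PlantedEnrichment:
    disease: str
    pathway: str
    hit_fraction: float


def _default_planted_pairs() -> tuple[PlantedPair, ...]:
    # two same-community pairs, two pairs >= 3 hops apart in the community
    # quotient path; no shared genes, so separation contrasts are purely
    # topological
    return (
        PlantedPair("D_NEAR_A1", "D_NEAR_B1", 0.0, True),
        PlantedPair("D_NEAR_A2", "D_NEAR_B2", 0.0, True),
        PlantedPair("D_FAR_A1", "D_FAR_B1", 0.0, False),
        PlantedPair("D_FAR_A2", "D_FAR_B2", 0.0, False),
    )


def _default_planted_enrichment() -> tuple[PlantedEnrichment, ...]:
    return (PlantedEnrichment("D_ENR", "PW_PLANTED", 0.8),)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the standard study conditions."""

    seed: int = 0
    n_genes: int = 500
    n_diseases: int = 30
    n_pathways: int = 40
    n_terms: int = 150
    n_mirnas: int = 60
    interactome_model: str = "scale_free"  # or "erdos_renyi"
    attachment_m: int = 3
    edge_prob: float = 0.02  # erdos_renyi only
    n_communities: int = 8
    inter_community_edges: int = 2
    genes_per_disease: tuple[int, int] = (8, 15)
    pleiotropy: float = 2.0  # target mean diseases per background gene
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=_default_planted_pairs)
    planted_enrichment: tuple[PlantedEnrichment, ...] = field(default_factory=_default_planted_enrichment)

    def __post_init__(self) -> None:
        self.planted_pairs = tuple(
            p if isinstance(p, PlantedPair) else PlantedPair(*p) for p in self.planted_pairs
        )
        self.planted_enrichment = tuple(
            p if isinstance(p, PlantedEnrichment) else PlantedEnrichment(*p)
            for p in self.planted_enrichment
        )
        self.genes_per_disease = tuple(self.genes_per_disease)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        for name in ("n_genes", "n_diseases", "n_pathways", "n_terms", "n_mirnas", "n_communities"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.genes_per_disease
        if not 1 <= lo <= hi:
            raise ConfigurationError("genes_per_disease must be an increasing range with lo >= 1")
        if self.pleiotropy < 0:
            raise ConfigurationError("pleiotropy must be >= 0")
        if self.interactome_model not in ("scale_free", "erdos_renyi"):
            raise ConfigurationError(f"unknown interactome model {self.interactome_model!r}")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ConfigurationError("edge_prob must be in [0, 1]")
        for p in self.planted_pairs:
            if not 0.0 <= p.overlap_fraction <= 1.0:
                raise ConfigurationError("overlap_fraction must be in [0, 1]")
            if p.disease_a == p.disease_b:
                raise ConfigurationError("a planted pair needs two distinct diseases")
        for e in self.planted_enrichment:
            if not 0.0 < e.hit_fraction <= 1.0:
                raise ConfigurationError("hit_fraction must be in (0, 1]")
        comm_size = self.n_genes // self.n_communities
        if comm_size < 2 * hi:
            raise ConfigurationError(
                f"communities of {comm_size} genes cannot host a planted pair of up to {hi} genes each"
            )
        # distant pair i uses communities (i, n_communities-1-i); the innermost
        # pair must still sit >= 3 hops apart in the community quotient path
        n_far = sum(not p.same_module for p in self.planted_pairs)
        if n_far and self.n_communities - 1 - 2 * (n_far - 1) < 3:
            raise ConfigurationError(
                "not enough communities to separate the distant planted pairs by >= 3 hops"
            )
        planted_ids = {p.disease_a for p in self.planted_pairs} | {p.disease_b for p in self.planted_pairs}
        planted_ids |= {e.disease for e in self.planted_enrichment}
        if len(planted_ids) > self.n_diseases:
            raise ConfigurationError("more planted diseases than n_diseases")


@dataclass
class SyntheticUniverse:
    config: SimulationConfig
    gene_disease: GeneDiseaseTable
    interactome: Interactome
    pathways: GeneSetCollection
    annotations: GeneSetCollection
    mirna: MirnaTables
    tissues: dict[str, frozenset[str]]
    gene_communities: dict[str, int]


# ---------------------------------------------------------------------------

def _build_interactome(cfg: SimulationConfig, rng: np.random.Generator, genes: Sequence[str],
                       communities: list[list[str]]) -> Interactome:
    edges: list[tuple[str, str, float]] = []
    if cfg.interactome_model == "scale_free":
        for comm in communities:
            m = min(cfg.attachment_m, len(comm) - 1)
            sub = nx.barabasi_albert_graph(len(comm), m, seed=int(rng.integers(2**31)))
            edges.extend((comm[a], comm[b], 0.0) for a, b in sub.edges)
        for c in range(len(communities) - 1):
            for _ in range(cfg.inter_community_edges):
                a = communities[c][int(rng.integers(len(communities[c])))]
                b = communities[c + 1][int(rng.integers(len(communities[c + 1])))]
                edges.append((a, b, 0.0))
    else:
        sub = nx.gnp_random_graph(len(genes), cfg.edge_prob, seed=int(rng.integers(2**31)))
        edges.extend((genes[a], genes[b], 0.0) for a, b in sub.edges)
    # deterministic per-edge confidence scores
    scored = []
    for a, b, _ in edges:
        scored.append((a, b, float(np.round(rng.uniform(0.4, 1.0), 4))))
    return Interactome.from_edges(scored, nodes=genes)


def _sample(rng: np.random.Generator, pool: Sequence[str], k: int,
            exclude: set[str] | None = None) -> list[str]:
    avail = [g for g in pool if not exclude or g not in exclude]
    if k > len(avail):
        raise ConfigurationError(f"cannot sample {k} genes from a pool of {len(avail)}")
    idx = rng.choice(len(avail), size=k, replace=False)
    return [avail[i] for i in sorted(idx)]


def simulate(config: SimulationConfig) -> SyntheticUniverse:
    """Generate the full universe in memory (nothing is written to disk).

    Raises :class:`ConfigurationError` for infeasible configs before any
    expensive work.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    comm_size = cfg.n_genes // cfg.n_communities
    communities = [
        genes[c * comm_size: (c + 1) * comm_size if c < cfg.n_communities - 1 else cfg.n_genes]
        for c in range(cfg.n_communities)
    ]
    gene_comm = {g: c for c, comm in enumerate(communities) for g in comm}

    net = _build_interactome(cfg, rng, genes, communities)

    # --- disease gene sets -------------------------------------------------
    lo, hi = cfg.genes_per_disease
    disease_genes: dict[str, list[str]] = {}
    same_counter, far_counter = 0, 0
    for pair in cfg.planted_pairs:
        size_a = int(rng.integers(lo, hi + 1))
        size_b = int(rng.integers(lo, hi + 1))
        n_shared = int(round(pair.overlap_fraction * min(size_a, size_b)))
        if pair.same_module:
            c = same_counter % cfg.n_communities
            same_counter += 1
            pool_a = pool_b = communities[c]
        else:
            c_a = far_counter
            c_b = cfg.n_communities - 1 - far_counter
            far_counter += 1
            pool_a, pool_b = communities[c_a], communities[c_b]
        shared = _sample(rng, pool_a, n_shared)
        rest_a = _sample(rng, pool_a, size_a - n_shared, exclude=set(shared))
        rest_b = _sample(rng, pool_b, size_b - n_shared, exclude=set(shared) | set(rest_a))
        disease_genes[pair.disease_a] = sorted(set(shared) | set(rest_a))
        disease_genes[pair.disease_b] = sorted(set(shared) | set(rest_b))

    extra_ids = [e.disease for e in cfg.planted_enrichment if e.disease not in disease_genes]
    n_background = cfg.n_diseases - len(disease_genes) - len(set(extra_ids))
    background_ids = [f"D{i:04d}" for i in range(n_background)]
    mean_size = (lo + hi) / 2
    n_rand = n_background + len(set(extra_ids))
    if cfg.pleiotropy > 0 and n_rand:
        pool_size = int(round(n_rand * mean_size / cfg.pleiotropy))
        pool_size = max(hi, min(cfg.n_genes, pool_size))
    else:
        pool_size = cfg.n_genes
    background_pool = _sample(rng, genes, pool_size)
    for d in sorted(set(extra_ids)) + background_ids:
        size = int(rng.integers(lo, hi + 1))
        disease_genes[d] = sorted(_sample(rng, background_pool, size))

    records = [
        (d, f"disease {d}", g) for d in sorted(disease_genes) for g in disease_genes[d]
    ]
    gd = GeneDiseaseTable(records)

    # --- pathways ----------------------------------------------------------
    planted_pw = {e.pathway for e in cfg.planted_enrichment}
    pathway_sets: dict[str, list[str]] = {}
    for e in cfg.planted_enrichment:
        dg = disease_genes[e.disease]
        n_hit = max(1, int(round(e.hit_fraction * len(dg))))
        hits = _sample(rng, dg, n_hit)
        filler = _sample(rng, genes, max(0, 25 - n_hit), exclude=set(dg))
        pathway_sets[e.pathway] = sorted(set(hits) | set(filler))
    n_fill = cfg.n_pathways - len(planted_pw)
    for i in range(n_fill):
        size = int(rng.integers(10, 31))
        pathway_sets[f"PW{i:04d}"] = sorted(_sample(rng, genes, size))
    pathways = GeneSetCollection(
        [GeneSet(sid, f"pathway {sid}", frozenset(gs)) for sid, gs in pathway_sets.items()]
    )

    # --- GO annotations (BP + MF) ------------------------------------------
    terms = [f"GO:{i:07d}" for i in range(cfg.n_terms)]
    term_ns = {t: ("BP" if i % 2 == 0 else "MF") for i, t in enumerate(terms)}
    term_genes: dict[str, set[str]] = {t: set() for t in terms}
    for g in genes:
        k = 1 + int(rng.poisson(2))
        for t in _sample(rng, terms, min(k, cfg.n_terms)):
            term_genes[t].add(g)
    annotations = GeneSetCollection(
        [GeneSet(t, term_ns[t], frozenset(gs)) for t, gs in term_genes.items() if gs]
    )

    # --- miRNA tables -------------------------------------------------------
    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirnas)]
    mirna_targets: dict[str, frozenset[str]] = {}
    for m in mirnas:
        size = int(rng.integers(10, 31))
        mirna_targets[m] = frozenset(_sample(rng, genes, size))
    disease_mirnas: dict[str, set[str]] = {}
    for d in sorted(disease_genes):
        k = 1 + int(rng.integers(0, 3))
        disease_mirnas[d] = set(_sample(rng, mirnas, k))
    for i, e in enumerate(cfg.planted_enrichment):
        # dedicated miRNA targeting most of the planted pathway, so the
        # miRNA-mode hypergeometric test flags it as strongly as the gene mode
        mid = f"mir-planted-{i:02d}"
        members = pathway_sets[e.pathway]
        n_hit = max(1, int(round(e.hit_fraction * len(members))))
        hits = _sample(rng, members, n_hit)
        filler = _sample(rng, genes, 5, exclude=set(members))
        mirna_targets[mid] = frozenset(hits) | frozenset(filler)
        disease_mirnas[e.disease].add(mid)
    mir = MirnaTables(
        disease_mirnas={d: frozenset(v) for d, v in disease_mirnas.items()},
        mirna_targets=mirna_targets,
    )

    # --- tissues ------------------------------------------------------------
    tissues = {
        g: frozenset(_sample(rng, TISSUES, 1 + int(rng.integers(0, 3)))) for g in genes
    }
    net.node_tissues = tissues

    return SyntheticUniverse(
        config=cfg,
        gene_disease=gd,
        interactome=net,
        pathways=pathways,
        annotations=annotations,
        mirna=mir,
        tissues=tissues,
        gene_communities=gene_comm,
    )


# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_universe(u: SyntheticUniverse, outdir: str | Path) -> dict:
    """Write all fixture files + a checksum manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_gene_disease(u.gene_disease, outdir / "gene_disease.tsv")
    io_formats.write_interactome(u.interactome, outdir / "interactome.tsv", outdir / "interactome_nodes.json")
    io_formats.write_gmt(u.pathways, outdir / "pathways.gmt")
    io_formats.write_annotations(u.annotations, outdir / "annotations.tsv")
    io_formats.write_mirna_tables(u.mirna, outdir / "mirna_disease.tsv", outdir / "mirna_targets.tsv")
    io_formats.write_tissue_table(u.tissues, outdir / "tissues.tsv")
    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": asdict(u.config),
        "files": {name: _sha256(outdir / name) for name in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from YAML/JSON (planted entries as lists or mappings)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    if "planted_pairs" in raw:
        raw["planted_pairs"] = tuple(
            PlantedPair(**p) if isinstance(p, dict) else PlantedPair(*p) for p in raw["planted_pairs"]
        )
    if "planted_enrichment" in raw:
        raw["planted_enrichment"] = tuple(
            PlantedEnrichment(**p) if isinstance(p, dict) else PlantedEnrichment(*p)
            for p in raw["planted_enrichment"]
        )
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "genes_per_disease" in raw:
        raw["genes_per_disease"] = tuple(raw["genes_per_disease"])
    return SimulationConfig(**raw)
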