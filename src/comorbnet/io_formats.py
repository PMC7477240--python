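"""Readers and writers for the tabular and graph formats the toolkit touches.

Formats
-------
* gene-disease association table: TSV with header, columns
  ``disease_id``, ``disease_name``, ``gene`` (extra columns ignored).
* interactome: plain TSV edge list (``protein1  protein2  [score]``, header
  required) or the STRING "detailed links" dialect (whitespace-separated,
  0-1000 integer evidence channels; the experimental channel is used and
  rescaled to [0, 1]).
* gene sets: standard GMT (``set_id TAB description TAB gene...``).
* GO annotations: two/three-column TSV (``gene  term  [namespace]``) or
  GAF 2.x (DB object symbol, GO id, aspect columns).
* miRNA tables, tissue table: two-column TSVs with header.

All writers emit rows in lexicographic order so output is byte-stable and a
write/read round trip reproduces an identical in-memory value.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, TextIO

from .datatypes import GeneDiseaseTable, GeneSet, GeneSetCollection, Interactome, MirnaTables
from .errors import FormatError

logger = logging.getLogger("comorbnet")

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}
_NAMESPACE_ALIASES = {
    "BP": "BP", "P": "BP", "BIOLOGICAL_PROCESS": "BP",
    "MF": "MF", "F": "MF", "MOLECULAR_FUNCTION": "MF",
    "CC": "CC", "C": "CC", "CELLULAR_COMPONENT": "CC",
}


def _open_rows(path: str | Path, delimiter: str = "\t"):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    return [r for r in rows if r and any(f.strip() for f in r)]


# ---------------------------------------------------------------------------
# gene-disease table

def read_gene_disease(path: str | Path, dialect: str = "plain_tsv") -> GeneDiseaseTable:
    """Read a gene-disease association TSV (header with disease_id, disease_name, gene)."""
    if dialect != "plain_tsv":
        raise FormatError(f"unknown gene-disease dialect: {dialect!r}")
    rows = _open_rows(path)
    if not rows:
        raise FormatError(f"empty gene-disease file: {path}")
    header = [c.strip().lower() for c in rows[0]]
    try:
        idx = {c: header.index(c) for c in ("disease_id", "disease_name", "gene")}
    except ValueError as exc:
        missing = next(c for c in ("disease_id", "disease_name", "gene") if c not in header)
        raise FormatError(f"{path}: missing required column {missing!r}") from exc
    records = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) <= max(idx.values()):
            raise FormatError(f"{path}: line {i}: expected {len(header)} fields, got {len(row)}")
        records.append((row[idx["disease_id"]], row[idx["disease_name"]], row[idx["gene"]]))
    if not records:
        raise FormatError(f"{path}: no association rows")
    return GeneDiseaseTable(records)


def write_gene_disease(gd: GeneDiseaseTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["disease_id", "disease_name", "gene"])
        w.writerows(gd.records())


# ---------------------------------------------------------------------------
# interactome

def read_interactome(
    path: str | Path,
    dialect: str = "plain_tsv",
    min_score: float = 0.0,
    tissues: str | Path | None = None,
) -> Interactome:
    """Read a PPI edge list; merge reciprocal duplicates (max score), drop
    self-loops, and filter edges scoring below ``min_score``."""
    if not 0.0 <= min_score <= 1.0:
        raise FormatError(f"min_score must be in [0, 1], got {min_score}")
    node_tissues = read_tissue_table(tissues) if tissues is not None else None
    if dialect == "plain_tsv":
        rows = _open_rows(path)
        if not rows:
            raise FormatError(f"empty interactome file: {path}")
        edges = []
        for i, row in enumerate(rows[1:], start=2):  # first row is the header
            if len(row) < 2:
                raise FormatError(f"{path}: line {i}: expected >= 2 fields, got {len(row)}")
            score = None
            if len(row) >= 3 and row[2].strip():
                try:
                    score = float(row[2])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {i}: bad score {row[2]!r}") from exc
            edges.append((row[0].strip(), row[1].strip(), score))
    elif dialect == "string_detailed":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        with open(path) as fh:
            lines = [ln.split() for ln in fh if ln.strip()]
        if not lines:
            raise FormatError(f"empty interactome file: {path}")
        header = [c.lower() for c in lines[0]]
        try:
            col = header.index("experiments") if "experiments" in header else header.index("experimental")
        except ValueError as exc:
            raise FormatError(f"{path}: no experimental-evidence column in STRING header") from exc
        edges = []
        for i, row in enumerate(lines[1:], start=2):
            if len(row) <= col:
                raise FormatError(f"{path}: line {i}: expected >= {col + 1} fields, got {len(row)}")
            try:
                raw = int(row[col])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: bad score {row[col]!r}") from exc
            if not 0 <= raw <= 1000:
                raise FormatError(f"{path}: line {i}: STRING score {raw} outside [0, 1000]")
            edges.append((row[0], row[1], raw / 1000.0))
    else:
        raise FormatError(f"unknown interactome dialect: {dialect!r}")
    return Interactome.from_edges(edges, min_score=min_score, node_tissues=node_tissues)


def write_interactome(net: Interactome, edge_path: str | Path, node_path: str | Path | None = None) -> None:
    """Write the edge list as TSV; node attributes (isolated nodes, tissues) as JSON."""
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein1", "protein2", "score"])
        for a, b in net.edges:
            score = net.graph.edges[a, b].get("score")
            w.writerow([a, b, "" if score is None else repr(score)])  # shortest exact repr
    if node_path is not None:
        attrs = {
            g: {"tissues": sorted((net.node_tissues or {}).get(g, ()))}
            for g in net.nodes
        }
        with open(node_path, "w") as fh:
            json.dump(attrs, fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_interactome_nodes(net: Interactome, node_path: str | Path) -> Interactome:
    """Merge a node-attribute JSON (isolated nodes + tissues) into ``net``."""
    with open(node_path) as fh:
        attrs = json.load(fh)
    net.graph.add_nodes_from(attrs)
    tissues = {g: frozenset(a.get("tissues", ())) for g, a in attrs.items() if a.get("tissues")}
    if tissues:
        merged = dict(net.node_tissues or {})
        merged.update(tissues)
        net.node_tissues = merged
    return net


# ---------------------------------------------------------------------------
# gene sets / annotations

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``set_id TAB description TAB gene...``."""
    rows = _open_rows(path)
    if not rows:
        raise FormatError(f"empty GMT file: {path}")
    sets = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=1):
        if len(row) < 3:
            raise FormatError(f"{path}: line {i}: GMT line needs >= 3 fields, got {len(row)}")
        set_id, desc = row[0], row[1]
        if set_id in seen:
            raise FormatError(f"{path}: line {i}: duplicate set id {set_id!r}")
        seen.add(set_id)
        genes = frozenset(g for g in row[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}: line {i}: set {set_id!r} has no genes")
        sets.append(GeneSet(set_id, desc, genes))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for s in coll:
            w.writerow([s.set_id, s.description, *sorted(s.genes)])


def _looks_like_header(row: list[str]) -> bool:
    lowered = {c.strip().lower() for c in row}
    return "gene" in lowered and "term" in lowered


def read_annotations(
    path: str | Path,
    namespaces: Iterable[str] = ("BP", "MF"),
) -> GeneSetCollection:
    """Read GO annotations as a term-keyed collection (term -> annotated genes).

    Accepts a TSV with columns ``gene``, ``term`` and optional ``namespace``
    (header optional), or a GAF 2.x file. When namespace information is
    present, terms outside ``namespaces`` are dropped; files without it are
    accepted as pre-filtered. The set description carries the namespace.
    """
    wanted = {_NAMESPACE_ALIASES.get(ns.strip().upper(), ns.strip().upper()) for ns in namespaces}
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    is_gaf = first.startswith("!") or path.suffix.lower() == ".gaf"
    pairs: list[tuple[str, str, str | None]] = []  # (gene, term, namespace-or-None)
    if is_gaf:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("!"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise FormatError(f"{path}: line {i}: GAF line needs >= 9 columns, got {len(fields)}")
                gene, term, aspect = fields[2], fields[4], fields[8]
                ns = _GAF_ASPECT.get(aspect.strip().upper())
                if ns is None:
                    raise FormatError(f"{path}: line {i}: unknown GAF aspect {aspect!r}")
                pairs.append((gene, term, ns))
    else:
        rows = _open_rows(path)
        if not rows:
            raise FormatError(f"empty annotation file: {path}")
        if _looks_like_header(rows[0]):
            header = [c.strip().lower() for c in rows[0]]
            gi, ti = header.index("gene"), header.index("term")
            ni = header.index("namespace") if "namespace" in header else None
            data = rows[1:]
        else:
            gi, ti = 0, 1
            ni = 2 if len(rows[0]) >= 3 else None
            data = rows
        for i, row in enumerate(data, start=1):
            if len(row) < 2:
                raise FormatError(f"{path}: line {i}: annotation row needs >= 2 fields")
            ns = None
            if ni is not None and len(row) > ni and row[ni].strip():
                raw = row[ni].strip().upper()
                ns = _NAMESPACE_ALIASES.get(raw)
                if ns is None:
                    raise FormatError(f"{path}: line {i}: unknown namespace {row[ni]!r}")
            pairs.append((row[gi].strip(), row[ti].strip(), ns))
    if not pairs:
        raise FormatError(f"{path}: no annotation rows")
    term_genes: dict[str, set[str]] = {}
    term_ns: dict[str, str] = {}
    n_dropped = 0
    for gene, term, ns in pairs:
        if ns is not None and ns not in wanted:
            n_dropped += 1
            continue
        term_genes.setdefault(term, set()).add(gene)
        if ns is not None:
            term_ns[term] = ns
    if n_dropped:
        logger.info("dropped %d annotation(s) outside namespaces %s", n_dropped, sorted(wanted))
    return GeneSetCollection(
        [GeneSet(t, term_ns.get(t, ""), frozenset(gs)) for t, gs in term_genes.items()]
    )


def write_annotations(coll: GeneSetCollection, path: str | Path) -> None:
    rows = []
    for s in coll:
        for g in sorted(s.genes):
            rows.append((g, s.set_id, s.description))
    rows.sort()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "term", "namespace"])
        w.writerows(rows)


# ---------------------------------------------------------------------------
# miRNA and tissue tables

def _read_two_column(path: str | Path, col_a: str, col_b: str) -> list[tuple[str, str]]:
    rows = _open_rows(path)
    if not rows:
        raise FormatError(f"empty file: {path}")
    header = [c.strip().lower() for c in rows[0]]
    if col_a not in header or col_b not in header:
        raise FormatError(f"{path}: expected columns {col_a!r} and {col_b!r}, got {header}")
    ia, ib = header.index(col_a), header.index(col_b)
    out = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) <= max(ia, ib):
            raise FormatError(f"{path}: line {i}: too few fields")
        out.append((row[ia].strip(), row[ib].strip()))
    if not out:
        raise FormatError(f"{path}: no data rows")
    return out


def read_mirna_tables(disease_mirna_path: str | Path, mirna_target_path: str | Path) -> MirnaTables:
    """Read disease->miRNA (columns disease_id, mirna) and miRNA->target (mirna, gene) TSVs."""
    dm: dict[str, set[str]] = {}
    for d, m in _read_two_column(disease_mirna_path, "disease_id", "mirna"):
        dm.setdefault(d, set()).add(m)
    mt: dict[str, set[str]] = {}
    for m, g in _read_two_column(mirna_target_path, "mirna", "gene"):
        mt.setdefault(m, set()).add(g)
    return MirnaTables(
        disease_mirnas={d: frozenset(v) for d, v in dm.items()},
        mirna_targets={m: frozenset(v) for m, v in mt.items()},
    )


def write_mirna_tables(mir: MirnaTables, disease_mirna_path: str | Path, mirna_target_path: str | Path) -> None:
    with open(disease_mirna_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["disease_id", "mirna"])
        for d in sorted(mir.disease_mirnas):
            for m in sorted(mir.disease_mirnas[d]):
                w.writerow([d, m])
    with open(mirna_target_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["mirna", "gene"])
        for m in sorted(mir.mirna_targets):
            for g in sorted(mir.mirna_targets[m]):
                w.writerow([m, g])


def read_tissue_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a gene->tissue expression TSV (columns gene, tissue)."""
    out: dict[str, set[str]] = {}
    for g, t in _read_two_column(path, "gene", "tissue"):
        out.setdefault(g, set()).add(t)
    return {g: frozenset(v) for g, v in out.items()}


def write_tissue_table(tissues: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "tissue"])
        for g in sorted(tissues):
            for t in sorted(tissues[g]):
                w.writerow([g, t])


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene per line (used for an explicit enrichment universe)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path) as fh:
        genes = frozenset(ln.strip() for ln in fh if ln.strip())
    if not genes:
        raise FormatError(f"empty gene list: {path}")
    return genes
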