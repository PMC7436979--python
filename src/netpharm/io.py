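"""Readers and writers for the tabular and graph formats the pipeline touches.

Supported formats: delimited compound->target and disease-target tables,
STRING-style PPI edge lists (0-1 or 0-1000 score dialects), GMT gene-set
collections, docking-score CSVs, plain gene lists, and GraphML / SIF /
TSV network output.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .model import (
    MISSING,
    CompoundTargetMap,
    DiseaseTargetSet,
    DockingTable,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    PPIEdge,
    Role,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_compound_targets",
    "read_disease_targets",
    "read_ppi_edges",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_docking_table",
    "write_docking_table",
    "read_alias_table",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """Raised when an input file does not match its expected dialect."""


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _require_columns(df: pd.DataFrame, required: Mapping[str, str], path) -> None:
    for role, col in required.items():
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing required {role} column {col!r} "
                f"(found: {list(df.columns)})"
            )


def read_compound_targets(
    path,
    compound_col: str = "compound",
    gene_col: str = "gene",
    source_col: Optional[str] = "source",
    alias_map: Optional[Mapping[str, str]] = None,
) -> CompoundTargetMap:
    """Load a compound->target association table.

    Symbols are uppercased and trimmed; duplicate (compound, gene) rows are
    merged with the union of their source tags. Rows with a blank gene cell
    are skipped (with a logged count). An empty file yields an empty map
    with a warning, not an error.
    """
    df = _read_table(path)
    ct = CompoundTargetMap()
    if df.empty:
        logger.warning("%s: empty compound-target table", path)
        return ct
    _require_columns(df, {"compound": compound_col, "gene": gene_col}, path)
    has_source = source_col is not None and source_col in df.columns
    skipped = 0
    for _, row in df.iterrows():
        gene = row[gene_col]
        compound = row[compound_col]
        if pd.isna(gene) or not str(gene).strip() or pd.isna(compound):
            skipped += 1
            continue
        gene = normalize_symbol(str(gene))
        if alias_map:
            gene = alias_map.get(gene, gene)
        source = None
        if has_source and not pd.isna(row[source_col]):
            source = str(row[source_col]).strip()
        ct.add(str(compound), gene, source)
    if skipped:
        logger.info("%s: skipped %d rows with blank cells", path, skipped)
    ct.validate()
    return ct


def read_disease_targets(
    path,
    gene_col: Optional[str] = None,
    source_col: Optional[str] = "source",
    alias_map: Optional[Mapping[str, str]] = None,
) -> DiseaseTargetSet:
    """Load a disease target list.

    Accepts either a one-symbol-per-line file or a delimited table (pass
    ``gene_col``; a ``gene`` column is auto-detected).
    """
    path = Path(path)
    dt = DiseaseTargetSet()

    def _add(gene: str, source: Optional[str] = None) -> None:
        gene = normalize_symbol(gene)
        if alias_map:
            gene = alias_map.get(gene, gene)
        dt.add(gene, source)

    df = _read_table(path)
    if df.empty:
        logger.warning("%s: empty disease-target file", path)
        return dt
    columns = list(df.columns)
    col = gene_col or ("gene" if "gene" in columns else None)
    if col is not None:
        _require_columns(df, {"gene": col}, path)
        has_source = source_col is not None and source_col in columns
        for _, row in df.iterrows():
            if pd.isna(row[col]) or not str(row[col]).strip():
                continue
            source = None
            if has_source and not pd.isna(row[source_col]):
                source = str(row[source_col]).strip()
            _add(str(row[col]), source)
    else:
        # plain list: no header, one symbol per line
        for line in path.read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                _add(line.split("\t")[0])
    return dt


def read_ppi_edges(
    path,
    min_score: float = 0.4,
    node_cols: Tuple[str, str] = ("node1", "node2"),
    score_col: str = "combined_score",
    scale: str = "auto",
) -> List[PPIEdge]:
    """Load a STRING-export-style PPI edge list.

    Scores may be on a 0-1 or 0-1000 scale; with ``scale='auto'`` the
    0-1000 dialect is assumed whenever any score exceeds 1 (override with
    ``scale='unit'`` or ``scale='thousand'``). Edges are kept only when
    their normalized score is strictly greater than ``min_score``;
    duplicate pairs collapse to the maximum score and self-loops are
    dropped with a logged count.
    """
    if scale not in {"auto", "unit", "thousand"}:
        raise ValueError(f"unknown scale {scale!r}")
    df = _read_table(path)
    if df.empty:
        logger.warning("%s: empty PPI edge list", path)
        return []
    _require_columns(
        df, {"node1": node_cols[0], "node2": node_cols[1], "score": score_col}, path
    )
    scores = pd.to_numeric(df[score_col], errors="raise").astype(float)
    if scale == "auto":
        scale = "thousand" if (scores > 1.0).any() else "unit"
    if scale == "thousand":
        scores = scores / 1000.0
    if (scores > 1.0).any() or (scores < 0.0).any():
        raise FormatError(
            f"{path}: scores outside [0, 1] after {scale!r}-scale normalization; "
            "pass an explicit scale"
        )
    best: Dict[Tuple[str, str], float] = {}
    self_loops = 0
    for a, b, s in zip(df[node_cols[0]], df[node_cols[1]], scores):
        a = normalize_symbol(str(a))
        b = normalize_symbol(str(b))
        if a == b:
            self_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or best[key] < s:
            best[key] = float(s)
    if self_loops:
        logger.info("%s: dropped %d self-loops", path, self_loops)
    edges = [
        PPIEdge(a, b, s) for (a, b), s in sorted(best.items()) if s > min_score
    ]
    logger.info(
        "%s: kept %d/%d unique pairs with score > %g", path, len(edges), len(best),
        min_score,
    )
    return edges


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path, universe: Optional[Sequence[str]] = None) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member genes...)."""
    sets: Dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, description = fields[0].strip(), fields[1].strip()
        members = frozenset(
            normalize_symbol(g) for g in fields[2:] if g.strip()
        )
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = GeneSet(name=name, description=description, members=members)
    return GeneSetCollection(sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for gs in collection:
        lines.append("\t".join([gs.name, gs.description, *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> List[str]:
    """One identifier per line; '#' comments and blank lines ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(items: Sequence[str], path) -> None:
    Path(path).write_text("\n".join(str(x) for x in items) + "\n")


# ---------------------------------------------------------------------------
# Docking tables
# ---------------------------------------------------------------------------

def read_docking_table(
    path,
    molecule_col: str = "molecule",
    target_col: str = "target",
    score_col: str = "score",
    ligand_col: str = "is_ligand",
) -> DockingTable:
    """Read a docking-score CSV.

    Blank score cells become MISSING (never 0). The ligand column is
    boolean-ish (1/0, true/false, yes/no).
    """
    df = _read_table(path)
    if df.empty:
        raise FormatError(f"{path}: empty docking table")
    _require_columns(
        df,
        {
            "molecule": molecule_col,
            "target": target_col,
            "score": score_col,
            "ligand": ligand_col,
        },
        path,
    )
    truthy = {"1", "true", "yes", "y"}
    records: Dict[Tuple[str, str], Optional[float]] = {}
    ligands: Dict[str, str] = {}
    for _, row in df.iterrows():
        mol = str(row[molecule_col]).strip()
        target = normalize_symbol(str(row[target_col]))
        raw = row[score_col]
        score = (
            MISSING
            if pd.isna(raw) or not str(raw).strip()
            else float(raw)
        )
        records[(mol, target)] = score
        flag = str(row[ligand_col]).strip().lower() in truthy
        if flag:
            if target in ligands and ligands[target] != mol:
                raise FormatError(
                    f"{path}: target {target} has multiple ligand rows"
                )
            ligands[target] = mol
    return DockingTable(records, ligands)


def write_docking_table(table: DockingTable, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule", "target", "score", "is_ligand"])
        for (mol, target) in sorted(table.records):
            score = table.records[(mol, target)]
            writer.writerow(
                [
                    mol,
                    target,
                    "" if score is MISSING else f"{score:.6g}",
                    int(table.ligands.get(target) == mol),
                ]
            )


def read_alias_table(path) -> Dict[str, str]:
    """Two-column alias -> symbol table used to remap identifiers."""
    df = _read_table(path)
    if df.empty or df.shape[1] < 2:
        raise FormatError(f"{path}: alias table needs two columns")
    alias_col, symbol_col = df.columns[:2]
    return {
        normalize_symbol(str(a)): normalize_symbol(str(s))
        for a, s in zip(df[alias_col], df[symbol_col])
        if not (pd.isna(a) or pd.isna(s))
    }


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

def write_network(net: InteractionNetwork, path, format: str = "graphml") -> None:
    """Write a network as GraphML, SIF, or a node/edge TSV pair.

    The TSV format writes ``<path>`` as the edge table and
    ``<path>.nodes.tsv`` as the node/role table.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "sif":
        with path.open("w") as fh:
            for a, b in sorted(net.edge_set()):
                fh.write(f"{a}\tpp\t{b}\n")
            connected = {n for e in net.edge_set() for n in e}
            for node in sorted(net.nodes - connected):
                fh.write(f"{node}\n")
    elif format == "tsv":
        with path.open("w") as fh:
            fh.write("node1\tnode2\tscore\n")
            for a, b in sorted(net.edge_set()):
                fh.write(f"{a}\t{b}\t{net.graph[a][b]['score']:.6f}\n")
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        with nodes_path.open("w") as fh:
            fh.write("gene\trole\n")
            for node in sorted(net.nodes):
                fh.write(f"{node}\t{net.role(node)}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> InteractionNetwork:
    """Read a network written by :func:`write_network` (GraphML or TSV)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        net = InteractionNetwork()
        for node, data in g.nodes(data=True):
            net.add_node(str(node), data.get("role", Role.NEIGHBOR))
        for a, b, data in g.edges(data=True):
            net.add_edge(PPIEdge(str(a), str(b), float(data["score"])))
        return net
    if format == "tsv":
        net = InteractionNetwork()
        nodes_path = path.with_suffix(path.suffix + ".nodes.tsv")
        ndf = pd.read_csv(nodes_path, sep="\t", dtype=str)
        for _, row in ndf.iterrows():
            net.add_node(row["gene"], row["role"])
        edf = pd.read_csv(path, sep="\t", dtype=str)
        for _, row in edf.iterrows():
            net.add_edge(PPIEdge(row["node1"], row["node2"], float(row["score"])))
        return net
    raise ValueError(f"unknown network format {format!r}")
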