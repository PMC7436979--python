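"""Compound-target and compound-target-pathway network assembly, and
ligand-normalized docking-score ratio matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    CompoundTargetMap,
    DockingTable,
    InteractionNetwork,
    Role,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TripartiteNetwork",
    "DockingRatioMatrix",
    "build_compound_key_target_network",
    "build_ctp_network",
    "docking_ratios",
    "ratio_heatmap",
    "DEFAULT_RATIO_CUTOFFS",
]

NODE_TYPES = ("compound", "target", "pathway")
EDGE_TYPES = ("compound-target", "target-target", "target-pathway")

#: (weak/moderate boundary, moderate/strong boundary)
DEFAULT_RATIO_CUTOFFS = (0.8, 1.0)


class TripartiteNetwork:
    """Typed compound / target / pathway graph.

    Allowed edges: compound-target, target-target (PPI), target-pathway.
    The endpoint-type invariant is enforced on every insertion.
    """

    _ALLOWED = {
        frozenset({"compound", "target"}): "compound-target",
        frozenset({"target"}): "target-target",
        frozenset({"target", "pathway"}): "target-pathway",
    }

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, name: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self.graph.nodes.get(name)
        if existing is not None and existing["type"] != node_type:
            raise ValueError(
                f"node {name!r} already has type {existing['type']!r}"
            )
        self.graph.add_node(name, type=node_type)

    def add_edge(self, u: str, v: str, **attrs) -> None:
        types = frozenset({self.graph.nodes[u]["type"], self.graph.nodes[v]["type"]})
        edge_type = self._ALLOWED.get(types)
        if edge_type is None:
            raise ValueError(
                f"edge {u!r}-{v!r} joins incompatible node types {sorted(types)}"
            )
        self.graph.add_edge(u, v, type=edge_type, **attrs)

    def nodes_of_type(self, node_type: str) -> Set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["type"] == node_type}

    def edges_of_type(self, edge_type: str):
        return [
            (u, v) for u, v, d in self.graph.edges(data=True) if d["type"] == edge_type
        ]

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            types = frozenset(
                {self.graph.nodes[u]["type"], self.graph.nodes[v]["type"]}
            )
            if self._ALLOWED.get(types) != d["type"]:
                raise ValueError(f"type invariant violated on edge {u!r}-{v!r}")


@dataclass
class DockingRatioMatrix:
    """compound x target ligand-normalized score ratios plus categories.

    ``ratios`` holds NaN for missing cells; ``categories`` holds one of
    none/weak/moderate/strong per cell (missing <-> none).
    """

    ratios: pd.DataFrame
    categories: pd.DataFrame
    cutoffs: Tuple[float, float] = DEFAULT_RATIO_CUTOFFS


def build_compound_key_target_network(
    ct: CompoundTargetMap,
    key: Set[str],
    hub: InteractionNetwork,
    keep_neighbors: bool = False,
) -> InteractionNetwork:
    """Bipartite compound/key-target network with PPI edges among targets.

    Targets are the key set (optionally plus all other hub-network nodes
    when ``keep_neighbors``); a compound-target edge is added wherever a
    compound's predicted target set contains an included target. PPI edges
    are restricted to included targets; isolates are removed and compounds
    with no key-target hit are dropped (logged). Node degree is exported
    as a ``size`` attribute for rendering.
    """
    key = set(key)
    if not key:
        raise ValueError("empty key-target set")
    missing = key - hub.nodes
    if missing:
        raise ValueError(
            f"{len(missing)} key targets not in the hub network: {sorted(missing)[:5]}"
        )
    targets = set(hub.nodes) if keep_neighbors else key

    net = InteractionNetwork()
    for gene in targets:
        net.add_node(gene, hub.role(gene))
    for edge in hub.edges():
        if edge.a in targets and edge.b in targets:
            net.add_edge(edge)

    skipped = 0
    for compound, genes in ct.entries.items():
        hits = genes & targets
        if not hits:
            skipped += 1
            continue
        net.add_node(compound, Role.COMPOUND)
        for gene in hits:
            net.graph.add_edge(compound, gene, score=1.0)
    if skipped:
        logger.info("%d compounds with no key-target hits were excluded", skipped)
    net.remove_isolates()
    for node in net.nodes:
        net.graph.nodes[node]["size"] = net.graph.degree[node]
    return net


def build_ctp_network(
    ct: CompoundTargetMap,
    key: Set[str],
    pathway_membership: Mapping[str, Set[str]],
    selected_pathways: Sequence[str],
) -> TripartiteNetwork:
    """Compound-target-pathway network over the selected pathways.

    Target nodes are key targets annotated to at least one selected
    pathway; target-pathway edges follow membership and compound-target
    edges follow targeting. Compounds with no surviving edge are dropped.
    """
    if not selected_pathways:
        raise ValueError("no pathways selected")
    unknown = [p for p in selected_pathways if p not in pathway_membership]
    if unknown:
        raise ValueError(f"selected pathways without membership data: {unknown}")

    key = set(key)
    tri = TripartiteNetwork()
    surviving: Set[str] = set()
    for pathway in selected_pathways:
        members = key & set(pathway_membership[pathway])
        if not members:
            continue
        tri.add_node(pathway, "pathway")
        for gene in members:
            tri.add_node(gene, "target")
            tri.add_edge(gene, pathway)
            surviving.add(gene)
    if not surviving:
        raise ValueError("no key target belongs to any selected pathway")
    for compound, genes in ct.entries.items():
        hits = genes & surviving
        if not hits:
            continue
        tri.add_node(compound, "compound")
        for gene in hits:
            tri.add_edge(compound, gene)
    tri.validate()
    return tri


def docking_ratios(
    table: DockingTable,
    cutoffs: Tuple[float, float] = DEFAULT_RATIO_CUTOFFS,
) -> DockingRatioMatrix:
    """Ligand-normalized score ratios with interaction categories.

    ratio = compound score / the target's original-ligand score. Missing
    scores propagate to NaN cells with category ``none``. Categories use
    half-open bands: weak ratio < cutoffs[0]; moderate cutoffs[0] <=
    ratio < cutoffs[1]; strong ratio >= cutoffs[1].
    """
    lo, hi = cutoffs
    if not (0 < lo < hi):
        raise ValueError(f"cutoffs must satisfy 0 < weak < strong, got {cutoffs}")
    compounds = table.compounds()
    targets = table.targets()
    for target in targets:
        if table.ligand_score(target) <= 0:
            raise ValueError(f"non-positive ligand score for target {target!r}")

    ratios = pd.DataFrame(np.nan, index=compounds, columns=targets, dtype=float)
    categories = pd.DataFrame("none", index=compounds, columns=targets, dtype=object)
    for target in targets:
        baseline = table.ligand_score(target)
        for compound in compounds:
            score = table.score(compound, target)
            if score is None:
                continue
            ratio = score / baseline
            ratios.loc[compound, target] = ratio
            if ratio >= hi:
                category = "strong"
            elif ratio >= lo:
                category = "moderate"
            else:
                category = "weak"
            categories.loc[compound, target] = category
    return DockingRatioMatrix(ratios=ratios, categories=categories, cutoffs=(lo, hi))


def ratio_heatmap(
    matrix: DockingRatioMatrix,
    out_image,
    out_csv=None,
) -> None:
    """Render the ratio matrix (rows = compounds, columns = targets).

    Missing cells are drawn in a neutral grey; a CSV twin of the plotted
    values is always written (default: ``<out_image>.csv``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_csv = out_csv if out_csv is not None else f"{out_image}.csv"
    matrix.ratios.to_csv(out_csv, index_label="compound")

    all_missing = [c for c in matrix.ratios.columns if matrix.ratios[c].isna().all()]
    if all_missing:
        logger.info("columns with no docking result at all: %s", all_missing)

    data = np.ma.masked_invalid(matrix.ratios.to_numpy(dtype=float))
    n_rows, n_cols = matrix.ratios.shape
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * n_cols + 2), max(3.0, 0.4 * n_rows + 1.5))
    )
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad(color="0.85")
    im = ax.imshow(data, cmap=cmap, aspect="auto")
    ax.set_xticks(range(n_cols), labels=matrix.ratios.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(n_rows), labels=matrix.ratios.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="score ratio vs. original ligand")
    fig.tight_layout()
    fig.savefig(out_image, dpi=150)
    plt.close(fig)
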