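"""Compound/disease target network construction.

Builds the compound-target / disease-target interaction network from a
score-filtered PPI edge list, computes the common-target set, and extracts
the hub subnetwork (seeds plus their distance-1 neighbors, induced).
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Set

from .model import (
    CompoundTargetMap,
    DiseaseTargetSet,
    InteractionNetwork,
    PPIEdge,
    Role,
)

logger = logging.getLogger(__name__)

__all__ = ["common_targets", "build_ct_ot_network", "extract_hub_network"]


def common_targets(ct: CompoundTargetMap, dt: DiseaseTargetSet) -> Set[str]:
    """Genes targeted by at least one compound that are also disease targets."""
    common = ct.all_targets() & dt.genes
    if not common:
        logger.info("no common targets between compound and disease sets")
    return common


def build_ct_ot_network(
    ct: CompoundTargetMap,
    dt: DiseaseTargetSet,
    ppi_edges: Iterable[PPIEdge],
    min_score: float = 0.4,
) -> InteractionNetwork:
    """Induce the PPI network on the union of compound and disease targets.

    Candidate nodes are all compound targets plus all disease targets;
    edges are PPI pairs with both endpoints among the candidates and score
    strictly greater than ``min_score``. Nodes left without any qualifying
    edge are removed. Roles: ``common`` for genes in both input sets,
    otherwise ``compound_target`` / ``disease_target``.
    """
    compound_genes = ct.all_targets()
    candidates = compound_genes | dt.genes
    if not candidates:
        raise ValueError("no targets supplied")
    common = compound_genes & dt.genes

    net = InteractionNetwork()
    for gene in candidates:
        if gene in common:
            role = Role.COMMON
        elif gene in compound_genes:
            role = Role.COMPOUND_TARGET
        else:
            role = Role.DISEASE_TARGET
        net.add_node(gene, role)
    for edge in ppi_edges:
        if edge.a in candidates and edge.b in candidates and edge.score > min_score:
            net.add_edge(edge)
    removed = net.remove_isolates()
    logger.info(
        "CT-OT network: %d nodes, %d edges (%d isolated targets removed)",
        net.n_nodes(), net.n_edges(), removed,
    )
    return net


def extract_hub_network(
    net: InteractionNetwork, seeds: Set[str]
) -> InteractionNetwork:
    """Induced subgraph on the seeds plus their distance-1 neighbors.

    Seeds absent from the network are dropped with a warning. Seed-seed,
    seed-neighbor, and neighbor-neighbor edges are all retained (full
    induced subgraph); isolated nodes are removed afterwards. Nodes that
    carry no prior role are labelled ``neighbor``.
    """
    effective = set(seeds) & net.nodes
    dropped = set(seeds) - effective
    if dropped:
        logger.warning(
            "%d seeds absent from the network were ignored: %s",
            len(dropped), sorted(dropped)[:5],
        )
    if not effective:
        raise ValueError("empty effective seed set")
    keep = set(effective)
    for seed in effective:
        keep |= net.neighbors(seed)
    sub = InteractionNetwork(net.graph.subgraph(keep).copy())
    for node in sub.nodes:
        if "role" not in sub.graph.nodes[node]:
            sub.graph.nodes[node]["role"] = Role.NEIGHBOR
    removed = sub.remove_isolates()
    logger.info(
        "hub network: %d nodes, %d edges (%d isolates removed)",
        sub.n_nodes(), sub.n_edges(), removed,
    )
    return sub
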