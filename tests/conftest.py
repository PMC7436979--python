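"""Shared fixtures: the hand-traceable toy network and small input files."""

from __future__ import annotations

import pytest

from netpharm.model import CompoundTargetMap, DiseaseTargetSet, InteractionNetwork, PPIEdge

# hand-enumerable toy: scored edges over genes G1..G8
TOY_EDGES = [
    ("G1", "G2", 0.9),
    ("G1", "G3", 0.8),
    ("G2", "G3", 0.7),
    ("G3", "G4", 0.6),
    ("G3", "G5", 0.8),
    ("G4", "G5", 0.5),
    ("G6", "G7", 0.3),
    ("G7", "G8", 0.9),
]
TOY_COMPOUND_TARGETS = {"C1": {"G1", "G2"}, "C2": {"G3", "G4"}}
TOY_DISEASE_TARGETS = {"G3", "G4", "G5", "G7"}


@pytest.fixture
def toy_edges():
    return [PPIEdge(a, b, s) for a, b, s in TOY_EDGES]


@pytest.fixture
def toy_compound_map():
    ct = CompoundTargetMap()
    for compound, genes in TOY_COMPOUND_TARGETS.items():
        for gene in genes:
            ct.add(compound, gene, source="toy")
    return ct


@pytest.fixture
def toy_disease_set():
    dt = DiseaseTargetSet()
    for gene in TOY_DISEASE_TARGETS:
        dt.add(gene, source="toy")
    return dt


def make_network(edges, roles=None):
    """Build an InteractionNetwork from (a, b, score) triples."""
    net = InteractionNetwork()
    roles = roles or {}
    nodes = {n for a, b, _ in edges for n in (a, b)}
    for node in nodes:
        net.add_node(node, roles.get(node, "neighbor"))
    for a, b, s in edges:
        net.add_edge(PPIEdge(a, b, s))
    return net


@pytest.fixture
def path5():
    """Path graph A-B-C-D-E, unit scores."""
    return make_network(
        [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0), ("D", "E", 1.0)]
    )


@pytest.fixture
def star5():
    """Star on 5 nodes, HUB at the center."""
    return make_network(
        [("HUB", leaf, 1.0) for leaf in ("L1", "L2", "L3", "L4")]
    )
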