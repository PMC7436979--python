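"""Node centralities and the median-threshold key-target screen.

Degree, betweenness, and closeness are computed from scratch on the
unweighted graph (edge confidence scores are ignored for topology):

* betweenness follows Brandes' accumulation and is normalized by
  (N-1)(N-2)/2, so the center of a star is exactly 1;
* closeness is the reciprocal of the mean shortest-path distance to the
  nodes actually reachable from each node (component-wise); an isolated
  node gets 0.

The screen keeps nodes whose degree is strictly greater than
``degree_fold`` times the median degree AND whose betweenness and
closeness are strictly greater than their respective medians, all medians
taken over every node of the screened network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Set

import numpy as np
import pandas as pd

from .model import InteractionNetwork

__all__ = [
    "CentralityTable",
    "ScreeningResult",
    "centralities",
    "screen_key_targets",
    "degree_betweenness_profile",
]

#: columns of a centrality table, in output order
CENTRALITY_COLUMNS = ["degree", "betweenness", "closeness"]

CentralityTable = pd.DataFrame  # index: gene; columns: CENTRALITY_COLUMNS


@dataclass
class ScreeningResult:
    degree_cutoff: float
    betweenness_cutoff: float
    closeness_cutoff: float
    key_targets: Set[str] = field(default_factory=set)


def _single_source_shortest_paths(adj: Dict[str, List[str]], source: str):
    """BFS returning (visit order, predecessors, path counts, distances)."""
    dist = {source: 0}
    sigma = {source: 1.0}
    preds: Dict[str, List[str]] = {source: []}
    order: List[str] = []
    queue = deque([source])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return order, preds, sigma, dist


def centralities(net: InteractionNetwork) -> CentralityTable:
    """Per-node degree, normalized betweenness, and closeness.

    Raises
    ------
    ValueError
        If the network has no nodes.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("empty network")
    adj: Dict[str, List[str]] = {n: sorted(net.neighbors(n)) for n in nodes}
    n = len(nodes)

    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for s in nodes:
        order, preds, sigma, dist = _single_source_shortest_paths(adj, s)
        # Brandes dependency accumulation
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                betweenness[w] += delta[w]
        reachable = len(dist) - 1
        total = sum(dist.values())
        closeness[s] = reachable / total if reachable else 0.0

    # each unordered pair was counted twice; normalize to [0, 1]
    pair_count = (n - 1) * (n - 2) / 2.0
    for v in nodes:
        betweenness[v] = betweenness[v] / 2.0 / pair_count if pair_count else 0.0

    return pd.DataFrame(
        {
            "degree": [net.graph.degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def screen_key_targets(
    table: CentralityTable, degree_fold: float = 2.0
) -> ScreeningResult:
    """Median-threshold triple screen over all nodes of the table.

    Cutoffs: ``degree_fold`` x median degree, median betweenness, median
    closeness; selection is strict ``>`` on all three. Medians of
    even-length lists are the mean of the two middle values.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    degree_cutoff = degree_fold * float(np.median(table["degree"]))
    betweenness_cutoff = float(np.median(table["betweenness"]))
    closeness_cutoff = float(np.median(table["closeness"]))
    mask = (
        (table["degree"] > degree_cutoff)
        & (table["betweenness"] > betweenness_cutoff)
        & (table["closeness"] > closeness_cutoff)
    )
    return ScreeningResult(
        degree_cutoff=degree_cutoff,
        betweenness_cutoff=betweenness_cutoff,
        closeness_cutoff=closeness_cutoff,
        key_targets=set(table.index[mask]),
    )


def degree_betweenness_profile(table: CentralityTable) -> pd.DataFrame:
    """(node, degree, betweenness) rows ordered by descending degree.

    Ties are broken lexicographically by node name so the output is
    deterministic.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    ordered = table.reset_index().sort_values(
        by=["degree", "gene"], ascending=[False, True], kind="mergesort"
    )
    return ordered[["gene", "degree", "betweenness"]].reset_index(drop=True)
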