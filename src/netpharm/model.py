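"""Domain types shared by all pipeline stages.

Gene identifiers are plain uppercase strings (HGNC-style symbols); the
light-weight containers here enforce the invariants the rest of the
pipeline relies on (deduplication, score bounds, unordered edge identity,
exactly one reference-ligand row per docking target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "normalize_symbol",
    "CompoundTargetMap",
    "DiseaseTargetSet",
    "PPIEdge",
    "InteractionNetwork",
    "GeneSet",
    "GeneSetCollection",
    "DockingTable",
    "Role",
]


class Role:
    """Node role labels used in interaction networks."""

    COMPOUND_TARGET = "compound_target"
    DISEASE_TARGET = "disease_target"
    COMMON = "common"
    NEIGHBOR = "neighbor"
    COMPOUND = "compound"

    ALL = frozenset(
        {COMPOUND_TARGET, DISEASE_TARGET, COMMON, NEIGHBOR, COMPOUND}
    )


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: trim surrounding whitespace and uppercase.

    Raises
    ------
    ValueError
        If the symbol is empty after trimming or contains internal
        whitespace.
    """
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in s):
        raise ValueError(f"gene symbol contains internal whitespace: {s!r}")
    return s


@dataclass
class CompoundTargetMap:
    """compound id -> set of gene symbols, with per-association provenance."""

    entries: Dict[str, Set[str]] = field(default_factory=dict)
    provenance: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)

    def add(self, compound: str, gene: str, source: Optional[str] = None) -> None:
        gene = normalize_symbol(gene)
        compound = str(compound).strip()
        if not compound:
            raise ValueError("empty compound id")
        self.entries.setdefault(compound, set()).add(gene)
        if source is not None:
            self.provenance.setdefault((compound, gene), set()).add(source)

    def all_targets(self) -> Set[str]:
        """Union of every compound's target set."""
        out: Set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return out

    def compounds(self) -> Set[str]:
        return set(self.entries)

    def validate(self) -> None:
        for (compound, gene) in self.provenance:
            if gene not in self.entries.get(compound, set()):
                raise ValueError(
                    f"provenance references unknown association ({compound}, {gene})"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DiseaseTargetSet:
    """Deduplicated disease-associated gene set with provenance tags."""

    genes: Set[str] = field(default_factory=set)
    provenance: Dict[str, Set[str]] = field(default_factory=dict)

    def add(self, gene: str, source: Optional[str] = None) -> None:
        gene = normalize_symbol(gene)
        self.genes.add(gene)
        if source is not None:
            self.provenance.setdefault(gene, set()).add(source)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class PPIEdge:
    """Undirected scored interaction between two distinct genes.

    Endpoints are stored in sorted order so that (a, b) and (b, a) compare
    and hash identically.
    """

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        a = normalize_symbol(self.a)
        b = normalize_symbol(self.b)
        if a == b:
            raise ValueError(f"self-loop rejected: {a}")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        score = float(self.score)
        if not (0.0 <= score <= 1.0) or math.isnan(score):
            raise ValueError(f"confidence score outside [0, 1]: {score}")
        object.__setattr__(self, "score", score)

    @property
    def key(self) -> Tuple[str, str]:
        return (self.a, self.b)


class InteractionNetwork:
    """Undirected simple gene graph with role-labelled nodes and scored edges.

    Thin wrapper around :class:`networkx.Graph`; node attribute ``role``
    and edge attribute ``score`` are the canonical payload.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, gene: str, role: str) -> None:
        if role not in Role.ALL:
            raise ValueError(f"unknown role: {role}")
        self.graph.add_node(gene, role=role)

    def add_edge(self, edge: PPIEdge) -> None:
        if edge.a not in self.graph or edge.b not in self.graph:
            raise ValueError(f"edge endpoint not a node: {edge.key}")
        existing = self.graph.get_edge_data(edge.a, edge.b)
        if existing is None or existing["score"] < edge.score:
            self.graph.add_edge(edge.a, edge.b, score=edge.score)

    # -- views ------------------------------------------------------------
    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def role(self, gene: str) -> str:
        return self.graph.nodes[gene]["role"]

    def roles(self) -> Dict[str, str]:
        return {n: d["role"] for n, d in self.graph.nodes(data=True)}

    def edges(self) -> Iterator[PPIEdge]:
        for a, b, d in self.graph.edges(data=True):
            yield PPIEdge(a, b, d["score"])

    def edge_set(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(tuple(sorted((a, b))) for a, b in self.graph.edges)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> Set[str]:
        return set(self.graph.neighbors(gene))

    # -- mutation ---------------------------------------------------------
    def remove_isolates(self) -> int:
        """Drop degree-0 nodes; returns how many were removed."""
        isolates = list(nx.isolates(self.graph))
        self.graph.remove_nodes_from(isolates)
        return len(isolates)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    def equals(self, other: "InteractionNetwork", score_decimals: int = 6) -> bool:
        if self.nodes != other.nodes or self.roles() != other.roles():
            return False
        if self.edge_set() != other.edge_set():
            return False
        for a, b in self.edge_set():
            s1 = round(self.graph[a][b]["score"], score_decimals)
            s2 = round(other.graph[a][b]["score"], score_decimals)
            if s1 != s2:
                return False
        return True


@dataclass
class GeneSet:
    name: str
    description: str
    members: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Named gene sets plus the background universe used for testing.

    ``universe_mode='annotation'`` (default) sets the universe to the union
    of all member genes; an explicit background can be supplied instead.
    """

    def __init__(
        self,
        sets: Mapping[str, GeneSet],
        universe: Optional[Iterable[str]] = None,
    ) -> None:
        self.sets: Dict[str, GeneSet] = dict(sets)
        annotation = set()
        for gs in self.sets.values():
            annotation |= gs.members
        if universe is None:
            self.universe: Set[str] = annotation
        else:
            self.universe = {normalize_symbol(g) for g in universe}
            missing = annotation - self.universe
            if missing:
                raise ValueError(
                    f"{len(missing)} annotated genes missing from the supplied "
                    f"universe (e.g. {sorted(missing)[:3]})"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list:
        return list(self.sets)


#: Sentinel for absent docking scores ("no proper docking result").
MISSING = None


class DockingTable:
    """Docking scores per (molecule, target) with one reference-ligand row
    per target.

    A missing score is stored as ``None`` and is distinct from 0.
    """

    def __init__(
        self,
        records: Mapping[Tuple[str, str], Optional[float]],
        ligands: Mapping[str, str],
    ) -> None:
        self.records: Dict[Tuple[str, str], Optional[float]] = dict(records)
        self.ligands: Dict[str, str] = dict(ligands)
        self._validate()

    def _validate(self) -> None:
        targets = {t for (_, t) in self.records}
        for target in targets:
            if target not in self.ligands:
                raise ValueError(f"target {target!r} has no ligand row")
        for target, mol in self.ligands.items():
            score = self.records.get((mol, target))
            if score is MISSING:
                raise ValueError(
                    f"ligand row for target {target!r} is absent or unscored"
                )

    def targets(self) -> list:
        return sorted({t for (_, t) in self.records})

    def molecules(self) -> list:
        return sorted({m for (m, _) in self.records})

    def compounds(self) -> list:
        """Molecules that are not ligand references."""
        ligand_mols = set(self.ligands.values())
        return [m for m in self.molecules() if m not in ligand_mols]

    def ligand_score(self, target: str) -> float:
        return float(self.records[(self.ligands[target], target)])

    def score(self, molecule: str, target: str) -> Optional[float]:
        return self.records.get((molecule, target), MISSING)
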